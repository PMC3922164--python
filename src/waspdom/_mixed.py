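"""Profiled-REML solver for small Gaussian mixed models.

The per-transcript expression model and the per-compound CHC model share the
same structure: a handful of fixed effects plus one or two crossed random
intercept terms (array and dye, or colony), each with an i.i.d. variance
component, fitted by REML.  The designs are tiny (40-160 observations) but a
simulation study fits tens of thousands of them, so the solver profiles out
the residual variance, optimises only the log variance *ratios*
gamma_i = sigma_i^2 / sigma_e^2, and evaluates the likelihood through the
Woodbury identity: with Z the stacked random-effect indicators (rank << n),
every evaluation costs one Cholesky of the q x q capacitance matrix
D^-1 + Z'Z instead of an n x n factorization.

When a ratio is driven to the lower search bound the component is
effectively zero and the model degenerates gracefully to the fit without
that term.  A noise-free response (exact linear structure) is detected up
front and handled by absorbing the random factors as fixed effects, which
recovers estimable fixed-effect contrasts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

# log-scale search box for variance ratios; exp(-12) is numerically zero
# relative to the residual variance, exp(12) is effectively "fixed effect"
_LOG_GAMMA_BOUNDS = (-12.0, 12.0)
_BOUNDARY_TOL = 1e-6

# per-design cache of rank and orthonormal-basis computations, keyed by the
# exact bytes of [X | Z]; simulation studies reuse a handful of patterns
_PATTERN_CACHE: dict = {}
_PATTERN_CACHE_MAX = 64


def _one_hot(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.shape[0], n_levels))
    Z[np.arange(codes.shape[0]), codes] = 1.0
    return Z


def _pattern_info(X: np.ndarray, Zfull: np.ndarray):
    XZ = np.hstack([X, Zfull])
    key = (XZ.shape, hash(XZ.tobytes()))
    info = _PATTERN_CACHE.get(key)
    if info is None:
        rank_x = int(np.linalg.matrix_rank(X))
        # one SVD gives both the rank and an orthonormal basis of col([X Z])
        U, s, _ = np.linalg.svd(XZ, full_matrices=False)
        tol = s.max() * max(XZ.shape) * np.finfo(float).eps if s.size else 0.0
        keep = s > tol
        info = {"rank_x": rank_x, "rank_xz": int(keep.sum()), "Q": U[:, keep]}
        if len(_PATTERN_CACHE) >= _PATTERN_CACHE_MAX:
            _PATTERN_CACHE.clear()
        _PATTERN_CACHE[key] = info
    return info


@dataclass
class MixedFit:
    """Result of a REML mixed-model fit."""

    beta: np.ndarray
    cov_beta: np.ndarray          # covariance of beta at the REML estimates
    sigma2_resid: float
    varcomps: dict[str, float]    # variance component per random factor
    n_obs: int
    rank_x: int
    df_resid: float               # containment-style denominator df
    converged: bool
    degenerate: bool              # noise-free or otherwise singular response
    coef_names: list[str] = field(default_factory=list)

    def contrast(self, L: np.ndarray) -> tuple[float, float]:
        """Point estimate and standard error of the scalar contrast L @ beta."""
        L = np.asarray(L, dtype=float)
        est = float(L @ self.beta)
        var = float(L @ self.cov_beta @ L)
        return est, float(np.sqrt(max(var, 0.0)))

    def wald_f(self, L: np.ndarray) -> tuple[float, float]:
        """Wald F statistic and p-value for the multi-row hypothesis L beta = 0.

        The denominator degrees of freedom are the containment residual df
        (observations minus the rank of the combined fixed + random design).
        """
        L = np.atleast_2d(np.asarray(L, dtype=float))
        q = L.shape[0]
        if self.degenerate or self.df_resid <= 0:
            return np.nan, np.nan
        lb = L @ self.beta
        M = L @ self.cov_beta @ L.T
        try:
            sol = linalg.solve(M, lb, assume_a="pos")
        except linalg.LinAlgError:
            return np.nan, np.nan
        f = float(lb @ sol) / q
        p = float(stats.f.sf(f, q, self.df_resid))
        return f, p

    def contrast_t(self, L: np.ndarray) -> tuple[float, float, float]:
        """Estimate, SE and two-sided p for a scalar contrast (t reference)."""
        est, se = self.contrast(L)
        if self.degenerate or se == 0.0 or self.df_resid <= 0:
            return est, se, np.nan
        t = est / se
        return est, se, float(2.0 * stats.t.sf(abs(t), self.df_resid))


def fit_mixed(
    y: np.ndarray,
    X: np.ndarray,
    random_factors: dict[str, np.ndarray],
    coef_names: list[str] | None = None,
) -> MixedFit:
    """Fit y = X beta + sum_i Z_i u_i + e by REML.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) full-rank fixed-effect design.
    random_factors : mapping from factor name to an (n,) code vector; each
        factor contributes a random intercept per level with its own
        variance component.  Factors with a single observed level are
        dropped (they carry no information).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have incompatible shapes")
    names = list(coef_names) if coef_names is not None else [f"b{i}" for i in range(p)]

    Zs = []
    factor_names = []
    sizes = []
    for name, codes in random_factors.items():
        codes = np.asarray(codes)
        levels = np.unique(codes)
        if levels.shape[0] < 2:
            continue
        lut = {lv: i for i, lv in enumerate(levels)}
        Zs.append(_one_hot(np.array([lut[c] for c in codes]), levels.shape[0]))
        factor_names.append(name)
        sizes.append(levels.shape[0])

    Zfull = np.hstack(Zs) if Zs else np.zeros((n, 0))
    info = _pattern_info(X, Zfull)
    rank_x, rank_xz, Q = info["rank_x"], info["rank_xz"], info["Q"]
    df_resid = n - rank_xz

    # --- degenerate (noise-free) detection: absorb random factors as fixed
    resid_full = y - Q @ (Q.T @ y)
    scale = max(float(y @ y), 1.0)
    if float(resid_full @ resid_full) <= 1e-16 * scale or df_resid <= 0:
        beta = _absorbed_beta(y, X, Zfull)
        return MixedFit(
            beta=beta,
            cov_beta=np.zeros((p, p)),
            sigma2_resid=0.0,
            varcomps={nm: 0.0 for nm in factor_names},
            n_obs=n,
            rank_x=rank_x,
            df_resid=max(df_resid, 0),
            converged=True,
            degenerate=True,
            coef_names=names,
        )

    # --- precomputed cross-products for the Woodbury likelihood
    q_all = Zfull.shape[1]
    ZtZ = Zfull.T @ Zfull
    ZtX = Zfull.T @ X
    Zty = Zfull.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    ZtXy = np.column_stack([ZtX, Zty])
    block = np.repeat(np.arange(len(sizes)), sizes) if sizes else np.zeros(0, int)

    state: dict = {}
    sizes_arr = np.asarray(sizes)
    starts = np.concatenate([[0], np.cumsum(sizes_arr)]).astype(int) if sizes else np.zeros(1, int)
    bad = (1e12, np.zeros(max(len(sizes), 1)))

    def neg2_reml(log_g: np.ndarray):
        """REML criterion and its analytic gradient wrt the log ratios.

        Uses V^-1 = I - Z W^-1 Z' with W = D^-1 + Z'Z; the score terms are
        the standard REML trace/quadratic forms assembled from the same
        Woodbury cross-products as the criterion itself.
        """
        log_g = np.asarray(log_g, dtype=float)
        if q_all:
            gam = np.exp(log_g)
            dinv = (1.0 / gam)[block]
            W = ZtZ + np.diag(dinv)
            try:
                cW = np.linalg.cholesky(W)
            except np.linalg.LinAlgError:
                return bad
            # log|V| = log|W| + log|D|
            logdet_v = 2.0 * float(np.sum(np.log(np.diag(cW)))) + float(log_g @ sizes_arr)
            S = linalg.cho_solve((cW, True), ZtXy, check_finite=False)
            xtvx = XtX - ZtX.T @ S[:, :p]
            xtvy = Xty - ZtX.T @ S[:, p]
            ytvy = yty - float(Zty @ S[:, p])
        else:
            logdet_v = 0.0
            xtvx, xtvy, ytvy = XtX, Xty, yty
        try:
            beta = linalg.solve(xtvx, xtvy, assume_a="pos", check_finite=False)
        except linalg.LinAlgError:
            return bad
        ypy = ytvy - float(xtvy @ beta)
        if ypy <= 0:
            return bad
        s2 = ypy / (n - rank_x)
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return bad
        val = (n - rank_x) * np.log(s2) + logdet_v + logdet_x
        state.update(beta=beta, s2=s2, xtvx=xtvx)
        if not q_all:
            return float(val), np.zeros(0)

        # gradient: d/dgamma_j of each term, then chain rule to log scale
        WiZtZ = linalg.cho_solve((cW, True), ZtZ, check_finite=False)
        ZVZ = ZtZ - ZtZ @ WiZtZ                      # Z' V^-1 Z
        XVZ = ZtX.T - (ZtX.T @ WiZtZ)                # X' V^-1 Z  (p x q)
        ZVy = Zty - ZtZ @ S[:, p]                    # Z' V^-1 y
        ZPy = ZVy - XVZ.T @ beta                     # Z' P y
        grad = np.empty(len(sizes))
        for j in range(len(sizes)):
            sl = slice(starts[j], starts[j + 1])
            tr_v = float(np.trace(ZVZ[sl, sl]))
            Cj = XVZ[:, sl]
            sol = linalg.solve(xtvx, Cj, assume_a="pos", check_finite=False)
            tr_x = float(np.sum(sol * Cj))
            quad = float(ZPy[sl] @ ZPy[sl])
            d_gamma = tr_v - tr_x - (n - rank_x) * quad / ypy
            grad[j] = gam[j] * d_gamma
        return float(val), grad

    converged = True
    if q_all:
        x0 = np.full(len(sizes), np.log(0.1))
        res = optimize.minimize(
            neg2_reml, x0, method="L-BFGS-B", jac=True,
            bounds=[_LOG_GAMMA_BOUNDS] * len(sizes),
        )
        if not res.success:
            res2 = optimize.minimize(
                neg2_reml, np.full(len(sizes), _LOG_GAMMA_BOUNDS[0]),
                method="L-BFGS-B", jac=True,
                bounds=[_LOG_GAMMA_BOUNDS] * len(sizes),
            )
            if res2.fun < res.fun:
                res = res2
            converged = res.success or np.isfinite(res.fun)
        neg2_reml(res.x)  # refresh state at the optimum
        log_g = np.asarray(res.x)
    else:
        neg2_reml(np.zeros(0))
        log_g = np.zeros(0)

    beta = state["beta"]
    s2 = state["s2"]
    cov_beta = s2 * linalg.inv(state["xtvx"])
    varcomps = {}
    for nm, lg in zip(factor_names, log_g):
        at_floor = lg <= _LOG_GAMMA_BOUNDS[0] + _BOUNDARY_TOL
        varcomps[nm] = 0.0 if at_floor else float(np.exp(lg) * s2)

    return MixedFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2_resid=float(s2),
        varcomps=varcomps,
        n_obs=n,
        rank_x=rank_x,
        df_resid=df_resid,
        converged=bool(converged),
        degenerate=False,
        coef_names=names,
    )


def _absorbed_beta(y: np.ndarray, X: np.ndarray, Zfull: np.ndarray) -> np.ndarray:
    """Fixed-effect solution with the random factors absorbed as fixed.

    Projects the random-factor column space out of both y and X and solves the
    reduced least-squares problem; estimable contrasts of beta (e.g. group
    differences in a connected loop design) are recovered exactly for an
    exactly linear response.  Non-estimable directions (the intercept once a
    factor absorbs it) take their minimum-norm values.
    """
    if Zfull.shape[1] == 0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta
    Q, _ = np.linalg.qr(Zfull)
    My = y - Q @ (Q.T @ y)
    MX = X - Q @ (Q.T @ X)
    beta, *_ = np.linalg.lstsq(MX, My, rcond=None)
    return beta
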