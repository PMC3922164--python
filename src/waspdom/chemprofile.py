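"""Cuticular-hydrocarbon chemometrics.

Absolute compound concentrations are log10-transformed and analysed with,
per compound, a mixed-model ANOVA (group fixed, colony random — the same
REML machinery as the expression analysis), Bonferroni-adjusted pairwise
group comparisons, a linear discriminant analysis of whole profiles, single-
linkage hierarchical clustering of the significantly different compounds on
their group-mean vectors, and a row-centered fold-difference matrix for
heatmap display.

Below-detection values arrive as exact zeros; the default policy replaces a
zero with half the smallest positive concentration of that compound before
the log, which keeps censored wasps in the model at a conservative level.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from waspdom._mixed import fit_mixed
from waspdom.synthdata import GROUPS

log = logging.getLogger(__name__)

PAIRS = tuple(itertools.combinations(GROUPS, 2))


def log_concentrations(table: pd.DataFrame, zero_policy="offset_halfmin") -> pd.DataFrame:
    """log10-transform concentrations with an explicit zero policy.

    ``zero_policy`` is ``"drop"``, ``"offset_halfmin"`` (replace zeros with
    half the compound's smallest positive value) or ``("offset", c)`` for a
    fixed additive constant applied to zeros only.  The applied policy is
    recorded in ``attrs["zero_policy"]``.
    """
    if (table["concentration"] < 0).any():
        raise ValueError("negative concentration")
    out = table.copy()
    zeros = out["concentration"] == 0
    if zero_policy == "drop":
        out = out.loc[~zeros].copy()
    elif zero_policy == "offset_halfmin":
        for c, sub in out.groupby("compound"):
            pos = sub.loc[sub["concentration"] > 0, "concentration"]
            if pos.empty:
                raise ValueError(f"compound {c!r} has no positive values")
            fill = float(pos.min()) / 2.0
            m = (out["compound"] == c) & zeros
            out.loc[m, "concentration"] = fill
    elif isinstance(zero_policy, tuple) and zero_policy[0] == "offset":
        out.loc[zeros, "concentration"] = float(zero_policy[1])
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    out["log10"] = np.log10(out["concentration"].to_numpy())
    out.attrs["zero_policy"] = str(zero_policy)
    return out


def _fit_compound(sub: pd.DataFrame):
    """Mixed fit for one compound: group fixed, colony random."""
    levels = [g for g in GROUPS if (sub["group"] == g).any()]
    n = len(sub)
    cols = [np.ones(n)]
    idx = {levels[0]: None}
    for g in levels[1:]:
        idx[g] = len(cols)
        cols.append((sub["group"] == g).to_numpy(float))
    X = np.column_stack(cols)
    fit = fit_mixed(sub["log10"].to_numpy(), X, {"colony": sub["colony"].to_numpy()})
    return fit, levels, idx


def per_compound_anova(table: pd.DataFrame) -> pd.DataFrame:
    """Omnibus group test per compound.

    Requires a ``log10`` column (run :func:`log_concentrations` first).
    Compounds that are constant (or otherwise degenerate) are flagged with
    status ``"degenerate"`` and an undefined p.
    """
    rows = []
    for compound, sub in table.groupby("compound", sort=True):
        groups = sub["group"].unique()
        if len(groups) < 2 or sub.groupby("group")["log10"].size().min() < 2:
            rows.append((compound, np.nan, np.nan, "unfit"))
            continue
        if np.allclose(sub["log10"], sub["log10"].iloc[0]):
            rows.append((compound, np.nan, np.nan, "degenerate"))
            continue
        fit, levels, idx = _fit_compound(sub)
        if fit.degenerate:
            rows.append((compound, np.nan, np.nan, "degenerate"))
            continue
        L = np.zeros((len(levels) - 1, fit.beta.shape[0]))
        for i, g in enumerate(levels[1:]):
            L[i, idx[g]] = 1.0
        F, p = fit.wald_f(L)
        rows.append((compound, F, p, "ok"))
    return pd.DataFrame(rows, columns=["compound", "F", "p", "status"])


def bonferroni_pairwise(table: pd.DataFrame, compound: str,
                        family_size: int | None = None) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise group comparisons for one compound.

    The family is the 10 group pairs within the compound by default; raw
    two-sided mixed-model contrast p-values are multiplied by the family
    size and capped at 1.
    """
    sub = table[table["compound"] == compound]
    if sub.empty:
        raise KeyError(f"compound {compound!r} not in table")
    fit, levels, idx = _fit_compound(sub)
    rows = []
    observed_pairs = [p for p in PAIRS if p[0] in levels and p[1] in levels]
    m = family_size if family_size is not None else len(observed_pairs)
    for g1, g2 in PAIRS:
        if (g1, g2) not in observed_pairs:
            rows.append((g1, g2, np.nan, np.nan, np.nan))
            continue
        L = np.zeros(fit.beta.shape[0])
        if idx[g1] is not None:
            L[idx[g1]] = 1.0
        if idx[g2] is not None:
            L[idx[g2]] -= 1.0
        est, se, p = fit.contrast_t(L)
        rows.append((g1, g2, est, p, min(1.0, m * p) if np.isfinite(p) else np.nan))
    return pd.DataFrame(rows, columns=["group1", "group2", "estimate", "p_raw", "p_adj"])


def profile_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Wasp x compound matrix of log10 concentrations."""
    return table.pivot_table(index="wasp", columns="compound", values="log10")


def lda_profiles(table: pd.DataFrame, shrinkage: bool | float = False):
    """Linear discriminant analysis of whole CHC profiles.

    Returns ``(scores, lda, confusion)``: per-wasp scores on the (up to
    groups-1) discriminant axes ordered by explained between-group variance,
    the fitted estimator, and the resubstitution classification table.  A
    singular within-group covariance (more compounds than wasps) raises with
    advice to enable shrinkage; ``shrinkage=True`` uses the Ledoit-Wolf
    amount, a float in (0, 1] fixes it.
    """
    mat = profile_matrix(table)
    labels = table.drop_duplicates("wasp").set_index("wasp")["group"].loc[mat.index]
    if shrinkage:
        amount = "auto" if shrinkage is True else float(shrinkage)
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=amount)
    else:
        if mat.shape[0] <= mat.shape[1]:
            raise ValueError(
                "fewer wasps than compounds: the within-group covariance is "
                "singular; call lda_profiles(..., shrinkage=True)"
            )
        lda = LinearDiscriminantAnalysis(solver="eigen")
    X = mat.to_numpy(float)
    y = labels.to_numpy()
    lda.fit(X, y)
    scores = pd.DataFrame(
        lda.transform(X),
        index=mat.index,
        columns=[f"LD{i + 1}" for i in range(lda.transform(X).shape[1])],
    )
    scores.insert(0, "group", y)
    pred = lda.predict(X)
    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(pred, name="predicted")
    )
    return scores, lda, confusion


def group_mean_matrix(table: pd.DataFrame, compounds=None) -> pd.DataFrame:
    """Compound x group matrix of mean log10 concentrations."""
    mat = table.pivot_table(index="compound", columns="group", values="log10",
                            aggfunc="mean")
    mat = mat[[g for g in GROUPS if g in mat.columns]]
    if compounds is not None:
        mat = mat.loc[[c for c in mat.index if c in set(compounds)]]
    return mat


def cluster_compounds(mean_matrix: pd.DataFrame, method: str = "single",
                      center: bool = False):
    """Single-linkage clustering of compounds on group-mean log10 vectors.

    Distances are Euclidean.  With ``center=True`` each compound's row mean
    is subtracted first, so compounds cluster by their *pattern* across
    groups rather than by absolute abundance — the same transformation the
    fold-difference heatmap displays.  Returns the scipy linkage matrix;
    pair it with ``mean_matrix.index`` for labels.
    """
    if mean_matrix.shape[0] < 2:
        raise ValueError("need at least 2 compounds to cluster")
    X = mean_matrix.to_numpy(float)
    if center:
        X = X - X.mean(axis=1, keepdims=True)
    d = pdist(X, metric="euclidean")
    return hierarchy.linkage(d, method=method)


def heatmap_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Compound x group fold differences in log10 relative to the compound mean.

    Entry (c, g) is the group-mean log10 level minus the grand mean log10
    level of compound c over all wasps; with equal group sizes every row
    mean is zero, so 0 marks the 1:1 level of the display.
    """
    mat = group_mean_matrix(table)
    grand = table.groupby("compound")["log10"].mean()
    return mat.sub(grand, axis=0)
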