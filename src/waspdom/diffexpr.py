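"""Per-transcript mixed-model differential expression.

Each retained transcript is fitted with the ANOVA model

    log2(intensity) = group + spot + array + dye + error

where group (the five female types) and spot (the duplicate-spot index) are
fixed effects, while array and dye are random intercepts estimated by REML
(see :mod:`waspdom._mixed`).  The group term is tested with a Wald F; the
ten pairwise group contrasts are tested with Wald t statistics.  Multiple
testing is controlled with Benjamini-Hochberg FDR: the omnibus tests form
one family across transcripts, and each pairwise contrast forms its own
family across transcripts.  Significance is called at a tissue-specific FDR
cutoff (0.05 for brain, 0.01 for ovary in the study's convention; the
stricter ovary cutoff reflects its far larger differential-expression
signal).

Dye has only two levels, which makes its variance component statistically
fragile; it is estimated as random by default (``dye_as_random=False``
treats it as a fixed effect instead).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from waspdom._mixed import MixedFit, fit_mixed
from waspdom.preprocess import ExpressionTable
from waspdom.synthdata import GROUPS

log = logging.getLogger(__name__)

PAIRS = tuple(itertools.combinations(GROUPS, 2))


@dataclass
class MixedModelSpec:
    """Model specification for the per-transcript ANOVA."""

    groups: tuple = GROUPS
    dye_as_random: bool = True
    spot_fixed: bool = True


@dataclass
class TranscriptFit:
    """A fitted per-transcript model with its group-effect bookkeeping."""

    transcript: str
    fit: MixedFit
    group_levels: tuple            # groups observed, first level is baseline
    group_coef_idx: dict           # group -> column of beta (baseline absent)

    def group_effect(self, group: str) -> float:
        """Estimated effect of a group relative to the baseline level."""
        if group not in self.group_levels:
            raise KeyError(f"group {group!r} not observed for {self.transcript}")
        idx = self.group_coef_idx.get(group)
        return 0.0 if idx is None else float(self.fit.beta[idx])

    def _contrast_vector(self, g1: str, g2: str) -> np.ndarray:
        L = np.zeros(self.fit.beta.shape[0])
        for g, sign in ((g1, 1.0), (g2, -1.0)):
            idx = self.group_coef_idx.get(g)
            if idx is not None:
                L[idx] = sign
        return L


class UnfitError(RuntimeError):
    """Raised when a transcript cannot support the model."""


def _design_for(values: pd.DataFrame, spec: MixedModelSpec):
    """Build the full-rank fixed design and random-factor codes."""
    groups_present = [g for g in spec.groups if (values["group"] == g).any()]
    if len(groups_present) < 2:
        raise UnfitError("fewer than 2 groups observed")
    counts = values["group"].value_counts()
    if (counts[groups_present] < 2).any():
        raise UnfitError("a group has fewer than 2 values")

    n = len(values)
    cols = [np.ones(n)]
    names = ["intercept"]
    group_coef_idx: dict = {groups_present[0]: None}
    for g in groups_present[1:]:
        group_coef_idx[g] = len(cols)
        cols.append((values["group"] == g).to_numpy(float))
        names.append(f"group[{g}]")
    if spec.spot_fixed:
        spot_levels = sorted(values["spot"].unique())
        for s in spot_levels[1:]:
            cols.append((values["spot"] == s).to_numpy(float))
            names.append(f"spot[{s}]")
    X = np.column_stack(cols)

    random_factors = {"array": values["array"].to_numpy()}
    if spec.dye_as_random:
        random_factors["dye"] = values["channel"].to_numpy()
    else:
        dyes = sorted(values["channel"].unique())
        extra = [(values["channel"] == d).to_numpy(float) for d in dyes[1:]]
        if extra:
            X = np.column_stack([X] + extra)
            names += [f"dye[{d}]" for d in dyes[1:]]
    return X, names, random_factors, tuple(groups_present), group_coef_idx


def fit_transcript_model(values: pd.DataFrame, spec: MixedModelSpec | None = None,
                         transcript: str = "") -> TranscriptFit:
    """REML-fit the mixed ANOVA for one transcript.

    ``values`` needs columns group, spot, array, channel, value.  Raises
    :class:`UnfitError` when the data cannot support the model (fewer than
    two groups, or a group with a single value).
    """
    spec = spec or MixedModelSpec()
    X, names, random_factors, levels, coef_idx = _design_for(values, spec)
    fit = fit_mixed(values["value"].to_numpy(), X, random_factors, coef_names=names)
    if not fit.converged:
        raise UnfitError("REML did not converge")
    return TranscriptFit(
        transcript=transcript or str(values.get("transcript", pd.Series([""])).iloc[0]),
        fit=fit,
        group_levels=levels,
        group_coef_idx=coef_idx,
    )


def omnibus_test(tfit: TranscriptFit) -> tuple[float, float]:
    """Wald F and p-value for the group term."""
    rows = []
    for g in tfit.group_levels[1:]:
        L = np.zeros(tfit.fit.beta.shape[0])
        L[tfit.group_coef_idx[g]] = 1.0
        rows.append(L)
    return tfit.fit.wald_f(np.vstack(rows))


def pairwise_contrasts(tfit: TranscriptFit) -> pd.DataFrame:
    """Estimates, SEs and p-values for all observed group pairs.

    Estimates are antisymmetric under pair reversal by construction; pairs
    with an unobserved group get NaN rows.
    """
    rows = []
    for g1, g2 in PAIRS:
        if g1 not in tfit.group_levels or g2 not in tfit.group_levels:
            rows.append((g1, g2, np.nan, np.nan, np.nan))
            continue
        est, se, p = tfit.fit.contrast_t(tfit._contrast_vector(g1, g2))
        rows.append((g1, g2, est, se, p))
    return pd.DataFrame(rows, columns=["group1", "group2", "estimate", "se", "p"])


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q(i) = min_{j >= i} m * p(j) / j over the ordered p-values, capped at 1.
    NaN entries are passed through and do not count toward the family size.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.shape[0]
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    qv = np.empty(m)
    qv[order] = q
    out[ok] = qv
    return out


@dataclass
class DEResult:
    """Omnibus and pairwise differential-expression results for one tissue."""

    omnibus: pd.DataFrame          # transcript, F, p, q, significant, status
    contrasts: pd.DataFrame | None # transcript, group1, group2, estimate, se, p, q, significant
    alpha: float
    tissue: str = ""

    def significant_transcripts(self) -> set[str]:
        m = self.omnibus["significant"]
        return set(self.omnibus.loc[m, "transcript"])

    def contrast_set(self, g1: str, g2: str) -> set[str]:
        if self.contrasts is None:
            raise ValueError("contrasts were not computed")
        c = self.contrasts
        m = (
            (((c["group1"] == g1) & (c["group2"] == g2))
             | ((c["group1"] == g2) & (c["group2"] == g1)))
            & c["significant"]
        )
        return set(c.loc[m, "transcript"])


def run_de(expr: ExpressionTable, alpha: float = 0.05, tissue: str = "brain",
           spec: MixedModelSpec | None = None, contrasts: bool = True) -> DEResult:
    """Fit every transcript, FDR-adjust, and call significance at ``alpha``.

    Transcripts whose fit fails or degenerates are kept in the output with a
    status flag and NaN statistics; they are excluded from the FDR families.
    """
    spec = spec or MixedModelSpec()
    data = expr.data.merge(
        expr.samples[["sample", "group"]], on="sample", how="left", validate="m:1"
    )
    omni_rows = []
    contrast_rows = []
    for transcript, values in data.groupby("transcript", sort=True):
        try:
            tfit = fit_transcript_model(values, spec, transcript=transcript)
        except UnfitError as e:
            log.warning("transcript %s unfit: %s", transcript, e)
            omni_rows.append((transcript, np.nan, np.nan, "unfit"))
            continue
        if tfit.fit.degenerate:
            omni_rows.append((transcript, np.nan, np.nan, "degenerate"))
            continue
        F, p = omnibus_test(tfit)
        omni_rows.append((transcript, F, p, "ok"))
        if contrasts:
            cdf = pairwise_contrasts(tfit)
            cdf.insert(0, "transcript", transcript)
            contrast_rows.append(cdf)

    omnibus = pd.DataFrame(omni_rows, columns=["transcript", "F", "p", "status"])
    omnibus["q"] = fdr_adjust(omnibus["p"])
    omnibus["significant"] = omnibus["q"] < alpha

    contrasts_df = None
    if contrasts and contrast_rows:
        contrasts_df = pd.concat(contrast_rows, ignore_index=True)
        contrasts_df["q"] = np.nan
        for g1, g2 in PAIRS:
            m = (contrasts_df["group1"] == g1) & (contrasts_df["group2"] == g2)
            contrasts_df.loc[m, "q"] = fdr_adjust(contrasts_df.loc[m, "p"])
        contrasts_df["significant"] = contrasts_df["q"] < alpha

    return DEResult(omnibus=omnibus, contrasts=contrasts_df, alpha=alpha, tissue=tissue)
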