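"""Raw spot intensities -> normalized expression values.

The pipeline order is fixed: background filter -> log2 transform -> per-array
lowess normalization -> missingness filter.  The stages are:

* ``filter_background``: drop flagged spots, then censor any channel whose
  foreground intensity falls below the background threshold (default 175,
  the study's median background level; boundary values are kept).  The two
  channels of a spot are treated independently: a spot losing one channel
  keeps the other, because the downstream mixed model tolerates unbalanced
  channels.
* ``log_transform``: melt to one row per surviving spot-channel value, attach
  the hybridised sample from the loop design, and take log2.
* ``lowess_normalize``: per array, regress M = log2(Cy5) - log2(Cy3) on
  A = (log2(Cy5) + log2(Cy3)) / 2 with a locally weighted fit and subtract
  half the fitted trend from each channel, which removes intensity-dependent
  dye bias while preserving every within-array A value exactly.
* ``filter_missingness``: drop transcripts absent (no unflagged surviving
  value) from strictly more than a fraction of the arrays (default 25%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

DEFAULT_BG_THRESHOLD = 175.0
DEFAULT_MAX_MISSING = 0.25
DEFAULT_SPAN = 0.4


class PreprocessError(ValueError):
    pass


@dataclass
class ExpressionTable:
    """Long-format normalized expression values with sample metadata.

    ``data`` has one row per (transcript, spot, array, channel) with the
    hybridised sample id and the (log2) value; ``samples`` is the sample
    sheet restricted to wasps present in the data.
    """

    data: pd.DataFrame
    samples: pd.DataFrame

    @property
    def n_arrays(self) -> int:
        return self.data["array"].nunique()

    def transcripts(self) -> np.ndarray:
        return self.data["transcript"].unique()


def filter_background(spots: pd.DataFrame, threshold: float | None = DEFAULT_BG_THRESHOLD,
                      from_data: bool = False) -> pd.DataFrame:
    """Remove flagged spots and censor sub-background channel intensities.

    A channel value survives iff fg >= threshold (the boundary is kept).
    With ``from_data=True`` the threshold is recomputed as the median of all
    background intensities in the table.
    """
    if from_data:
        threshold = float(
            np.median(np.concatenate([spots["bg_cy3"].to_numpy(), spots["bg_cy5"].to_numpy()]))
        )
    if threshold is None or threshold <= 0:
        raise PreprocessError(f"background threshold must be > 0, got {threshold}")

    out = spots.loc[spots["flag"] == 0].copy()
    n_flagged = len(spots) - len(out)
    n_censored = 0
    for c in ("fg_cy3", "fg_cy5"):
        low = out[c] < threshold
        n_censored += int(low.sum())
        out.loc[low, c] = np.nan
    log.info(
        "background filter (threshold=%.6g): dropped %d flagged spot(s), "
        "censored %d channel value(s)", threshold, n_flagged, n_censored,
    )
    if out[["fg_cy3", "fg_cy5"]].isna().all().all():
        warnings.warn("background filter removed every intensity value", stacklevel=2)
    out.attrs["bg_threshold"] = threshold
    out.attrs["n_flagged"] = n_flagged
    out.attrs["n_censored"] = n_censored
    return out


def log_transform(spots: pd.DataFrame, design: pd.DataFrame,
                  samples: pd.DataFrame, base: float = 2.0) -> ExpressionTable:
    """Melt the two-channel spot table to long format and take logs.

    Non-positive intensities must have been filtered already and raise.
    """
    frames = []
    for ch, col in (("Cy3", "fg_cy3"), ("Cy5", "fg_cy5")):
        sub = spots[["array", "spot", "transcript", col]].rename(columns={col: "fg"})
        sub = sub.dropna(subset=["fg"])
        sub["channel"] = ch
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)
    if (long["fg"] <= 0).any():
        raise PreprocessError("non-positive intensity: run filter_background first")
    long["value"] = np.log(long["fg"].to_numpy()) / np.log(base)
    long = long.merge(design, on=["array", "channel"], how="left", validate="m:1")
    if long["sample"].isna().any():
        missing = long.loc[long["sample"].isna(), "array"].unique()
        raise PreprocessError(f"design has no sample for array/channel on {list(missing)[:5]}")
    long = long[["transcript", "spot", "array", "channel", "sample", "value"]]
    keep = samples[samples["sample"].isin(long["sample"].unique())].reset_index(drop=True)
    return ExpressionTable(data=long.reset_index(drop=True), samples=keep)


def lowess_normalize(expr: ExpressionTable, span: float = DEFAULT_SPAN) -> ExpressionTable:
    """Per-array intensity-dependent (MA) loess normalization.

    The fitted M-on-A trend is split symmetrically: Cy5 values lose half the
    local trend, Cy3 values gain half, so per-spot A is unchanged.  Spots
    with a single surviving channel are corrected with the trend evaluated at
    their own log intensity (the best available A proxy).
    """
    df = expr.data.copy()
    out_values = df["value"].to_numpy().copy()
    for array, sub in df.groupby("array", sort=False):
        wide = sub.pivot_table(index="spot", columns="channel", values="value", aggfunc="mean")
        for ch in ("Cy3", "Cy5"):
            if ch not in wide.columns or wide[ch].notna().sum() == 0:
                raise PreprocessError(f"array {array!r} has no surviving {ch} values")
        both = wide.dropna(subset=["Cy3", "Cy5"])
        if len(both) < 10:
            raise PreprocessError(f"array {array!r} has too few two-channel spots to normalize")
        M = (both["Cy5"] - both["Cy3"]).to_numpy()
        A = ((both["Cy5"] + both["Cy3"]) / 2.0).to_numpy()
        fit = sm.nonparametric.lowess(M, A, frac=span, return_sorted=True)
        grid_a, grid_m = fit[:, 0], fit[:, 1]

        # location polish: the loess fit is not mean-unbiased, so absorb the
        # leftover constant into the correction and zero the mean M exactly
        resid_mean = float(np.mean(M - np.interp(A, grid_a, grid_m)))

        idx = sub.index.to_numpy()
        spot_a = sub["spot"].map(both["Cy5"].add(both["Cy3"]).div(2.0)).to_numpy()
        own = sub["value"].to_numpy()
        a_eval = np.where(np.isnan(spot_a), own, spot_a)
        m_hat = np.interp(a_eval, grid_a, grid_m) + resid_mean
        signed = np.where(sub["channel"].to_numpy() == "Cy5", -0.5, +0.5)
        out_values[df.index.get_indexer(idx)] = own + signed * m_hat
    df["value"] = out_values
    return ExpressionTable(data=df, samples=expr.samples)


def filter_missingness(expr: ExpressionTable,
                       max_missing_frac: float = DEFAULT_MAX_MISSING,
                       n_arrays: int | None = None) -> ExpressionTable:
    """Drop transcripts missing from strictly more than a fraction of arrays.

    A transcript is present on an array when at least one surviving
    spot-channel value exists there.  With the study's rule (>25%), a
    transcript missing from exactly 25% of the arrays is retained.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise PreprocessError("max_missing_frac must lie in [0, 1]")
    total = n_arrays if n_arrays is not None else expr.n_arrays
    present = expr.data.groupby("transcript")["array"].nunique()
    missing_frac = 1.0 - present / total
    keep = missing_frac.index[missing_frac <= max_missing_frac]
    out = expr.data[expr.data["transcript"].isin(keep)].reset_index(drop=True)
    log.info(
        "missingness filter (> %.0f%%): retained %d / %d transcripts",
        100 * max_missing_frac, len(keep), len(missing_frac),
    )
    return ExpressionTable(data=out, samples=expr.samples)


def preprocess_pipeline(spots: pd.DataFrame, design: pd.DataFrame, samples: pd.DataFrame,
                        bg_threshold: float = DEFAULT_BG_THRESHOLD,
                        bg_from_data: bool = False,
                        span: float = DEFAULT_SPAN,
                        max_missing_frac: float = DEFAULT_MAX_MISSING) -> ExpressionTable:
    """Run the four preprocessing stages in their fixed order."""
    filtered = filter_background(spots, bg_threshold, from_data=bg_from_data)
    expr = log_transform(filtered, design, samples)
    expr = lowess_normalize(expr, span=span)
    n_arrays = design["array"].nunique()
    return filter_missingness(expr, max_missing_frac, n_arrays=n_arrays)
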