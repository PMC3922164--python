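"""Cross-species ortholog mapping and gene-list overlap enrichment.

Focal-platform transcripts are mapped to another species' genes by one-way
best BLAST hit under an e-value cutoff (1e-5 for the insect comparisons,
1e-3 for mouse in the study's convention).  The background "universe" for an
overlap test is the set of focal transcripts whose best hit passes the
cutoff and whose subject is present on the other species' array — putative
orthologs present on both test platforms.  The 2x2 table of
significant-in-both / focal-only / other-only / neither over that universe
is tested against the hypergeometric null with a two-tailed Fisher exact
test under the minimum-likelihood rule (the convention of mainstream
statistical software): p is the sum of hypergeometric point probabilities
not exceeding the observed table's.

Point probabilities are compared and summed in exact integer arithmetic
(binomial-coefficient numerators over a common denominator), so ties are
resolved exactly and the returned p is correct to double-precision rounding
for any table size used here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_EVALUE_CUTOFF = 1e-5


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 overlap counts over a shared ortholog universe."""

    n11: int  # significant in both species
    n10: int  # significant in the focal species only
    n01: int  # significant in the other species only
    n00: int  # significant in neither

    def __post_init__(self):
        for v in (self.n11, self.n10, self.n01, self.n00):
            if v < 0:
                raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def transposed(self) -> "ContingencyTable":
        return ContingencyTable(self.n11, self.n01, self.n10, self.n00)


def best_hits(hits: pd.DataFrame, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF) -> pd.DataFrame:
    """One-way best-hit ortholog map from a BLAST tabular hit table.

    Hits with e-value above the cutoff are discarded; among the survivors of
    each query the minimum e-value wins, ties broken by higher bit score and
    then by lexicographically smaller subject id.  Queries with no surviving
    hit are absent from the map.  Returns a frame with one row per query:
    qseqid, sseqid, evalue, bitscore.
    """
    if not evalue_cutoff > 0:
        raise ValueError("evalue_cutoff must be > 0")
    ok = hits.loc[hits["evalue"] <= evalue_cutoff,
                  ["qseqid", "sseqid", "evalue", "bitscore"]].copy()
    if ok.empty:
        return ok.reset_index(drop=True)
    ok = ok.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    return ok.drop_duplicates("qseqid", keep="first").reset_index(drop=True)


def shared_universe(ortholog_map: pd.DataFrame, focal_platform, other_platform) -> set[str]:
    """Focal transcripts on the focal array whose subject is on the other array."""
    focal_platform = set(focal_platform)
    other_platform = set(other_platform)
    m = ortholog_map[
        ortholog_map["qseqid"].isin(focal_platform)
        & ortholog_map["sseqid"].isin(other_platform)
    ]
    universe = set(m["qseqid"])
    if not universe:
        raise ValueError("shared ortholog universe is empty; overlap test undefined")
    return universe


def overlap_table(focal_sig, other_sig, universe, ortholog_map: pd.DataFrame) -> ContingencyTable:
    """Count the 2x2 overlap cells at the focal-transcript level.

    Identifiers outside the universe (or, for the other species, subjects
    not mapped from the universe) are dropped with a logged count.
    """
    focal_sig = set(focal_sig)
    other_sig = set(other_sig)
    universe = set(universe)
    sub = ortholog_map[ortholog_map["qseqid"].isin(universe)]
    subject_of = dict(zip(sub["qseqid"], sub["sseqid"]))

    dropped_focal = len(focal_sig - universe)
    mapped_subjects = set(subject_of.values())
    dropped_other = len(other_sig - mapped_subjects)
    if dropped_focal or dropped_other:
        log.info(
            "overlap_table: dropped %d focal and %d other significant id(s) "
            "outside the shared universe", dropped_focal, dropped_other,
        )

    n11 = n10 = n01 = n00 = 0
    for q in universe:
        f = q in focal_sig
        o = subject_of[q] in other_sig
        if f and o:
            n11 += 1
        elif f:
            n10 += 1
        elif o:
            n01 += 1
        else:
            n00 += 1
    return ContingencyTable(n11, n10, n01, n00)


def fisher_two_tailed(table: ContingencyTable | tuple) -> float:
    """Two-tailed Fisher exact p under the minimum-likelihood rule.

    With row margin R = n11 + n10, column margin C = n11 + n01 and total N
    fixed, the point probability of k successes is
    ``C(R, k) * C(N - R, C - k) / C(N, C)``; the two-sided p sums the point
    probabilities of every attainable table whose probability does not
    exceed the observed one.  Computed exactly in integer arithmetic.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*table)
    N = table.total
    if N < 1:
        raise ValueError("the table must contain at least one observation")
    R = table.n11 + table.n10
    C = table.n11 + table.n01
    kmin = max(0, R + C - N)
    kmax = min(R, C)
    obs = math.comb(R, table.n11) * math.comb(N - R, C - table.n11)
    acc = 0
    for k in range(kmin, kmax + 1):
        w = math.comb(R, k) * math.comb(N - R, C - k)
        if w <= obs:
            acc += w
    p = Fraction(acc, math.comb(N, C))
    return min(float(p), 1.0)


def run_overlap_analysis(comparisons: list[dict],
                         alpha: float = 0.05) -> pd.DataFrame:
    """Batch overlap testing; one row per cross-species comparison.

    Each comparison dict needs: ``name``, ``focal_sig``, ``other_sig``,
    ``blast`` (hit DataFrame), ``focal_platform``, ``other_platform`` and
    optionally ``evalue_cutoff``.  Output mirrors the published comparative
    table: the four cells, the universe size, p and a significance flag.
    """
    rows = []
    for cmp_ in comparisons:
        cutoff = cmp_.get("evalue_cutoff", DEFAULT_EVALUE_CUTOFF)
        omap = best_hits(cmp_["blast"], cutoff)
        universe = shared_universe(omap, cmp_["focal_platform"], cmp_["other_platform"])
        t = overlap_table(cmp_["focal_sig"], cmp_["other_sig"], universe, omap)
        p = fisher_two_tailed(t)
        rows.append(
            {
                "comparison": cmp_["name"],
                "sig_both": t.n11,
                "sig_focal_only": t.n10,
                "sig_other_only": t.n01,
                "sig_neither": t.n00,
                "universe": t.total,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)
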