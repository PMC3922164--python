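"""Derived gene sets and group-level summaries of the DE results.

The study's headline lists are unions of significant pairwise-contrast sets:
"dominance-associated" transcripts are the union of the dominant-vs-
subordinate contrasts within each colony phase (DF vs SF, DW vs SW), and
"caste-associated" transcripts are the union of the queen-vs-worker
contrasts (Q vs DW, Q vs SW).  Group-level structure is summarised with a
5x5 distance matrix counting significant transcripts per pairwise contrast,
hierarchical clustering of that matrix, and a PCA of the expression matrix
with per-axis metadata associations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from waspdom.diffexpr import DEResult, PAIRS
from waspdom.preprocess import ExpressionTable
from waspdom.synthdata import GROUPS, PHASE


@dataclass(frozen=True)
class GeneSet:
    """A named transcript set with the provenance that defines it."""

    name: str
    members: frozenset
    tissue: str
    alpha: float
    contrasts: tuple = ()

    def __post_init__(self):
        if not self.contrasts:
            raise ValueError("a GeneSet needs non-empty provenance (contrasts)")

    def __len__(self) -> int:
        return len(self.members)


def contrast_gene_set(de: DEResult, g1: str, g2: str, name: str | None = None) -> GeneSet:
    """Significant transcripts of one pairwise contrast, as a GeneSet."""
    return GeneSet(
        name=name or f"{de.tissue}_{g1}_vs_{g2}",
        members=frozenset(de.contrast_set(g1, g2)),
        tissue=de.tissue,
        alpha=de.alpha,
        contrasts=(f"{g1}_vs_{g2}",),
    )


def union_contrast_sets(a: GeneSet, b: GeneSet, name: str) -> GeneSet:
    """Union of two contrast sets from the same tissue and cutoff."""
    if a.tissue != b.tissue or a.alpha != b.alpha:
        raise ValueError(
            f"cannot union sets with mismatched provenance: "
            f"({a.tissue}, {a.alpha}) vs ({b.tissue}, {b.alpha})"
        )
    return GeneSet(
        name=name,
        members=a.members | b.members,
        tissue=a.tissue,
        alpha=a.alpha,
        contrasts=tuple(dict.fromkeys(a.contrasts + b.contrasts)),
    )


def venn_counts(a: GeneSet, b: GeneSet) -> tuple[int, int, int]:
    """(only in a, only in b, in both) — three disjoint counts."""
    both = a.members & b.members
    return len(a.members - both), len(b.members - both), len(both)


def dominance_set(de: DEResult, name: str | None = None) -> GeneSet:
    """Union of the within-phase dominant-vs-subordinate contrasts."""
    a = contrast_gene_set(de, "DF", "SF")
    b = contrast_gene_set(de, "DW", "SW")
    return union_contrast_sets(a, b, name or f"{de.tissue}_dominance_associated")


def caste_set(de: DEResult, name: str | None = None) -> GeneSet:
    """Union of the queen-vs-worker contrasts."""
    a = contrast_gene_set(de, "Q", "DW")
    b = contrast_gene_set(de, "Q", "SW")
    return union_contrast_sets(a, b, name or f"{de.tissue}_caste_associated")


def build_distance_matrix(de: DEResult) -> pd.DataFrame:
    """5x5 symmetric matrix of significant-transcript counts per contrast."""
    d = pd.DataFrame(0, index=list(GROUPS), columns=list(GROUPS), dtype=int)
    for g1, g2 in PAIRS:
        n = len(de.contrast_set(g1, g2))
        d.loc[g1, g2] = n
        d.loc[g2, g1] = n
    return d


def cluster_groups(dist: pd.DataFrame, method: str = "average"):
    """Hierarchical clustering of the groups from the DE-count distances.

    Returns the scipy linkage matrix; leaf order follows ``dist``'s index.
    """
    condensed = squareform(dist.to_numpy(float), checks=True)
    return hierarchy.linkage(condensed, method=method)


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Serialise a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return str(labels[node.id])
        left, right = walk(node.left), walk(node.right)
        dl = max(node.dist - node.left.dist, 0.0)
        dr = max(node.dist - node.right.dist, 0.0)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"


def first_split(Z: np.ndarray, labels) -> tuple[frozenset, frozenset]:
    """The two leaf sets separated by the final (root) merge."""
    n = len(labels)
    members = {i: frozenset([labels[i]]) for i in range(n)}
    for k, (i, j, _, _) in enumerate(Z):
        members[n + k] = members[int(i)] | members[int(j)]
    i, j = int(Z[-1, 0]), int(Z[-1, 1])
    return members[i], members[j]


def expression_matrix(expr: ExpressionTable) -> pd.DataFrame:
    """Transcript x sample matrix of mean normalized values."""
    return expr.data.pivot_table(
        index="transcript", columns="sample", values="value", aggfunc="mean"
    )


def pca_summary(expr: ExpressionTable, factors: tuple = ("group", "phase"),
                n_components: int = 5) -> pd.DataFrame:
    """PCA of the sample profiles with per-axis metadata associations.

    The expression matrix is centered per transcript but not scaled.  For
    each retained component the table reports the variance fraction and, per
    metadata factor, the R-squared of the one-way regression of the sample
    scores on that factor — i.e. how much of that axis the factor explains.
    """
    mat = expression_matrix(expr)
    meta = expr.samples.set_index("sample").loc[mat.columns].copy()
    meta["phase"] = meta["group"].map(
        lambda g: "founding" if PHASE[g] < 0 else "worker"
    )
    X = mat.to_numpy(float)
    X = np.where(np.isnan(X), np.nanmean(X, axis=1, keepdims=True), X)
    Xc = (X - X.mean(axis=1, keepdims=True)).T  # samples x transcripts
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    k = min(n_components, len(s))
    scores = U[:, :k] * s[:k]

    rows = []
    for i in range(k):
        row = {"component": i + 1, "variance_fraction": float(frac[i])}
        y = scores[:, i]
        for f in factors:
            codes = pd.get_dummies(meta[f]).to_numpy(float)
            # R^2 of projecting the scores on the factor's indicator space
            beta, *_ = np.linalg.lstsq(codes, y, rcond=None)
            fitted = codes @ beta
            ss_tot = float(((y - y.mean()) ** 2).sum())
            ss_res = float(((y - fitted) ** 2).sum())
            row[f"r2_{f}"] = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        rows.append(row)
    return pd.DataFrame(rows)


def factor_variance_fraction(summary: pd.DataFrame, factor: str) -> float:
    """Share of total expression variance a metadata factor accounts for.

    Sums variance_fraction x R^2(factor) over the retained components — the
    usual reading of "factor X accounted for N% of the overall variation".
    """
    col = f"r2_{factor}"
    if col not in summary.columns:
        raise KeyError(f"factor {factor!r} not in summary")
    return float((summary["variance_fraction"] * summary[col]).sum())
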