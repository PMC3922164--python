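"""CHC statistics: log policies, mixed ANOVA, Bonferroni, LDA, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from waspdom import chemprofile
from waspdom.chemprofile import (
    bonferroni_pairwise,
    cluster_compounds,
    group_mean_matrix,
    heatmap_matrix,
    lda_profiles,
    log_concentrations,
    per_compound_anova,
    profile_matrix,
)
from waspdom.synthdata import GROUPS, SimConfig, simulate_chc


@pytest.fixture(scope="module")
def logged(chc_sim):
    _, table, _, truth, _ = chc_sim
    return log_concentrations(table), truth


class TestLogConcentrations:
    def test_known_value_and_order(self, chc_sim):
        _, table, _, _, _ = chc_sim
        small = table.head(20).copy()
        small.loc[small.index[0], "concentration"] = 100.0
        out = log_concentrations(small)
        assert out["log10"].iloc[0] == pytest.approx(2.0)
        sorted_in = small["concentration"].iloc[1:].rank()
        sorted_out = out["log10"].iloc[1:].rank()
        pd.testing.assert_series_equal(sorted_in, sorted_out, check_names=False)

    def test_halfmin_offset_for_zeros(self):
        table = pd.DataFrame(
            {"wasp": ["w1", "w2", "w3"], "group": ["DF", "SF", "Q"],
             "colony": ["F01", "F01", "W01"], "compound": ["c"] * 3,
             "concentration": [0.0, 8.0, 2.0]}
        )
        out = log_concentrations(table, "offset_halfmin")
        assert out.loc[out["wasp"] == "w1", "log10"].iloc[0] == pytest.approx(np.log10(1.0))

    def test_drop_policy_removes_zeros(self):
        table = pd.DataFrame(
            {"wasp": ["w1", "w2"], "group": ["DF", "SF"],
             "colony": ["F01", "F01"], "compound": ["c", "c"],
             "concentration": [0.0, 8.0]}
        )
        out = log_concentrations(table, "drop")
        assert len(out) == 1

    def test_negative_rejected(self):
        table = pd.DataFrame(
            {"wasp": ["w1"], "group": ["DF"], "colony": ["F01"],
             "compound": ["c"], "concentration": [-1.0]}
        )
        with pytest.raises(ValueError, match="negative"):
            log_concentrations(table)


class TestPerCompoundAnova:
    def test_planted_compounds_recovered_exactly_at_high_power(self):
        cfg = SimConfig(chc_effect=1.2, sd_colony=0.05, sd_resid_chc=0.1,
                        below_detection_rate=0.0, seed=55)
        table, _, truth, _ = simulate_chc(cfg)
        res = per_compound_anova(log_concentrations(table))
        called = set(res.loc[res["p"] < 0.05, "compound"])
        planted = set(truth.loc[truth["is_sig"], "compound"])
        assert called == planted
        assert len(planted) == 13

    def test_constant_compound_flagged(self):
        table = pd.DataFrame([
            {"wasp": f"w{i}", "group": g, "colony": f"C{i % 4}",
             "compound": "flat", "concentration": 10.0}
            for i, g in enumerate(np.repeat(GROUPS, 4))
        ])
        res = per_compound_anova(log_concentrations(table))
        assert res.loc[0, "status"] == "degenerate"
        assert np.isnan(res.loc[0, "p"])


class TestBonferroni:
    def test_multiplication_and_cap(self, logged):
        table, _ = logged
        compound = table["compound"].iloc[0]
        res = bonferroni_pairwise(table, compound)
        ok = res.dropna(subset=["p_raw"])
        np.testing.assert_allclose(
            ok["p_adj"], np.minimum(1.0, 10 * ok["p_raw"]), atol=1e-12
        )

    def test_family_size_override(self, logged):
        table, _ = logged
        compound = table["compound"].iloc[0]
        res = bonferroni_pairwise(table, compound, family_size=3)
        ok = res.dropna(subset=["p_raw"])
        np.testing.assert_allclose(
            ok["p_adj"], np.minimum(1.0, 3 * ok["p_raw"]), atol=1e-12
        )

    def test_unknown_compound_rejected(self, logged):
        table, _ = logged
        with pytest.raises(KeyError):
            bonferroni_pairwise(table, "nope")


class TestLda:
    def test_separated_groups_perfectly_classified(self, logged):
        table, _ = logged
        shifted = table.copy()
        shifted["log10"] = shifted["log10"] + shifted["group"].map(
            {g: 10.0 * i for i, g in enumerate(GROUPS)}
        )
        scores, lda, confusion = lda_profiles(shifted)
        assert np.trace(confusion.to_numpy()) == confusion.to_numpy().sum()
        assert list(scores.columns[1:]) == [f"LD{i + 1}" for i in range(4)]

    def test_axes_ordered_by_explained_variance(self, logged):
        table, _ = logged
        _, lda, _ = lda_profiles(table)
        ev = lda.explained_variance_ratio_
        assert all(a >= b for a, b in zip(ev, ev[1:]))

    def test_two_class_matches_fisher_discriminant(self, logged):
        table, _ = logged
        keep = sorted(table["compound"].unique())[:8]  # keep n > p
        two = table[table["group"].isin(["DF", "Q"]) & table["compound"].isin(keep)]
        scores, lda, _ = lda_profiles(two)
        mat = profile_matrix(two)
        labels = two.drop_duplicates("wasp").set_index("wasp")["group"].loc[mat.index]
        X = mat.to_numpy()
        mu = {g: X[(labels == g).to_numpy()].mean(axis=0) for g in ("DF", "Q")}
        Sw = sum(
            np.cov(X[(labels == g).to_numpy()].T, bias=False)
            * ((labels == g).sum() - 1)
            for g in ("DF", "Q")
        ) / (len(labels) - 2)
        w = np.linalg.solve(Sw, mu["Q"] - mu["DF"])
        got = lda.scalings_[:, 0]
        cos = abs(w @ got) / (np.linalg.norm(w) * np.linalg.norm(got))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_scores_invariant_under_compound_reordering(self, logged):
        table, _ = logged
        scores_a, _, _ = lda_profiles(table)
        shuffled = table.sort_values("compound", ascending=False,
                                     kind="stable").reset_index(drop=True)
        scores_b, _, _ = lda_profiles(shuffled)
        for c in ("LD1", "LD2"):
            a = scores_a[c].to_numpy()
            b = scores_b.loc[scores_a.index, c].to_numpy()
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_singular_covariance_advises_shrinkage(self, logged):
        table, _ = logged
        few = table[table["wasp"].isin(table["wasp"].unique()[:15])]
        with pytest.raises(ValueError, match="shrinkage"):
            lda_profiles(few)
        scores, _, _ = lda_profiles(few, shrinkage=True)
        assert len(scores) == 15


def _brute_force_single_linkage(points):
    """Repeated-minimum single-linkage agglomeration; returns merge order."""
    clusters = {i: {i} for i in range(len(points))}
    d = {
        (i, j): float(np.linalg.norm(points[i] - points[j]))
        for i in range(len(points)) for j in range(i + 1, len(points))
    }
    merges = []
    nxt = len(points)
    while len(clusters) > 1:
        best, bd = None, np.inf
        keys = sorted(clusters)
        for ai, a in enumerate(keys):
            for b in keys[ai + 1:]:
                dist = min(
                    d[(min(x, y), max(x, y))]
                    for x in clusters[a] for y in clusters[b]
                )
                if dist < bd - 1e-12:
                    best, bd = (a, b), dist
        a, b = best
        merges.append((bd, frozenset(clusters[a] | clusters[b])))
        clusters[nxt] = clusters.pop(a) | clusters.pop(b)
        nxt += 1
    return merges


class TestClusterCompounds:
    def test_identical_profiles_merge_first_at_zero(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0]] * 2 + [[9.0, 9.0, 9.0, 9.0, 9.0]],
            index=["c1", "c2", "c3"], columns=list(GROUPS),
        )
        Z = cluster_compounds(mat)
        assert Z[0, 2] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = int(rng.integers(4, 11))
            pts = rng.normal(size=(n, 5))
            mat = pd.DataFrame(pts, index=[f"c{i}" for i in range(n)],
                               columns=list(GROUPS))
            Z = cluster_compounds(mat)
            expected = _brute_force_single_linkage(pts)
            # compare merge distances and cluster compositions
            members = {i: frozenset([i]) for i in range(n)}
            for k, (i, j, dist, _) in enumerate(Z):
                merged = members[int(i)] | members[int(j)]
                members[n + k] = merged
                ed, emembers = expected[k]
                assert dist == pytest.approx(ed, abs=1e-10)
                assert merged == emembers

    def test_planted_phase_block_forms_clade(self):
        # a fixture with a cleanly planted correlated block: clustering of
        # the centered group-mean patterns must recover it as one clade
        cfg = SimConfig(chc_effect=0.6, sd_colony=0.1, sd_resid_chc=0.15,
                        below_detection_rate=0.0, seed=61)
        raw, _, truth, _ = simulate_chc(cfg)
        table = log_concentrations(raw)
        res = per_compound_anova(table)
        sig = res.loc[res["p"] < 0.05, "compound"]
        mat = group_mean_matrix(table, compounds=sig)
        Z = cluster_compounds(mat, center=True)
        phase = set(truth.loc[truth["pattern"] == "phase", "compound"])
        assert phase <= set(mat.index)
        labels = list(mat.index)
        members = {i: frozenset([labels[i]]) for i in range(len(labels))}
        smallest = None
        for k, (i, j, _, _) in enumerate(Z):
            members[len(labels) + k] = members[int(i)] | members[int(j)]
        for m in members.values():
            if phase <= m and (smallest is None or len(m) < len(smallest)):
                smallest = m
        assert smallest == frozenset(phase)

    def test_single_compound_rejected(self):
        mat = pd.DataFrame([[1.0] * 5], index=["c1"], columns=list(GROUPS))
        with pytest.raises(ValueError):
            cluster_compounds(mat)


class TestHeatmapMatrix:
    def test_identical_groups_all_zero(self):
        rows = [
            {"wasp": f"w{i}", "group": g, "colony": "X", "compound": c,
             "concentration": 10.0 ** (1.0 + j)}
            for j, c in enumerate(["c1", "c2"])
            for i, g in enumerate(np.repeat(GROUPS, 2))
        ]
        table = log_concentrations(pd.DataFrame(rows))
        np.testing.assert_allclose(heatmap_matrix(table).to_numpy(), 0.0, atol=1e-12)

    def test_row_means_zero_for_equal_group_sizes(self, logged):
        table, _ = logged
        h = heatmap_matrix(table)
        np.testing.assert_allclose(h.mean(axis=1), 0.0, atol=1e-10)

    def test_hand_computed_two_compound_fixture(self):
        rows = []
        for c, level in (("c1", {"DF": 1.0, "SF": 1.0, "Q": 2.0, "DW": 2.0, "SW": 2.0}),
                         ("c2", {g: 3.0 for g in GROUPS})):
            for i, g in enumerate(GROUPS):
                rows.append({"wasp": f"w{i}", "group": g, "colony": "X",
                             "compound": c, "concentration": 10.0 ** level[g]})
        h = heatmap_matrix(log_concentrations(pd.DataFrame(rows)))
        # c1 grand mean log10 = 1.6: founding groups sit 0.6 below, worker 0.4 above
        assert h.loc["c1", "DF"] == pytest.approx(-0.6)
        assert h.loc["c1", "Q"] == pytest.approx(0.4)
        np.testing.assert_allclose(h.loc["c2"], 0.0, atol=1e-12)
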