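import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tedrecon.scenarios import (
    FeatureMatrix,
    dendrogram_text,
    kruskal_wallis,
    scenario_summary,
    select_key_segments,
    steel_dwass,
    ward_cluster,
    zscore_columns,
)


def fm(X, ids=None):
    X = np.asarray(X, dtype=float)
    ids = ids or [f"S{k}" for k in range(X.shape[0])]
    return FeatureMatrix(ids, X, [f"f{j}" for j in range(X.shape[1])])


class TestSelectKeySegments:
    def test_single_dominant_segment(self):
        X = np.zeros((5, 10))
        X[:, 3] = [1, 2, 3, 4, 5]
        assert select_key_segments(X) == [3]

    def test_two_independent_half_contributors(self):
        # 4-subject toy: columns 2 and 7 each explain half the variance
        X = np.zeros((4, 10))
        X[:, 2] = [0, 0, 1, 1]
        X[:, 7] = [0, 1, 0, 1]
        got = select_key_segments(X)
        assert sorted(got) == [2, 7]

    def test_tie_broken_by_earlier_segment(self):
        X = np.zeros((4, 10))
        X[:, 5] = [0, 1, 0, 1]
        X[:, 2] = [0, 1, 0, 1]  # identical contribution, earlier column
        assert select_key_segments(X)[0] == 2

    def test_constant_total_returns_empty(self):
        assert select_key_segments(np.zeros((5, 10))) == []
        assert select_key_segments(np.ones((5, 10))) == []

    def test_stops_at_max_k(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 56))
        got = select_key_segments(X, max_k=3, r2_stop=0.999)
        assert len(got) == 3


def brute_force_ward(X):
    """Exhaustive Ward agglomeration via the ESS merge-cost formula."""
    clusters = [[i] for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = X[clusters[a]], X[clusters[b]]
            na, nb = len(ca), len(cb)
            delta = (
                na * nb / (na + nb) * float(np.sum((ca.mean(0) - cb.mean(0)) ** 2))
            )
            if best is None or delta < best[0]:
                best = (delta, a, b)
        delta, a, b = best
        merged = clusters[a] + clusters[b]
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), delta))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


class TestWardCluster:
    def test_two_tight_groups_recovered(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (12, 2))])
        assign = ward_cluster(fm(X), k=2)
        labels = np.array([assign.labels[f"S{k}"] for k in range(22)])
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]
        # labels ordered by descending size: the 12-point group is cluster 1
        assert labels[-1] == 1

    def test_merge_sequence_matches_brute_force(self):
        rng = np.random.default_rng(2)
        X = rng.random((6, 3))
        Xz = zscore_columns(X)
        expected = brute_force_ward(Xz)
        assign = ward_cluster(fm(X), k=1)
        Z = assign.linkage
        # replay scipy's merges into member sets
        members = {i: frozenset([i]) for i in range(6)}
        for row_idx, (a, b, dist, _) in enumerate(Z):
            members[6 + row_idx] = members[int(a)] | members[int(b)]
        for row, (ea, eb, edelta) in zip(Z, expected):
            sa, sb = members_of_row(row, members)
            assert {sa, sb} == {ea, eb}
            # scipy's ward height is sqrt(2 * merge cost)
            assert row[2] == pytest.approx(np.sqrt(2 * edelta), rel=1e-9)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        assign = ward_cluster(fm(rng.random((20, 4))), k=1)
        heights = assign.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(4)
        assign = ward_cluster(fm(rng.random((7, 2))), k=7)
        assert sorted(assign.labels.values()) == list(range(1, 8))

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(fm(np.zeros((3, 2))), k=4)

    def test_usage_rates_sum_to_100(self):
        rng = np.random.default_rng(5)
        assign = ward_cluster(fm(rng.random((40, 3))), k=4)
        assert sum(assign.usage_rates().values()) == pytest.approx(100.0)

    def test_dendrogram_export_contains_all_leaves(self):
        rng = np.random.default_rng(6)
        ids = [f"S{k}" for k in range(5)]
        assign = ward_cluster(fm(rng.random((5, 2)), ids), k=1)
        text = dendrogram_text(assign, ids)
        assert text.endswith(";") and all(i in text for i in ids)


def members_of_row(row, members):
    return members[int(row[0])], members[int(row[1])]


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        h, p = kruskal_wallis([np.array([2.0, 2.0]), np.array([2.0, 2.0, 2.0])])
        assert h == 0.0 and p == 1.0

    def test_hand_computed_no_ties(self):
        h, p = kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6])])
        assert h == pytest.approx(27 / 7, rel=1e-9)
        assert 0 < p < 1

    def test_permutation_symmetry(self):
        g = [np.array([1.0, 5.0, 2.0]), np.array([3.0, 8.0]), np.array([4.0, 0.5, 9.0])]
        h1, _ = kruskal_wallis(g)
        h2, _ = kruskal_wallis(g[::-1])
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        g = [rng.random(8), rng.random(10) + 0.2, rng.random(6)]
        h1, _ = kruskal_wallis(g)
        h2, _ = kruskal_wallis([np.exp(3 * x) for x in g])
        assert h1 == pytest.approx(h2, rel=1e-12)


class TestSteelDwass:
    def test_k2_reduces_to_normal_rank_sum(self):
        rng = np.random.default_rng(8)
        x, y = rng.random(12), rng.random(15) + 0.3
        out = steel_dwass([x, y])
        t = out.loc[0, "statistic"]
        # q(2, inf)/sqrt(2) is the standard normal
        assert out.loc[0, "p"] == pytest.approx(2 * stats.norm.sf(abs(t)), rel=1e-6)

    def test_identical_groups_p_one(self):
        g = np.array([1.0, 1.0, 1.0])
        out = steel_dwass([g, g.copy(), g.copy()])
        assert np.all(out["statistic"] == 0.0)
        assert np.allclose(out["p"].to_numpy(), 1.0)

    def test_valid_p_and_relabel_invariance(self):
        rng = np.random.default_rng(9)
        g = [rng.random(9), rng.random(11) + 0.5, rng.random(10) - 0.2]
        out = steel_dwass(g)
        assert np.all((out["p"] >= 0) & (out["p"] <= 1))
        out_rev = steel_dwass(g[::-1])
        ps = sorted(out["p"])
        ps_rev = sorted(out_rev["p"])
        assert np.allclose(ps, ps_rev, rtol=1e-9)

    def test_conservative_versus_unadjusted_for_k3(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            g = [rng.normal(size=15), rng.normal(0.4, size=15), rng.normal(0.8, size=15)]
            out = steel_dwass(g)
            for _, r in out.iterrows():
                unadjusted = 2 * stats.norm.sf(abs(r["statistic"]))
                assert r["p"] >= unadjusted - 1e-12

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            steel_dwass([np.array([1.0]), np.array([])])


class TestScenarioSummary:
    def test_single_cluster_usage_100(self):
        from tedrecon.scenarios import ScenarioAssignment

        assign = ScenarioAssignment({f"S{k}": 1 for k in range(5)}, np.zeros((0, 4)))
        out = scenario_summary(assign, {f"S{k}": float(k) for k in range(5)})
        assert out.loc[0, "usage_rate_pct"] == 100.0
        assert out.loc[0, "median"] == 2.0

    def test_usage_rate_split_25_75(self):
        from tedrecon.scenarios import ScenarioAssignment

        labels = {f"S{k}": (1 if k < 75 else 2) for k in range(100)}
        assign = ScenarioAssignment(labels, np.zeros((0, 4)))
        rng = np.random.default_rng(11)
        doses = {s: float(rng.random()) for s in labels}
        out = scenario_summary(assign, doses)
        assert list(out["usage_rate_pct"]) == [75.0, 25.0]

    def test_medians_match_direct_computation(self):
        from tedrecon.scenarios import ScenarioAssignment

        rng = np.random.default_rng(12)
        labels = {f"S{k}": rng.integers(1, 4) for k in range(60)}
        doses = {s: float(rng.gamma(2.0)) for s in labels}
        assign = ScenarioAssignment(labels, np.zeros((0, 4)))
        out = scenario_summary(assign, doses)
        for _, row in out.iterrows():
            direct = np.median([doses[s] for s, c in labels.items() if c == row["cluster"]])
            assert row["median"] == pytest.approx(direct)


class TestArchetypeRecovery:
    def test_rand_index_on_well_separated_cohort(self):
        """Clustering on stepwise-selected segment doses recovers the
        generating evacuation archetypes on a well-separated cohort."""
        from tedrecon.behaviour import assign_landmarks, discretize
        from tedrecon.config import load_reference_config
        from tedrecon.dosimetry import inhalation_dose
        from tedrecon.synthetic_data import (
            default_episodes,
            gen_cohort,
            gen_concentration_table,
        )

        vent, coeffs, cf = load_reference_config()
        table = gen_concentration_table(default_episodes())
        records, membership = gen_cohort(seed=20110312, jitter_km=0.3)
        per_segment = np.array(
            [
                inhalation_dose(
                    assign_landmarks(discretize(r), table), table, vent, coeffs, cf
                ).per_segment_mSv
                for r in records
            ]
        )
        keys = select_key_segments(per_segment, max_k=5, r2_stop=0.9999)
        assert 1 <= len(keys) <= 5
        matrix = fm(per_segment[:, keys], [r.subject_id for r in records])
        assign = ward_cluster(matrix, k=4)
        truth = [membership[r.subject_id] for r in records]
        labels = [assign.labels[r.subject_id] for r in records]
        n = len(truth)
        agree = sum(
            (truth[i] == truth[j]) == (labels[i] == labels[j])
            for i, j in itertools.combinations(range(n), 2)
        )
        rand = agree / (n * (n - 1) / 2)
        assert rand > 0.95
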