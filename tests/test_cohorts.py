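"""Relatedness groups, close relatives, power curve and re-ranking tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rfieval as rv


def _ped(rows):
    return pd.DataFrame(rows, columns=["animal", "sire", "dam"])


class TestGroups:
    def test_paternal_half_sib_is_group1(self):
        # deep male line so ancestry resolves: 1->2->3 sires training 10 and
        # candidate 11
        ped = _ped(
            [(1, 0, 0), (2, 1, 0), (3, 2, 0), (4, 0, 0), (5, 0, 0),
             (10, 3, 4), (11, 3, 5)]
        )
        groups, unresolved = rv.assign_groups(ped, [10], [11])
        assert unresolved == []
        assert groups.loc[0, "group"] == 1

    def test_shared_grandsire_only_is_group2(self):
        # candidate's sire (21) is another son of the training grandsire 3
        ped = _ped(
            [(1, 0, 0), (2, 1, 0), (3, 2, 0), (20, 3, 0), (21, 3, 0),
             (4, 0, 0), (10, 20, 4), (11, 21, 4)]
        )
        groups, _ = rv.assign_groups(ped, [10], [11])
        assert groups.loc[0, "group"] == 2

    def test_shared_great_grandsire_only_is_group3(self):
        ped = _ped(
            [(30, 0, 0),                    # shared great-grandsire
             (40, 30, 0), (41, 30, 0),      # his two sons: disjoint grandsires
             (50, 40, 0), (51, 41, 0),      # sire tier, disjoint
             (10, 50, 0), (11, 51, 0)]
        )
        groups, _ = rv.assign_groups(ped, [10], [11])
        assert groups.loc[0, "group"] == 3

    def test_immigrant_line_is_group4(self):
        ped = _ped(
            [(1, 0, 0), (2, 1, 0), (3, 2, 0), (10, 3, 0),
             (7, 0, 0), (8, 7, 0), (9, 8, 0), (11, 9, 0)]
        )
        groups, _ = rv.assign_groups(ped, [10], [11])
        assert groups.loc[0, "group"] == 4

    def test_unresolvable_candidates_reported(self):
        ped = _ped([(1, 0, 0), (2, 1, 0), (3, 2, 0), (10, 3, 0), (11, 0, 0)])
        groups, unresolved = rv.assign_groups(ped, [10], [11])
        assert unresolved == [11]
        assert groups.empty

    def test_synthetic_group_pedigree_recovered(self):
        ped, roles = rv.simulate_group_pedigree(seed=1)
        groups, unresolved = rv.assign_groups(ped, roles["training"], np.concatenate(
            [roles[f"group{k}"] for k in range(1, 5)]
        ))
        assert unresolved == []
        got = groups.set_index("animal_id")["group"]
        for k in range(1, 5):
            assert (got.loc[roles[f"group{k}"]] == k).all(), f"group {k}"

    def test_permutation_stability(self):
        ped, roles = rv.simulate_group_pedigree(seed=2)
        cands = np.concatenate([roles[f"group{k}"] for k in range(1, 5)])
        g1, _ = rv.assign_groups(ped, roles["training"], cands)
        rng = np.random.default_rng(3)
        g2, _ = rv.assign_groups(ped, roles["training"], rng.permutation(cands))
        m1 = g1.set_index("animal_id")["group"].sort_index()
        m2 = g2.set_index("animal_id")["group"].sort_index()
        pd.testing.assert_series_equal(m1, m2)


class TestCloseRelatives:
    def test_threshold_boundary_inclusive(self):
        G = np.array([[0.45, 0.449, 0.5, 0.0]])
        assert rv.count_close_relatives(G)[0] == 2

    def test_zero_matrix(self):
        assert rv.count_close_relatives(np.zeros((3, 5))).tolist() == [0, 0, 0]

    def test_duplicate_of_training_animal_counts(self):
        G = np.array([[0.98, 0.1], [0.2, 0.3]])
        counts = rv.count_close_relatives(G)
        assert counts[0] >= 1 and counts[1] == 0


class TestPowerCurve:
    def test_exact_recovery(self):
        counts = np.array([0, 1, 2, 5, 10, 20])
        rel = 0.2 * (counts + 1) ** 0.3
        fit = rv.fit_power_curve(rel, counts)
        assert fit.a == pytest.approx(0.2, abs=1e-6)
        assert fit.b == pytest.approx(0.3, abs=1e-6)
        assert fit.rss < 1e-12

    def test_constant_reliability_flat_exponent(self):
        counts = np.array([0, 1, 3, 8, 15])
        fit = rv.fit_power_curve(np.full(5, 0.4), counts)
        assert abs(fit.b) < 1e-6
        assert fit.a == pytest.approx(0.4, abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3 points"):
            rv.fit_power_curve([0.1, 0.2], [0, 1])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            rv.fit_power_curve([0.1, 0.2, 0.3], [0, -1, 2])


@pytest.fixture(scope="module")
def group_study():
    """Gene-dropped genotypes over the structured pedigree; GBLUP
    reliabilities per relatedness group."""
    ped, roles = rv.simulate_group_pedigree(n_sires=10, n_per_family=12, seed=5)
    cfg = rv.SimulationConfig(n_founders=10, n_snps=1200, maf_range=(0.1, 0.5))
    gm = rv.simulate_genotypes(ped, cfg, seed=6)
    G = rv.stabilize(rv.build_G(gm))
    train = list(roles["training"])
    rng = np.random.default_rng(7)
    A = rv.build_A(ped)
    u = rv.simulate_true_breeding_values(A.values, 1.16, seed=8)
    idx = {a: i for i, a in enumerate(ped["animal"])}
    ytr = np.array([u[idx[a]] for a in train]) + rng.normal(
        0, np.sqrt(1.55), len(train)
    )
    res = rv.GBLUP(ytr, G.submatrix(train), 1.16, 1.55).fit()
    rels, counts, labels = [], [], []
    for k in range(1, 5):
        cand = list(roles[f"group{k}"])
        G_PT = G.submatrix(cand, train)
        rel = res.reliability(G_PT, np.diag(G.submatrix(cand)) + 0.01)
        rels.append(rel)
        counts.append(rv.count_close_relatives(G_PT))
        labels.extend([k] * len(cand))
    return rels, counts, labels


class TestMonotoneDecayAndCurve:
    def test_reliability_decays_group1_to_group4(self, group_study):
        rels, _, _ = group_study
        means = [r.mean() for r in rels]
        assert means[0] > means[1] > means[2] > means[3]

    def test_close_relative_counts_decay(self, group_study):
        _, counts, _ = group_study
        assert counts[0].mean() > counts[3].mean()

    def test_fitted_exponent_positive(self, group_study):
        rels, counts, _ = group_study
        rel = np.concatenate(rels)
        cnt = np.concatenate(counts)
        fit = rv.fit_power_curve(rel, cnt)
        assert fit.b > 0


class TestRankCrossTab:
    def _series(self, vals):
        return pd.Series(vals, index=np.arange(1, len(vals) + 1))

    def test_perfect_concordance_diagonal(self):
        rng = np.random.default_rng(9)
        v = self._series(rng.normal(0, 1, 200))
        ct = rv.rank_cross_tab(v, v.copy())
        assert np.allclose(np.diag(ct.table.to_numpy()), 100.0)

    def test_perfect_reversal(self):
        rng = np.random.default_rng(10)
        v = self._series(rng.normal(0, 1, 200))
        ct = rv.rank_cross_tab(v, -v)
        assert ct.table.loc["most", "least"] == pytest.approx(100.0)
        assert ct.table.loc["least", "most"] == pytest.approx(100.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_rows_sum_to_hundred(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 300))
        h = self._series(rng.normal(0, 1, n))
        c = self._series(rng.normal(0, 1, n))
        ct = rv.rank_cross_tab(h, c)
        assert np.allclose(ct.table.sum(axis=1), 100.0, atol=0.1)

    def test_class_sizes_match_cutoffs(self):
        rng = np.random.default_rng(11)
        v = self._series(rng.normal(0, 1, 1516))
        ct = rv.rank_cross_tab(v, self._series(rng.normal(0, 1, 1516)))
        row_tot = ct.counts.sum(axis=1)
        assert row_tot["most"] == 151 and row_tot["least"] == 151
        assert row_tot["medium"] == 1516 - 302

    def test_independence_under_null(self):
        # r_g = 0: rows converge to the 10/80/10 base rates
        rng = np.random.default_rng(12)
        acc = np.zeros((3, 3))
        reps = 60
        for _ in range(reps):
            h = self._series(rng.normal(0, 1, 1000))
            c = self._series(rng.normal(0, 1, 1000))
            acc += rv.rank_cross_tab(h, c).table.to_numpy()
        acc /= reps
        expected = np.tile([10.0, 80.0, 10.0], (3, 1))
        assert np.abs(acc - expected).max() < 2.0

    def test_correlated_ebvs_monte_carlo_window(self):
        # heifer/cow EBVs correlated at the published 0.42: extreme-to-
        # -opposite-extreme flow is small, diagonal beats the 10% base rate
        rng = np.random.default_rng(13)
        cov = np.array([[1.0, 0.42], [0.42, 1.0]])
        top_to_bottom, diag = [], []
        for _ in range(200):
            x = rng.multivariate_normal([0, 0], cov, size=1516)
            h = self._series(x[:, 0])
            c = self._series(x[:, 1])
            tab = rv.rank_cross_tab(h, c).table
            top_to_bottom.append(tab.loc["most", "least"])
            diag.append(np.diag(tab.to_numpy()).mean())
        assert np.mean(top_to_bottom) < 10.0
        assert np.mean(diag) > 10.0

    def test_too_few_animals(self):
        v = self._series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            rv.rank_cross_tab(v, v)

    def test_plot_helper_writes_file(self, tmp_path):
        rng = np.random.default_rng(14)
        cnt = rng.integers(0, 20, 50)
        rel = 0.2 * (cnt + 1) ** 0.3 + rng.normal(0, 0.01, 50)
        fit = rv.fit_power_curve(rel, cnt)
        out = tmp_path / "curve.png"
        rv.cohorts.plot_reliability_curve(cnt, rel, fit, path=out)
        assert out.exists() and out.stat().st_size > 0
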