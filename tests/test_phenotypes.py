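"""Energy-corrected milk, daily-record QC and the RFI regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rfieval as rv
from conftest import make_clean_cow_daily


class TestECM:
    @pytest.mark.parametrize(
        "my,fy,py,expected",
        [
            (0.0, 0.0, 0.0, 0.0),
            (1.0, 0.0, 0.0, 0.327),
            (0.0, 1.0, 0.0, 12.95),
            (0.0, 0.0, 1.0, 7.2),
            # hand arithmetic: 0.327*30.84 + 12.95*1.37 + 7.2*1.02
            (30.84, 1.37, 1.02, 35.17),
        ],
    )
    def test_values(self, my, fy, py, expected):
        assert rv.compute_ecm(my, fy, py) == pytest.approx(expected, abs=0.005)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            rv.compute_ecm(-1.0, 0.0, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.tuples(*[st.floats(0, 100)] * 3),
        b=st.tuples(*[st.floats(0, 100)] * 3),
    )
    def test_linearity(self, a, b):
        s = tuple(x + y for x, y in zip(a, b))
        assert rv.compute_ecm(*s) == pytest.approx(
            rv.compute_ecm(*a) + rv.compute_ecm(*b), rel=1e-12, abs=1e-9
        )


class TestDailyQC:
    def test_clean_cow_no_removals(self):
        daily = make_clean_cow_daily(noise=2.0, seed=1)
        filtered, report = rv.filter_daily_records(daily)
        assert report.n_removed == 0
        assert report.fraction_removed == 0.0

    def test_single_dmi_spike_removed(self):
        daily = make_clean_cow_daily(n_cows=1, noise=1.0, seed=2)
        j = daily.index[70]
        resid_sd = 0.1  # dmi noise sd used by the fixture
        daily.loc[j, "dmi"] += 5 * resid_sd
        filtered, report = rv.filter_daily_records(daily)
        assert report.per_animal[1]["dmi"]["removed"] == 1
        assert not filtered.loc[j, "keep_dmi"]
        assert report.per_animal[1]["bw"]["removed"] == 0

    def test_same_direction_dmi_my_spike_retained(self):
        daily = make_clean_cow_daily(n_cows=1, noise=1.0, seed=3)
        j = daily.index[70]
        daily.loc[j, "dmi"] += 5 * 0.1
        daily.loc[j, "my"] += 8.0  # same direction, well past 3 SD
        filtered, report = rv.filter_daily_records(daily)
        assert filtered.loc[j, "keep_dmi"]
        assert report.per_animal[1]["dmi"]["removed"] == 0

    def test_opposite_direction_spike_still_removed(self):
        daily = make_clean_cow_daily(n_cows=1, noise=1.0, seed=4)
        j = daily.index[70]
        daily.loc[j, "dmi"] += 5 * 0.1
        daily.loc[j, "my"] -= 8.0
        filtered, _ = rv.filter_daily_records(daily)
        assert not filtered.loc[j, "keep_dmi"]

    def test_short_record_animal_dropped(self):
        daily = make_clean_cow_daily(n_cows=2, noise=1.0, seed=5)
        short = daily[daily["animal_id"] == 2].head(10)
        daily = pd.concat([daily[daily["animal_id"] == 1], short])
        filtered, report = rv.filter_daily_records(daily)
        assert 2 in report.animals_removed
        assert "fewer than 30" in report.animals_removed[2]
        assert set(filtered["animal_id"]) == {1}

    def test_zero_residual_variance_no_removals(self):
        daily = make_clean_cow_daily(n_cows=1, noise=0.0, seed=6)
        _, report = rv.filter_daily_records(daily)
        assert report.n_removed == 0


class TestSummaries:
    def test_constant_bw(self):
        daily = make_clean_cow_daily(n_cows=1, slope_bw=0.0)
        filtered, _ = rv.filter_daily_records(daily)
        rec = rv.summarize_cows(filtered)
        assert rec["avg_bw"].iloc[0] == pytest.approx(650.0)
        assert rec["delta_bw"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_exact_linear_bw(self):
        daily = make_clean_cow_daily(n_cows=1, slope_bw=0.5)  # 140 d span
        filtered, _ = rv.filter_daily_records(daily)
        rec = rv.summarize_cows(filtered)
        assert rec["delta_bw"].iloc[0] == pytest.approx(70.0, abs=1e-9)

    def test_noisy_linear_bw_ols_endpoint_oracle(self):
        # fitted-line endpoints, not raw records, define the BW change
        rng = np.random.default_rng(7)
        dims = np.arange(100, 241).astype(float)
        errs = []
        for rep in range(20):
            # bounded noise keeps every day under the 3-SD rule, so the
            # oracle OLS fit sees exactly the kept records
            y = 600 + 0.5 * (dims - 100) + rng.uniform(-17, 17, len(dims))
            X = np.column_stack([np.ones_like(dims), dims])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            oracle = beta[1] * 140
            daily = make_clean_cow_daily(n_cows=1)
            daily["bw"] = y
            filtered, _ = rv.filter_daily_records(daily)
            rec = rv.summarize_cows(filtered)
            assert rec["delta_bw"].iloc[0] == pytest.approx(oracle, abs=1e-8)
            errs.append(abs(oracle - 70.0))
        assert np.mean(errs) < 15  # OLS endpoint error is modest at n=141

    def test_raw_delta_bw_mode(self):
        daily = make_clean_cow_daily(n_cows=1, noise=1.0, seed=12, slope_bw=0.5)
        expected = daily["bw"].iloc[-1] - daily["bw"].iloc[0]
        filtered, report = rv.filter_daily_records(daily)
        assert report.n_removed == 0
        rec = rv.summarize_cows(filtered, delta_bw_mode="raw")
        assert rec["delta_bw"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_two_point_adg(self):
        sbw = pd.DataFrame({"animal_id": 1, "day": [0, 70], "bw": [300.0, 370.0]})
        dmi = pd.DataFrame({"animal_id": 1, "day": [0], "dmi": [8.0]})
        meta = pd.DataFrame({"animal_id": [1], "trial": ["H1"], "age": [300.0]})
        rec = rv.summarize_heifers(sbw, dmi, meta)
        assert rec["adg"].iloc[0] == pytest.approx(1.0)

    def test_metabolic_weight_256(self):
        sbw = pd.DataFrame({"animal_id": 1, "day": [0, 70], "bw": [256.0, 256.0]})
        dmi = pd.DataFrame({"animal_id": 1, "day": [0], "dmi": [8.0]})
        meta = pd.DataFrame({"animal_id": [1], "trial": ["H1"], "age": [300.0]})
        rec = rv.summarize_heifers(sbw, dmi, meta)
        assert rec["mbw"].iloc[0] == pytest.approx(64.0)

    def test_single_bw_point_fails(self):
        sbw = pd.DataFrame({"animal_id": 1, "day": [0], "bw": [300.0]})
        dmi = pd.DataFrame({"animal_id": 1, "day": [0], "dmi": [8.0]})
        meta = pd.DataFrame({"animal_id": [1], "trial": ["H1"], "age": [300.0]})
        with pytest.raises(ValueError, match="single BW point"):
            rv.summarize_heifers(sbw, dmi, meta)

    def test_simulated_mbw_in_study_range(self):
        cfg = rv.SimulationConfig()
        sbw, dmi, meta = rv.simulate_heifer_records(
            np.arange(300), np.zeros(300), cfg, seed=10
        )
        rec = rv.summarize_heifers(sbw, dmi, meta)
        assert rec["mbw"].between(35.22, 84.59).mean() > 0.95


class TestHeiferRFI:
    def _records(self, n=40, seed=0, noise=0.3, trials=2):
        rng = np.random.default_rng(seed)
        adg = rng.uniform(0.5, 1.8, n)
        mbw = rng.uniform(45, 75, n)
        age = rng.uniform(220, 420, n)
        trial = np.array([f"H{i % trials + 1}" for i in range(n)])
        mu = {f"H{t + 1}": 1.0 + 0.5 * t for t in range(trials)}
        dmi = (
            np.array([mu[t] for t in trial])
            + 1.5 * adg
            + 0.09 * mbw
            + 0.002 * age
            + rng.normal(0, noise, n)
        )
        return pd.DataFrame(
            {
                "animal_id": np.arange(1, n + 1),
                "trial": trial,
                "avg_dmi": dmi,
                "mbw": mbw,
                "adg": adg,
                "avg_age": age,
            }
        )

    def test_residuals_sum_to_zero_per_trial(self):
        rec = self._records()
        rfi, _ = rv.fit_heifer_rfi(rec)
        merged = rec.set_index("animal_id").join(rfi)
        for _, sub in merged.groupby("trial"):
            assert sub["rfi_heifer"].sum() == pytest.approx(0.0, abs=1e-8)

    def test_noiseless_coefficients_recovered(self):
        rec = self._records(noise=0.0)
        rfi, coefs = rv.fit_heifer_rfi(rec)
        assert np.allclose(rfi.to_numpy(), 0.0, atol=1e-8)
        assert np.allclose(coefs["b_adg"], 1.5, atol=1e-8)
        assert np.allclose(coefs["b_mbw"], 0.09, atol=1e-8)

    def test_rfi_variance_matches_noise(self):
        rec = self._records(n=2000, noise=0.65, trials=4, seed=3)
        rfi, _ = rv.fit_heifer_rfi(rec)
        assert rfi.var(ddof=1) == pytest.approx(0.65**2, rel=0.12)

    def test_small_trial_rejected(self):
        rec = self._records(n=8, trials=2)
        with pytest.raises(ValueError, match="need >="):
            rv.fit_heifer_rfi(rec, min_per_trial=5)

    def test_collinear_design_named(self):
        rec = self._records(n=20, trials=1)
        rec["mbw"] = 2.0 * rec["adg"]
        with pytest.raises(ValueError, match="mbw"):
            rv.fit_heifer_rfi(rec)


def _cow_records(n=400, seed=1, resid_sd=1.2):
    rng = np.random.default_rng(seed)
    trial = np.array([f"T{i % 10 + 1}" for i in range(n)])
    lact = 1 + (rng.random(n) < 0.2)
    dim = rng.uniform(150, 190, n)
    age = rng.uniform(800, 1100, n)
    bw = rng.normal(677, 60, n)
    ecm = rng.normal(35, 5, n)
    dbw = rng.normal(0.5, 1.0, n)
    t_eff = {f"T{t}": 0.3 * t for t in range(1, 11)}
    resid = rng.normal(0, resid_sd, n)
    dmi = (
        4.0
        + np.array([t_eff[t] for t in trial])
        + 1.2 * (lact - 1)
        + 0.02 * dim
        - 4e-5 * dim**2
        + 1e-3 * age
        - 2e-7 * age**2
        + 0.01 * bw
        + 0.35 * ecm
        + 0.2 * dbw
        + resid
    )
    return (
        pd.DataFrame(
            {
                "animal_id": np.arange(1, n + 1),
                "trial": trial,
                "lactation": lact,
                "avg_dmi": dmi,
                "avg_bw": bw,
                "avg_ecm": ecm,
                "delta_bw": dbw,
                "avg_dim": dim,
                "avg_age": age,
            }
        ),
        resid,
    )


class TestCowRFI:
    def test_residual_orthogonality(self):
        rec, _ = _cow_records()
        rfi, res = rv.fit_cow_rfi(rec)
        assert rfi.sum() == pytest.approx(0.0, abs=1e-6)
        for col in ("avg_bw", "avg_ecm", "delta_bw", "avg_dim", "avg_age"):
            r = np.corrcoef(rfi.to_numpy(), rec[col].to_numpy())[0, 1]
            assert abs(r) < 1e-8

    def test_noiseless_rfi_zero(self):
        rec, _ = _cow_records(resid_sd=0.0)
        rfi, _ = rv.fit_cow_rfi(rec)
        assert np.allclose(rfi.to_numpy(), 0.0, atol=1e-7)

    def test_first_lactation_record_preferred(self):
        rec, _ = _cow_records(n=60)
        dup = rec.iloc[:5].copy()
        dup["lactation"] = 2
        dup["avg_dmi"] += 100.0  # absurd second-lactation records
        rfi, _ = rv.fit_cow_rfi(pd.concat([rec, dup], ignore_index=True))
        assert len(rfi) == 60
        rfi0, _ = rv.fit_cow_rfi(rec)
        assert np.allclose(rfi.sort_index(), rfi0.sort_index(), atol=1e-9)

    def test_dmi_injection_raises_rfi_by_one_minus_leverage(self):
        rec, _ = _cow_records(n=200, seed=5)
        rfi0, res = rv.fit_cow_rfi(rec)
        X = res.model.exog
        H = X @ np.linalg.solve(X.T @ X, X.T)
        i = 17
        rec2 = rec.copy()
        rec2.loc[i, "avg_dmi"] += 1.0
        rfi1, _ = rv.fit_cow_rfi(rec2)
        animal = rec.loc[i, "animal_id"]
        expected = 1.0 * (1.0 - H[i, i])
        assert rfi1[animal] - rfi0[animal] == pytest.approx(expected, abs=1e-8)

    def test_divergent_deciles_differ_in_dmi_not_sinks(self):
        rec, _ = _cow_records(n=1000, seed=6)
        rfi, _ = rv.fit_cow_rfi(rec)
        from scipy import stats

        merged = rec.set_index("animal_id").join(rfi)
        q = merged["rfi_cow"].quantile([0.1, 0.9])
        low = merged[merged["rfi_cow"] <= q[0.1]]
        high = merged[merged["rfi_cow"] >= q[0.9]]
        t_dmi = stats.ttest_ind(low["avg_dmi"], high["avg_dmi"])
        assert t_dmi.pvalue < 1e-6
        for col in ("avg_ecm", "avg_bw", "delta_bw"):
            t = stats.ttest_ind(low[col], high[col])
            assert t.pvalue > 0.01  # energy sinks already absorbed

    def test_rfi_uncorrelated_with_sinks_on_simulated_herd(self):
        cfg = rv.SimulationConfig()
        n = 1000
        rng = np.random.default_rng(8)
        tbv = rng.normal(0, np.sqrt(cfg.cow.additive), n)
        daily = rv.simulate_cow_daily_records(np.arange(1, n + 1), tbv, cfg, seed=9)
        filtered, report = rv.filter_daily_records(daily)
        assert report.fraction_removed < 0.05
        rec = rv.summarize_cows(filtered)
        rfi, _ = rv.fit_cow_rfi(rec)
        merged = rec.set_index("animal_id").join(rfi)
        for col in ("avg_ecm", "avg_bw", "delta_bw"):
            r = np.corrcoef(merged["rfi_cow"], merged[col])[0, 1]
            assert abs(r) < 0.05

    def test_unbalanced_level_rejected(self):
        rec, _ = _cow_records(n=40)
        rec.loc[0, "trial"] = "T_singleton"
        with pytest.raises(ValueError, match="trial"):
            rv.fit_cow_rfi(rec)
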