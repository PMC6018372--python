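"""Exact signed-rank test, GEE models, and the paired strain table."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, wilcoxon

from lcstrain import build_paired_table, fit_gee_exchangeable, wilcoxon_signed_rank_exact
from lcstrain.stats import strain_change_models


def brute_force_two_sided_p(diffs):
    """Enumerate all 2^n sign assignments of the rank statistic."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = []
    for signs in itertools.product((0, 1), repeat=len(d)):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.asarray(stats)
    lo = (stats <= w_obs).mean()
    hi = (stats >= w_obs).mean()
    return min(1.0, 2.0 * min(lo, hi))


class TestWilcoxonExact:
    def test_six_same_sign_gives_003125(self):
        res = wilcoxon_signed_rank_exact([0.4, 1.2, 0.9, 2.2, 0.1, 0.6])
        assert res.p_value == pytest.approx(2.0 / 64.0)
        assert round(res.p_value, 2) == 0.03
        assert res.n == 6

    def test_symmetric_pair_p_one(self):
        res = wilcoxon_signed_rank_exact([1.0, -1.0])
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            d = rng.normal(0.3, 1.0, 8)
            res = wilcoxon_signed_rank_exact(d)
            assert res.p_value == pytest.approx(brute_force_two_sided_p(d), abs=1e-12)

    def test_matches_scipy_exact_on_untied_data(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            d = rng.normal(0.5, 1.0, 10)
            res = wilcoxon_signed_rank_exact(d)
            ref = wilcoxon(d, alternative="two-sided", mode="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_handles_ties_with_midranks(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 0.5])
        res = wilcoxon_signed_rank_exact(d)
        assert res.p_value == pytest.approx(brute_force_two_sided_p(d), abs=1e-12)

    def test_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.2, 1.0, 9)
        p1 = wilcoxon_signed_rank_exact(d).p_value
        p2 = wilcoxon_signed_rank_exact(1000.0 * d).p_value
        p3 = wilcoxon_signed_rank_exact(np.sign(d) * np.abs(d) ** 3).p_value
        assert p1 == p2 == p3

    def test_zeros_dropped_and_all_zero_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank_exact([0.0, 0.0, 0.0])
        assert res.p_value == 1.0
        res2 = wilcoxon_signed_rank_exact([0.0, 1.0, 2.0, 0.0, 3.0])
        assert res2.n == 3

    def test_large_n_rejected(self):
        with pytest.raises(ValueError, match="n <= 20"):
            wilcoxon_signed_rank_exact(np.ones(25))


def _clustered_data(rng, n_clusters=12, m=4, beta=0.8, rho_sd=0.5):
    rows = []
    for c in range(n_clusters):
        b = rng.normal(0, rho_sd)
        for _ in range(m):
            x = rng.normal()
            rows.append({"cluster": c, "x": x, "y": 1.0 + beta * x + b + rng.normal()})
    return pd.DataFrame(rows)


class TestGee:
    def test_independence_equals_ols(self):
        rng = np.random.default_rng(3)
        df = _clustered_data(rng)
        res = fit_gee_exchangeable(df, "y ~ x", groups="cluster", independence=True)
        import statsmodels.api as sm

        X = np.column_stack([np.ones(len(df)), df["x"]])
        ols = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
        assert res.params["Intercept"] == pytest.approx(ols[0], abs=1e-8)
        assert res.params["x"] == pytest.approx(ols[1], abs=1e-8)

    def test_one_row_per_cluster_equals_ols(self):
        rng = np.random.default_rng(4)
        df = _clustered_data(rng, n_clusters=30, m=1)
        res = fit_gee_exchangeable(df, "y ~ x", groups="cluster")
        X = np.column_stack([np.ones(len(df)), df["x"]])
        ols = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
        assert res.params["x"] == pytest.approx(ols[1], abs=1e-8)

    def test_robust_se_matches_sandwich_oracle(self):
        """Cluster-robust SEs equal the closed-form sandwich under independence."""
        rng = np.random.default_rng(5)
        df = _clustered_data(rng, n_clusters=16, m=3)
        res = fit_gee_exchangeable(df, "y ~ x", groups="cluster", independence=True)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        y = df["y"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        bread = np.linalg.inv(X.T @ X)
        meat = np.zeros((2, 2))
        for c in df["cluster"].unique():
            sel = (df["cluster"] == c).to_numpy()
            meat += X[sel].T @ np.outer(r[sel], r[sel]) @ X[sel]
        se = np.sqrt(np.diag(bread @ meat @ bread))
        assert res.robust_se["Intercept"] == pytest.approx(se[0], rel=1e-8)
        assert res.robust_se["x"] == pytest.approx(se[1], rel=1e-8)

    def test_slope_recovery_with_exchangeable_correlation(self):
        """Known slope recovered within 3 robust SEs in >= 95/100 replicates."""
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(100):
            rows = []
            for c in range(200):
                b = rng.normal(0, np.sqrt(0.3))  # shared cluster effect, ICC ~ 0.3
                for _ in range(4):
                    x = rng.normal()
                    rows.append(
                        {"cluster": c, "x": x, "y": 0.5 * x + b + rng.normal(0, np.sqrt(0.7))}
                    )
            df = pd.DataFrame(rows)
            res = fit_gee_exchangeable(df, "y ~ x", groups="cluster")
            if abs(res.params["x"] - 0.5) < 3.0 * res.robust_se["x"]:
                hits += 1
        assert hits >= 95

    def test_exchangeable_rho_estimated(self):
        rng = np.random.default_rng(7)
        df = _clustered_data(rng, n_clusters=80, m=4, rho_sd=1.0)
        res = fit_gee_exchangeable(df, "y ~ x", groups="cluster")
        assert 0.1 < res.working_correlation < 0.9
        assert res.n_clusters == 80

    def test_too_few_clusters_rejected(self):
        df = pd.DataFrame({"cluster": [0, 0], "x": [1.0, 2.0], "y": [0.1, 0.2]})
        with pytest.raises(ValueError, match="clusters"):
            fit_gee_exchangeable(df, "y ~ x", groups="cluster")


def _state_table(specimens, regions, value=0.02, pressure="5-45"):
    rows = []
    for s in specimens:
        for r in regions:
            for m in ("E_XX", "E_max"):
                rows.append(
                    {"specimen": s, "region": r, "measure": m, "pressure_pair": pressure, "value": value}
                )
    return pd.DataFrame(rows)


class TestBuildPairedTable:
    REGIONS = [f"{loc}_{q}" for loc in ("central", "peripheral") for q in "SITN"]

    def test_full_join_counts(self):
        specs = [f"s{i}" for i in range(6)]
        t = build_paired_table(_state_table(specs, self.REGIONS), _state_table(specs, self.REGIONS, 0.015))
        per_measure = t[t["measure"] == "E_XX"]
        assert len(per_measure) == 48
        assert np.allclose(per_measure["change"], -0.005)

    def test_dropped_regions_give_45_rows(self):
        specs = [f"s{i}" for i in range(6)]
        after = _state_table(specs, self.REGIONS, 0.015)
        drop = after["specimen"].eq("s5") & after["region"].isin(
            ["central_I", "peripheral_I", "peripheral_T"]
        )
        with pytest.warns(UserWarning, match="dropping"):
            t = build_paired_table(_state_table(specs, self.REGIONS), after[~drop])
        assert len(t[t["measure"] == "E_max"]) == 45

    def test_row_order_invariance(self):
        specs = [f"s{i}" for i in range(4)]
        before = _state_table(specs, self.REGIONS)
        after = _state_table(specs, self.REGIONS, 0.01)
        t1 = build_paired_table(before, after)
        t2 = build_paired_table(
            before.sample(frac=1.0, random_state=0), after.sample(frac=1.0, random_state=1)
        )
        pd.testing.assert_frame_equal(t1, t2)

    def test_location_and_quadrant_parsed(self):
        t = build_paired_table(_state_table(["s0"], self.REGIONS), _state_table(["s0"], self.REGIONS))
        assert set(t["location"]) == {"central", "peripheral"}
        assert set(t["quadrant"]) == {"S", "I", "T", "N"}

    def test_specimen_missing_in_one_state_rejected(self):
        with pytest.raises(ValueError, match="one state only"):
            build_paired_table(
                _state_table(["s0", "s1"], self.REGIONS), _state_table(["s0"], self.REGIONS)
            )

    def test_metadata_merged_and_models_run(self):
        rng = np.random.default_rng(8)
        specs = [f"s{i}" for i in range(6)]
        before = _state_table(specs, self.REGIONS)
        before["value"] = rng.uniform(0.01, 0.05, len(before))
        after = before.copy()
        after["value"] = before["value"] * rng.uniform(0.7, 0.95, len(before))
        meta = pd.DataFrame(
            {"specimen": specs, "age_group": ["middle"] * 3 + ["older"] * 3}
        )
        t = build_paired_table(before, after, meta)
        assert "age_group" in t.columns
        models = strain_change_models(t, "E_max", "5-45")
        assert set(models) == {"change", "vs_baseline", "vs_location", "vs_age"}
        assert models["change"].params["Intercept"] < 0  # constructed decrease
        assert models["change"].n_clusters == 6


from hypothesis import given, settings
from hypothesis import strategies as st

finite_diff = st.floats(-100.0, 100.0).filter(lambda x: abs(x) > 1e-6)


@given(st.lists(finite_diff, min_size=1, max_size=12))
@settings(deadline=None, derandomize=True, max_examples=60)
def test_wilcoxon_p_valid_and_scale_invariant(diffs):
    """p lies in (0, 1] and depends only on the signed rank pattern."""
    res = wilcoxon_signed_rank_exact(diffs)
    assert 0.0 < res.p_value <= 1.0
    scaled = wilcoxon_signed_rank_exact([3.5 * d for d in diffs])
    assert scaled.p_value == pytest.approx(res.p_value, abs=1e-12)
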