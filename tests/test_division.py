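"""Daughter pairing, delta-MOB mixture, inheritance and screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mobflim import division as dv
from mobflim import synthetic as syn


def benchmark_records(seed=4, n=500):
    spec = syn.DivisionSpec(n_pairs=n, asym_fraction=0.3, delta_mean_sym=0.3,
                            delta_mean_asym=2.0, delta_sd=0.2,
                            inheritance_r=0.8, seed=seed)
    df = syn.simulate_division_dataset(spec)
    df["delta_mob"] = dv.delta_mob(df["daughter1_score"],
                                   df["daughter2_score"])
    return spec, df


class TestPairing:
    def _pre(self):
        return pd.DataFrame({"x": [0.0, 100.0, 200.0],
                             "y": [0.0, 0.0, 0.0],
                             "mob_score": [1.0, 2.0, 3.0]})

    def test_two_daughters_form_record(self):
        post = pd.DataFrame({"x": [2.0, -3.0], "y": [1.0, -2.0],
                             "mob_score": [0.8, 1.2]})
        rec = dv.pair_daughters(self._pre(), post, site_radius=20)
        assert len(rec) == 1
        assert rec.loc[0, "parent_score"] == 1.0
        assert rec.loc[0, "delta_mob"] == pytest.approx(0.4)

    def test_single_cell_site_no_record(self):
        post = pd.DataFrame({"x": [100.0], "y": [0.0], "mob_score": [2.0]})
        rec = dv.pair_daughters(self._pre(), post, site_radius=20)
        assert len(rec) == 0

    def test_crowded_site_excluded(self):
        post = pd.DataFrame({"x": [199.0, 200.0, 201.0], "y": [0.0] * 3,
                             "mob_score": [1.0, 2.0, 3.0]})
        rec = dv.pair_daughters(self._pre(), post, site_radius=20)
        assert len(rec) == 0
        assert rec.attrs["excluded_sites"] == [2]

    def test_jittered_positions_fully_paired(self):
        """Daughters jittered within the site radius all map back to
        their true parent (generator ground truth)."""
        spec, df = benchmark_records(seed=1, n=100)
        rng = np.random.default_rng(0)
        pre = pd.DataFrame({"x": df["site_x_um"], "y": df["site_y_um"],
                            "mob_score": df["parent_score"]})
        post_rows = []
        for _, row in df.iterrows():
            for d in ("daughter1_score", "daughter2_score"):
                post_rows.append({
                    "x": row["site_x_um"] + rng.uniform(-10, 10),
                    "y": row["site_y_um"] + rng.uniform(-10, 10),
                    "mob_score": row[d]})
        post = pd.DataFrame(post_rows)
        rec = dv.pair_daughters(pre, post, site_radius=20)
        assert len(rec) == 100
        merged = rec.merge(df, left_on="pair_id", right_on="pair_id",
                           suffixes=("", "_true"))
        np.testing.assert_allclose(merged["parent_score"],
                                   merged["parent_score_true"])
        np.testing.assert_allclose(
            merged["delta_mob"],
            dv.delta_mob(merged["daughter1_score_true"],
                         merged["daughter2_score_true"]))


class TestDeltaMixture:
    def test_equal_variance_equal_weight_midpoint(self):
        rng = np.random.default_rng(0)
        deltas = np.r_[rng.normal(0.3, 0.05, 400), rng.normal(2.0, 0.05, 400)]
        fit = dv.fit_delta_mixture(deltas, seed=0)
        assert fit.threshold == pytest.approx(1.15, abs=0.05)

    def test_benchmark_threshold_and_accuracy(self):
        spec, df = benchmark_records()
        fit = dv.fit_delta_mixture(df["delta_mob"], seed=0)
        assert 0.8 <= fit.threshold <= 1.5
        labeled = dv.classify_divisions(df, fit)
        acc = (labeled["pattern"] == df["true_pattern"]).mean()
        assert acc >= 0.95

    def test_unimodal_collapse(self):
        rng = np.random.default_rng(1)
        fit = dv.fit_delta_mixture(np.abs(rng.normal(0.5, 0.2, 300)), seed=0)
        assert fit.collapsed
        labeled = dv.classify_divisions(
            pd.DataFrame({"delta_mob": np.abs(rng.normal(0.5, 0.2, 50))}), fit)
        assert labeled["pattern"].isna().all()

    def test_too_few_divisions_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            dv.fit_delta_mixture(np.ones(5))

    def test_classification_invariant_to_daughter_swap(self):
        spec, df = benchmark_records(seed=7, n=100)
        fit = dv.fit_delta_mixture(df["delta_mob"], seed=0)
        swapped = df.rename(columns={"daughter1_score": "daughter2_score",
                                     "daughter2_score": "daughter1_score"})
        swapped["delta_mob"] = dv.delta_mob(swapped["daughter1_score"],
                                            swapped["daughter2_score"])
        a = dv.classify_divisions(df, fit)["pattern"]
        b = dv.classify_divisions(swapped, fit)["pattern"]
        assert (a == b).all()

    def test_threshold_recovery_across_seeds(self):
        """Median absolute threshold error < 0.15 score units across 100
        seeded draws of the documented division spec (oracle: the
        closed-form equal-variance crossing of the generating modes)."""
        from mobflim.scoring import two_gaussian_threshold
        oracle = two_gaussian_threshold([0.3, 2.0], [0.2, 0.2], [0.7, 0.3])
        errors = []
        for seed in range(100):
            _, df = benchmark_records(seed=seed)
            fit = dv.fit_delta_mixture(df["delta_mob"], seed=0)
            if fit.threshold is not None:
                errors.append(abs(fit.threshold - oracle))
        assert len(errors) >= 95
        assert np.median(errors) < 0.15


class TestInheritance:
    def test_identical_daughters_r_one(self):
        df = pd.DataFrame({"parent_score": [1.0, 2.0, 3.0, 4.0],
                           "daughter1_score": [1.0, 2.0, 3.0, 4.0],
                           "daughter2_score": [1.0, 2.0, 3.0, 4.0]})
        out = dv.inheritance_correlation(df)
        assert out.loc["all", "r"] == pytest.approx(1.0)

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"parent_score": rng.standard_normal(200),
                           "daughter1_score": rng.standard_normal(200),
                           "daughter2_score": rng.standard_normal(200)})
        out = dv.inheritance_correlation(df)
        assert abs(out.loc["all", "r"]) < 0.15

    def test_generator_recovery_within_ci(self):
        """The estimated r covers the generating inheritance_r within its
        Fisher 95% confidence interval (cluster-corrected: siblings share
        a midpoint, so the effective n is below 2N)."""
        spec, df = benchmark_records(seed=11)
        out = dv.inheritance_correlation(df)
        r = out.loc["all", "r"]
        rho_sib = np.corrcoef(df["daughter1_score"],
                              df["daughter2_score"])[0, 1]
        n_eff = 2 * len(df) / (1.0 + max(rho_sib, 0.0))
        zr = np.arctanh(r)
        half = 1.96 / np.sqrt(n_eff - 3)
        assert np.tanh(zr - half) <= spec.inheritance_r <= np.tanh(zr + half)

    def test_per_pattern_groups(self):
        _, df = benchmark_records(seed=13)
        fit = dv.fit_delta_mixture(df["delta_mob"], seed=0)
        labeled = dv.classify_divisions(df, fit)
        out = dv.inheritance_correlation(labeled, group_col="pattern")
        assert {"M-symmetric", "M-asymmetric"} <= set(out.index)

    def test_too_few_pairs_flagged(self):
        df = pd.DataFrame({"parent_score": [1.0, 2.0],
                           "daughter1_score": [1.0, 2.0],
                           "daughter2_score": [1.0, 2.0]})
        out = dv.inheritance_correlation(df)
        assert out.loc["all", "flag"] == "too_few_pairs"

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"parent_score": [1.0] * 5,
                           "daughter1_score": [1.0] * 5,
                           "daughter2_score": [1.0] * 5})
        out = dv.inheritance_correlation(df)
        assert out.loc["all", "flag"] == "zero_variance"


class TestScoreDynamics:
    def _long(self):
        # constructed: symmetric daughters decay below 0, asymmetric
        # stem-like daughters stay above
        rows = []
        for pid in range(10):
            for t in (0, 8):
                rows.append({"pattern": "M-symmetric", "timepoint": t,
                             "daughter_score": 1.0 - 0.3 * t, "pair": pid})
                rows.append({"pattern": "M-asymmetric", "timepoint": t,
                             "daughter_score": 1.5, "pair": pid})
        return pd.DataFrame(rows)

    def test_constructed_fractions_exact(self):
        summary, tests = dv.score_dynamics(self._long(), stem_threshold=0.0)
        frac = summary.set_index(["pattern", "timepoint"])[
            "fraction_above_threshold"]
        assert frac[("M-symmetric", 0)] == 1.0
        assert frac[("M-symmetric", 8)] == 0.0  # 1 - 2.4 < 0
        assert frac[("M-asymmetric", 8)] == 1.0

    def test_identical_groups_null_p_calibrated(self):
        """Under the null (identical groups) the rank-test p value is
        approximately uniform: the rejection rate at alpha = 0.05 stays
        near 0.05 over repeated draws."""
        rng = np.random.default_rng(0)
        rejections = 0
        runs = 200
        for _ in range(runs):
            df = pd.DataFrame({
                "pattern": ["M-symmetric"] * 30 + ["M-asymmetric"] * 30,
                "timepoint": 0,
                "daughter_score": rng.standard_normal(60)})
            _, tests = dv.score_dynamics(df, stem_threshold=0.0)
            if tests["p"].iloc[0] < 0.05:
                rejections += 1
        assert rejections / runs < 0.1

    def test_single_timepoint_summary_only(self):
        df = self._long()
        df = df[df["timepoint"] == 0]
        summary, tests = dv.score_dynamics(df, stem_threshold=0.0)
        assert summary["timepoint"].nunique() == 1
        assert len(tests) == 1


class TestConditionScreen:
    def _records(self, seed, asym_fraction):
        spec = syn.DivisionSpec(n_pairs=150, asym_fraction=asym_fraction,
                                delta_mean_sym=0.3, delta_mean_asym=2.0,
                                delta_sd=0.2, inheritance_r=0.5, seed=seed)
        df = syn.simulate_division_dataset(spec)
        df["delta_mob"] = dv.delta_mob(df["daughter1_score"],
                                       df["daughter2_score"])
        return df

    def test_identical_conditions_not_significant(self):
        """Two conditions drawn from the same spec: the omnibus ANOVA
        stays non-significant in the clear majority of null draws."""
        sig = 0
        for seed in range(40):
            a = self._records(2 * seed, 0.3).assign(condition="ctrl")
            b = self._records(2 * seed + 1, 0.3).assign(condition="sham")
            pooled = pd.concat([a, b], ignore_index=True)
            fit = dv.fit_delta_mixture(pooled["delta_mob"], seed=0)
            pooled = dv.classify_divisions(pooled, fit)
            _, p = dv.condition_screen(pooled)
            if p < 0.05:
                sig += 1
        assert sig / 40 < 0.15

    def test_doubled_asymmetry_detected_in_direction(self):
        a = self._records(5, 0.15).assign(condition="ctrl")
        b = self._records(6, 0.30).assign(condition="drug")
        pooled = pd.concat([a, b], ignore_index=True)
        fit = dv.fit_delta_mixture(pooled["delta_mob"], seed=0)
        pooled = dv.classify_divisions(pooled, fit)
        summary, p = dv.condition_screen(pooled)
        s = summary.set_index("condition")
        assert s.loc["drug", "asymmetric_fraction"] > \
            s.loc["ctrl", "asymmetric_fraction"]

    def test_single_condition_no_test(self):
        a = self._records(9, 0.3).assign(condition="only")
        summary, p = dv.condition_screen(a)
        assert len(summary) == 1 and np.isnan(p)

    def test_tiny_condition_excluded(self):
        a = self._records(10, 0.3).assign(condition="big")
        b = a.iloc[:2].assign(condition="tiny")
        summary, _ = dv.condition_screen(pd.concat([a, b], ignore_index=True))
        assert summary.attrs["excluded_conditions"] == ["tiny"]
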