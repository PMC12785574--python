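"""The statistical core against independent oracles and its invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import studentized_range

import simscape as sc


def brute_force_anova(groups):
    """Sums-of-squares oracle, written from the textbook definition."""
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_between = sum(len(v) * (np.mean(v) - grand) ** 2
                     for v in groups.values())
    ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum()
                    for v in groups.values())
    k, n = len(groups), len(all_vals)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    from scipy.stats import f as fdist
    return f, fdist.sf(f, k - 1, n - k)


class TestAnova:
    def test_identical_groups(self):
        # equal group means, nonzero within-variance: F = 0 exactly
        f, p = sc.one_way_anova({g: np.array([1.0, 2.0, 3.0]) for g in "abc"})
        assert (f, p) == (0.0, 1.0)

    def test_all_constant(self):
        with pytest.warns(UserWarning, match="identical"):
            f, p = sc.one_way_anova({"a": np.zeros(3), "b": np.zeros(3)})
        assert (f, p) == (0.0, 1.0)

    def test_separated_constant_groups(self):
        f, p = sc.one_way_anova({"a": np.array([0.0, 0.0]),
                                 "b": np.array([1.0, 1.0])})
        assert math.isinf(f) and p == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than two"):
            sc.one_way_anova({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})

    def test_matches_sums_of_squares_oracle(self):
        groups = {"a": np.array([1.0, 2.0]), "b": np.array([2.0, 3.0]),
                  "c": np.array([3.0, 4.0])}
        f, p = sc.one_way_anova(groups)
        f0, p0 = brute_force_anova(groups)
        assert f == pytest.approx(f0, rel=1e-10)
        assert p == pytest.approx(p0, rel=1e-10)

    def test_random_inputs_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            sizes = rng.integers(2, 9, size=rng.integers(2, 5))
            groups = {f"g{i}": rng.normal(size=n) for i, n in enumerate(sizes)}
            f, p = sc.one_way_anova(groups)
            f0, p0 = brute_force_anova(groups)
            assert f == pytest.approx(f0, rel=1e-10)
            assert p == pytest.approx(p0, rel=1e-10)


class TestTukey:
    def test_identical_groups_p_one(self):
        groups = {g: np.array([1.0, 1.0, 1.0]) for g in "abc"}
        assert all(p == 1.0 for p in sc.tukey_hsd(groups).values())

    def test_matches_studentized_range_oracle(self):
        rng = np.random.default_rng(7)
        groups = {"a": rng.normal(0, 1, 4), "b": rng.normal(1, 1, 8),
                  "c": rng.normal(0.5, 1, 8)}
        arrays = list(groups.values())
        n_total = sum(a.size for a in arrays)
        df = n_total - len(arrays)
        mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
        for (ga, gb) in [("a", "b"), ("b", "c"), ("a", "c")]:
            va, vb = groups[ga], groups[gb]
            q = abs(va.mean() - vb.mean()) / math.sqrt(
                mse / 2 * (1 / va.size + 1 / vb.size))
            expected = studentized_range.sf(q, len(arrays), df)
            assert sc.tukey_hsd(groups, (ga, gb)) == pytest.approx(
                expected, rel=1e-6)

    def test_wider_separation_never_increases_p(self):
        rng = np.random.default_rng(3)
        base = {"a": rng.normal(0, 1, 6), "b": rng.normal(0, 1, 6),
                "c": rng.normal(0, 1, 6)}
        last = 1.0
        for shift in (0.0, 0.5, 1.0, 2.0, 4.0):
            groups = dict(base, b=base["b"] + shift)
            p = sc.tukey_hsd(groups, ("a", "b"))
            assert p <= last + 1e-12
            last = p


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(sc.benjamini_hochberg(np.array([0.03])),
                                   [0.03])

    def test_step_up_example(self):
        q = sc.benjamini_hochberg(np.array([0.01, 0.02, 0.04, 0.05]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.05, 0.05])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sc.benjamini_hochberg(np.array([0.5, 1.2]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_step_up_formula_and_invariants(self, ps):
        p = np.array(ps)
        q = sc.benjamini_hochberg(p)
        # direct evaluation of the step-up formula as oracle
        m = p.size
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            running = min(running, p[order[rank - 1]] * m / rank)
            expected[order[rank - 1]] = min(running, 1.0)
        np.testing.assert_allclose(q, expected, atol=1e-12)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(sc.benjamini_hochberg(p)[perm],
                                   sc.benjamini_hochberg(p[perm]))


class TestFoldChangeAndTrend:
    @pytest.mark.parametrize("a,b,expected", [
        (1.28e-3, 9.06e-4, 0.50),
        (1.87e-5, 5.89e-6, 1.67),
    ])
    def test_published_fold_changes(self, a, b, expected):
        assert round(sc.log2_fold_change(a, b), 2) == expected

    def test_equal_means_zero(self):
        assert sc.log2_fold_change(3e-4, 3e-4) == 0.0

    def test_nonpositive_mean_missing(self):
        assert math.isnan(sc.log2_fold_change(0.0, 1e-3))
        assert math.isnan(sc.log2_fold_change(1e-3, 0.0))

    @pytest.mark.parametrize("fc1,fc2,label", [
        (1.16, 0.24, "Up"),
        (-0.66, -0.09, "Down"),
        (-1.75, 0.52, "Mixed"),
        (0.0, 0.5, "Mixed"),
        (0.5, 0.0, "Mixed"),
    ])
    def test_trend_taxonomy(self, fc1, fc2, label):
        assert sc.classify_trend(fc1, fc2) == label

    def test_missing_input_unclassified(self):
        assert sc.classify_trend(float("nan"), 0.5) is None


class TestRecoveryIndex:
    @pytest.mark.parametrize("lean,p1,p2,expected", [
        (1.28e-3, 9.06e-4, 9.24e-4, 4.8),
        (9.14e-5, 1.36e-4, 1.06e-4, 67.3),
    ])
    def test_published_values(self, lean, p1, p2, expected):
        assert round(sc.recovery_index(lean, p1, p2), 1) == expected

    def test_endpoints(self):
        assert sc.recovery_index(2.0, 1.0, 1.0) == 0.0
        assert sc.recovery_index(2.0, 1.0, 2.0) == 100.0

    def test_overshoot_not_clipped(self):
        assert sc.recovery_index(2.0, 1.0, 3.0) == 200.0

    def test_degenerate_denominator_nan(self):
        assert math.isnan(sc.recovery_index(1.0, 1.0, 2.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=1e-6, max_value=1e-2),
        st.floats(min_value=1e-6, max_value=1e-2),
        st.floats(min_value=1e-6, max_value=1e-2),
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=-1e-3, max_value=1e-3),
    )
    def test_affine_invariance(self, lean, p1, p2, a, b):
        base = sc.recovery_index(lean, p1, p2)
        mapped = sc.recovery_index(a * lean + b, a * p1 + b, a * p2 + b)
        if math.isnan(base):
            assert math.isnan(mapped) or abs(lean - p1) * a <= 1e-11
        else:
            assert mapped == pytest.approx(base, rel=1e-6, abs=1e-6)


class TestClassContribution:
    def test_closure_and_fractions(self, tiny_table):
        per_sample, summary = sc.class_contribution(tiny_table)
        np.testing.assert_allclose(
            per_sample["amino_pct"] + per_sample["lipid_pct"], 100.0)
        row = per_sample.loc["a1"]
        assert row["amino_pct"] == pytest.approx(25.0)  # 1e-3 vs 3e-3
        assert row["lipid_pct"] == pytest.approx(75.0)

    def test_scale_invariance(self, tiny_table):
        doubled = sc.PeakTable(meta=tiny_table.meta.copy(),
                               values=tiny_table.values * 0.5,
                               ions=tiny_table.ions.copy())
        a, _ = sc.class_contribution(tiny_table)
        b, _ = sc.class_contribution(doubled)
        np.testing.assert_allclose(a["amino_pct"], b["amino_pct"])

    def test_missing_class_rejected(self, tiny_table):
        ions = tiny_table.ions.copy()
        ions["ion_class"] = "lipid"
        bad = sc.PeakTable(meta=tiny_table.meta.copy(),
                           values=tiny_table.values.copy(), ions=ions)
        with pytest.raises(ValueError, match="amino_acid"):
            sc.class_contribution(bad)


class TestAssumptionChecks:
    def test_null_levene_rarely_rejects(self):
        rng = np.random.default_rng(0)
        hits = 0
        reps = 500
        for _ in range(reps):
            groups = {"a": rng.normal(0, 1, 4), "b": rng.normal(0, 1, 8),
                      "c": rng.normal(0, 1, 8)}
            _, levene_p = sc.assumption_checks(groups)
            hits += levene_p > 0.05
        assert hits / reps >= 0.90

    def test_heteroscedastic_groups_detected(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(100):
            groups = {"a": rng.normal(0, 1, 8), "b": rng.normal(0, 10, 8),
                      "c": rng.normal(0, 1, 8)}
            _, levene_p = sc.assumption_checks(groups)
            ps.append(levene_p)
        assert np.median(ps) < 0.05

    def test_tiny_group_flagged_undefined(self):
        shapiro_p, _ = sc.assumption_checks(
            {"a": np.array([1.0, 2.0]), "b": np.array([1.0, 2.0, 3.0, 2.5])})
        assert math.isnan(shapiro_p["a"])
        assert not math.isnan(shapiro_p["b"])


class TestRunDifferential:
    def test_noise_free_study_reproduces_published_trends(
            self, noise_free_table, ref_frame):
        results = sc.run_differential(noise_free_table)
        assert len(results) == 26
        for r in results:
            assert r.trend == ref_frame.loc[r.mz, "trend"]

    def test_default_noise_recovers_well_separated_trends(self, noisy_table,
                                                          ref_frame):
        """Ions whose published |log2FC| exceed the biological noise floor
        must classify correctly; near-zero fold changes are irreducibly
        ambiguous at 10% animal-level CV."""
        results = sc.run_differential(noisy_table)
        strong = ref_frame[
            ref_frame[["log2fc_lean_p1", "log2fc_p2_p1"]].abs().min(axis=1)
            > 0.1
        ]
        for r in results:
            if r.mz in strong.index:
                assert r.trend == strong.loc[r.mz, "trend"], f"m/z {r.mz}"

    def test_q_is_bh_within_family(self, noise_free_table):
        results = sc.run_differential(noise_free_table)
        for family in ("lipid", "amino_acid"):
            fam = [r for r in results if r.ion_class == family]
            q = sc.benjamini_hochberg(np.array([r.p_anova for r in fam]))
            np.testing.assert_allclose([r.q for r in fam], q)
            for r in fam:
                assert r.q >= r.p_anova - 1e-12

    def test_trend_agrees_with_recovery_sign_structure(self, noisy_table):
        for r in sc.run_differential(noisy_table):
            if r.trend == "Up":
                assert r.mean["LEAN"] > r.mean["P1"]
            elif r.trend == "Down":
                assert r.mean["LEAN"] < r.mean["P1"]

    def test_results_frame_round_trip(self, noise_free_table, tmp_path):
        from simscape.stats import frame_to_results, results_to_frame

        results = sc.run_differential(noise_free_table)
        frame = results_to_frame(results)
        path = tmp_path / "results.csv"
        frame.to_csv(path, index=False, float_format="%.12g")
        back = frame_to_results(pd.read_csv(path))
        by_mz = {r.mz: r for r in results}
        for r in back:
            assert r.trend == by_mz[r.mz].trend
            assert r.q == pytest.approx(by_mz[r.mz].q, rel=1e-9)
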