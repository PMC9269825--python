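"""Tests for the agreement statistics, each against a brute-force oracle
or a hand-computed value."""

from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wristox.agreement import (
    bland_altman,
    build_report,
    classify_at_cutoff,
    cohens_kappa,
    compute_arms,
    compute_bias,
    lin_ccc,
    mape,
    pearson_r,
    regress_difference,
)
from wristox.synth import ErrorModel, generate_paired_dataset

paired_series = st.lists(
    st.tuples(st.floats(-50, 50), st.floats(-50, 50)), min_size=3, max_size=50
).map(lambda ps: (np.array([a for a, _ in ps]), np.array([b for _, b in ps])))


class TestArms:
    def test_identical_series_zero(self):
        x = np.arange(10.0)
        assert compute_arms(x, x) == 0.0

    def test_hand_computed(self):
        assert compute_arms([93.0, 87.0], [90.0, 90.0]) == pytest.approx(3.0)
        assert compute_arms([1, 2, 3, 4], [0, 1, 2, 3]) == pytest.approx(1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_arms([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            compute_arms([], [])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(paired_series)
    def test_bruteforce_oracle(self, dr):
        d, r = dr
        expected = math.sqrt(sum((a - b) ** 2 for a, b in zip(d, r)) / len(d))
        assert compute_arms(d, r) == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(paired_series)
    def test_algebraic_identity_with_bias_and_sd(self, dr):
        """A_RMS^2 = bias^2 + ((n-1)/n) * sd_diff^2 and A_RMS >= |bias|."""
        d, r = dr
        n = len(d)
        bias, sd, _ = bland_altman(d, r)
        arms = compute_arms(d, r)
        assert arms**2 == pytest.approx(bias**2 + (n - 1) / n * sd**2, abs=1e-6)
        assert arms >= abs(bias) - 1e-12


class TestBias:
    def test_mean_difference(self):
        res = compute_bias([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.bias == pytest.approx(2.0)

    def test_zero_variance_flagged_degenerate(self):
        x = np.arange(5.0)
        res = compute_bias(x, x)
        assert res.degenerate and res.p == 1.0 and res.bias == 0.0

    def test_null_simulation_rarely_rejects(self):
        """With differences ~ Normal(0.18, 2.7^2) at n=219 the paired t
        test against zero mostly retains the null."""
        retained = 0
        reps = 100
        for i in range(reps):
            rng = np.random.default_rng(300 + i)
            r = rng.uniform(80, 100, 219)
            d = r + rng.normal(0.18, 2.7, 219)
            retained += compute_bias(d, r).p > 0.05
        assert retained > reps / 2

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(paired_series)
    def test_bruteforce_oracle(self, dr):
        d, r = dr
        diff = [a - b for a, b in zip(d, r)]
        n = len(diff)
        mean = sum(diff) / n
        res = compute_bias(d, r)
        assert res.bias == pytest.approx(mean, abs=1e-9)
        var = sum((e - mean) ** 2 for e in diff) / (n - 1)
        if var > 0:
            t = mean / math.sqrt(var / n)
            assert res.t_stat == pytest.approx(t, abs=1e-9)


class TestBlandAltman:
    def test_printed_whole_range_limits(self):
        # bias 0.18, SD 2.7: limits (-5.112, 5.472) print as (-5.1, 5.5)
        bias, sd = 0.18, 2.7
        lo = bias - 1.96 * sd
        hi = bias + 1.96 * sd
        assert round(lo, 1) == -5.1 and round(hi, 1) == 5.5

    def test_identical_series(self):
        x = np.arange(10.0)
        bias, sd, loa = bland_altman(x, x)
        assert bias == 0.0 and sd == 0.0 and loa == (0.0, 0.0)

    def test_constant_shift(self):
        r = np.arange(10.0)
        bias, sd, loa = bland_altman(r + 1.0, r)
        assert bias == pytest.approx(1.0) and sd == 0.0
        assert loa == (pytest.approx(1.0), pytest.approx(1.0))

    def test_limits_bracket_95pct_of_gaussian_differences(self):
        rng = np.random.default_rng(17)
        r = rng.uniform(80, 100, 100_000)
        d = r + rng.normal(0.2, 2.0, 100_000)
        bias, sd, loa = bland_altman(d, r)
        frac = np.mean((d - r >= loa[0]) & (d - r <= loa[1]))
        assert frac == pytest.approx(0.95, abs=0.01)


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_null_simulation(self):
        small = 0
        for i in range(20):
            rng = np.random.default_rng(400 + i)
            r, _ = pearson_r(rng.normal(size=10_000), rng.normal(size=10_000))
            small += abs(r) < 0.05
        assert small >= 19

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(paired_series)
    def test_bruteforce_oracle(self, xy):
        x, y = xy
        if np.std(x) == 0 or np.std(y) == 0:
            return
        n = len(x)
        mx, my = sum(x) / n, sum(y) / n
        num = sum((a - mx) * (b - my) for a, b in zip(x, y))
        den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
        if den < 1e-9:
            return
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(num / den, abs=1e-7)


class TestLinCCC:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        ccc, _ = lin_ccc(x, x)
        assert ccc == pytest.approx(1.0)

    def test_large_shift_kills_concordance(self):
        x = np.arange(1.0, 11.0)
        ccc, _ = lin_ccc(x, x + 100.0)
        assert ccc == pytest.approx(0.0016, abs=2e-4)

    def test_perfect_negative(self):
        x = np.arange(-5.0, 6.0)  # zero mean
        ccc, _ = lin_ccc(x, -x)
        assert ccc == pytest.approx(-1.0)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(23)
        x = rng.uniform(80, 100, 200)
        y = x + rng.normal(0, 2, 200)
        ccc, (lo, hi) = lin_ccc(x, y)
        assert lo <= ccc <= hi and lo < hi

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            lin_ccc(np.ones(5), np.arange(5.0))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(paired_series)
    def test_bruteforce_oracle(self, xy):
        x, y = xy
        if np.std(x) == 0 or np.std(y) == 0:
            return
        n = len(x)
        mx, my = sum(x) / n, sum(y) / n
        sx2 = sum((a - mx) ** 2 for a in x) / n
        sy2 = sum((b - my) ** 2 for b in y) / n
        sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
        expected = 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)
        ccc, _ = lin_ccc(x, y)
        assert ccc == pytest.approx(expected, abs=1e-7)


class TestMape:
    def test_identical_zero(self):
        assert mape([70.0, 80.0], [70.0, 80.0]) == 0.0

    def test_hand_computed(self):
        assert mape([90.0, 110.0], [100.0, 100.0]) == pytest.approx(10.0)

    def test_uniform_scaling(self):
        r = np.array([60.0, 75.0, 90.0])
        assert mape(1.05 * r, r) == pytest.approx(5.0)

    def test_nonpositive_reference_raises(self):
        with pytest.raises(ValueError):
            mape([1.0], [0.0])


class TestClassification:
    def test_perfect_agreement(self):
        ref = np.array([85.0, 92.0, 96.0, 98.0, 90.0])
        c = classify_at_cutoff(ref, ref, 94.0)
        assert c.sensitivity == c.specificity == c.ppv == c.npv == 1.0
        assert c.kappa == pytest.approx(1.0)

    def test_hand_computed_table(self):
        # tp=40, fn=10, fp=10, tn=40: sens=spec=0.8, po=0.8, pe=0.5, kappa=0.6
        ref = np.array([90.0] * 50 + [98.0] * 50)
        dev = np.concatenate(
            [
                np.full(40, 90.0), np.full(10, 98.0),  # condition positive
                np.full(10, 90.0), np.full(40, 98.0),  # condition negative
            ]
        )
        c = classify_at_cutoff(dev, ref, 94.0)
        assert (c.tp, c.fn, c.fp, c.tn) == (40, 10, 10, 40)
        assert c.sensitivity == pytest.approx(0.8)
        assert c.specificity == pytest.approx(0.8)
        assert c.kappa == pytest.approx(0.6)

    def test_empty_positive_class_reported_missing(self):
        ref = np.array([97.0, 98.0, 99.0])
        c = classify_at_cutoff(ref, ref, 94.0)
        assert c.sensitivity is None and c.specificity == 1.0

    def test_counts_partition_sample(self):
        rng = np.random.default_rng(31)
        ref = rng.uniform(80, 100, 57)
        dev = ref + rng.normal(0, 3, 57)
        c = classify_at_cutoff(dev, ref, 90.0)
        assert c.tp + c.fp + c.fn + c.tn == 57

    def test_kappa_invariant_under_label_swap(self):
        # swapping positive/negative convention transposes the table
        assert cohens_kappa(40, 10, 7, 43) == pytest.approx(cohens_kappa(43, 7, 10, 40))


class TestRegression:
    def _pairs(self, n, seed, effect_sex=0.0):
        # split the error symmetrically so the difference is independent of
        # the pair average (the regression's first covariate)
        rng = np.random.default_rng(seed)
        df = generate_paired_dataset(n, error_model=ErrorModel(0.0, 0.0, seed=seed))
        truth = df["spo2_ref"].to_numpy().copy()
        e = rng.normal(0, 1.0, n)
        if effect_sex:
            e = e + effect_sex * (df["sex"] == "M").to_numpy()
        df["spo2_ref"] = truth - e / 2.0
        df["spo2_dev"] = truth + e / 2.0
        return df

    def test_null_covariates_rarely_significant(self):
        reps, alpha_hits = 40, {}
        for i in range(reps):
            table = regress_difference(self._pairs(219, 500 + i), "spo2")
            for name, p in table.p.items():
                if name == "Intercept":
                    continue
                alpha_hits[name] = alpha_hits.get(name, 0) + (p < 0.05)
        for name, hits in alpha_hits.items():
            assert hits <= reps * 0.1, f"{name} rejected too often"

    def test_sex_effect_recovered(self):
        inside = 0
        for i in range(20):
            table = regress_difference(self._pairs(219, 700 + i, effect_sex=0.5), "spo2")
            row = [n for n in table.index if "sex" in n][0]
            inside += table.ci_lo[row] <= 0.5 <= table.ci_hi[row]
        assert inside >= 18

    def test_zero_variance_covariate_raises(self):
        df = self._pairs(50, 3)
        df["sex"] = "M"
        with pytest.raises(ValueError, match="sex"):
            regress_difference(df, "spo2")

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            regress_difference(self._pairs(20, 1), "spo2", subset_max_ref=82.0)


class TestReport:
    def test_zero_error_pairs_give_perfect_report(self, zero_error_pairs):
        rep = build_report(zero_error_pairs)
        assert rep.spo2["all"].bias == 0.0
        assert rep.spo2["all"].arms == 0.0
        for c in rep.classification.values():
            assert c.kappa == pytest.approx(1.0)

    def test_report_roundtrips_through_json(self, zero_error_pairs):
        rep = build_report(zero_error_pairs)
        data = json.loads(rep.to_json())
        assert data["spo2"]["all"]["n"] == rep.spo2["all"].n
        assert data["classification"]["le_94"]["tp"] == rep.classification["le_94"].tp

    def test_gaussian_calibrated_arms(self):
        """Pairs with Normal(0.18, 2.7^2) disagreement yield a whole-range
        A_RMS near sqrt(0.18^2 + 2.7^2) = 2.71 on average."""
        vals = []
        for i in range(60):
            df = generate_paired_dataset(
                219, error_model=ErrorModel(0.18, 2.7, 0.25, 3.7, seed=900 + i)
            )
            vals.append(build_report(df).spo2["all"].arms)
        assert np.mean(vals) == pytest.approx(2.706, abs=0.1)

    def test_empty_subset_warned_not_crashed(self):
        df = generate_paired_dataset(
            40, truth_distribution=(96.0, 100.0), error_model=ErrorModel(seed=8)
        )
        rep = build_report(df)
        assert "all" in rep.spo2
        assert any("ref_le_90" in w for w in rep.warnings)
        assert "ref_le_90" not in rep.spo2

    def test_summary_mentions_key_quantities(self, zero_error_pairs):
        text = build_report(zero_error_pairs).summary()
        assert "A_RMS" in text and "kappa" in text and "MAPE" in text
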