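import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snrnatail.quant import (
    delta_delta_ct,
    ddct_all_targets,
    fit_half_life,
    normalize_decay,
    significance_tier,
    two_tailed_t,
    validate_ct_table,
)
from snrnatail.simulate import simulate_ct_table, simulate_decay_series


def ct_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "condition", "target_id", "replicate", "ct"])


class TestDeltaDeltaCt:
    def test_closed_form_example(self):
        rows = []
        for cond, tct in (("cond", 24.0), ("ref", 25.0)):
            rows.append((f"{cond}_0", cond, "U1", 0, tct))
            rows.append((f"{cond}_0", cond, "7SK", 0, 20.0))
            rows.append((f"{cond}_0", cond, "12S", 0, 22.0))
        r = delta_delta_ct(ct_table(rows), "U1", ["7SK", "12S"], "cond", "ref")
        assert math.isclose(r.ddct, -1.0)
        assert math.isclose(r.relative_level, 2.0)

    def test_identical_conditions_give_unity(self):
        rows = [
            (f"{c}_{r}", c, t, r, ct)
            for c in ("a", "b")
            for r in range(3)
            for t, ct in (("U1", 24.0), ("7SK", 20.0))
        ]
        r = delta_delta_ct(ct_table(rows), "U1", ["7SK"], "a", "b")
        assert math.isclose(r.relative_level, 1.0)

    def test_generator_inversion_exact(self):
        table = simulate_ct_table({"U1": 0.25}, ["7SK", "12S"], ct_noise_sd=0.0)
        r = delta_delta_ct(table, "U1", ["7SK", "12S"], "treated", "reference")
        assert math.isclose(r.relative_level, 0.25, abs_tol=1e-9)

    def test_reciprocity(self):
        table = simulate_ct_table({"U1": 3.7}, ["7SK"], ct_noise_sd=0.2, seed=5)
        fwd = delta_delta_ct(table, "U1", ["7SK"], "treated", "reference")
        rev = delta_delta_ct(table, "U1", ["7SK"], "reference", "treated")
        assert math.isclose(fwd.relative_level * rev.relative_level, 1.0)

    def test_constant_ct_shift_invariance(self):
        table = simulate_ct_table({"U1": 2.0, "U2": 0.5}, ["7SK", "12S"], ct_noise_sd=0.3, seed=6)
        shifted = table.copy()
        shifted["ct"] += 3.0
        a = ddct_all_targets(table, ["7SK", "12S"], "treated", "reference")
        b = ddct_all_targets(shifted, ["7SK", "12S"], "treated", "reference")
        assert np.allclose(a["relative_level"], b["relative_level"])

    def test_missing_target_raises(self):
        table = simulate_ct_table({"U1": 2.0}, ["7SK"])
        with pytest.raises(ValueError, match="no Ct rows"):
            delta_delta_ct(table, "U9", ["7SK"], "treated", "reference")

    def test_ct_range_validated(self):
        bad = ct_table([("s", "a", "U1", 0, 50.0)])
        with pytest.raises(ValueError, match="Ct values"):
            validate_ct_table(bad)


class TestNormalizeDecay:
    def test_target_halves_controls_constant(self):
        out = normalize_decay(
            {0: 100.0, 10: 50.0, 20: 25.0},
            [{0: 7.0, 10: 7.0, 20: 7.0}, {0: 3.0, 10: 3.0, 20: 3.0}],
        )
        assert np.allclose(out["fraction"], [1.0, 0.5, 0.25])

    def test_global_decay_cancels(self):
        out = normalize_decay(
            {0: 100.0, 10: 50.0, 20: 25.0},
            [{0: 8.0, 10: 4.0, 20: 2.0}],
        )
        assert np.allclose(out["fraction"], 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        t = [0, 10, 20, 30]
        target = {tp: float(v) for tp, v in zip(t, rng.uniform(1, 10, 4))}
        ctrls = [{tp: float(v) for tp, v in zip(t, rng.uniform(1, 10, 4))} for _ in range(2)]
        base = normalize_decay(target, ctrls)
        scaled = normalize_decay(
            {k: 13.0 * v for k, v in target.items()},
            [{k: 0.2 * v for k, v in c.items()} for c in ctrls],
        )
        assert np.allclose(base["fraction"], scaled["fraction"])

    def test_nonpositive_controls_rejected(self):
        with pytest.raises(ValueError):
            normalize_decay({0: 1.0, 10: 0.5}, [{0: 0.0, 10: 1.0}])


class TestFitHalfLife:
    def test_exact_exponential(self):
        series = pd.DataFrame({"time_min": [0, 10, 20, 30], "fraction": [1, 0.5, 0.25, 0.125]})
        fit = fit_half_life(series)
        assert math.isclose(fit.t_half, 10.0)
        assert math.isclose(fit.r_squared, 1.0)
        assert not fit.no_decay

    def test_constant_series_flagged_no_decay(self):
        series = pd.DataFrame({"time_min": [0, 10, 20, 30], "fraction": [1.0] * 4})
        fit = fit_half_life(series)
        assert fit.no_decay and math.isinf(fit.t_half)

    def test_monte_carlo_recovery(self):
        medians = []
        df = simulate_decay_series(8.0, [0, 10, 20, 30], noise_cv=0.1, n_replicates=100, seed=9)
        fits = [fit_half_life(grp).t_half for _, grp in df.groupby("replicate")]
        assert abs(np.median(fits) - 8.0) / 8.0 < 0.10

    def test_bias_vanishes_with_noise(self):
        errors = []
        for cv in (0.2, 0.1, 0.05, 0.0):
            df = simulate_decay_series(10.0, [0, 10, 20, 30], noise_cv=cv, n_replicates=200, seed=10)
            fits = [fit_half_life(grp).t_half for _, grp in df.groupby("replicate")]
            errors.append(abs(np.median(fits) - 10.0))
        assert errors[-1] < 1e-9
        assert errors[-1] <= errors[0]

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            fit_half_life(pd.DataFrame({"time_min": [0, 10], "fraction": [1, 0.5]}))

    def test_nonpositive_fraction_rejected(self):
        with pytest.raises(ValueError):
            fit_half_life(pd.DataFrame({"time_min": [0, 10, 20], "fraction": [1, 0.5, 0.0]}))


class TestTwoTailedT:
    def test_identical_groups_p_one(self):
        t, p = two_tailed_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert math.isclose(p, 1.0)

    def test_extreme_separation_significant(self):
        t, p = two_tailed_t([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert p < 0.01
        assert significance_tier(p) == "***"

    def test_zero_variance_equal_means(self):
        t, p = two_tailed_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_matches_scipy_equal_variance(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 8)
        t, p = two_tailed_t(a, b)
        t2, p2 = stats.ttest_ind(a, b, equal_var=True)
        assert math.isclose(t, t2) and math.isclose(p, p2)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            two_tailed_t([1.0], [1.0, 2.0])

    def test_log2_mode_requires_positive(self):
        with pytest.raises(ValueError):
            two_tailed_t([1.0, -2.0], [1.0, 2.0], log2_transform=True)

    def test_tiers(self):
        assert significance_tier(0.2) == "ns"
        assert significance_tier(0.07) == "*"
        assert significance_tier(0.03) == "**"
        assert significance_tier(0.005) == "***"
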