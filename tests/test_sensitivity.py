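"""Tornado analysis, PSA distributions, CEAC and quadrant summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from flcea import (
    ceac,
    fit_beta,
    fit_gamma,
    nmb_outcome,
    one_way,
    quadrant_summary,
    run_psa,
    tornado,
)
from flcea.sensitivity import (
    DISCOUNT_RANGE,
    PSAResult,
    _one_way_bounds,
    base_value,
    apply_override,
    default_varied_parameters,
)


class TestOneWayBounds:
    def test_cost_bounds_pm_30pct(self):
        lo, hi = _one_way_bounds("cost.asct", 5000.0)
        assert (lo, hi) == (3500.0, 6500.0)

    def test_utility_bounds_pm_10pct(self):
        lo, hi = _one_way_bounds("utility.u_ffs", 0.88)
        assert lo == pytest.approx(0.792)
        assert hi == pytest.approx(0.968)

    def test_utility_bounds_clipped_to_unit_interval(self):
        lo, hi = _one_way_bounds("utility.u_ffs", 0.95)
        assert hi == 1.0

    def test_disutility_bounds_on_magnitude(self):
        lo, hi = _one_way_bounds("utility.d_systemic", -0.15)
        assert lo == pytest.approx(-0.165)
        assert hi == pytest.approx(-0.135)

    def test_discount_bounds(self):
        assert _one_way_bounds("config.discount_rate", 0.05) == DISCOUNT_RANGE

    def test_unknown_parameter_rejected(self, base_inputs):
        with pytest.raises(KeyError):
            base_value(base_inputs, "cost.nope")
        with pytest.raises(KeyError):
            apply_override(base_inputs, "nonsense.param", 1.0)


class TestOneWayModelRuns:
    def test_uninfluential_parameter_has_zero_bar(self, base_inputs):
        """The single-agent rituximab cycle price feeds no modelled pathway
        (no strategy uses rituximab monotherapy), so its tornado bar is
        exactly zero."""
        entry = one_way(base_inputs, "cost.drug_rituximab",
                        nmb_outcome("RT+R-CVP", "RT", 50_000))
        assert entry.bar_width == 0.0

    def test_influential_cost_moves_outcome_monotonically(self, base_inputs):
        """RT+R-CVP has fewer transplants than RT, so a dearer ASCT raises
        its incremental NMB: the bar must bracket the base case."""
        outcome = nmb_outcome("RT+R-CVP", "RT", 50_000)
        from flcea import run_all_strategies

        base = outcome(run_all_strategies(base_inputs))
        entry = one_way(base_inputs, "cost.asct", outcome)
        lo, hi = sorted([entry.outcome_at_low, entry.outcome_at_high])
        assert lo < base < hi
        assert entry.outcome_at_high > entry.outcome_at_low

    def test_tornado_sorted_by_bar_width(self, base_inputs):
        names = ["cost.asct", "cost.drug_rituximab", "utility.u_ffs",
                 "rate.RT.progression", "config.discount_rate"]
        entries = tornado(base_inputs, nmb_outcome("RT+R-CVP", "RT", 50_000),
                          names=names)
        widths = [e.bar_width for e in entries]
        assert widths == sorted(widths, reverse=True)
        assert {e.parameter for e in entries} == set(names)


class TestFittedDistributions:
    def test_gamma_moment_identities(self):
        d = fit_gamma(5000.0, 0.30)
        assert d.mean == pytest.approx(5000.0, abs=1e-9)
        assert d.sd == pytest.approx(0.30 * 5000 / 1.96, rel=1e-12)  # ~765.31
        assert d.shape == pytest.approx(1.96**2 / 0.30**2, rel=1e-12)  # ~42.68
        assert d.shape == pytest.approx(42.68, abs=5e-3)

    def test_gamma_requires_positive_mean(self):
        with pytest.raises(ValueError):
            fit_gamma(0.0)
        with pytest.raises(ValueError):
            fit_gamma(-10.0)

    def test_gamma_degenerate_limit(self):
        d = fit_gamma(5000.0, 0.0)
        assert d.mean == 5000.0 and d.sd == 0.0
        assert d.sample(np.random.default_rng(0)) == 5000.0

    def test_beta_moment_identities(self):
        d = fit_beta(0.88, 0.10)
        assert d.mean == pytest.approx(0.88, abs=1e-9)
        assert d.sd == pytest.approx(0.10 * 0.88 / 1.96, rel=1e-12)  # ~0.04490
        assert d.sd == pytest.approx(0.04490, abs=5e-6)
        assert d.alpha > 0 and d.beta > 0

    def test_beta_symmetry_at_half(self):
        d = fit_beta(0.5, 0.2)
        assert d.alpha == pytest.approx(d.beta, rel=1e-12)

    def test_beta_sd_capped_inside_feasible_region(self):
        d = fit_beta(0.9, 3.0)  # uncapped sd would exceed sqrt(m(1-m))
        assert d.alpha > 0 and d.beta > 0
        assert d.sd < math.sqrt(0.9 * 0.1)
        assert d.mean == pytest.approx(0.9, abs=1e-9)

    def test_beta_domain(self):
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                fit_beta(bad)


@pytest.fixture(scope="module")
def small_psa(base_inputs):
    return run_psa(base_inputs, n_iter=60, seed=123)


class TestPSA:
    def test_zero_spreads_collapse_to_base_case(self, base_inputs):
        from flcea import run_all_strategies

        psa = run_psa(
            base_inputs, n_iter=5, seed=1,
            spreads={"cost": 0.0, "probability": 0.0, "utility": 0.0},
        )
        base = {r.strategy: r for r in run_all_strategies(base_inputs)}
        for s in psa.strategies:
            assert np.allclose(psa.outcomes[f"cost_{s}"], base[s].cost)
            assert np.allclose(psa.outcomes[f"qaly_{s}"], base[s].qaly)

    def test_fixed_seed_reproducible(self, base_inputs):
        a = run_psa(base_inputs, n_iter=10, seed=7)
        b = run_psa(base_inputs, n_iter=10, seed=7)
        pd.testing.assert_frame_equal(a.params, b.params)
        pd.testing.assert_frame_equal(a.outcomes, b.outcomes)

    def test_sample_means_near_base_case(self, small_psa, base_inputs):
        """Each varied parameter's sample mean sits within 3 SE of its
        base-case value (the fitted distributions are mean-preserving; rates
        pick up a small convexity shift from the probability-scale mapping)."""
        n = small_psa.n_iter
        for name in small_psa.params.columns:
            base = base_value(base_inputs, name)
            col = small_psa.params[name]
            se = col.std(ddof=1) / math.sqrt(n)
            assert abs(col.mean() - base) < 3 * se + 0.02 * abs(base), name

    def test_no_rejections_on_fixture(self, small_psa):
        assert small_psa.n_rejected == 0

    def test_quadrant_fractions_sum_to_one(self, small_psa):
        frac = quadrant_summary(small_psa, "RT+R-CVP", "RT", 50_000)
        total = (frac["lower_right"] + frac["upper_right"]
                 + frac["lower_left"] + frac["upper_left"])
        assert total == pytest.approx(1.0, abs=1e-12)
        assert 0 <= frac["cost_effective"] <= 1

    def test_quadrant_enumeration_on_synthetic_draws(self):
        outcomes = pd.DataFrame(
            {
                "cost_A": [100.0, 100.0, 100.0, 100.0],
                "qaly_A": [1.0, 1.0, 1.0, 1.0],
                "cost_B": [90.0, 110.0, 90.0, 110.0],
                "qaly_B": [1.2, 1.2, 0.8, 0.8],
            }
        )
        psa = PSAResult(params=pd.DataFrame(index=range(4)),
                        outcomes=outcomes, strategies=("A", "B"))
        frac = quadrant_summary(psa, "B", "A", wtp=50.0)
        assert frac["lower_right"] == 0.25   # cheaper, more effective
        assert frac["upper_right"] == 0.25
        assert frac["lower_left"] == 0.25
        assert frac["upper_left"] == 0.25

    def test_all_identical_dominant_draws(self):
        outcomes = pd.DataFrame(
            {"cost_A": [100.0] * 3, "qaly_A": [1.0] * 3,
             "cost_B": [90.0] * 3, "qaly_B": [1.5] * 3}
        )
        psa = PSAResult(params=pd.DataFrame(index=range(3)),
                        outcomes=outcomes, strategies=("A", "B"))
        frac = quadrant_summary(psa, "B", "A", wtp=50_000.0)
        assert frac["lower_right"] == 1.0
        assert frac["cost_effective"] == 1.0

    def test_empty_samples_rejected(self):
        psa = PSAResult(params=pd.DataFrame(), outcomes=pd.DataFrame(),
                        strategies=("A", "B"))
        with pytest.raises(ValueError):
            quadrant_summary(psa, "A", "B", 50_000)


class TestCEAC:
    def test_probabilities_sum_to_one_on_fixture(self, base_inputs):
        psa = run_psa(base_inputs, n_iter=40, seed=5)
        curves = ceac(psa, wtp_grid=np.arange(0, 100_001, 12_500))
        sums = curves[list(psa.strategies)].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert ((curves[list(psa.strategies)] >= 0)
                & (curves[list(psa.strategies)] <= 1)).all().all()

    def test_single_strategy_probability_one(self):
        outcomes = pd.DataFrame({"cost_A": [10.0, 20.0], "qaly_A": [1.0, 2.0]})
        psa = PSAResult(params=pd.DataFrame(index=range(2)),
                        outcomes=outcomes, strategies=("A",))
        curves = ceac(psa, wtp_grid=[0, 50_000])
        assert (curves["A"] == 1.0).all()

    def test_deterministic_two_strategy_step_at_icer(self):
        """With identical draws, the winner flips exactly at the pairwise
        ICER: B costs 1000 more and gains 0.1 QALY, so ICER = 10,000."""
        outcomes = pd.DataFrame(
            {"cost_A": [0.0] * 5, "qaly_A": [1.0] * 5,
             "cost_B": [1000.0] * 5, "qaly_B": [1.1] * 5}
        )
        psa = PSAResult(params=pd.DataFrame(index=range(5)),
                        outcomes=outcomes, strategies=("A", "B"))
        curves = ceac(psa, wtp_grid=[5000, 9999, 10_000, 10_001, 20_000])
        assert curves.loc[curves.wtp == 5000, "A"].item() == 1.0
        assert curves.loc[curves.wtp == 9999, "A"].item() == 1.0
        # exact tie at the ICER: split equally
        assert curves.loc[curves.wtp == 10_000, "A"].item() == pytest.approx(0.5)
        assert curves.loc[curves.wtp == 10_001, "B"].item() == 1.0
        assert curves.loc[curves.wtp == 20_000, "B"].item() == 1.0

    def test_dominant_strategy_curve_non_decreasing(self, base_inputs):
        psa = run_psa(base_inputs, n_iter=40, seed=11)
        curves = ceac(psa, wtp_grid=np.arange(0, 100_001, 10_000))
        # RT+R-CVP gains the most QALYs; its acceptability must rise with WTP
        rcvp = curves["RT+R-CVP"].to_numpy()
        assert rcvp[-1] >= rcvp[0]

    def test_empty_grid_rejected(self, base_inputs):
        psa = run_psa(base_inputs, n_iter=3, seed=2)
        with pytest.raises(ValueError):
            ceac(psa, wtp_grid=[])


class TestDefaultVariedParameters:
    def test_zero_valued_parameters_held_fixed(self, base_inputs):
        names = default_varied_parameters(base_inputs)
        assert "ae.RT.admission_incidence" not in names  # base 0
        assert "ae.RT+CVP.admission_incidence" in names
        assert "rate.RT.progression" in names
        assert "cost.asct" in names
        assert "utility.d_systemic" in names
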