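"""Bias/RSD, LOD/LOQ, En comparison, precision and GUM propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cdbalance import (
    Chromatogram,
    bias_and_rsd,
    en_consistent,
    en_value,
    lod_loq,
    noise_sd_from_blank,
    precision_report,
    propagate_uncertainty,
    rsd,
)
from cdbalance.reference_data import PINS_MASS_FRACTIONS


class TestBiasAndRSD:
    def test_perfect_estimates(self):
        row = bias_and_rsd([1.0, 1.0, 1.0], 1.0)
        assert row.bias == 0.0 and row.rsd == 0.0

    def test_hand_computed_pair(self):
        row = bias_and_rsd([1.01, 0.99], 1.0)
        assert row.bias == pytest.approx(0.0, abs=1e-12)
        # sd = 0.01*sqrt(2), mean = 1.0 -> RSD = 1.41421...%
        assert row.rsd == pytest.approx(100 * 0.01 * math.sqrt(2), rel=1e-9)

    def test_reference_grid_rsd(self):
        values = [v for row in PINS_MASS_FRACTIONS for v in row]
        assert round(rsd(values), 1) == 1.5

    @settings(derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        base = bias_and_rsd([1.01, 0.98, 1.02], 1.0)
        scaled = bias_and_rsd([scale * 1.01, scale * 0.98, scale * 1.02], scale * 1.0)
        assert scaled.bias == pytest.approx(base.bias, rel=1e-9, abs=1e-9)
        assert scaled.rsd == pytest.approx(base.rsd, rel=1e-9)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            bias_and_rsd([1.0, 1.1], 0.0)


class TestLodLoq:
    def test_zero_noise(self):
        assert lod_loq(0.0, 100.0) == (0.0, 0.0)

    def test_direct_arithmetic(self):
        lod, loq = lod_loq(1.2, 1000.0)
        assert lod == pytest.approx(0.0036)
        assert loq == pytest.approx(0.012)

    @settings(derandomize=True)
    @given(
        noise=st.floats(min_value=1e-6, max_value=1e3),
        k=st.floats(min_value=1e-3, max_value=1e6),
    )
    def test_loq_is_ten_thirds_of_lod(self, noise, k):
        lod, loq = lod_loq(noise, k)
        assert loq == pytest.approx(lod * 10.0 / 3.0, rel=1e-12)

    def test_zero_sensitivity_rejected(self):
        with pytest.raises(ValueError):
            lod_loq(1.0, 0.0)

    def test_blank_noise_estimator_ignores_drift(self, rng):
        t = np.arange(0, 5, 0.005)
        noise = 0.05 * rng.standard_normal(t.shape)
        cd = 3.0 + 0.5 * t + noise  # strong drift, known point noise
        chrom = Chromatogram(time=t, dad=np.zeros_like(t), cd=cd)
        est = noise_sd_from_blank(chrom, "cd")
        assert est == pytest.approx(0.05, rel=0.2)


class TestEnValue:
    def test_identical_results(self):
        assert en_value(1.0, 0.1, 1.0, 0.2) == 0.0

    def test_direct_arithmetic(self):
        assert en_value(1.0, 0.1, 0.9, 0.1) == pytest.approx(0.70710678, rel=1e-6)

    def test_published_comparison_recomputes_below_one(self):
        """The LC-CD vs IDMS insulin comparison (0.922±0.035 vs 0.892±0.036)
        recomputes to En = 0.597: the two methods agree (En < 1)."""
        en = en_value(0.922, 0.035, 0.892, 0.036)
        assert en == pytest.approx(0.5975, abs=5e-4)
        assert en_consistent(0.922, 0.035, 0.892, 0.036)

    @settings(derandomize=True)
    @given(
        xa=st.floats(-10, 10), xb=st.floats(-10, 10),
        ua=st.floats(0.01, 5), ub=st.floats(0.01, 5),
    )
    def test_symmetry(self, xa, xb, ua, ub):
        assert en_value(xa, ua, xb, ub) == pytest.approx(en_value(xb, ub, xa, ua))

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            en_value(1.0, 0.0, 2.0, 0.0)


class TestPropagation:
    def test_zero_input_uncertainties(self):
        res = propagate_uncertainty(lambda a, b: a * b, {"a": 2.0, "b": 3.0}, {})
        assert res.value == 6.0 and res.combined == 0.0
        assert res.expanded == 0.0

    def test_product_quadrature(self):
        """1% relative uncertainty on each factor -> sqrt(2)% combined."""
        res = propagate_uncertainty(
            lambda a, b: a * b, {"a": 2.0, "b": 5.0}, {"a": 0.02, "b": 0.05}
        )
        assert res.combined / res.value == pytest.approx(0.01 * math.sqrt(2), rel=1e-4)
        assert res.expanded == pytest.approx(2 * res.combined)

    def test_linear_function_is_exact(self):
        res = propagate_uncertainty(
            lambda x, y: 3.0 * x - 2.0 * y, {"x": 1.0, "y": 2.0}, {"x": 0.1, "y": 0.2}
        )
        assert res.combined == pytest.approx(math.hypot(0.3, 0.4), rel=1e-6)

    def test_taylor_and_monte_carlo_agree_on_conversion_equation(self):
        def mass_fraction_fn(c_l, m_protein, m_total, m_diluted, m_sample, n_phe, m_phe, m_solid):
            return (c_l / 1000.0) * m_protein * m_total * m_diluted / (
                m_sample * n_phe * m_phe * m_solid
            )

        values = dict(c_l=0.172, m_protein=5777.5, m_total=1100.0, m_diluted=1000.0,
                      m_sample=200.0, n_phe=3.0, m_phe=165.19, m_solid=12.0)
        uncert = {k: 0.01 * abs(v) for k, v in values.items() if k != "n_phe"}
        taylor = propagate_uncertainty(mass_fraction_fn, values, uncert, method="taylor")
        n_draws = 20_000
        mc = propagate_uncertainty(
            mass_fraction_fn, values, uncert, method="mc", n_draws=n_draws, seed=7
        )
        # SE of an SD estimate from n normal draws ~ sd / sqrt(2(n-1))
        se = mc.combined / math.sqrt(2 * (n_draws - 1))
        assert abs(taylor.combined - mc.combined) < 3 * se

    def test_budget_lists_contributions(self):
        res = propagate_uncertainty(
            lambda a, b: a + b, {"a": 1.0, "b": 2.0}, {"a": 0.1, "b": 0.0}
        )
        budget = res.budget.set_index("input")
        assert budget.loc["a", "contribution"] == pytest.approx(0.1, rel=1e-6)
        assert budget.loc["b", "contribution"] == 0.0

    def test_negative_uncertainty_rejected(self):
        with pytest.raises(ValueError):
            propagate_uncertainty(lambda a: a, {"a": 1.0}, {"a": -0.1})


class TestPrecision:
    def test_identical_values_give_zero_rsds(self):
        rep = precision_report({"d1": [1.0, 1.0], "d2": [1.0, 1.0]})
        assert all(v == 0.0 for v in rep.per_group.values())
        assert rep.overall == 0.0

    def test_reference_grid_overall(self):
        groups = {f"vial{i}": row for i, row in enumerate(PINS_MASS_FRACTIONS)}
        rep = precision_report(groups)
        assert round(rep.overall, 1) == 1.5

    def test_two_day_hand_computation(self):
        d1, d2 = [10.0, 10.2], [9.8, 10.4]
        rep = precision_report({"d1": d1, "d2": d2})
        assert rep.per_group["d1"] == pytest.approx(rsd(d1))
        assert rep.per_group["d2"] == pytest.approx(rsd(d2))
        assert rep.overall == pytest.approx(rsd(d1 + d2))
        assert rep.between_group == pytest.approx(rsd([np.mean(d1), np.mean(d2)]))

    def test_insufficient_replication_rejected(self):
        with pytest.raises(ValueError):
            precision_report({"d1": [1.0, 1.1]})
        with pytest.raises(ValueError):
            precision_report({"d1": [1.0, 1.1], "d2": [1.0]})
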