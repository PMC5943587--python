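"""The chiral-balance signal model and its three inverses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cdbalance import (
    BracketStandards,
    CDMeasurement,
    DetectorModel,
    EnantiomerMix,
    bracket_detector,
    cd_signal,
    solve_bracket,
    solve_direct_titration,
    solve_single_point,
)

conc = st.floats(min_value=0.0, max_value=10.0, allow_nan=False)
pos_conc = st.floats(min_value=1e-4, max_value=10.0, allow_nan=False)
sens = st.floats(min_value=0.1, max_value=1e4, allow_nan=False)
offset = st.floats(min_value=-10.0, max_value=10.0, allow_nan=False)


def make_brackets(low_mix, high_mix, det):
    return BracketStandards(
        low=(low_mix, CDMeasurement(cd_signal(low_mix, det))),
        high=(high_mix, CDMeasurement(cd_signal(high_mix, det))),
    )


class TestCDSignal:
    @settings(derandomize=True)
    @given(c=conc, k=sens)
    def test_racemate_reads_zero(self, c, k):
        """Equal enantiomer amounts balance the detector to exactly zero."""
        assert cd_signal(EnantiomerMix(c, c), DetectorModel(k=k)) == 0.0

    @settings(derandomize=True)
    @given(c_l=conc, c_d=conc, k=sens)
    def test_additivity_of_enantiomer_signals(self, c_l, c_d, k):
        """Mixture signal is the sum of each enantiomer's own signal (b=0)."""
        det = DetectorModel(k=k)
        whole = cd_signal(EnantiomerMix(c_l, c_d), det)
        parts = cd_signal(EnantiomerMix(c_l, 0.0), det) + cd_signal(
            EnantiomerMix(0.0, c_d), det
        )
        assert whole == pytest.approx(parts, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize(
        "c_l, c_d, k, b, expected",
        [
            (0.1, 0.0, 1.0, 0.0, 0.1),
            (0.06, 0.05, 200.0, 0.5, 2.5),
        ],
    )
    def test_worked_examples(self, c_l, c_d, k, b, expected):
        assert cd_signal(EnantiomerMix(c_l, c_d), DetectorModel(k=k, b=b)) == pytest.approx(
            expected
        )

    def test_rejects_non_finite_concentration(self):
        with pytest.raises(ValueError):
            EnantiomerMix(float("nan"), 0.0)
        with pytest.raises(ValueError):
            CDMeasurement(float("inf"))


class TestSinglePoint:
    def test_null_signal_returns_internal_standard_level(self):
        """Zero sample signal means the pans balance: c_L equals c_D2."""
        std = EnantiomerMix(0.10, 0.05)
        assert solve_single_point(0.0, 1.0, std, sample_c_d=0.05) == 0.05

    def test_sample_identical_to_standard(self):
        std = EnantiomerMix(0.10, 0.05)
        assert solve_single_point(1.7, 1.7, std, sample_c_d=0.05) == pytest.approx(0.10)

    def test_round_trip_inverts_signal_model(self):
        det = DetectorModel(k=150.0, b=0.0)
        std = EnantiomerMix(0.10, 0.05)
        truth = EnantiomerMix(0.0794, 0.05)
        i_std = cd_signal(std, det)
        i = cd_signal(truth, det)
        est = solve_single_point(i, i_std, std, sample_c_d=0.05)
        assert est == pytest.approx(0.0794, rel=1e-12)

    def test_linearity_in_sample_intensity(self):
        std = EnantiomerMix(0.10, 0.05)
        vals = [solve_single_point(i, 2.0, std, 0.05) for i in (0.0, 1.0, 2.0)]
        assert vals[1] - vals[0] == pytest.approx(vals[2] - vals[1], rel=1e-12)

    def test_degenerate_standards_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            solve_single_point(1.0, 0.0, EnantiomerMix(0.1, 0.05), 0.05)
        with pytest.raises(ValueError, match="degenerate"):
            solve_single_point(1.0, 1.0, EnantiomerMix(0.05, 0.05), 0.05)


class TestBracket:
    def test_sample_coinciding_with_low_standard(self):
        det = DetectorModel(k=3.0, b=0.2)
        low = EnantiomerMix(0.04, 0.05)
        high = EnantiomerMix(0.06, 0.05)
        br = make_brackets(low, high, det)
        est = solve_bracket(br.low[1], br, sample_c_d=0.05)
        assert est == pytest.approx(low.c_l, rel=1e-12)

    def test_worked_example_with_offset(self):
        det = DetectorModel(k=2.0, b=0.1)
        low = EnantiomerMix(0.04, 0.05)    # delta -0.01 -> I1 = 0.08
        high = EnantiomerMix(0.06, 0.05)   # delta +0.01 -> I2 = 0.12
        br = make_brackets(low, high, det)
        assert br.low[1].intensity == pytest.approx(0.08)
        assert br.high[1].intensity == pytest.approx(0.12)
        est = solve_bracket(0.108, br, sample_c_d=0.05)  # sample delta 0.004
        assert est == pytest.approx(0.054, rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(c_l=pos_conc, c_d=conc, k=sens, b=offset, span=st.floats(0.01, 0.5))
    def test_offset_invariant_round_trip(self, c_l, c_d, k, b, span):
        """The bracket cancels any constant detector offset exactly."""
        truth = EnantiomerMix(c_l + c_d, c_d)  # keep delta = c_l > 0
        det = DetectorModel(k=k, b=b)
        low = EnantiomerMix(c_d + (1 - span) * truth.delta, c_d)
        high = EnantiomerMix(c_d + (1 + span) * truth.delta, c_d)
        br = make_brackets(low, high, det)
        est = solve_bracket(cd_signal(truth, det), br, sample_c_d=c_d)
        assert est == pytest.approx(truth.c_l, rel=1e-10, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(c_l=pos_conc, c_d=conc, k=sens)
    def test_agrees_with_single_point_when_unoffset(self, c_l, c_d, k):
        """With b=0 standards, bracket and single-point give the same answer."""
        truth = EnantiomerMix(c_l + c_d, c_d)
        det = DetectorModel(k=k, b=0.0)
        low = EnantiomerMix(c_d + 0.5 * truth.delta, c_d)
        high = EnantiomerMix(c_d + 1.5 * truth.delta, c_d)
        br = make_brackets(low, high, det)
        i = cd_signal(truth, det)
        est_br = solve_bracket(i, br, c_d)
        est_sp = solve_single_point(i, cd_signal(low, det), low, c_d)
        assert est_br == pytest.approx(est_sp, rel=1e-12, abs=1e-12)

    def test_fitted_detector_recovers_k_and_b(self):
        det = DetectorModel(k=37.5, b=-1.25)
        br = make_brackets(EnantiomerMix(0.04, 0.05), EnantiomerMix(0.07, 0.05), det)
        fit = bracket_detector(br)
        assert fit.k == pytest.approx(det.k, rel=1e-12)
        assert fit.b == pytest.approx(det.b, rel=1e-12, abs=1e-12)

    def test_unresolvable_bracket_rejected(self):
        with pytest.raises(ValueError):
            BracketStandards(
                low=(EnantiomerMix(0.04, 0.05), CDMeasurement(1.0)),
                high=(EnantiomerMix(0.06, 0.05), CDMeasurement(1.0)),
            )
        with pytest.raises(ValueError):
            BracketStandards(
                low=(EnantiomerMix(0.5, 0.25), CDMeasurement(1.0)),
                high=(EnantiomerMix(0.75, 0.5), CDMeasurement(2.0)),
            )


class TestDirectTitration:
    def test_symmetric_sign_change_midpoint(self):
        fit = solve_direct_titration([(0.04, 0.02), (0.06, -0.02)])
        assert fit.c_l == pytest.approx(0.05, rel=1e-12)

    def test_round_trip_on_noise_free_series(self):
        det = DetectorModel(k=100.0)
        truth = 0.0793
        series = [
            (c_d, cd_signal(EnantiomerMix(truth, c_d), det))
            for c_d in (0.05, 0.06, 0.07, 0.08, 0.09, 0.10)
        ]
        fit = solve_direct_titration(series)
        assert fit.c_l == pytest.approx(truth, rel=1e-10)
        assert fit.slope == pytest.approx(-det.k, rel=1e-10)

    def test_constant_offset_shifts_estimate_by_b_over_k(self):
        det = DetectorModel(k=100.0)
        b = 0.37
        truth = 0.0793
        c_ds = (0.05, 0.06, 0.07, 0.08, 0.09, 0.10)
        clean = [(c, cd_signal(EnantiomerMix(truth, c), det)) for c in c_ds]
        shifted = [(c, i + b) for c, i in clean]
        est0 = solve_direct_titration(clean).c_l
        est1 = solve_direct_titration(shifted).c_l
        assert est1 - est0 == pytest.approx(b / det.k, rel=1e-9)

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            solve_direct_titration([(0.05, 1.0), (0.05, 2.0)])
        with pytest.raises(ValueError):
            solve_direct_titration([(0.05, 1.0)])
        with pytest.raises(ValueError, match="slope"):
            solve_direct_titration([(0.04, 1.0), (0.06, 1.0)])
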