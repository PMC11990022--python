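"""HOMA/QUICKI formulas, reference-range flagging, and panel invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycendo import (DEFAULT_REFERENCE_RANGES, FastingSample, Flag, ReferenceRange,
                      compute_panel, homa_beta, homa_ir, homa_is, quicki,
                      quicki_from_homa_ir, spina_parameters)

sample_st = st.builds(
    FastingSample,
    glucose=st.floats(1.5, 20.0),
    insulin=st.floats(5.0, 1500.0),
)


def test_homa_ir_normalisation_point():
    # glucose 4.5 mmol/L and insulin 5 µIU/mL is the unit point of the formula
    assert homa_ir(FastingSample(4.5, 5 * 6.945)) == pytest.approx(1.0)


def test_homa_ir_hand_computed():
    assert homa_ir(FastingSample(5.1, 97.2)) == pytest.approx(5.1 * (97.2 / 6.945) / 22.5)
    assert homa_ir(FastingSample(5.1, 97.2)) == pytest.approx(3.172, abs=5e-4)


@pytest.mark.parametrize("ir,expected_2dp", [(1.0, 1.0), (3.47, 0.29), (2.57, 0.39)])
def test_homa_is_reciprocal_of_published_medians(ir, expected_2dp):
    assert round(1.0 / ir, 2) == pytest.approx(expected_2dp)


def test_homa_beta():
    assert homa_beta(FastingSample(4.5, 5 * 6.945)) == pytest.approx(100.0)
    assert homa_beta(FastingSample(5.1, 97.2)) == pytest.approx(20 * (97.2 / 6.945) / 1.6)
    assert homa_beta(FastingSample(3.5, 97.2)) is None  # zero denominator


def test_quicki_log_powers_of_ten():
    # 100 mg/dL and 10 µIU/mL -> log10 sum = 3
    s = FastingSample(100 / 18.0, 10 * 6.945)
    assert quicki(s) == pytest.approx(1 / 3)


@pytest.mark.parametrize("ir,expected_2dp", [(3.47, 0.32), (2.57, 0.33), (7.3, 0.29)])
def test_quicki_matches_published_medians_via_homa_identity(ir, expected_2dp):
    assert round(quicki_from_homa_ir(ir), 2) == pytest.approx(expected_2dp)


def test_quicki_identity_with_direct_formula():
    s = FastingSample(5.1, 97.2)
    assert quicki(s) == pytest.approx(quicki_from_homa_ir(homa_ir(s)), rel=1e-12)


def test_zero_insulin_not_evaluable():
    panel = compute_panel(FastingSample(5.0, 0.0))
    assert panel.homa_ir is None and panel.homa_is is None and panel.quicki is None
    assert panel.spina_gr is None and panel.spina_di is None
    assert panel.flags["homa_ir"] is Flag.NOT_EVALUABLE


@settings(max_examples=200, deadline=None, derandomize=True)
@given(sample_st)
def test_reciprocity_and_positivity(sample):
    ir, is_ = homa_ir(sample), homa_is(sample)
    assert ir > 0 and is_ > 0
    assert abs(is_ * ir - 1.0) <= 1e-12 * max(1.0, is_ * ir)


def test_reciprocity_and_monotone_link_bulk():
    """HOMA-IS·HOMA-IR = 1 and QUICKI reverses the HOMA-IR ordering,
    over 10,000 random fasting samples."""
    rng = np.random.default_rng(12345)
    glucose = rng.uniform(1.5, 20.0, 10_000)
    insulin = np.exp(rng.normal(4.5, 0.9, 10_000)).clip(2.0, 2500.0)
    samples = [FastingSample(g, i) for g, i in zip(glucose, insulin)]
    ir = np.array([homa_ir(s) for s in samples])
    is_ = np.array([homa_is(s) for s in samples])
    qk = np.array([quicki(s) for s in samples])
    assert np.all(np.abs(ir * is_ - 1.0) < 1e-12)
    order_ir = np.argsort(ir)
    order_qk = np.argsort(qk)
    assert np.array_equal(order_ir, order_qk[::-1])


def test_median_commutation_for_odd_cohorts():
    """For odd n, the cohort median QUICKI is QUICKI of the median HOMA-IR —
    the mechanism behind the cross-table reciprocal consistency."""
    rng = np.random.default_rng(3)
    ir = np.exp(rng.normal(1.0, 0.5, 101))
    qk = np.array([quicki_from_homa_ir(v) for v in ir])
    assert np.median(qk) == pytest.approx(quicki_from_homa_ir(np.median(ir)), rel=1e-12)


@pytest.mark.parametrize("index,value,expected", [
    ("homa_ir", 2.5, Flag.ABOVE),       # "<2.5" is strict: 2.5 is not within
    ("homa_ir", 2.49, Flag.WITHIN),
    ("homa_is", 0.4, Flag.BELOW),       # ">0.4" strict
    ("homa_is", 0.41, Flag.WITHIN),
    ("quicki", 0.32, Flag.BELOW),
    ("spina_di", 5.0, Flag.WITHIN),
    ("spina_di", 4.01, Flag.WITHIN),    # two-sided ranges are closed
    ("spina_di", 7.66, Flag.ABOVE),
    ("spina_gbeta", 0.5, Flag.BELOW),
])
def test_reference_flag_boundary_semantics(index, value, expected):
    assert DEFAULT_REFERENCE_RANGES[index].flag(value) is expected


def test_reference_range_orientation_validated():
    with pytest.raises(ValueError):
        ReferenceRange("x", lower=2.0, upper=1.0)


def test_healthy_grid_never_flags_all_spina_above():
    """On a physiological (glucose, insulin) grid, the three SPINA indices are
    never simultaneously above their reference ranges: high receptor gain
    requires low insulin while high secretion requires high insulin."""
    for g in np.linspace(3.0, 8.0, 11):
        for i in np.linspace(20.0, 200.0, 10):
            panel = compute_panel(FastingSample(float(g), float(i)))
            flags = {panel.flags[k] for k in ("spina_gbeta", "spina_gr", "spina_di")}
            assert flags != {Flag.ABOVE}


def test_homa_beta_has_no_reference_range_flag():
    panel = compute_panel(FastingSample(5.1, 97.2))
    assert panel.flags["homa_beta"] is Flag.NOT_EVALUABLE
    assert panel.homa_beta is not None


def test_spina_gbeta_vanishes_with_insulin():
    # secretory capacity is proportional to equilibrium insulin
    gbeta_small, _, _ = spina_parameters(FastingSample(5.0, 1e-6))
    gbeta_tiny, _, _ = spina_parameters(FastingSample(5.0, 1e-8))
    assert gbeta_small == pytest.approx(0.0, abs=1e-6)
    assert gbeta_tiny == pytest.approx(gbeta_small / 100.0, rel=1e-9)


def test_panel_finite_and_positive_for_valid_samples():
    rng = np.random.default_rng(7)
    for _ in range(200):
        s = FastingSample(float(rng.uniform(3.6, 9.0)), float(rng.uniform(10, 400)))
        panel = compute_panel(s)
        for name, v in panel.as_dict().items():
            assert v is not None and math.isfinite(v) and v > 0, name
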