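"""SMR quantile, rolling/routine MMR, aerobic scope and Q10 tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ectophys as ep
from ectophys.trace import Phase, RawTrace, TraceMeta

COND = ep.WaterConditions(2.0, 33.0)


def _records(values, t0=16.0):
    return [ep.MO2Record(time_h=t0 + i, mo2=v) for i, v in enumerate(values)]


# --- SMR --------------------------------------------------------------------


def test_constant_series_gives_that_smr_for_any_q():
    recs = _records([0.38] * 20)
    for q in (0.1, 0.2, 0.5, 0.9):
        assert ep.estimate_smr(recs, q=q, exclusion_window_h=15.0).value == pytest.approx(0.38)


def test_quantile_matches_hand_interpolation():
    # sorted {0.30,0.35,0.40,0.45,0.50}: h = (n-1)q = 0.8 -> 0.30 + 0.8*0.05
    recs = _records([0.45, 0.30, 0.50, 0.35, 0.40])
    est = ep.estimate_smr(recs, q=0.2, exclusion_window_h=15.0, min_n=5)
    assert est.value == pytest.approx(0.34)
    assert est.n_used == 5


def test_exclusion_window_drops_early_records():
    recs = _records([5.0] * 10, t0=1.0) + _records([0.4] * 12, t0=20.0)
    est = ep.estimate_smr(recs, exclusion_window_h=15.0)
    assert est.value == pytest.approx(0.4)
    assert est.n_used == 12


def test_insufficient_records_raises():
    with pytest.raises(ValueError, match="insufficient accepted slopes"):
        ep.estimate_smr(_records([0.4] * 5), exclusion_window_h=15.0, min_n=10)


@given(q1=st.floats(0.05, 0.45), q2=st.floats(0.5, 0.95))
def test_smr_quantile_monotone_in_q(q1, q2):
    rng = np.random.default_rng(0)
    recs = _records(rng.uniform(0.3, 0.6, 40).tolist())
    a = ep.estimate_smr(recs, q=q1, exclusion_window_h=15.0).value
    b = ep.estimate_smr(recs, q=q2, exclusion_window_h=15.0).value
    assert a <= b


def test_smr_q_to_zero_approaches_minimum():
    rng = np.random.default_rng(1)
    vals = rng.uniform(0.3, 0.6, 40)
    recs = _records(vals.tolist())
    est = ep.estimate_smr(recs, q=0.001, exclusion_window_h=15.0)
    assert est.value == pytest.approx(vals.min(), rel=1e-2)


def test_exclusion_window_lookup_by_oxygen_level():
    assert ep.exclusion_window_for(100.0) == 15.0
    assert ep.exclusion_window_for(35.0) == 24.0
    assert ep.exclusion_window_for(35.0, override=10.0) == 10.0


def test_epoc_contamination_biases_unexcluded_smr_upward():
    """With EPOC decaying inside 10 h, a 15-h window recovers SMR but a 0-h
    window inflates it."""
    cfg = ep.TraceSimConfig(
        epoc_tau=1.5, noise_sd=0.0, burst_rate=0.0,
        background_intercept=0.0, background_slope=0.0,
        acclimation_elevation=0.0, total_duration=40.0, seed=2,
    )
    trace, truth = ep.simulate_do_trace(cfg)
    from ectophys.pipeline import process_trace

    records = process_trace(trace).records
    with_window = ep.estimate_smr(records, exclusion_window_h=15.0).value
    without = ep.estimate_smr(records, exclusion_window_h=0.0).value
    assert abs(with_window - truth.smr) / truth.smr < 0.03
    assert without > with_window


# --- MMR --------------------------------------------------------------------


def _long_trace(do, dt=1.0):
    t = np.arange(len(do), dtype=float) * dt
    return RawTrace(
        t, do, [Phase("long_closed", 0.0, len(do) * dt)],
        TraceMeta(mass_g=8.0, volume_ml=300.0, temperature_c=2.0, salinity=33.0),
    )


def test_linear_long_phase_rolling_equals_global_slope():
    slope = -0.0145
    tr = _long_trace(100.0 + slope * np.arange(1200.0))
    est = ep.rolling_mmr(tr, tr.phases[0], COND, 300.0, 8.0)
    expected = ep.slope_to_mo2(slope, COND, 300.0, 8.0)
    assert est.value == pytest.approx(expected, rel=1e-9)
    assert est.source == "post_chase_rolling"


def test_piecewise_trace_steepest_window_inside_steep_piece():
    t = np.arange(1200.0)
    do = np.where(t < 300, 100.0 - 0.02 * t, 94.0 - 0.01 * (t - 300))
    tr = _long_trace(do)
    est = ep.rolling_mmr(tr, tr.phases[0], COND, 300.0, 8.0)
    expected = ep.slope_to_mo2(-0.02, COND, 300.0, 8.0)
    assert est.value == pytest.approx(expected, rel=1e-9)


def test_window_equal_to_phase_length_degenerates_to_single_regression():
    rng = np.random.default_rng(4)
    do = 100.0 - 0.01 * np.arange(600.0) + rng.normal(0, 0.1, 600)
    tr = _long_trace(do)
    est = ep.rolling_mmr(tr, tr.phases[0], COND, 300.0, 8.0, window_s=600.0)
    fit = ep.fit_phase_slope(tr, tr.phases[0], measurement_window=600.0)
    expected = ep.slope_to_mo2(fit, COND, 300.0, 8.0)
    assert est.value == pytest.approx(expected, rel=1e-6)


def test_short_phase_yields_no_candidate():
    tr = _long_trace(100.0 - 0.01 * np.arange(100.0))
    assert ep.rolling_mmr(tr, tr.phases[0], COND, 300.0, 8.0, window_s=180.0) is None


def test_routine_max_picks_highest():
    est = ep.routine_max_mo2(_records([0.3, 0.9, 0.5]))
    assert est.value == pytest.approx(0.9)
    assert est.source == "routine_max"


def test_routine_max_all_equal():
    assert ep.routine_max_mo2(_records([0.4] * 5)).value == pytest.approx(0.4)


def test_burst_to_mmr_in_regular_cycle_recovered_by_routine_max():
    # a forced full-magnitude burst covering a whole regular closed phase:
    # cycle 96 is sealed over [99660, 100320) s
    cfg = ep.TraceSimConfig(
        noise_sd=0.0, burst_rate=0.0, background_intercept=0.0,
        background_slope=0.0, total_duration=30.0,
        forced_bursts=[(99650.0, 700.0, 1.0)], seed=0,
    )
    trace, truth = ep.simulate_do_trace(cfg)
    from ectophys.pipeline import process_trace

    routine = ep.routine_max_mo2(process_trace(trace).records)
    assert routine.value == pytest.approx(truth.mmr, rel=0.02)


def _mmr(v, source="post_chase_rolling"):
    return ep.MMREstimate(value=v, source=source)


def test_select_mmr_prefers_larger_value():
    sel = ep.select_mmr(_mmr(1.66), _mmr(1.20, "routine_max"))
    assert sel.value == 1.66 and sel.source == "post_chase_rolling"
    sel = ep.select_mmr(_mmr(1.2), _mmr(1.8, "routine_max"))
    assert sel.value == 1.8 and sel.source == "routine_max"


def test_select_mmr_tie_prefers_post_chase():
    sel = ep.select_mmr(_mmr(1.5), _mmr(1.5, "routine_max"))
    assert sel.source == "post_chase_rolling"


def test_select_mmr_requires_a_candidate():
    with pytest.raises(ValueError):
        ep.select_mmr(None, None)
    assert ep.select_mmr(None, _mmr(1.0, "routine_max")).value == 1.0


# --- aerobic scope and Q10 --------------------------------------------------


def test_aerobic_scope_difference():
    smr = ep.SMREstimate(0.38, 0.2, 20, 15.0)
    assert ep.aerobic_scope(_mmr(1.66), smr) == pytest.approx(1.28)


def test_mean_scope_equals_difference_of_means():
    rng = np.random.default_rng(6)
    smrs = rng.uniform(0.3, 0.5, 30)
    mmrs = smrs + rng.uniform(0.5, 1.5, 30)
    scopes = [
        ep.aerobic_scope(_mmr(m), ep.SMREstimate(s, 0.2, 20, 15.0))
        for s, m in zip(smrs, mmrs)
    ]
    assert np.mean(scopes) == pytest.approx(np.mean(mmrs) - np.mean(smrs))


def test_as_from_routine_source_invariant_to_uptake_offset():
    """Shifting every record by a constant moves SMR and routine MMR equally."""
    rng = np.random.default_rng(7)
    vals = rng.uniform(0.3, 0.9, 40).tolist()
    for offset in (0.0, 0.25):
        recs = _records([v + offset for v in vals])
        smr = ep.estimate_smr(recs, exclusion_window_h=15.0)
        mmr = ep.routine_max_mo2(recs)
        if offset == 0.0:
            base = ep.aerobic_scope(mmr, smr)
        else:
            assert ep.aerobic_scope(mmr, smr) == pytest.approx(base)


def test_q10_identities():
    assert ep.q10(0.5, 0.5, 2.0, 10.0).q10 == pytest.approx(1.0)
    assert ep.q10(0.4, 0.9, 2.0, 12.0).q10 == pytest.approx(0.9 / 0.4)


def test_q10_errors():
    with pytest.raises(ValueError):
        ep.q10(0.4, 0.5, 10.0, 2.0)
    with pytest.raises(ValueError):
        ep.q10(0.0, 0.5, 2.0, 10.0)


@given(
    r1=st.floats(0.1, 2.0), r2=st.floats(0.1, 2.0), r3=st.floats(0.1, 2.0),
    t2=st.floats(4.0, 8.0),
)
def test_q10_transitivity(r1, r2, r3, t2):
    """(R3/R1)^(10/(T3−T1)) equals the geometric combination of the two legs
    weighted by their temperature spans."""
    t1, t3 = 2.0, 10.0
    q13 = ep.q10(r1, r3, t1, t3).q10
    q12 = ep.q10(r1, r2, t1, t2).q10
    q23 = ep.q10(r2, r3, t2, t3).q10
    combined = (q12 ** (t2 - t1) * q23 ** (t3 - t2)) ** (1.0 / (t3 - t1))
    assert q13 == pytest.approx(combined, rel=1e-9)


# --- QC ---------------------------------------------------------------------


def _summary(smr_v=0.38, mmr_v=1.66):
    return ep.MetabolicSummary(
        animal_id="a", treatment="2C", wet_mass=8.4,
        smr=ep.SMREstimate(smr_v, 0.2, 20, 15.0),
        mmr=_mmr(mmr_v),
        aerobic_scope=mmr_v - smr_v,
    )


def test_clean_animal_has_no_flags():
    recs = _records([0.38 + 0.01 * (i % 3) for i in range(20)])
    flags = ep.qc_animal(_summary(), records=recs, post_chase=_mmr(1.6))
    assert flags == set()


def test_failed_exercise_response_flagged():
    flags = ep.qc_animal(_summary(), post_chase=_mmr(0.40))
    assert "no_exercise_response" in flags


def test_unstable_low_mo2_flagged():
    rng = np.random.default_rng(8)
    recs = _records((0.4 + rng.exponential(0.4, 30)).tolist())
    flags = ep.qc_animal(_summary(), records=recs)
    assert "no_stable_low_mo2" in flags


def test_external_death_flag_passes_through():
    flags = ep.qc_animal(_summary(), external_flags={"death"})
    assert "death" in flags
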