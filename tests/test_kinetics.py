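"""Closed-form kinetics vs an independent ODE oracle, plus the structural
invariants (linearity, continuity, accumulation)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import voripk as v
from voripk.kinetics import DoseEvent, Regimen, steady_state_trough

from oracles import ode_profile


def test_zero_dose_and_zero_tau_give_zero(typical_params):
    assert v.conc_oral_single(0.0, 7.3, typical_params) == 0.0
    assert v.conc_oral_single(200.0, 0.0, typical_params) == 0.0
    assert v.conc_infusion_single(200.0, 1.0, 0.0, typical_params) == 0.0


def test_continuous_infusion_reaches_plateau(typical_params):
    """Mass balance: an unending infusion plateaus at R0/CL."""
    r0 = 200.0  # mg/h for a very long infusion
    c = v.conc_infusion_single(r0 * 5000, 5000.0, 4000.0, typical_params)
    assert c == pytest.approx(r0 / typical_params.CL, rel=1e-8)


def test_oral_single_dose_matches_ode_oracle(typical_params):
    c = v.conc_oral_single(200.0, 12.0, typical_params)
    ref = ode_profile([DoseEvent(0, 200, "oral")], 12.0, typical_params)
    assert c == pytest.approx(ref, rel=1e-8)


def test_infusion_single_dose_matches_ode_oracle(typical_params):
    c = v.conc_infusion_single(200.0, 1.0, 24.0, typical_params)
    ref = ode_profile([DoseEvent(0, 200, "iv_infusion", 1.0)], 24.0,
                      typical_params)
    assert c == pytest.approx(ref, rel=1e-8)


def test_full_regimen_profile_matches_ode_oracle(typical_params):
    reg = v.make_regimen(250, 100, "iv", duration=168.0)
    events = reg.events()
    c = v.conc_profile(events, 168.0, typical_params)
    ref = ode_profile(events, 168.0, typical_params)
    assert c == pytest.approx(ref, rel=1e-7)


def test_random_schedules_match_ode_oracle():
    """Closed form vs stiff-ODE integration on random parameter and
    schedule draws (relative error <= 1e-6)."""
    rng = np.random.default_rng(11)
    for _ in range(100):
        p = v.IndividualParams(
            CL=float(rng.uniform(0.5, 20)), V=float(rng.uniform(20, 200)),
            Ka=float(rng.uniform(0.3, 3)), F=float(rng.uniform(0.3, 1.0)))
        events = []
        t0 = 0.0
        for _ in range(rng.integers(1, 5)):
            if rng.random() < 0.5:
                events.append(DoseEvent(t0, float(rng.uniform(50, 400)),
                                        "oral"))
            else:
                events.append(DoseEvent(t0, float(rng.uniform(50, 400)),
                                        "iv_infusion",
                                        float(rng.uniform(0.5, 2.0))))
            t0 += float(rng.uniform(6, 24))
        t = t0 + float(rng.uniform(0.25, 24))
        c = v.conc_profile(events, t, p)
        ref = ode_profile(events, t, p)
        assert c == pytest.approx(ref, rel=1e-6, abs=1e-10)


def test_superposition_identity(typical_params):
    """Two identical doses: C(24) = C1(24) + C1(12)."""
    e = [DoseEvent(0, 200, "oral"), DoseEvent(12, 200, "oral")]
    c = v.conc_profile(e, 24.0, typical_params)
    expected = (v.conc_oral_single(200, 24.0, typical_params)
                + v.conc_oral_single(200, 12.0, typical_params))
    assert c == pytest.approx(expected, rel=1e-14)
    assert v.conc_profile([], 24.0, typical_params) == 0.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(scale=st.floats(0.1, 10), t=st.floats(0.1, 200))
def test_profile_homogeneous_in_dose(scale, t, typical_params):
    """Linear kinetics: scaling every amount scales the output exactly."""
    e1 = [DoseEvent(0, 200, "iv_infusion", 1.0), DoseEvent(12, 100, "oral")]
    e2 = [DoseEvent(0, 200 * scale, "iv_infusion", 1.0),
          DoseEvent(12, 100 * scale, "oral")]
    c1 = v.conc_profile(e1, t, typical_params)
    c2 = v.conc_profile(e2, t, typical_params)
    assert c2 == pytest.approx(scale * c1, rel=1e-12, abs=1e-300)


def test_continuity_at_infusion_end(typical_params):
    eps = 1e-9
    lo = v.conc_infusion_single(200, 1.0, 1.0 - eps, typical_params)
    hi = v.conc_infusion_single(200, 1.0, 1.0 + eps, typical_params)
    assert abs(hi - lo) < 1e-6


def test_continuity_at_ka_degeneracy():
    """Oral solution is continuous across the Ka -> k degenerate limit."""
    k = 1.1  # choose V so that CL/V == Ka exactly
    p_eq = v.IndividualParams(CL=k * 97.4, V=97.4, Ka=1.1, F=0.951)
    p_near = v.IndividualParams(CL=k * 97.4 * (1 + 1e-9), V=97.4, Ka=1.1,
                                F=0.951)
    c_eq = v.conc_oral_single(200, 3.0, p_eq)
    c_near = v.conc_oral_single(200, 3.0, p_near)
    assert c_eq == pytest.approx(c_near, abs=1e-9)


def test_accumulation_to_steady_state(typical_params):
    """q12h troughs rise monotonically to the closed-form steady state."""
    troughs = []
    for n_dose in range(1, 40):
        ev = [DoseEvent(12.0 * i, 100, "iv_infusion", 1.0)
              for i in range(n_dose)]
        troughs.append(v.conc_profile(ev, 12.0 * n_dose, typical_params))
    diffs = np.diff(troughs)
    assert np.all(diffs > -1e-12)
    ss = steady_state_trough(100, 12.0, typical_params)
    assert troughs[-1] == pytest.approx(ss, rel=1e-3)


def test_trough_times_examples():
    q12 = Regimen(maintenance_dose=100, maintenance_interval=12, duration=48)
    assert v.trough_times(q12) == [12.0, 24.0, 36.0, 48.0]
    loaded = v.make_regimen(250, 100, "iv", duration=60)
    tt = v.trough_times(loaded)
    assert 24.0 in tt  # the C24 assessment time ends the loading day
    single = Regimen(loading_dose=200, n_loading=1, loading_interval=12,
                     duration=12)
    assert v.trough_times(single) == [12.0]


def test_domain_errors(typical_params):
    with pytest.raises(ValueError):
        v.conc_oral_single(200, -1.0, typical_params)
    with pytest.raises(ValueError):
        v.conc_infusion_single(200, 0.0, 5.0, typical_params)
    with pytest.raises(ValueError):
        v.conc_profile([DoseEvent(12, 100, "oral"), DoseEvent(0, 100, "oral")],
                       24.0, typical_params)
    with pytest.raises(ValueError):
        v.IndividualParams(CL=-1, V=97, Ka=1.1, F=0.9)
    with pytest.raises(ValueError):
        DoseEvent(0, 100, "oral", infusion_duration=1.0)
    with pytest.raises(ValueError):
        DoseEvent(0, 100, "iv_infusion")


def test_regimen_expansion_deterministic():
    reg = v.make_regimen(250, 100, "iv", duration=72)
    ev = reg.events()
    assert [e.time for e in ev] == [0.0, 12.0, 24.0, 36.0, 48.0, 60.0]
    assert ev[0].amount == 250 and ev[-1].amount == 100
    assert reg.events() == ev
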