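"""Marginal-likelihood machinery: EBE modes, OFV approximation quality,
fit behavior and conditional weighted residuals."""

import numpy as np
import pytest
from dataclasses import replace

import voripk as v
from voripk.data import PKDataset, Subject
from voripk.estimation import (EstModel, FitResult, MichaelisMentenStructure,
                               OneCompartmentStructure, _Design,
                               compare_structures, ebe_modes, fit, ofv)
from voripk.kinetics import DoseEvent
from voripk.model import CovariateTerm, OmegaMatrix, ResidualModel

from conftest import CHEAP_FIT, make_est_model, make_iv_dataset
from oracles import gauss_hermite_neg2ll


def one_eta_subject(eta_cl=0.4, sigma=0.05, n_obs=4, rng=None):
    """IV subject generated at a known eta_CL (no eta on V)."""
    rng = rng or np.random.default_rng(3)
    ev = [DoseEvent(0.0, 300.0, "iv_infusion", 1.0)]
    t = np.linspace(2, 12, n_obs)
    p = v.IndividualParams(CL=4.0 * np.exp(eta_cl), V=90.0, Ka=1.1, F=1.0)
    f = np.asarray(v.conc_profile(ev, t, p), float)
    y = f + rng.normal(0, sigma, f.shape)
    return Subject("one", ev, t, np.maximum(y, 1e-6), np.zeros(t.size, bool), {})


def em_one_eta(omega2=0.3, sigma=0.05):
    return EstModel(OneCompartmentStructure(),
                    {"cl": 4.0, "v": 90.0, "ka": 1.1, "f": 1.0}, (),
                    {"cl": omega2, "v": 0.0},
                    ResidualModel("additive", 0.0, sigma))


def test_ebe_mode_recovers_generating_eta_when_noise_tiny():
    s = one_eta_subject(eta_cl=0.4, sigma=1e-6)
    eta, H = ebe_modes(s, em_one_eta(omega2=10.0, sigma=1e-5))
    assert eta[0] == pytest.approx(0.4, abs=1e-3)
    assert H[0, 0] > 0


def test_ebe_mode_shrinks_to_zero_under_tight_prior():
    s = one_eta_subject(eta_cl=0.4, sigma=0.05)
    eta, _ = ebe_modes(s, em_one_eta(omega2=1e-8))
    assert abs(eta[0]) < 1e-3


def test_ebe_mode_matches_grid_search_oracle():
    """Rich-data subject: the Newton mode agrees with brute-force grid
    minimization of the joint density over a 2-D eta lattice."""
    rng = np.random.default_rng(8)
    ev = [DoseEvent(12.0 * i, 300.0, "iv_infusion", 1.0) for i in range(8)]
    t = np.sort(rng.uniform(0.5, 96, 20))
    p = v.IndividualParams(CL=4.0 * np.exp(0.3), V=90.0 * np.exp(-0.2),
                           Ka=1.1, F=1.0)
    f = np.asarray(v.conc_profile(ev, t, p), float)
    y = f * (1 + rng.normal(0, 0.05, f.shape)) + rng.normal(0, 0.05, f.shape)
    s = Subject("rich", ev, t, np.maximum(y, 1e-6), np.zeros(t.size, bool), {})
    em = EstModel(OneCompartmentStructure(),
                  {"cl": 4.0, "v": 90.0, "ka": 1.1, "f": 1.0}, (),
                  {"cl": 0.5, "v": 0.5},
                  ResidualModel("combined", 0.05, 0.05))
    eta, _ = ebe_modes(s, em)

    from voripk.estimation import _make_g
    g, q = _make_g(_Design(s), em)
    # two-stage lattice: coarse then refined around the coarse minimum
    grid = np.linspace(-1.5, 1.5, 61)
    vals = np.array([[g(np.array([a, b])) for b in grid] for a in grid])
    i, j = np.unravel_index(np.argmin(vals), vals.shape)
    fine_a = np.linspace(grid[i] - 0.06, grid[i] + 0.06, 121)
    fine_b = np.linspace(grid[j] - 0.06, grid[j] + 0.06, 121)
    vals = np.array([[g(np.array([a, b])) for b in fine_b] for a in fine_a])
    i2, j2 = np.unravel_index(np.argmin(vals), vals.shape)
    assert eta[0] == pytest.approx(fine_a[i2], abs=1e-3)
    assert eta[1] == pytest.approx(fine_b[j2], abs=1e-3)


def test_ofv_matches_quadrature_oracle():
    """Laplace OFV vs Gauss-Hermite integration of the exact marginal.

    The approximation error vanishes with the eta variance; at a small
    omega^2 the two agree to 1e-6, and at a realistic omega^2 they stay
    within a fraction of an OFV unit.
    """
    s = one_eta_subject(eta_cl=0.2, sigma=0.3)
    d = _Design(s)

    def pred(eta):
        em = em_one_eta()
        return em.structure.predict(d, em.individual_values(d, np.array([eta])))

    ds = PKDataset([s])
    for omega2, tol in ((1e-4, 1e-6), (0.3, 0.2)):
        laplace = ofv(ds, em_one_eta(omega2=omega2, sigma=0.3))
        exact = gauss_hermite_neg2ll(pred, d.dv, omega2, 0.3)
        assert laplace == pytest.approx(exact, abs=tol)


def test_ofv_additive_over_subjects():
    ds = make_iv_dataset(6, omega_cl=0.4, rng=np.random.default_rng(2))
    em = make_est_model(omega_cl=0.4)
    doubled = PKDataset([
        Subject(f"{s.sid}_{rep}", s.events, s.t_obs, s.dv, s.blq, s.covariates)
        for rep in (0, 1) for s in ds])
    assert ofv(doubled, em) == pytest.approx(2 * ofv(ds, em), rel=1e-10)


def test_ofv_invariant_to_subject_order():
    ds = make_iv_dataset(8, omega_cl=0.4, rng=np.random.default_rng(4))
    em = make_est_model(omega_cl=0.4)
    shuffled = PKDataset(list(reversed(ds.subjects)))
    assert ofv(shuffled, em) == pytest.approx(ofv(ds, em), rel=1e-12)


def test_noiseless_theta_recovery():
    """Data generated with eta = eps = 0: thetas recovered to optimizer
    tolerance when variances are held at the generating values."""
    ds = make_iv_dataset(10, sigma=1e-5, rng=np.random.default_rng(6))
    em = make_est_model(sigma=1e-5, cl=3.2, v_=70.0)  # perturbed init
    fr = fit(ds, em, fixed=("ka", "f", "sigma2_add"), maxiter=400,
             max_rounds=2)
    assert fr.est.theta["cl"] == pytest.approx(4.0, rel=1e-3)
    assert fr.est.theta["v"] == pytest.approx(90.0, rel=1e-3)


def test_fixed_ka_respected_exactly(small_fit):
    assert small_fit.est.theta["ka"] == 1.1
    assert "ka" in small_fit.fixed


def test_fit_shrinkage_pattern(small_fit):
    """Sparse sampling in the absorption phase: V-shrinkage well above
    CL-shrinkage, as in the study."""
    assert small_fit.shrinkage["v"] > small_fit.shrinkage["cl"]
    assert 0 <= small_fit.shrinkage["cl"] <= 100


def test_cwres_scalar_case_closed_form():
    """Single observation, additive error, no IIV: CWRES = (DV-PRED)/sigma."""
    ev = [DoseEvent(0.0, 300.0, "iv_infusion", 1.0)]
    em = make_est_model(sigma=0.25)
    p = v.IndividualParams(CL=4.0, V=90.0, Ka=1.1, F=0.951)
    f = float(v.conc_profile(ev, 6.0, p))
    s = Subject("s", ev, [6.0], [f + 0.4], [False], {})
    fr = FitResult(est=em, ofv=0.0, converged=True,
                   eta=np.zeros((1, 0)), eta_params=[], shrinkage={},
                   fixed=(), subject_ids=["s"])
    res = v.cwres(PKDataset([s]), fr)
    assert res[0] == pytest.approx(0.4 / 0.25, rel=1e-10)


def test_cwres_standard_normal_under_true_model(model_final):
    """Simulating from the model and computing CWRES against it gives
    approximately N(0,1) residuals with ~95% of points inside +/-2."""
    rng = np.random.default_rng(9)
    em = EstModel.from_population(model_final)
    subs = []
    for i in range(120):
        crp = float(rng.uniform(5, 150))
        ev = [DoseEvent(12.0 * j, 300.0, "iv_infusion", 1.0) for j in range(10)]
        t = np.sort(rng.choice(np.arange(96.5, 120, 0.5), 5, replace=False))
        p = v.realize_individual({"CRP": crp}, model_final, rng=rng)
        f = np.asarray(v.conc_profile(ev, t, p), float)
        y = np.maximum(v.apply_residual(f, model_final.residual, rng), 1e-3)
        subs.append(Subject(f"c{i}", ev, t, y, np.zeros(t.size, bool),
                            {"CRP": crp}))
    ds = PKDataset(subs)
    fr = FitResult(est=em, ofv=0.0, converged=True, eta=np.zeros((0, 0)),
                   eta_params=["cl", "v"], shrinkage={}, fixed=(),
                   subject_ids=[])
    res = v.cwres(ds, fr)
    assert res.size >= 500
    assert abs(res.mean()) < 0.1
    assert 0.85 < res.std() < 1.15
    assert np.mean(np.abs(res) < 2) >= 0.9


def test_compare_structures_prefers_true_kinetics():
    """Linear-elimination data do not elect the saturable model; strongly
    saturated data do."""
    rng = np.random.default_rng(12)
    lin = make_iv_dataset(10, sigma=0.15, rng=rng)
    rep = compare_structures(lin, init=make_est_model().to_population(),
                             **CHEAP_FIT)
    assert abs(rep["delta_ofv"]) < 3.84
    assert not rep["mm_selected"]

    # saturated generator: Km well inside the observed concentration range
    mm = MichaelisMentenStructure()
    subs = []
    for i in range(10):
        ev = [DoseEvent(0.0, 300.0, "iv_infusion", 1.0)]
        t = np.array([1.0, 6.0, 12.0, 24.0])
        d = _Design(Subject(f"m{i}", ev, t, np.ones(4), np.zeros(4, bool), {}))
        f = mm.predict(d, {"vmax": 8.0, "km": 1.0, "v": 90.0, "ka": 1.1,
                           "f": 0.951})
        y = np.maximum(f + rng.normal(0, 0.1, f.shape), 1e-3)
        subs.append(Subject(f"m{i}", ev, t, y, np.zeros(4, bool), {}))
    sat = PKDataset(subs)
    rep2 = compare_structures(sat, init=make_est_model(sigma=0.1).to_population(),
                              **CHEAP_FIT)
    assert rep2["mm_selected"]
    assert rep2["delta_ofv"] > 3.84


def test_blq_observations_dropped_with_count():
    ds = make_iv_dataset(5, sigma=0.1, rng=np.random.default_rng(3))
    ds.subjects[0].blq[1] = True
    fr = fit(ds, make_est_model(), **CHEAP_FIT)
    assert fr.n_blq_dropped == 1
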