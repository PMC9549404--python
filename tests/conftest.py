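import numpy as np
import pytest

import voripk as v
from voripk.cohort import CohortSpec
from voripk.data import PKDataset, Subject
from voripk.estimation import EstModel, OneCompartmentStructure
from voripk.kinetics import DoseEvent
from voripk.model import CovariateTerm, ResidualModel


@pytest.fixture(scope="session")
def model_final():
    return v.final_model()


@pytest.fixture(scope="session")
def typical_params():
    return v.IndividualParams(CL=4.34, V=97.4, Ka=1.1, F=0.951)


@pytest.fixture(scope="session")
def small_cohort():
    """16-subject study-like cohort (shared across estimation tests)."""
    return v.generate_cohort(CohortSpec(n_subjects=16), seed=3)


@pytest.fixture(scope="session")
def small_fit(small_cohort, model_final):
    """One moderately converged fit of the small cohort, reused by the
    diagnostic tests."""
    return v.fit(small_cohort, model_final, maxiter=300, max_rounds=2)


def make_iv_dataset(n_subj, beta=0.0, sigma=0.2, rng=None, cl=4.0, v_=90.0,
                    t_obs=(1.0, 6.0, 12.0), omega_cl=0.0, covariate="CRP",
                    center=50.0):
    """Single-infusion test dataset with an optional exponential covariate
    effect on CL and optional lognormal IIV; additive residual error."""
    rng = rng or np.random.default_rng(0)
    t = np.array(t_obs, float)
    subs = []
    for i in range(n_subj):
        x = float(rng.lognormal(np.log(center), 0.5))
        ev = [DoseEvent(0.0, 300.0, "iv_infusion", 1.0)]
        eta = rng.normal(0, omega_cl) if omega_cl else 0.0
        cl_i = cl * np.exp(beta * x / center) * np.exp(eta)
        p = v.IndividualParams(CL=cl_i, V=v_, Ka=1.1, F=0.951)
        f = np.asarray(v.conc_profile(ev, t, p), float)
        y = np.maximum(f + rng.normal(0, sigma, f.shape), 1e-3)
        subs.append(Subject(f"N{i}", ev, t, y, np.zeros(t.size, bool),
                            {covariate: x}))
    return PKDataset(subs)


def make_est_model(with_cov=False, sigma=0.2, cl=4.0, v_=90.0, omega_cl=0.0,
                   covariate="CRP", center=50.0, beta0=0.0):
    terms = ((CovariateTerm("CL", covariate, "exponential", beta0, center),)
             if with_cov else ())
    return EstModel(
        OneCompartmentStructure(),
        {"cl": cl, "v": v_, "ka": 1.1, "f": 0.951},
        terms,
        {"cl": omega_cl, "v": 0.0},
        ResidualModel("additive", 0.0, sigma),
    )


CHEAP_FIT = dict(fixed=("ka", "f"), maxiter=200, max_rounds=1,
                 fatol=5e-3, xatol=5e-3)
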