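"""Population PK model: fixed effects, covariate terms, IIV and residual error.

The structural individual model is

    P_i = P_typical(covariates) * exp(eta_i),   eta_i ~ N(0, omega^2)

with a diagonal Omega over (CL, V).  The published final model carries a
single covariate relation, an exponential CRP effect on clearance,

    CL (L/h) = theta_CL * exp(theta_CRP * CRP / CRP_center)

with theta_CL = 4.34 L/h, theta_CRP = -0.135 and CRP_center = 43.6 mg/L
(the cohort median), so clearance falls as inflammation rises.  Residual
error families: additive, proportional, exponential and combined
(Y = f*(1+eps1) + eps2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import IndividualParams

__all__ = [
    "FixedEffects",
    "OmegaMatrix",
    "ResidualModel",
    "CovariateTerm",
    "CovariateVector",
    "PopulationModel",
    "typical_clearance",
    "realize_individual",
    "apply_residual",
    "residual_variance",
    "final_model",
    "base_model",
]

RESIDUAL_KINDS = ("additive", "proportional", "exponential", "combined")


@dataclass(frozen=True)
class FixedEffects:
    """Population-typical parameter values (theta vector)."""

    theta_CL: float = 4.34       # L/h
    theta_V: float = 97.4        # L
    Ka_fixed: float = 1.1        # 1/h, fixed (sparse absorption sampling)
    theta_F: float = 0.951       # oral bioavailability fraction
    theta_CRP: float = -0.135    # exponential CRP-on-CL coefficient
    CRP_center: float = 43.6     # mg/L, cohort median CRP

    def __post_init__(self) -> None:
        if self.theta_CL <= 0 or self.theta_V <= 0 or self.Ka_fixed <= 0:
            raise ValueError("theta_CL, theta_V and Ka_fixed must be > 0")
        if not 0 < self.theta_F <= 1.5:
            raise ValueError("theta_F must lie in (0, 1.5]")


@dataclass(frozen=True)
class OmegaMatrix:
    """Diagonal inter-individual variance matrix (variances of eta)."""

    omega2_CL: float = 1.01      # -> IIV 100.5 %CV
    omega2_V: float = 0.0973     # -> IIV 31.2 %CV

    def __post_init__(self) -> None:
        if self.omega2_CL < 0 or self.omega2_V < 0:
            raise ValueError("omega^2 variances must be >= 0")

    @property
    def cv_CL(self) -> float:
        """IIV of CL as %CV = 100*sqrt(omega^2)."""
        return 100.0 * np.sqrt(self.omega2_CL)

    @property
    def cv_V(self) -> float:
        return 100.0 * np.sqrt(self.omega2_V)


@dataclass(frozen=True)
class ResidualModel:
    """Residual (unexplained) variability model.

    ``sigma_prop`` is the proportional CV fraction, ``sigma_add`` the
    additive SD in mg/L; the combined model uses both.
    """

    kind: str = "combined"
    sigma_prop: float = 0.071
    sigma_add: float = 0.373

    def __post_init__(self) -> None:
        if self.kind not in RESIDUAL_KINDS:
            raise ValueError(f"unknown residual model kind {self.kind!r}")
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("sigma values must be >= 0")
        if self.kind == "combined" and (self.sigma_prop == 0 and self.sigma_add == 0):
            raise ValueError("at least one sigma must be > 0")


@dataclass(frozen=True)
class CovariateTerm:
    """One covariate-parameter relation contributing a multiplier to a
    typical parameter.  Forms follow the stepwise screening conventions;
    the exponential form is exp(theta * x / center) so the multiplier at
    the median is exp(theta), matching the published final-model equation.
    """

    parameter: str           # "CL", "V" or "F"
    covariate: str           # column name, e.g. "CRP"
    form: str                # linear | proportion | power | exponential | categorical
    theta: float = 0.0
    center: float = 1.0

    def multiplier(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "linear":
            return 1.0 + self.theta * (x - self.center)
        if self.form == "proportion":
            return 1.0 + self.theta * (x - self.center) / self.center
        if self.form == "power":
            if np.any(x <= 0):
                raise ValueError(f"{self.covariate}: power form needs x > 0")
            return (x / self.center) ** self.theta
        if self.form == "exponential":
            if np.any(x <= 0):
                raise ValueError(f"{self.covariate}: exponential form needs x > 0")
            return np.exp(self.theta * x / self.center)
        if self.form == "categorical":
            return np.exp(self.theta * (x != 0))
        raise ValueError(f"unknown covariate form {self.form!r}")


@dataclass
class CovariateVector:
    """Per-subject covariates; missing entries stay None and raise when a
    model term actually needs them (never silently imputed)."""

    values: dict = field(default_factory=dict)

    def get(self, name: str) -> float:
        v = self.values.get(name)
        if v is None:
            raise KeyError(f"covariate {name!r} missing but required by the model")
        return float(v)


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects + covariate terms + Omega + residual model."""

    fe: FixedEffects = field(default_factory=FixedEffects)
    omega: OmegaMatrix = field(default_factory=OmegaMatrix)
    residual: ResidualModel = field(default_factory=ResidualModel)
    terms: tuple = ()            # tuple[CovariateTerm, ...]

    def _multiplier(self, parameter: str, cov: dict) -> float:
        m = 1.0
        for t in self.terms:
            if t.parameter == parameter:
                m *= float(t.multiplier(_cov_get(cov, t.covariate)))
        return m

    def typical_params(self, cov: dict) -> IndividualParams:
        """Population-typical individual parameters for given covariates
        (all eta = 0)."""
        return IndividualParams(
            CL=self.fe.theta_CL * self._multiplier("CL", cov),
            V=self.fe.theta_V * self._multiplier("V", cov),
            Ka=self.fe.Ka_fixed,
            F=self.fe.theta_F * self._multiplier("F", cov),
        )

    def with_term(self, term: CovariateTerm) -> "PopulationModel":
        return replace(self, terms=self.terms + (term,))

    def without_term(self, term: CovariateTerm) -> "PopulationModel":
        return replace(self, terms=tuple(t for t in self.terms if t is not term and t != term))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "theta": {
                "CL": self.fe.theta_CL, "V": self.fe.theta_V,
                "Ka": self.fe.Ka_fixed, "F": self.fe.theta_F,
            },
            "omega2": {"CL": self.omega.omega2_CL, "V": self.omega.omega2_V},
            "sigma": {
                "kind": self.residual.kind,
                "prop": self.residual.sigma_prop,
                "add": self.residual.sigma_add,
            },
            "covariate_terms": [
                {"parameter": t.parameter, "covariate": t.covariate,
                 "form": t.form, "theta": t.theta, "center": t.center}
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        th = d.get("theta", {})
        om = d.get("omega2", {})
        sg = d.get("sigma", {})
        return cls(
            fe=FixedEffects(
                theta_CL=float(th.get("CL", 4.34)),
                theta_V=float(th.get("V", 97.4)),
                Ka_fixed=float(th.get("Ka", 1.1)),
                theta_F=float(th.get("F", 0.951)),
            ),
            omega=OmegaMatrix(float(om.get("CL", 1.01)), float(om.get("V", 0.0973))),
            residual=ResidualModel(
                kind=sg.get("kind", "combined"),
                sigma_prop=float(sg.get("prop", 0.071)),
                sigma_add=float(sg.get("add", 0.373)),
            ),
            terms=tuple(
                CovariateTerm(t["parameter"], t["covariate"], t["form"],
                              float(t.get("theta", 0.0)), float(t.get("center", 1.0)))
                for t in d.get("covariate_terms", [])
            ),
        )


def _cov_get(cov, name: str) -> float:
    if isinstance(cov, CovariateVector):
        return cov.get(name)
    v = cov.get(name)
    if v is None:
        raise KeyError(f"covariate {name!r} missing but required by the model")
    return float(v)


def typical_clearance(crp: float, fe: FixedEffects) -> float:
    """Typical clearance at a given CRP level (final-model equation).

    theta_CL * exp(theta_CRP * CRP / CRP_center); strictly decreasing in
    CRP for theta_CRP < 0.
    """
    crp = np.asarray(crp, dtype=float)
    if np.any(crp <= 0):
        raise ValueError("CRP must be > 0 for the exponential covariate model")
    out = fe.theta_CL * np.exp(fe.theta_CRP * crp / fe.CRP_center)
    return float(out) if out.ndim == 0 else out


def realize_individual(cov, model: PopulationModel,
                       rng: np.random.Generator | int | None = None,
                       eta: np.ndarray | None = None) -> IndividualParams:
    """Draw one individual's parameters: P_i = typical * exp(eta).

    Pass ``eta`` explicitly to reproduce a known individual; otherwise
    eta ~ N(0, Omega) from ``rng``.  With Omega = 0 the draw is the
    population-typical individual exactly.
    """
    tp = model.typical_params(cov if isinstance(cov, dict) else cov.values)
    if eta is None:
        rng = np.random.default_rng(rng)
        eta = rng.normal(0.0, [np.sqrt(model.omega.omega2_CL),
                               np.sqrt(model.omega.omega2_V)])
    return IndividualParams(
        CL=tp.CL * float(np.exp(eta[0])),
        V=tp.V * float(np.exp(eta[1])),
        Ka=tp.Ka,
        F=tp.F,
    )


def residual_variance(f_pred, rm: ResidualModel):
    """Analytic observation variance of the residual model at prediction f.

    combined: f^2 sigma_prop^2 + sigma_add^2 ; proportional: f^2 sigma_prop^2 ;
    additive: sigma_add^2 ; exponential (linearized): f^2 sigma_prop^2.
    """
    f = np.asarray(f_pred, dtype=float)
    if rm.kind == "additive":
        out = np.full_like(f, rm.sigma_add**2)
    elif rm.kind in ("proportional", "exponential"):
        out = f**2 * rm.sigma_prop**2
    else:
        out = f**2 * rm.sigma_prop**2 + rm.sigma_add**2
    return float(out) if out.ndim == 0 else out


def apply_residual(f_pred, rm: ResidualModel,
                   rng: np.random.Generator | int | None = None):
    """Draw observed value(s) Y from prediction(s) under the residual model."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    f = np.asarray(f_pred, dtype=float)
    if np.any(f < 0):
        raise ValueError("predictions must be >= 0")
    if rm.kind == "additive":
        y = f + rng.normal(0.0, rm.sigma_add, f.shape)
    elif rm.kind == "proportional":
        y = f * (1.0 + rng.normal(0.0, rm.sigma_prop, f.shape))
    elif rm.kind == "exponential":
        y = f * np.exp(rng.normal(0.0, rm.sigma_prop, f.shape))
    else:
        y = f * (1.0 + rng.normal(0.0, rm.sigma_prop, f.shape)) \
            + rng.normal(0.0, rm.sigma_add, f.shape)
    return float(y) if y.ndim == 0 else y


def final_model() -> PopulationModel:
    """Published final model: CRP-on-CL exponential covariate included."""
    return PopulationModel(
        fe=FixedEffects(),
        omega=OmegaMatrix(),
        residual=ResidualModel(),
        terms=(CovariateTerm("CL", "CRP", "exponential", theta=-0.135, center=43.6),),
    )


def base_model() -> PopulationModel:
    """Covariate-free base structural model (published base estimates)."""
    return PopulationModel(
        fe=FixedEffects(theta_CL=3.43, theta_V=95.2, theta_F=0.818,
                        theta_CRP=0.0),
        omega=OmegaMatrix(1.015**2, 0.329**2),
        residual=ResidualModel("combined", 0.070, 0.387),
    )
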