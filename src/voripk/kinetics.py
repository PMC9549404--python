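"""Closed-form one-compartment kinetics with linear superposition.

Concentration-time solutions for first-order elimination with either
first-order oral absorption (gut depot) or zero-order intravenous infusion,
plus superposition over arbitrary dosing histories.  All solutions are
analytic; linearity of the kinetics makes the multi-dose profile an exact
sum of single-dose contributions.

Units throughout: time h, amount mg, volume L, clearance L/h,
concentration mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoseEvent",
    "Regimen",
    "IndividualParams",
    "conc_oral_single",
    "conc_infusion_single",
    "conc_profile",
    "conc_events_vec",
    "trough_times",
    "steady_state_trough",
]

#: relative Ka ~ k degeneracy threshold below which the analytic limit
#: formula replaces the two-exponential oral solution (avoids catastrophic
#: cancellation in Ka - k).
KA_DEGENERACY_RTOL = 1e-8

ROUTE_ORAL = "oral"
ROUTE_IV = "iv_infusion"


@dataclass(frozen=True)
class DoseEvent:
    """A single timed drug input.

    ``infusion_duration`` applies to intravenous events only and must be
    strictly positive; oral events carry no infusion duration.
    """

    time: float
    amount: float
    route: str
    infusion_duration: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")
        if self.route not in (ROUTE_ORAL, ROUTE_IV):
            raise ValueError(f"unknown route {self.route!r}")
        if self.route == ROUTE_ORAL and self.infusion_duration is not None:
            raise ValueError("oral dose events carry no infusion_duration")
        if self.route == ROUTE_IV:
            if self.infusion_duration is None or self.infusion_duration <= 0:
                raise ValueError("iv_infusion requires infusion_duration > 0")

    @property
    def is_oral(self) -> bool:
        return self.route == ROUTE_ORAL


@dataclass(frozen=True)
class IndividualParams:
    """Realized PK parameters for one subject (random effects applied)."""

    CL: float
    V: float
    Ka: float
    F: float

    def __post_init__(self) -> None:
        for name in ("CL", "V", "Ka"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.F:
            raise ValueError("F must be > 0")

    @property
    def k(self) -> float:
        """Elimination rate constant CL/V (1/h)."""
        return self.CL / self.V


@dataclass(frozen=True)
class Regimen:
    """Loading/maintenance dosing schedule.

    A loading phase of ``n_loading`` doses of ``loading_dose`` mg every
    ``loading_interval`` h starting at time 0, followed by maintenance
    doses of ``maintenance_dose`` mg every ``maintenance_interval`` h until
    ``duration``.  Route is set per phase; intravenous doses are 1-h
    zero-order infusions by default.  ``maintenance_dose=0`` or
    ``n_loading=0`` drop the respective phase.
    """

    loading_dose: float = 0.0
    loading_interval: float = 12.0
    n_loading: int = 0
    maintenance_dose: float = 0.0
    maintenance_interval: float = 12.0
    loading_route: str = ROUTE_IV
    maintenance_route: str = ROUTE_IV
    infusion_duration: float = 1.0
    duration: float = 168.0

    def __post_init__(self) -> None:
        if self.loading_interval <= 0 or self.maintenance_interval <= 0:
            raise ValueError("dose intervals must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    @property
    def maintenance_start(self) -> float:
        """Time of the first maintenance dose (h)."""
        return self.n_loading * self.loading_interval

    def events(self) -> list[DoseEvent]:
        """Expand to the ordered DoseEvent list (doses strictly before
        ``duration``)."""
        out: list[DoseEvent] = []

        def _mk(t: float, amt: float, route: str) -> DoseEvent:
            tinf = self.infusion_duration if route == ROUTE_IV else None
            return DoseEvent(t, amt, route, tinf)

        if self.loading_dose > 0 and self.n_loading > 0:
            for i in range(self.n_loading):
                t = i * self.loading_interval
                if t >= self.duration:
                    break
                out.append(_mk(t, self.loading_dose, self.loading_route))
        if self.maintenance_dose > 0:
            t = self.maintenance_start
            while t < self.duration:
                out.append(_mk(t, self.maintenance_dose, self.maintenance_route))
                t += self.maintenance_interval
        return out


def _oral_conc(tau, amount, CL, V, Ka, F):
    """Single oral dose concentration at tau >= 0 h after the dose.

    Broadcasts over any mix of array arguments.  Uses the analytic
    Ka -> k limit near the degenerate point.
    """
    tau = np.asarray(tau, dtype=float)
    k = CL / V
    degenerate = np.abs(Ka - k) < KA_DEGENERACY_RTOL * Ka
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.asarray(V * (Ka - k), dtype=float)  # may be 0 at degeneracy
        regular = (
            F * amount * Ka / denom * (np.exp(-k * tau) - np.exp(-Ka * tau))
        )
    limit = F * amount * k * tau / V * np.exp(-k * tau)
    c = np.where(degenerate, limit, regular)
    return np.where(tau > 0, c, 0.0)


def _infusion_conc(tau, amount, tinf, CL, V):
    """Zero-order infusion concentration at tau >= 0 h after infusion start."""
    tau = np.asarray(tau, dtype=float)
    k = CL / V
    r0 = amount / tinf
    te = np.minimum(tau, tinf)  # elapsed infusion time
    c = (r0 / CL) * (1.0 - np.exp(-k * te)) * np.exp(-k * np.maximum(tau - tinf, 0.0))
    return np.where(tau > 0, c, 0.0)


def _check(tau, p: IndividualParams) -> None:
    if np.any(np.asarray(tau) < 0):
        raise ValueError("time since dose must be >= 0")
    # IndividualParams validates positivity at construction


def conc_oral_single(amount: float, tau, p: IndividualParams):
    """Concentration ``tau`` h after a single oral dose of ``amount`` mg.

    C(tau) = F D Ka / (V (Ka - k)) (e^{-k tau} - e^{-Ka tau}), k = CL/V,
    with the limit (F D k tau / V) e^{-k tau} when Ka ~ k.
    """
    if amount < 0:
        raise ValueError("amount must be >= 0")
    _check(tau, p)
    return _oral_conc(tau, amount, p.CL, p.V, p.Ka, p.F)


def conc_infusion_single(amount: float, tinf: float, tau, p: IndividualParams):
    """Concentration ``tau`` h after the start of a ``tinf``-h infusion.

    During infusion: (R0/CL)(1 - e^{-k tau}) with R0 = amount/tinf; after
    the stop the value at ``tinf`` decays mono-exponentially.
    """
    if amount < 0:
        raise ValueError("amount must be >= 0")
    if tinf <= 0:
        raise ValueError("infusion duration must be > 0")
    _check(tau, p)
    return _infusion_conc(tau, amount, tinf, p.CL, p.V)


def conc_profile(events: list[DoseEvent], t, p: IndividualParams):
    """Superposed concentration at time(s) ``t`` for a dosing history.

    Events must be sorted by time; only events with time <= t contribute.
    Linear kinetics make the sum exact.
    """
    times = [e.time for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("dose events must be sorted by time")
    t = np.asarray(t, dtype=float)
    c = np.zeros_like(t)
    for e in events:
        tau = np.maximum(t - e.time, 0.0)
        if e.is_oral:
            c = c + _oral_conc(tau, e.amount, p.CL, p.V, p.Ka, p.F)
        else:
            c = c + _infusion_conc(tau, e.amount, e.infusion_duration, p.CL, p.V)
    return c if c.ndim else float(c)


def conc_events_vec(events: list[DoseEvent], t: float, CL, V, Ka, F):
    """Vectorized profile evaluation at scalar time ``t`` for arrays of
    individual parameters (one entry per simulated subject)."""
    CL, V = np.asarray(CL, float), np.asarray(V, float)
    c = np.zeros(np.broadcast(CL, V).shape)
    for e in events:
        tau = t - e.time
        if tau <= 0:
            continue
        if e.is_oral:
            c = c + _oral_conc(tau, e.amount, CL, V, Ka, F)
        else:
            c = c + _infusion_conc(tau, e.amount, e.infusion_duration, CL, V)
    return c


def trough_times(regimen: Regimen) -> list[float]:
    """Idealized pre-dose evaluation times of a regimen.

    Each scheduled next-dose time up to and including ``duration``; the
    loading-phase end (e.g. 24 h, the C24 time) is included.
    """
    out: list[float] = []
    if regimen.loading_dose > 0 and regimen.n_loading > 0:
        for i in range(1, regimen.n_loading + 1):
            t = i * regimen.loading_interval
            if t <= regimen.duration:
                out.append(t)
    start = regimen.maintenance_start
    if regimen.maintenance_dose > 0:
        t = start + regimen.maintenance_interval
        while t <= regimen.duration:
            out.append(t)
            t += regimen.maintenance_interval
    return sorted(set(out))


def steady_state_trough(dose: float, interval: float, p: IndividualParams,
                        route: str = ROUTE_IV, tinf: float = 1.0) -> float:
    """Closed-form steady-state trough for repeated identical dosing.

    Single-dose trough at ``interval`` scaled by the accumulation factor
    1/(1 - e^{-k tau}).
    """
    k = p.k
    acc = 1.0 / (1.0 - np.exp(-k * interval))
    if route == ROUTE_ORAL:
        # both exponentials accumulate with their own rate
        ka = p.Ka
        if abs(ka - k) < KA_DEGENERACY_RTOL * ka:
            raise NotImplementedError("degenerate Ka ~ k steady state")
        a = np.exp(-k * interval) / (1 - np.exp(-k * interval))
        b = np.exp(-ka * interval) / (1 - np.exp(-ka * interval))
        return float(p.F * dose * ka / (p.V * (ka - k)) * (a - b))
    c_single = _infusion_conc(interval, dose, tinf, p.CL, p.V)
    return float(c_single * acc)
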