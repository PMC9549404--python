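"""Stepwise covariate modeling with likelihood-ratio gates.

Forward inclusion admits the single best candidate whose addition drops
the OFV by more than 3.84 (chi-square, df=1, p<0.05) and repeats until no
candidate passes; backward elimination then removes any retained relation
whose deletion raises the OFV by at most 6.63 (p<0.01), to a fixed point.
Continuous covariates are centered at their cohort medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import EstModel, FitResult, fit
from .model import CovariateTerm, PopulationModel

__all__ = [
    "CovariateCandidate",
    "relation_builder",
    "forward_step",
    "backward_step",
    "stepwise",
    "FORWARD_DOFV",
    "BACKWARD_DOFV",
    "DEFAULT_CANDIDATE_COVARIATES",
]

log = logging.getLogger(__name__)

FORWARD_DOFV = 3.84
BACKWARD_DOFV = 6.63

#: covariates collected in the study and screened by default
DEFAULT_CANDIDATE_COVARIATES = (
    "WT", "AGE", "SEX", "ALB", "ALT", "AST", "TP", "TBIL", "GGT", "UREA",
    "CRP", "WBC", "HGB", "PLT", "NEU", "HIV", "PPI", "GLUCO", "EM",
)


@dataclass(frozen=True)
class CovariateCandidate:
    """A candidate covariate-parameter relation to screen."""

    parameter: str      # "CL", "V" or "F"
    covariate: str
    form: str           # linear | proportion | power | exponential | categorical
    center: float = 1.0

    def term(self, theta: float = 0.0) -> CovariateTerm:
        return CovariateTerm(self.parameter, self.covariate, self.form,
                             theta=theta, center=self.center)


def relation_builder(candidate: CovariateCandidate, theta: float):
    """Multiplier function x -> multiplier applied to the typical parameter."""
    term = candidate.term(theta)
    return term.multiplier


def _fit_with(dataset, em: EstModel, extra_fixed=(), **kw) -> FitResult:
    fixed = tuple(set(tuple(kw.pop("fixed", ("ka",))) + tuple(extra_fixed)))
    return fit(dataset, em, fixed=fixed, **kw)


def forward_step(current: FitResult, candidates, dataset,
                 dofv_gate: float = FORWARD_DOFV, **fit_kwargs):
    """Try each candidate singly on top of the current model.

    Returns (selected candidate or None, new FitResult or None, table of
    per-candidate delta-OFV).  Selection: largest delta-OFV above the
    gate; ties broken toward the larger drop then the earlier candidate.
    """
    rows = []
    best = None
    for cand in candidates:
        em_try = EstModel(
            structure=current.est.structure,
            theta=current.est.theta,
            terms=current.est.terms + (cand.term(0.0),),
            omega2=current.est.omega2,
            residual=current.est.residual,
        )
        try:
            res = _fit_with(dataset, em_try, **dict(fit_kwargs))
        except Exception as err:  # candidate fit failure: skip with log entry
            log.warning("candidate %s-%s (%s) failed to fit: %s",
                        cand.covariate, cand.parameter, cand.form, err)
            rows.append({"candidate": f"{cand.covariate} on {cand.parameter}",
                         "form": cand.form, "dofv": np.nan, "status": "failed"})
            continue
        dofv = current.ofv - res.ofv
        rows.append({"candidate": f"{cand.covariate} on {cand.parameter}",
                     "form": cand.form, "dofv": float(dofv),
                     "status": "ok"})
        if dofv > dofv_gate and (best is None or dofv > best[2]):
            best = (cand, res, dofv)
    table = pd.DataFrame(rows)
    if best is None:
        return None, None, table
    return best[0], best[1], table


def backward_step(full: FitResult, dataset,
                  dofv_gate: float = BACKWARD_DOFV, **fit_kwargs):
    """Backward elimination to a fixed point.

    Repeatedly refits the model with each retained covariate term removed;
    the term whose removal raises the OFV the least is deleted while that
    rise is <= the gate.  Returns (final FitResult, trace table).
    """
    current = full
    rows = []
    step = 0
    while current.est.terms:
        step += 1
        weakest = None
        for i, term in enumerate(current.est.terms):
            em_try = EstModel(
                structure=current.est.structure,
                theta=current.est.theta,
                terms=tuple(t for j, t in enumerate(current.est.terms) if j != i),
                omega2=current.est.omega2,
                residual=current.est.residual,
            )
            try:
                res = _fit_with(dataset, em_try, **dict(fit_kwargs))
            except Exception as err:
                log.warning("removal refit failed for %s on %s: %s",
                            term.covariate, term.parameter, err)
                continue
            rise = res.ofv - current.ofv
            rows.append({"step": step,
                         "candidate": f"{term.covariate} on {term.parameter}",
                         "form": term.form, "dofv": float(rise),
                         "decision": "pending"})
            if weakest is None or rise < weakest[2]:
                weakest = (term, res, rise)
        if weakest is None or weakest[2] > dofv_gate:
            break
        for r in rows:
            if (r["step"] == step
                    and r["candidate"] == f"{weakest[0].covariate} on {weakest[0].parameter}"
                    and r["decision"] == "pending"):
                r["decision"] = "removed"
        current = weakest[1]
    for r in rows:
        if r["decision"] == "pending":
            r["decision"] = "kept"
    return current, pd.DataFrame(rows)


def stepwise(dataset, base: FitResult | PopulationModel, candidates,
             **fit_kwargs):
    """Full forward-inclusion / backward-elimination loop.

    Returns (final FitResult, tidy selection trace: step, phase,
    candidate, form, dofv, decision).
    """
    if not isinstance(base, FitResult):  # a model: fit it first
        base = fit(dataset, base, **dict(fit_kwargs))
    current = base
    remaining = list(candidates)
    traces = []
    step = 0
    while remaining:
        step += 1
        cand, res, table = forward_step(current, remaining, dataset, **fit_kwargs)
        table.insert(0, "phase", "forward")
        table.insert(0, "step", step)
        table["decision"] = "rejected"
        if cand is None:
            traces.append(table)
            break
        table.loc[table["candidate"] == f"{cand.covariate} on {cand.parameter}",
                  "decision"] = "included"
        traces.append(table)
        current = res
        remaining = [c for c in remaining
                     if not (c.parameter == cand.parameter
                             and c.covariate == cand.covariate)]
    final, btable = backward_step(current, dataset, **fit_kwargs)
    if len(btable):
        btable.insert(1, "phase", "backward")
        traces.append(btable)
    trace = pd.concat(traces, ignore_index=True) if traces else pd.DataFrame()
    return final, trace
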