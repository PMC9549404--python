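"""Model validation: bootstrap, visual predictive check, goodness-of-fit
tables and the post-hoc clearance-vs-CRP analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import PKDataset, Subject
from .estimation import FitResult, _Design, cwres, fit
from .kinetics import conc_profile
from .model import PopulationModel, apply_residual, realize_individual

__all__ = [
    "BootstrapReport",
    "VPCReport",
    "bootstrap",
    "vpc",
    "gof_table",
    "ebe_crp_analysis",
]

log = logging.getLogger(__name__)


@dataclass
class BootstrapReport:
    """Resampling distribution summary of the parameter estimates."""

    n_requested: int
    n_converged: int
    summary: pd.DataFrame        # parameter, median, ci_lo, ci_hi
    estimates: pd.DataFrame      # one row per converged replicate
    valid: bool = True

    def __post_init__(self) -> None:
        if len(self.summary):
            bad = (self.summary["ci_lo"] > self.summary["median"]) | \
                  (self.summary["median"] > self.summary["ci_hi"])
            if bad.any():
                raise ValueError("bootstrap CI ordering violated")


def _flatten_params(fr: FitResult) -> dict:
    out = {f"theta_{k}": v for k, v in fr.est.theta.items()}
    for i, t in enumerate(fr.est.terms):
        out[f"beta_{t.covariate}_{t.parameter}"] = t.theta
    for k, v in fr.est.omega2.items():
        out[f"omega2_{k}"] = v
    out["sigma_prop"] = fr.est.residual.sigma_prop
    out["sigma_add"] = fr.est.residual.sigma_add
    out["ofv"] = fr.ofv
    return out


def bootstrap(dataset: PKDataset, model, n: int = 1000,
              seed: int = 0, **fit_kwargs) -> BootstrapReport:
    """Nonparametric subject-level bootstrap of the model fit.

    Subjects are resampled with replacement (dataset size preserved) and
    the model refit per replicate; non-converged or non-finite replicates
    are excluded from the percentile summaries.  A report with more than
    half the replicates failing is flagged invalid.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_conv = 0
    subjects = list(dataset)
    for b in range(n):
        idx = rng.integers(0, len(subjects), len(subjects))
        resampled = PKDataset([
            Subject(f"B{b}_{j}", subjects[i].events, subjects[i].t_obs,
                    subjects[i].dv, subjects[i].blq, subjects[i].covariates)
            for j, i in enumerate(idx)])
        try:
            fr = fit(resampled, model, **fit_kwargs)
        except Exception as err:
            log.warning("bootstrap replicate %d failed: %s", b, err)
            continue
        vals = _flatten_params(fr)
        ok = fr.converged and all(np.isfinite(v) for v in vals.values())
        if ok:
            n_conv += 1
            rows.append(vals)
    est = pd.DataFrame(rows)
    if len(est):
        summary = pd.DataFrame({
            "parameter": est.columns,
            "median": est.median().to_numpy(),
            "ci_lo": est.quantile(0.025).to_numpy(),
            "ci_hi": est.quantile(0.975).to_numpy(),
        })
    else:
        summary = pd.DataFrame(columns=["parameter", "median", "ci_lo", "ci_hi"])
    return BootstrapReport(
        n_requested=n, n_converged=n_conv, summary=summary, estimates=est,
        valid=(n == 0) or (n_conv > n / 2))


@dataclass
class VPCReport:
    """Observed percentiles vs simulated percentile confidence bands per
    time-after-dose bin."""

    n_sim: int
    percentiles: tuple
    table: pd.DataFrame   # bin, t_mid, n_obs, obs_p*, lo_p*, hi_p*
    ci: float = 0.95

    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells whose observed percentile
        falls inside the simulated band."""
        hits, total = 0, 0
        for p in self.percentiles:
            obs = self.table[f"obs_p{p:g}"]
            ok = (obs >= self.table[f"lo_p{p:g}"]) & (obs <= self.table[f"hi_p{p:g}"])
            hits += int(ok.sum())
            total += len(ok)
        return hits / total if total else np.nan


#: nominal TAD bin edges: the sampling grid plus the pre-dose trough bin
VPC_BIN_EDGES = (0.0, 0.75, 1.5, 3.0, 5.0, 7.0, 9.0, 11.0, 12.01)


def vpc(dataset: PKDataset, model: PopulationModel, n_sim: int = 2000,
        seed: int = 0, percentiles=(5, 50, 95), ci: float = 0.95,
        bin_edges=VPC_BIN_EDGES, min_bin: int = 3) -> VPCReport:
    """Visual predictive check.

    Simulates ``n_sim`` replicates of the dataset under its own dosing and
    sampling design, then per time-after-dose bin compares the observed
    5/50/95th percentiles with the simulation-based confidence bands.
    Bins with fewer than ``min_bin`` observations merge into their left
    neighbor (logged).
    """
    rng = np.random.default_rng(seed)
    tads, dvs, f_typ = [], [], []
    per_subject = []
    for s in dataset:
        keep = ~s.blq
        t = s.t_obs[keep]
        if t.size == 0:
            continue
        tads.append(s.tad()[keep])
        dvs.append(s.dv[keep])
        per_subject.append((s, keep))
    tad = np.concatenate(tads)
    dv = np.concatenate(dvs)

    edges = np.asarray(bin_edges, float)
    idx = np.clip(np.digitize(tad, edges) - 1, 0, len(edges) - 2)
    # merge sparse bins leftward
    for b in range(len(edges) - 1):
        if 0 < np.sum(idx == b) < min_bin:
            tgt = b - 1
            while tgt >= 0 and np.sum(idx == tgt) == 0:
                tgt -= 1
            if tgt >= 0:
                log.info("VPC: merging sparse bin %d into %d", b, tgt)
                idx[idx == b] = tgt

    sims = np.empty((n_sim, dv.size))
    for r in range(n_sim):
        chunks = []
        for s, keep in per_subject:
            p = realize_individual(s.covariates, model, rng=rng)
            f = np.asarray(conc_profile(s.events, s.t_obs[keep], p), float)
            y = apply_residual(f.reshape(-1), model.residual, rng)
            chunks.append(np.maximum(np.atleast_1d(y), 0.0))
        sims[r] = np.concatenate(chunks)

    alpha = (1 - ci) / 2
    rows = []
    for b in sorted(set(idx)):
        m = idx == b
        row = {"bin": int(b), "t_mid": float(np.median(tad[m])),
               "n_obs": int(m.sum())}
        for p in percentiles:
            row[f"obs_p{p:g}"] = float(np.percentile(dv[m], p))
            sim_p = np.percentile(sims[:, m], p, axis=1)
            row[f"lo_p{p:g}"] = float(np.quantile(sim_p, alpha))
            row[f"hi_p{p:g}"] = float(np.quantile(sim_p, 1 - alpha))
        rows.append(row)
    table = pd.DataFrame(rows)
    return VPCReport(n_sim=n_sim, percentiles=tuple(percentiles), table=table,
                     ci=ci)


def gof_table(dataset: PKDataset, fitresult: FitResult) -> pd.DataFrame:
    """Per-observation goodness-of-fit table: DV, PRED (eta=0), IPRED
    (eta at the EBE mode), CWRES and time after dose."""
    em = fitresult.est
    active = em.active_etas()
    res = cwres(dataset, fitresult)
    eta_by_sid = dict(zip(fitresult.subject_ids, fitresult.eta))
    rows = []
    k = 0
    for s in dataset:
        d = _Design(s)
        if d.n_obs == 0:
            continue
        eta = np.asarray(eta_by_sid.get(s.sid), float)[:len(active)]
        pred = em.structure.predict(d, em.individual_values(d, None))
        ipred = em.structure.predict(d, em.individual_values(d, eta if active else None))
        keep = ~s.blq
        tad = s.tad()[keep]
        for j in range(d.n_obs):
            rows.append({"ID": s.sid, "TIME": d.t_obs[j], "TAD": tad[j],
                         "DV": d.dv[j], "PRED": pred[j], "IPRED": ipred[j],
                         "CWRES": res[k]})
            k += 1
    return pd.DataFrame(rows)


def ebe_crp_analysis(fitresult: FitResult, dataset: PKDataset,
                     threshold: float = 96.0) -> dict:
    """Post-hoc analyses of empirical-Bayes clearance against CRP.

    Ordinary least squares of EBE CL on CRP, plus a two-group Mann-Whitney
    comparison split at ``threshold`` mg/L.  Each subject contributes its
    EBE clearance paired with its (baseline) CRP.
    """
    ebe = fitresult.ebe_params(dataset)
    crp = np.array([s.covariates.get("CRP", np.nan) for s in dataset], float)
    cl = ebe["CL"].to_numpy()
    ok = np.isfinite(crp) & np.isfinite(cl)
    crp, cl = crp[ok], cl[ok]

    if crp.size < 3 or np.ptp(crp) == 0:
        reg = None
    else:
        reg = stats.linregress(crp, cl)
    lo_g = cl[crp <= threshold]
    hi_g = cl[crp > threshold]
    out = {
        "slope": float(reg.slope) if reg else np.nan,
        "slope_p": float(reg.pvalue) if reg else np.nan,
        "intercept": float(reg.intercept) if reg else np.nan,
        "n": int(crp.size),
        "median_low_group": float(np.median(lo_g)) if lo_g.size else np.nan,
        "median_high_group": float(np.median(hi_g)) if hi_g.size else np.nan,
    }
    if lo_g.size >= 2 and hi_g.size >= 2:
        u = stats.mannwhitneyu(lo_g, hi_g, alternative="two-sided")
        out["rank_test_p"] = float(u.pvalue)
    else:
        out["rank_test_p"] = np.nan
        log.info("CRP group comparison skipped: a group has < 2 members")
    return out
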