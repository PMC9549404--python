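"""Synthetic study-like cohort generator.

The study data are not public, so estimation and validation are exercised
on cohorts that emulate the published design: 69 adults with talaromycosis
from two hospitals (35/34), ~233 sparse plasma samples (median 4 per
patient, range 1-9, ~75 of them steady-state troughs), a mix of IV and
oral loading and non-loading q12h regimens with weight-based label dosing,
nominal post-dose sampling at 0.5-12 h, covariates drawn per the published
site-level summaries, CYP2C19 genotypes in Hardy-Weinberg proportions, and
an assay quantitation limit of 0.2 mg/L.

Continuous covariates are drawn from lognormals moment-matched to each
site's mean/SD and truncated to the observed range (the labs are positive
and right-skewed); binary covariates are Bernoulli at the observed
frequencies.  CRP is drawn once per subject and held constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import PKDataset, Subject
from .kinetics import DoseEvent, ROUTE_IV, ROUTE_ORAL
from .model import PopulationModel, apply_residual, final_model, realize_individual

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "genotype_sampler",
    "hwe_check",
    "sample_weights",
    "SITE_COVARIATES",
    "DEFAULT_ALLELE_FREQS",
]

LLOQ_DEFAULT = 0.2  # mg/L

#: per-site continuous covariate summaries: (mean, sd, low, high)
SITE_COVARIATES = {
    1: {
        "AGE": (58.1, 4.62, 54, 69), "WT": (62.7, 6.66, 52, 72),
        "ALB": (26.9, 4.02, 17.4, 36.0), "ALT": (26.1, 14.6, 4.0, 61.0),
        "CRP": (93.9, 71.0, 1.6, 207.7), "DBIL": (4.76, 4.29, 1.2, 16.7),
        "GGT": (260.9, 176.2, 19.0, 662.0), "PLT": (437.4, 113.2, 246.1, 625.7),
        "TP": (69.2, 12.2, 54.7, 95.4), "WBC": (15.16, 3.71, 7.04, 27.81),
        "UREA": (6.42, 2.55, 2.5, 10.97),
    },
    2: {
        "AGE": (38.0, 10.4, 20, 65), "WT": (52.0, 9.65, 38, 87),
        "ALB": (25.7, 5.9, 1.0, 43.8), "ALT": (46.0, 44.7, 10.0, 236),
        "CRP": (61.3, 41.8, 0.9, 202), "DBIL": (10.5, 12.8, 1.0, 102.2),
        "GGT": (153.5, 174.8, 20, 1154), "PLT": (123.7, 88.8, 6, 451),
        "TP": (61.8, 11.9, 43, 103.2), "WBC": (3.79, 2.41, 1.0, 16.2),
        "UREA": (4.83, 3.25, 0.95, 18.47),
    },
}

#: per-site binary covariate frequencies
SITE_BINARY = {
    1: {"SEX": 24 / 35, "HIV": 0.0, "PPI": 14 / 35, "GLUCO": 6 / 35},
    2: {"SEX": 31 / 34, "HIV": 1.0, "PPI": 11 / 34, "GLUCO": 1 / 34},
}

#: CYP2C19 allele frequencies solved from the cohort phenotype split
#: (EM 30/69 -> f(*1)=sqrt(30/69)=0.659; PM 8/69 -> f(*2)+f(*3)=0.341,
#: apportioned to *2/*3 at the ratio typical of southern Chinese cohorts)
DEFAULT_ALLELE_FREQS = {"*1": 0.6594, "*2": 0.2830, "*3": 0.0576}

PHENOTYPE_MAP = {
    frozenset(["*1"]): "EM",
    frozenset(["*1", "*2"]): "IM",
    frozenset(["*1", "*3"]): "IM",
    frozenset(["*2"]): "PM",
    frozenset(["*2", "*3"]): "PM",
    frozenset(["*3"]): "PM",
}

#: distribution of samples per subject (support 1..9; mean ~3.38 so 69
#: subjects yield ~233 samples, median 4 as observed)
SAMPLES_PMF = (0.25, 0.10, 0.10, 0.35, 0.10, 0.05, 0.03, 0.01, 0.01)
#: troughs per subject (support 0..2; mean ~1.09, 75 expected over 69)
TROUGHS_PMF = (0.15, 0.61, 0.24)

#: nominal post-dose sampling grid (h after a dose)
SAMPLING_GRID = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)


@dataclass(frozen=True)
class CohortSpec:
    """Design parameters of a generated cohort."""

    n_subjects: int = 69
    site_fractions: tuple = (35 / 69, 34 / 69)
    #: regimen mix: iv loading, oral loading, mixed (iv load/oral maint),
    #: non-loading iv, non-loading oral
    regimen_counts: tuple = (50, 4, 1, 3, 11)
    samples_pmf: tuple = SAMPLES_PMF
    troughs_pmf: tuple = TROUGHS_PMF
    lloq: float = LLOQ_DEFAULT
    duration: float = 240.0          # h of dosing simulated
    infusion_h: float = 1.0
    interval: float = 12.0
    allele_freqs: dict = field(default_factory=lambda: dict(DEFAULT_ALLELE_FREQS))

    def regimen_probs(self) -> np.ndarray:
        c = np.asarray(self.regimen_counts, float)
        return c / c.sum()


def _trunc_lognormal(mean, sd, lo, hi, n, rng):
    """Lognormal matched by moments to (mean, sd), truncated to [lo, hi]."""
    if not (lo < mean < hi):
        raise ValueError(f"infeasible covariate moments: mean {mean} outside "
                         f"range ({lo}, {hi})")
    s2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    s = np.sqrt(s2)
    out = np.empty(n)
    got = 0
    lo = max(lo, 1e-9)
    for _ in range(1000):
        if got >= n:
            break
        x = rng.lognormal(mu, s, max(4 * (n - got), 64))
        x = x[(x >= lo) & (x <= hi)]
        take = min(x.size, n - got)
        out[got:got + take] = x[:take]
        got += take
    else:
        raise ValueError(f"covariate range ({lo}, {hi}) incompatible with "
                         f"moments mean={mean}, sd={sd}")
    return out


def sample_weights(n: int, rng: np.random.Generator) -> np.ndarray:
    """Body weights (kg) from the two-site mixture."""
    site = 1 + (rng.random(n) >= 35 / 69).astype(int)
    wt = np.empty(n)
    for s in (1, 2):
        m = site == s
        if m.any():
            wt[m] = _trunc_lognormal(*SITE_COVARIATES[s]["WT"], int(m.sum()), rng)
    return wt


def genotype_sampler(n: int, allele_freqs: dict | None = None,
                     rng: np.random.Generator | int | None = None):
    """Draw CYP2C19 diplotypes under Hardy-Weinberg equilibrium.

    Returns (genotype list like "*1/*2", phenotype list EM/IM/PM).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    freqs = dict(allele_freqs or DEFAULT_ALLELE_FREQS)
    alleles = list(freqs)
    p = np.array([freqs[a] for a in alleles], float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("allele frequencies must be nonnegative and sum to 1")
    draws = rng.choice(len(alleles), size=(n, 2), p=p)
    genotypes, phenotypes = [], []
    for a, b in draws:
        pair = sorted([alleles[a], alleles[b]])
        genotypes.append("/".join(pair))
        phenotypes.append(PHENOTYPE_MAP[frozenset(pair)])
    return genotypes, phenotypes


def hwe_check(genotype_counts):
    """Hardy-Weinberg goodness-of-fit chi-square.

    ``genotype_counts`` is either a 3-sequence (AA, Aa, aa) for a
    biallelic locus or a dict mapping "a/b" genotype strings to counts.
    Allele frequencies are estimated from the counts; df = genotypes -
    alleles.  Returns (statistic, p value).
    """
    if isinstance(genotype_counts, dict):
        counts = {tuple(sorted(k.split("/"))): float(v)
                  for k, v in genotype_counts.items()}
    else:
        aa, ab, bb = (float(v) for v in genotype_counts)
        counts = {("A", "A"): aa, ("A", "B"): ab, ("B", "B"): bb}
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("all-zero genotype counts")
    alleles = sorted({a for pair in counts for a in pair})
    freq = {a: 0.0 for a in alleles}
    for (a, b), c in counts.items():
        freq[a] += c
        freq[b] += c
    for a in alleles:
        freq[a] /= 2 * total
    stat = 0.0
    n_geno = 0
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            n_geno += 1
            expected = total * (freq[a] ** 2 if a == b else 2 * freq[a] * freq[b])
            observed = counts.get((a, b), 0.0)
            if expected > 0:
                stat += (observed - expected) ** 2 / expected
    df = max(n_geno - len(alleles), 1)
    return float(stat), float(stats.chi2.sf(stat, df))


def _assign_regimen(kind: int, wt: float, spec: CohortSpec) -> list:
    """Expand a regimen-mix category to dose events over the study window."""
    iv = lambda t, mg: DoseEvent(t, mg, ROUTE_IV, spec.infusion_h)
    po = lambda t, mg: DoseEvent(t, mg, ROUTE_ORAL)
    oral_md = 100.0 if wt < 40 else 200.0
    oral_ld = 200.0 if wt < 40 else 400.0
    tau = spec.interval
    times_ld = [0.0, tau]
    times_md = list(np.arange(2 * tau, spec.duration, tau))
    if kind == 0:      # iv loading + iv maintenance (6 -> 4 mg/kg)
        ev = [iv(t, 6.0 * wt) for t in times_ld]
        ev += [iv(t, 4.0 * wt) for t in times_md]
    elif kind == 1:    # oral loading + oral maintenance
        ev = [po(t, oral_ld) for t in times_ld]
        ev += [po(t, oral_md) for t in times_md]
    elif kind == 2:    # iv loading, oral maintenance
        ev = [iv(t, 6.0 * wt) for t in times_ld]
        ev += [po(t, oral_md) for t in times_md]
    elif kind == 3:    # non-loading iv
        ev = [iv(t, 4.0 * wt) for t in [0.0, tau] + times_md]
    else:              # non-loading oral
        ev = [po(t, oral_md) for t in [0.0, tau] + times_md]
    return ev


def _sampling_times(kind: int, n_samples: int, n_troughs: int,
                    spec: CohortSpec, rng) -> np.ndarray:
    """Sampling times: steady-state pre-dose troughs plus post-dose grid
    picks on a randomly chosen dosing occasion (any treatment day, as in
    the sparse design; only troughs are restricted to steady state)."""
    tau = spec.interval
    # steady state: 5 doses after the loading day (or 5 days non-loading)
    first_ss = 2 * tau + 5 * tau if kind in (0, 1, 2) else 10 * tau
    dose_times = np.arange(0.0, spec.duration, tau)
    ss_doses = dose_times[dose_times >= first_ss]
    times = []
    k = min(n_troughs, n_samples)
    if k:
        pre = rng.choice(ss_doses[:len(ss_doses) - 1], size=k, replace=False)
        times += list(pre + tau)  # idealized exactly-pre-dose draw
    n_rest = n_samples - k
    while n_rest > 0:
        base = rng.choice(dose_times[:len(dose_times) - 1])
        grid = rng.choice(SAMPLING_GRID, size=min(n_rest, len(SAMPLING_GRID)),
                          replace=False)
        times += list(base + np.sort(grid))
        n_rest -= len(grid)
    return np.unique(np.round(np.asarray(times), 6))


def generate_cohort(spec: CohortSpec | None = None,
                    model: PopulationModel | None = None,
                    seed: int | np.random.Generator | None = 0,
                    noise: bool = True) -> PKDataset:
    """Simulate a full study-like PKDataset.

    Covariates, genotypes, regimens and sampling schedules are drawn per
    the design summaries; concentrations come from the population model
    (IIV realized per subject, residual error per observation unless
    ``noise=False``).  Values below the quantitation limit are flagged
    BLQ, not removed; draws pushed negative by the additive error are
    floored at zero and flagged.
    """
    spec = spec or CohortSpec()
    model = model or final_model()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = spec.n_subjects
    n_site1 = int(round(n * spec.site_fractions[0]))
    sites = np.array([1] * n_site1 + [2] * (n - n_site1))

    # regimen mix: exact counts when n matches the study, else multinomial
    counts = list(spec.regimen_counts)
    if sum(counts) == n:
        kinds = np.repeat(np.arange(5), counts)
    else:
        kinds = rng.choice(5, size=n, p=spec.regimen_probs())
    rng.shuffle(kinds)

    genos, phenos = genotype_sampler(n, spec.allele_freqs, rng)

    subjects = []
    for i in range(n):
        site = int(sites[i])
        cov = {"SITE": site}
        for name, args in SITE_COVARIATES[site].items():
            cov[name] = float(_trunc_lognormal(*args, 1, rng)[0])
        for name, f in SITE_BINARY[site].items():
            cov[name] = int(rng.random() < f)
        cov["EM"] = int(phenos[i] == "EM")
        cov["CYP2C19"] = {"EM": 0, "IM": 1, "PM": 2}[phenos[i]]

        events = _assign_regimen(int(kinds[i]), cov["WT"], spec)
        n_samples = 1 + int(rng.choice(len(spec.samples_pmf), p=spec.samples_pmf))
        n_troughs = int(rng.choice(len(spec.troughs_pmf), p=spec.troughs_pmf))
        t_obs = _sampling_times(int(kinds[i]), n_samples, n_troughs, spec, rng)

        p = realize_individual(cov, model, rng=rng)
        from .kinetics import conc_profile
        f = np.asarray(conc_profile(events, t_obs, p), float).reshape(-1)
        y = apply_residual(f, model.residual, rng) if noise else f.copy()
        blq = y < spec.lloq
        y = np.maximum(y, 0.0)
        subjects.append(Subject(f"S{i + 1:03d}", events, t_obs, y, blq, cov))
    return PKDataset(subjects)
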