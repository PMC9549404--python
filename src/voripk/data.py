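"""PK dataset containers and NONMEM-style CSV I/O.

The rectangular interchange format uses one row per dosing or observation
record with the conventional columns ID, TIME, AMT, RATE, EVID, MDV, DV,
CMT plus any covariate columns.  EVID=1 marks dose rows (DV missing),
EVID=0 observation rows (AMT missing); RATE > 0 on a dose row encodes a
zero-order infusion with duration AMT/RATE; CMT=1 is the oral depot,
CMT=2 the central compartment.  Dots and empty cells are accepted as
missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import DoseEvent, ROUTE_IV, ROUTE_ORAL

__all__ = ["Subject", "PKDataset", "read_dataset", "write_dataset"]

REQUIRED_COLS = ["ID", "TIME", "AMT", "RATE", "EVID", "MDV", "DV", "CMT"]


@dataclass
class Subject:
    """Dosing history, observations and covariates for one individual."""

    sid: object
    events: list = field(default_factory=list)       # list[DoseEvent]
    t_obs: np.ndarray = field(default_factory=lambda: np.empty(0))
    dv: np.ndarray = field(default_factory=lambda: np.empty(0))
    blq: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_obs = np.asarray(self.t_obs, dtype=float)
        self.dv = np.asarray(self.dv, dtype=float)
        self.blq = (np.zeros(self.t_obs.size, dtype=bool)
                    if np.size(self.blq) == 0 and self.t_obs.size
                    else np.asarray(self.blq, dtype=bool))
        if self.t_obs.size and np.any(self.t_obs < 0):
            raise ValueError(f"subject {self.sid}: negative observation time")
        if self.t_obs.size != self.dv.size:
            raise ValueError(f"subject {self.sid}: t_obs/dv length mismatch")

    @property
    def n_obs(self) -> int:
        return int(self.t_obs.size)

    def tad(self) -> np.ndarray:
        """Time after the most recent dose for each observation."""
        dose_times = np.array([e.time for e in self.events])
        out = np.empty(self.n_obs)
        for j, t in enumerate(self.t_obs):
            # strict: a sample drawn exactly at a dose time is the pre-dose
            # trough of the *previous* dose, not t=0 of the new one
            prior = dose_times[dose_times < t]
            if prior.size == 0:
                raise ValueError(
                    f"subject {self.sid}: observation at {t} h precedes first dose")
            out[j] = t - prior.max()
        return out


@dataclass
class PKDataset:
    """Ordered collection of subjects."""

    subjects: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.subjects:
            if s.n_obs < 1:
                raise ValueError(f"subject {s.sid} has no observations")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.subjects)


def _parse_num(x, default=0.0):
    if pd.isna(x) or x in (".", ""):
        return default
    return float(x)


def read_dataset(path_or_df, lloq: float | None = None) -> PKDataset:
    """Parse a NONMEM-style table into a validated PKDataset.

    Covariate columns are any columns beyond the required eight; the
    subject-level covariate value is taken from the first row (covariates
    are baseline constants here).  ``lloq`` flags DV below the limit as
    BLQ without deleting them.
    """
    df = (path_or_df if isinstance(path_or_df, pd.DataFrame)
          else pd.read_csv(path_or_df, float_precision="round_trip"))
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    cov_cols = [c for c in df.columns if c not in REQUIRED_COLS]

    subjects = []
    for sid, grp in df.groupby("ID", sort=False):
        times = grp["TIME"].map(_parse_num).to_numpy()
        if np.any(np.diff(times) < 0):
            raise ValueError(f"subject {sid}: TIME not nondecreasing")
        events, t_obs, dv, blq = [], [], [], []
        for idx, row in grp.iterrows():
            evid = int(_parse_num(row["EVID"]))
            t = _parse_num(row["TIME"])
            if evid == 1:
                if not pd.isna(row["DV"]) and row["DV"] not in (".", ""):
                    raise ValueError(f"row {idx}: dose record carries a DV value")
                amt = _parse_num(row["AMT"])
                rate = _parse_num(row["RATE"])
                cmt = int(_parse_num(row["CMT"], 1))
                if rate > 0:
                    events.append(DoseEvent(t, amt, ROUTE_IV, amt / rate))
                elif cmt == 1:
                    events.append(DoseEvent(t, amt, ROUTE_ORAL))
                else:
                    raise ValueError(
                        f"row {idx}: iv dose (CMT=2) requires RATE > 0 "
                        "(bolus not supported)")
            elif evid == 0:
                mdv = int(_parse_num(row["MDV"]))
                if mdv == 1:
                    continue
                amt = _parse_num(row["AMT"])
                if amt != 0:
                    raise ValueError(f"row {idx}: observation record carries AMT")
                y = _parse_num(row["DV"], np.nan)
                if np.isnan(y):
                    raise ValueError(f"row {idx}: observation with missing DV and MDV=0")
                t_obs.append(t)
                dv.append(y)
                flag = False
                if "BLQ" in grp.columns:
                    flag = bool(_parse_num(row.get("BLQ", 0)))
                if lloq is not None and y < lloq:
                    flag = True
                blq.append(flag)
            else:
                raise ValueError(f"row {idx}: unknown EVID {evid}")
        cov = {c: _parse_num(grp.iloc[0][c], np.nan) for c in cov_cols if c != "BLQ"}
        subjects.append(Subject(sid, events, np.array(t_obs), np.array(dv),
                                np.array(blq, dtype=bool), cov))
    return PKDataset(subjects)


def write_dataset(ds: PKDataset, path=None) -> pd.DataFrame:
    """Serialize a PKDataset to the NONMEM-style table (and CSV if ``path``)."""
    cov_cols: list[str] = []
    for s in ds:
        for c in s.covariates:
            if c not in cov_cols:
                cov_cols.append(c)
    rows = []
    for s in ds:
        recs = [("dose", e.time, e) for e in s.events]
        recs += [("obs", t, j) for j, t in enumerate(s.t_obs)]
        recs.sort(key=lambda r: (r[1], 0 if r[0] == "dose" else 1))
        for kind, t, payload in recs:
            base = {c: s.covariates.get(c, ".") for c in cov_cols}
            if kind == "dose":
                e = payload
                rate = 0.0 if e.is_oral else e.amount / e.infusion_duration
                rows.append({"ID": s.sid, "TIME": t, "AMT": e.amount,
                             "RATE": rate, "EVID": 1, "MDV": 1, "DV": ".",
                             "CMT": 1 if e.is_oral else 2, "BLQ": 0, **base})
            else:
                j = payload
                rows.append({"ID": s.sid, "TIME": t, "AMT": 0, "RATE": 0,
                             "EVID": 0, "MDV": 0, "DV": s.dv[j], "CMT": 2,
                             "BLQ": int(s.blq[j]), **base})
    df = pd.DataFrame(rows, columns=REQUIRED_COLS + ["BLQ"] + cov_cols)
    if path is not None:
        df.to_csv(path, index=False)
    return df
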