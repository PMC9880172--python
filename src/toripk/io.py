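"""NONMEM-style CSV dataset reading/writing and small report helpers.

Dialect: one row per dose or observation event, columns

    ID, TIME, AMT, RATE, DV, EVID, MDV, CMT, BLQ,
    WT, ALB, LDH, CRCL, SEXF, RACE, ADA

Dose rows have EVID=1, MDV=1, AMT in mg and RATE in mg/h (zero-order
infusion, duration AMT/RATE); observation rows have EVID=0, MDV=0 and DV
in ug/mL.  TIME is absolute hours after the first dose.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import PKDataset, SubjectData
from .model_core import CovariateProfile
from .simulate import DoseEvent

__all__ = ["read_pk_dataset", "write_pk_dataset", "dataset_to_frame"]

REQUIRED_COLUMNS = ["ID", "TIME", "AMT", "RATE", "DV", "EVID", "MDV"]
_RACE_CODES = {0: "asian", 1: "white", 2: "other"}
_RACE_NAMES = {v: k for k, v in _RACE_CODES.items()}


def dataset_to_frame(dataset: PKDataset) -> pd.DataFrame:
    rows = []
    for s in dataset.subjects:
        p = s.profile
        cov = {
            "WT": p.weight, "ALB": p.albumin, "LDH": p.ldh, "CRCL": p.crcl,
            "SEXF": int(p.sex == "female"), "RACE": _RACE_NAMES[p.race],
            "ADA": int(p.ada_positive),
        }
        for ev in s.events:
            rows.append(
                {"ID": s.subject_id, "TIME": ev.start, "AMT": ev.rate * ev.duration,
                 "RATE": ev.rate, "DV": 0.0, "EVID": 1, "MDV": 1, "CMT": 1,
                 "BLQ": 0, **cov}
            )
        for t, dv, blq in zip(s.obs_times, s.dv, s.blq):
            rows.append(
                {"ID": s.subject_id, "TIME": t, "AMT": 0.0, "RATE": 0.0,
                 "DV": dv, "EVID": 0, "MDV": 0, "CMT": 1, "BLQ": int(blq), **cov}
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["ID", "TIME", "EVID"], kind="stable",
                          ascending=[True, True, False]).reset_index(drop=True)


def write_pk_dataset(dataset: PKDataset, path) -> None:
    dataset_to_frame(dataset).to_csv(path, index=False)


def read_pk_dataset(path) -> PKDataset:
    """Read and validate a NONMEM-style CSV.

    Raises a named error for a missing required column; malformed rows are
    reported with their (1-based, header-inclusive) line numbers.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    bad = df.index[df["TIME"] < 0].tolist()
    if bad:
        lines = [i + 2 for i in bad]
        raise ValueError(f"negative TIME on line(s) {lines}")
    bad = df.index[~df["EVID"].isin([0, 1])].tolist()
    if bad:
        raise ValueError(f"EVID must be 0 or 1; bad line(s) {[i + 2 for i in bad]}")

    subjects = []
    for sid, sub in df.groupby("ID", sort=True):
        doses = sub[sub["EVID"] == 1]
        obs = sub[sub["EVID"] == 0]
        events = [
            DoseEvent(
                float(r.TIME),
                float(r.RATE) if r.RATE > 0 else float(r.AMT),
                float(r.AMT / r.RATE) if r.RATE > 0 else 1.0,
            )
            for r in doses.itertuples()
        ]
        first = sub.iloc[0]
        profile = CovariateProfile(
            weight=float(first.get("WT", 64.0)),
            albumin=float(first.get("ALB", 43.7)),
            ldh=float(first.get("LDH", 199.0)),
            crcl=float(first.get("CRCL", 94.31)),
            sex="female" if int(first.get("SEXF", 0)) else "male",
            race=_RACE_CODES[int(first.get("RACE", 0))],
            ada_positive=bool(int(first.get("ADA", 0))),
        )
        blq = (
            obs["BLQ"].to_numpy().astype(bool)
            if "BLQ" in obs.columns
            else np.zeros(len(obs), dtype=bool)
        )
        subjects.append(
            SubjectData(
                subject_id=sid,
                events=events,
                obs_times=obs["TIME"].to_numpy(dtype=float),
                dv=obs["DV"].to_numpy(dtype=float),
                blq=blq,
                profile=profile,
            )
        )
    return PKDataset(subjects)
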