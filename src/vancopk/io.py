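"""Rectangular dataset I/O and run configuration.

Cohorts are written as NONMEM-convention CSV files: one dose row per
patient (EVID=1, SS=1 with II = inter-dose interval, AMT in mg, DUR in
h) followed by observation rows (EVID=0, MDV=0, DV in mg/L, TIME in
hours from the start of the steady-state infusion). Covariates travel
on every row (WT kg, PNA days, GA weeks, PMA weeks, HT cm, SEX 0=male
1=female, SCR µmol/L); the extra LABEL column marks observation rows as
peak or trough. Missing values are encoded as ``.``.

Malformed rows are rejected with row-numbered log messages — an
explicit validation report rather than silent dropping.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .bayes import Observation, ObservationSet
from .cohort import PatientRecord
from .pk import CovariateRecord, DoseEvent, Regimen

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ["ID", "TIME", "EVID", "AMT", "DUR", "II", "DV", "MDV",
                     "WT", "PNA", "SCR"]
ALL_COLUMNS = MANDATORY_COLUMNS + ["RATE", "SS", "GA", "PMA", "HT", "SEX",
                                   "LABEL"]

_NA = "."


class RunConfig(BaseModel):
    """End-to-end pipeline configuration (CLI `all`)."""

    model_config = ConfigDict(extra="forbid")

    cohort: str = "A"
    n_patients: int = 50
    seed: int = 1
    generating_model: str = ""        # default: first cohort-matched model
    models: list[str] = []            # bundled names; default: cohort-matched
    scenarios: list[str] = ["peak+trough", "peak", "trough", "a priori"]
    bootstrap_resamples: int = 2000
    rbias_threshold: float = 15.0
    rrmse_threshold: float = 20.0
    noise_scale: float = 1.0
    outdir: str = "vancopk_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def write_dataset(patients: list[PatientRecord], path) -> None:
    rows = []
    for p in patients:
        cov = p.covariates
        base = {"ID": p.id, "WT": cov.weight, "PNA": cov.postnatal_age,
                "GA": cov.gestational_age, "PMA": cov.postmenstrual_age,
                "HT": cov.height,
                "SEX": {None: None, "male": 0, "female": 1}[cov.sex],
                "SCR": cov.serum_creatinine}
        rows.append({**base, "TIME": 0.0, "EVID": 1,
                     "AMT": p.regimen.maintenance_dose,
                     "RATE": p.regimen.maintenance_dose
                     / p.regimen.infusion_duration,
                     "DUR": p.regimen.infusion_duration,
                     "II": p.regimen.tau, "SS": 1, "DV": None, "MDV": 1,
                     "LABEL": None})
        for o in sorted(p.observations.observations, key=lambda o: o.time):
            rows.append({**base, "TIME": o.time, "EVID": 0, "AMT": None,
                         "RATE": None, "DUR": None, "II": None, "SS": None,
                         "DV": o.concentration, "MDV": 0, "LABEL": o.label})
    df = pd.DataFrame(rows, columns=ALL_COLUMNS)
    df.to_csv(path, index=False, na_rep=_NA, float_format="%.6g")


def read_dataset(path) -> list[PatientRecord]:
    """Parse a dataset back into patient records, validating rows."""
    df = pd.read_csv(path, na_values=[_NA], dtype={"ID": str, "LABEL": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    patients: list[PatientRecord] = []
    for pid, grp in df.groupby("ID", sort=False):
        grp = grp.reset_index().rename(columns={"index": "row"})
        times = grp["TIME"].to_numpy()
        if np.any(times < 0) or np.any(np.diff(times) < 0):
            logger.warning("patient %s rejected: times negative or "
                           "non-monotone (rows %s)", pid,
                           list(grp["row"] + 2))
            continue
        dose_rows = grp[grp["EVID"] == 1]
        if len(dose_rows) < 1:
            logger.warning("patient %s rejected: no dose row", pid)
            continue
        d = dose_rows.iloc[0]
        try:
            events = [DoseEvent(float(r.AMT), float(r.TIME), float(r.DUR))
                      for r in dose_rows.itertuples()]
            regimen = Regimen(maintenance_dose=float(d["AMT"]),
                              tau=float(d["II"]),
                              infusion_duration=float(d["DUR"]),
                              dose_events=tuple(events))
        except (ValueError, TypeError) as err:
            logger.warning("patient %s rejected: invalid dosing row %d (%s)",
                           pid, int(d["row"]) + 2, err)
            continue
        obs = []
        ok = True
        for r in grp[grp["EVID"] == 0].itertuples():
            if not (np.isfinite(r.DV) and r.DV > 0):
                logger.warning("row %d rejected: observation DV must be "
                               "positive, got %s (patient %s)",
                               int(r.row) + 2, r.DV, pid)
                ok = False
                continue
            label = r.LABEL if isinstance(r.LABEL, str) else (
                "peak" if r.TIME <= regimen.infusion_duration + 3.0
                else "trough")
            obs.append(Observation(float(r.TIME), float(r.DV), label))
        if not ok:
            logger.warning("patient %s retained with %d valid observations "
                           "after rejections", pid, len(obs))
        try:
            cov = CovariateRecord(
                weight=float(d["WT"]), postnatal_age=float(d["PNA"]),
                serum_creatinine=float(d["SCR"]),
                gestational_age=_opt(d, "GA"),
                postmenstrual_age=_opt(d, "PMA"), height=_opt(d, "HT"),
                sex={0: "male", 1: "female"}.get(_opt(d, "SEX")))
        except ValueError as err:
            logger.warning("patient %s rejected: invalid covariates (%s)",
                           pid, err)
            continue
        patients.append(PatientRecord(id=str(pid), covariates=cov,
                                      regimen=regimen,
                                      observations=ObservationSet(tuple(obs))))
    return patients


def _opt(row, name):
    if name not in row.index:
        return None
    v = row[name]
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return None
    return float(v) if name != "SEX" else int(v)


def write_truth(patients: list[PatientRecord], path) -> None:
    """Hidden-truth sidecar: generator AUC and random effects per patient."""
    rows = []
    for p in patients:
        row = {"ID": p.id, "TRUE_AUC24": p.true_auc24}
        if p.true_eta is not None:
            for i, e in enumerate(np.atleast_1d(p.true_eta)):
                row[f"ETA{i + 1}"] = e
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8g")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"ID": str})


def ensure_outdir(outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out
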