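"""Virtual replicates of the single-dose healthy-volunteer trial.

The emulated design: n subjects (default 12) receive 500 mg of meropenem as
a 0.5-h IV infusion, with plasma sampled at 0 (pre-dose), 0.5, 0.75, 1, 2,
3 and 6 h after the start of infusion.  Individual parameters come from the
population model (creatinine covariate + shared-eta IIV); observations are
the model-predicted concentrations perturbed by proportional residual error
y = C*(1 + eps), eps ~ N(0, sigma_prop^2), truncated at zero.

Datasets are NONMEM-style rectangular CSVs: one EVID=1 dosing record per
subject (AMT, RATE, MDV=1) followed by EVID=0 observation records (DV,
MDV=0), plus covariate columns CR, AGE, WT, HT, SEX (1 = male).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .model_core import PKParameters, Regimen, concentration
from .nca import SubjectProfile
from .population import (
    CovariateDistribution,
    PopulationModel,
    sample_population,
)

__all__ = [
    "StudyDesign",
    "generate_study",
    "write_dataset",
    "read_dataset",
    "profiles_from_dataset",
]

DATASET_COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "DV", "EVID", "MDV",
    "CR", "AGE", "WT", "HT", "SEX",
]


@dataclass(frozen=True)
class StudyDesign:
    """The trial design being replicated."""

    n_subjects: int = 12
    dose: float = 500.0
    infusion_duration: float = 0.5
    sampling_times: tuple = (0.0, 0.5, 0.75, 1.0, 2.0, 3.0, 6.0)
    sigma_prop: float = 0.109
    error_on: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.dose <= 0 or self.infusion_duration <= 0:
            raise ValueError("dose and infusion_duration must be positive")
        times = tuple(float(t) for t in self.sampling_times)
        if any(t < 0 for t in times) or sorted(set(times)) != list(times):
            raise ValueError("sampling times must be unique, sorted, non-negative")
        if self.infusion_duration not in times:
            raise ValueError("sampling times must include the end of infusion")
        if self.sigma_prop < 0:
            raise ValueError("sigma_prop must be non-negative")
        object.__setattr__(self, "sampling_times", times)


def generate_study(
    design: StudyDesign = StudyDesign(),
    model: PopulationModel = PopulationModel(),
    covs: CovariateDistribution = CovariateDistribution(),
    seed: Union[int, np.random.Generator, None] = None,
) -> pd.DataFrame:
    """Simulate one study replicate as a NONMEM-style DataFrame.

    Deterministic under ``seed``: the same seed yields a byte-identical
    dataset.  With ``error_on=False`` the DV column equals the model
    prediction exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = sample_population(model, covs, design.n_subjects, rng, demographics=True)
    regimen = Regimen(
        dose=design.dose,
        infusion_duration=design.infusion_duration,
        interval=max(design.sampling_times[-1], design.infusion_duration),
    )
    times = np.asarray(design.sampling_times)
    records = []
    for row in pop.itertuples(index=False):
        params = PKParameters(row.CL, row.V1, row.Q, row.V2)
        pred = concentration(params, regimen, times, n_doses=1)
        if design.error_on and design.sigma_prop > 0:
            eps = rng.normal(0.0, design.sigma_prop, times.size)
            dv = np.maximum(pred * (1.0 + eps), 0.0)
        else:
            dv = pred
        cov = dict(
            CR=row.CR, AGE=row.AGE, WT=row.WT, HT=row.HT, SEX=int(row.SEX)
        )
        records.append(
            dict(
                ID=int(row.ID), TIME=0.0, AMT=design.dose,
                RATE=design.dose / design.infusion_duration,
                DV=0.0, EVID=1, MDV=1, **cov,
            )
        )
        for t, y in zip(times, dv):
            records.append(
                dict(
                    ID=int(row.ID), TIME=float(t), AMT=0.0, RATE=0.0,
                    DV=float(y), EVID=0, MDV=0, **cov,
                )
            )
    return pd.DataFrame.from_records(records, columns=DATASET_COLUMNS)


def write_dataset(dataset: pd.DataFrame, path) -> None:
    """Write a NONMEM-style dataset to CSV (shortest round-trip floats)."""
    dataset.to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read a NONMEM-style CSV written by :func:`write_dataset`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("ID", "TIME", "DV", "EVID") if c not in df.columns]
    if missing:
        raise ValueError(f"dataset missing required columns: {missing}")
    return df


def profiles_from_dataset(dataset: pd.DataFrame) -> list[SubjectProfile]:
    """Split a dataset into per-subject profiles for NCA or fitting.

    Dose and infusion duration are recovered from each subject's EVID=1
    record (duration = AMT/RATE).
    """
    profiles = []
    for sid, grp in dataset.groupby("ID", sort=True):
        doses = grp[grp["EVID"] == 1]
        if len(doses) != 1:
            raise ValueError(f"subject {sid}: expected exactly one dosing record")
        amt = float(doses["AMT"].iloc[0])
        rate = float(doses["RATE"].iloc[0])
        if amt <= 0 or rate <= 0:
            raise ValueError(f"subject {sid}: dosing record needs positive AMT and RATE")
        obs = grp[grp["EVID"] == 0].sort_values("TIME")
        profiles.append(
            SubjectProfile(
                subject_id=sid,
                dose=amt,
                infusion_duration=amt / rate,
                times=obs["TIME"].to_numpy(dtype=float),
                concentrations=obs["DV"].to_numpy(dtype=float),
                weight=float(grp["WT"].iloc[0]) if "WT" in grp.columns else None,
            )
        )
    return profiles
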