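"""Final population-PK model of meropenem in healthy adults.

Typical values, the serum-creatinine covariate law on clearance, the
shared-eta interindividual-variability (IIV) structure, virtual-patient
sampling for Monte Carlo simulation, and the renal-function equation suite
(Cockcroft-Gault, MDRD, CKD-EPI creatinine / cystatin C / combined, du Bois
body surface area).

Model structure
---------------
CL_i  = theta1 * (CR_i / 0.86)**theta2 * exp(eta_CL,i)
V1_i  = tv_V1 * exp(shared_exponent * eta_CL,i)      (shared eta)
Q_i   = tv_Q  * exp(eta_Q,i)
V2_i  = tv_V2 * exp(eta_V2,i)

with eta_CL ~ N(0, omega_CL^2) and independent eta_Q, eta_V2.  The single
eta driving both CL and V1 induces perfect log-scale correlation between
them, with the V1 log-deviation 1.53 times that of CL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd

from .model_core import PKParameters

__all__ = [
    "PopulationModel",
    "CovariateDistribution",
    "Subject",
    "typical_cl",
    "typical_params",
    "sample_population",
    "lognormal_mean_cv",
    "body_surface_area",
    "renal_functions",
]

Sex = Literal["male", "female"]


@dataclass(frozen=True)
class PopulationModel:
    """Fixed and random effects of the final model.

    Defaults are the published estimates: typical CL 12.4 L/h at the
    reference creatinine 0.86 mg/dL with covariate exponent -0.392; typical
    V1 8.26 L, Q 5.22 L/h, V2 4.06 L; omega values are SDs of the
    log-scale etas (26.2% CL, 14.4% Q fixed, 17.9% V2 fixed); V1 shares
    CL's eta scaled by 1.53; proportional residual SD 10.9%.
    """

    theta1: float = 12.4
    theta2: float = -0.392
    tv_V1: float = 8.26
    tv_Q: float = 5.22
    tv_V2: float = 4.06
    omega_CL: float = 0.262
    shared_exponent: float = 1.53
    omega_Q: float = 0.144
    omega_V2: float = 0.179
    sigma_prop: float = 0.109
    cr_ref: float = 0.86

    def __post_init__(self) -> None:
        if self.theta1 <= 0:
            raise ValueError("theta1 must be positive")
        for name in ("omega_CL", "omega_Q", "omega_V2", "sigma_prop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CovariateDistribution:
    """Arithmetic means and CVs (fractions) of the study covariates.

    Creatinine drives the kinetics; the demographic entries matter only for
    per-kg reporting and the renal-function table.  All are sampled
    log-normal with the stated arithmetic mean and CV.
    """

    cr_mean: float = 0.863
    cr_cv: float = 0.190
    weight_mean: float = 65.7
    weight_cv: float = 0.208
    age_mean: float = 36.8
    age_cv: float = 0.199
    height_mean: float = 168.0
    height_cv: float = 0.0429
    cystatin_mean: float = 0.790
    cystatin_cv: float = 0.159
    male_fraction: float = 8.0 / 12.0

    def __post_init__(self) -> None:
        if self.cr_mean <= 0 or self.cr_cv < 0:
            raise ValueError("creatinine mean must be > 0 and CV >= 0")


@dataclass
class Subject:
    """One (virtual) subject: covariates plus individual PK parameters."""

    id: int
    CR: float
    params: PKParameters
    age: Optional[float] = None
    weight: Optional[float] = None
    height: Optional[float] = None
    sex: Optional[Sex] = None
    eta_CL: float = 0.0


def typical_cl(cr, model: PopulationModel = PopulationModel()):
    """Typical (population) clearance at serum creatinine ``cr`` mg/dL.

    CL = theta1 * (cr / cr_ref)**theta2; strictly decreasing in cr for
    theta2 < 0.  Accepts scalars or arrays.
    """
    cr = np.asarray(cr, dtype=float)
    if np.any(cr <= 0) or not np.all(np.isfinite(cr)):
        raise ValueError("serum creatinine must be strictly positive")
    out = model.theta1 * (cr / model.cr_ref) ** model.theta2
    return float(out) if out.ndim == 0 else out


def typical_params(
    cr: Optional[float] = None, model: PopulationModel = PopulationModel()
) -> PKParameters:
    """PKParameters of the typical subject (at ``cr``, default reference)."""
    cl = model.theta1 if cr is None else typical_cl(cr, model)
    return PKParameters(CL=cl, V1=model.tv_V1, Q=model.tv_Q, V2=model.tv_V2)


def lognormal_mean_cv(mean: float, cv: float, size, rng: np.random.Generator):
    """Log-normal draws with a given *arithmetic* mean and CV."""
    if cv == 0:
        return np.full(size, mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def sample_population(
    model: PopulationModel,
    covs: CovariateDistribution,
    n: int,
    seed: Union[int, np.random.Generator, None] = None,
    *,
    include_fixed_iiv: bool = True,
    demographics: bool = False,
    fixed_cr: Optional[float] = None,
) -> pd.DataFrame:
    """Sample ``n`` virtual subjects from the population model.

    Creatinine is drawn log-normal (arithmetic mean/CV from ``covs``) unless
    ``fixed_cr`` pins it; etas are normal on the log scale with the model's
    omegas.  ``include_fixed_iiv=False`` zeroes the fixed-omega variability
    on Q and V2.  With ``demographics=True``, age/weight/height/sex (and
    cystatin C) are added for record completeness; they do not enter the
    kinetics.

    Returns a DataFrame with columns ID, CR, CL, V1, Q, V2, ETA_CL (plus
    AGE, WT, HT, SEX, CYSC when requested), reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cr = (
        np.full(n, float(fixed_cr))
        if fixed_cr is not None
        else lognormal_mean_cv(covs.cr_mean, covs.cr_cv, n, rng)
    )
    eta_cl = rng.normal(0.0, model.omega_CL, n)
    cl = typical_cl(cr, model) * np.exp(eta_cl)
    v1 = model.tv_V1 * np.exp(model.shared_exponent * eta_cl)
    if include_fixed_iiv:
        q = model.tv_Q * np.exp(rng.normal(0.0, model.omega_Q, n))
        v2 = model.tv_V2 * np.exp(rng.normal(0.0, model.omega_V2, n))
    else:
        q = np.full(n, model.tv_Q)
        v2 = np.full(n, model.tv_V2)
    out = pd.DataFrame(
        {
            "ID": np.arange(1, n + 1),
            "CR": cr,
            "CL": cl,
            "V1": v1,
            "Q": q,
            "V2": v2,
            "ETA_CL": eta_cl,
        }
    )
    if demographics:
        out["AGE"] = lognormal_mean_cv(covs.age_mean, covs.age_cv, n, rng)
        out["WT"] = lognormal_mean_cv(covs.weight_mean, covs.weight_cv, n, rng)
        out["HT"] = lognormal_mean_cv(covs.height_mean, covs.height_cv, n, rng)
        out["CYSC"] = lognormal_mean_cv(covs.cystatin_mean, covs.cystatin_cv, n, rng)
        out["SEX"] = np.where(rng.random(n) < covs.male_fraction, 1, 0)  # 1 male
    return out


def subjects_from_frame(frame: pd.DataFrame) -> list[Subject]:
    """Convert a sampled population DataFrame into Subject records."""
    subs = []
    for row in frame.itertuples(index=False):
        subs.append(
            Subject(
                id=int(row.ID),
                CR=float(row.CR),
                params=PKParameters(row.CL, row.V1, row.Q, row.V2),
                age=float(row.AGE) if hasattr(row, "AGE") else None,
                weight=float(row.WT) if hasattr(row, "WT") else None,
                height=float(row.HT) if hasattr(row, "HT") else None,
                sex=("male" if row.SEX == 1 else "female") if hasattr(row, "SEX") else None,
                eta_CL=float(row.ETA_CL) if hasattr(row, "ETA_CL") else 0.0,
            )
        )
    return subs


def body_surface_area(height_cm: float, weight_kg: float) -> float:
    """du Bois BSA (m^2): 0.007185 * height^0.725 * weight^0.425."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return 0.007185 * height_cm**0.725 * weight_kg**0.425


def renal_functions(
    *,
    age: float,
    weight: float,
    height: float,
    sex: Sex,
    cr: float,
    cystatin_c: Optional[float] = None,
) -> dict:
    """Creatinine clearance and eGFR by the standard equation suite.

    Returns a dict with Cockcroft-Gault (absolute mL/min and BSA-normalized
    mL/min/1.73 m^2), MDRD, CKD-EPI creatinine, CKD-EPI cystatin C, CKD-EPI
    creatinine-cystatin (all mL/min/1.73 m^2), their BSA-adjusted absolute
    variants (mL/min), and the du Bois BSA.  Cystatin-dependent entries are
    ``None`` when ``cystatin_c`` is missing.
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    for name, v in (("age", age), ("weight", weight), ("height", height), ("cr", cr)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    female = sex == "female"
    bsa = body_surface_area(height, weight)

    cg = (140.0 - age) * weight / (72.0 * cr)
    if female:
        cg *= 0.85
    cg_norm = cg / bsa * 1.73

    mdrd = 175.0 * cr**-1.154 * age**-0.203
    if female:
        mdrd *= 0.742

    kappa = 0.7 if female else 0.9
    if female:
        ckdepi_cr = (
            142.0
            * min(cr / kappa, 1.0) ** -0.241
            * max(cr / kappa, 1.0) ** -1.200
            * 0.9938**age
            * 1.012
        )
    else:
        ckdepi_cr = (
            142.0
            * min(cr / kappa, 1.0) ** -0.302
            * max(cr / kappa, 1.0) ** -1.200
            * 0.9938**age
        )

    ckdepi_cys = ckdepi_cr_cys = None
    if cystatin_c is not None:
        if cystatin_c <= 0:
            raise ValueError("cystatin_c must be positive")
        cc = cystatin_c
        ckdepi_cys = (
            133.0
            * min(cc / 0.7, 1.0) ** -0.499
            * max(cc / 0.7, 1.0) ** -1.328
            * 0.9962**age
        )
        if female:
            ckdepi_cys *= 0.932
        ckdepi_cr_cys = (
            135.0
            * min(cr / kappa, 1.0) ** (-0.219 if female else -0.144)
            * max(cr / kappa, 1.0) ** -0.544
            * min(cc / 0.8, 1.0) ** 0.323
            * max(cc / 0.8, 1.0) ** -0.778
            * 0.9961**age
        )
        if female:
            ckdepi_cr_cys *= 0.963

    def absolute(egfr):
        return None if egfr is None else egfr / 1.73 * bsa

    return {
        "bsa": bsa,
        "clcr_cg": cg,
        "clcr_cg_normalized": cg_norm,
        "egfr_mdrd": mdrd,
        "egfr_ckdepi_cr": ckdepi_cr,
        "egfr_ckdepi_cys": ckdepi_cys,
        "egfr_ckdepi_cr_cys": ckdepi_cr_cys,
        "egfr_mdrd_adjusted": absolute(mdrd),
        "egfr_ckdepi_cr_adjusted": absolute(ckdepi_cr),
        "egfr_ckdepi_cys_adjusted": absolute(ckdepi_cys),
        "egfr_ckdepi_cr_cys_adjusted": absolute(ckdepi_cr_cys),
    }
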