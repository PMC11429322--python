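"""Noncompartmental analysis of concentration-time profiles.

Implements the standard single-dose IV-infusion NCA parameter set:
terminal slope lambda_z by log-linear regression, AUC/AUMC by the
linear-up/log-down trapezoid, extrapolation to infinity, and the derived
clearance and volume terms

    AUCinf  = AUClast + Clast/lambda_z
    AUMCinf = AUMClast + Tlast*Clast/lambda_z + Clast/lambda_z**2
    MRTinf  = AUMCinf/AUCinf - T_inf/2
    CL_NCA  = dose/AUCinf,  Vz = CL_NCA/lambda_z,  Vss = MRTinf*CL_NCA,
    t_half  = ln(2)/lambda_z.

Cmax, Tlast and Clast are taken from the observed data only (no
interpolation); Tlast/Clast refer to the last strictly positive
observation.  Falling segments with both endpoints positive use the log
trapezoid, which is exact for mono-exponential decline; rising, flat, or
zero-ending segments fall back to the linear trapezoid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SubjectProfile",
    "LambdaZFit",
    "NCAResult",
    "lambda_z",
    "auc_aumc",
    "extrapolate",
    "analyze_profile",
    "analyze_dataset",
    "summarize",
]

LOG2 = math.log(2.0)


@dataclass(frozen=True)
class SubjectProfile:
    """One subject's dose and sorted concentration-time observations."""

    subject_id: object
    dose: float
    infusion_duration: float
    times: np.ndarray
    concentrations: np.ndarray
    weight: Optional[float] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(t < 0) or np.any(c < 0):
            raise ValueError("times and concentrations must be non-negative")
        if self.dose <= 0 or self.infusion_duration <= 0:
            raise ValueError("dose and infusion_duration must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression result."""

    lambda_z: float
    intercept: float  # ln-concentration at t = 0 of the regression line
    n_points: int
    adj_r_squared: float
    success: bool
    message: str = ""

    def predict(self, t: float) -> float:
        return math.exp(self.intercept - self.lambda_z * t)


@dataclass
class NCAResult:
    subject_id: object
    dose: float
    cmax: float
    tmax: float
    tlast: float
    clast: float
    auc_last: float
    auc_inf: Optional[float]
    aumc_last: float
    aumc_inf: Optional[float]
    mrt_inf: Optional[float]
    lambda_z: Optional[float]
    lambda_z_n_points: Optional[int]
    lambda_z_adj_r2: Optional[float]
    cl_nca: Optional[float]
    vz_nca: Optional[float]
    vss_nca: Optional[float]
    t_half_lambda_z: Optional[float]
    lambda_z_failed: bool = False


def _loglin_fit(t: np.ndarray, c: np.ndarray) -> tuple:
    """Least-squares slope/intercept of ln(c) on t with adjusted R^2."""
    y = np.log(c)
    n = t.size
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return slope, intercept, adj


def lambda_z(
    profile: SubjectProfile,
    *,
    rule: Literal["best_fit", "last_n"] = "best_fit",
    n_points: int = 3,
    min_points: int = 3,
) -> LambdaZFit:
    """Terminal elimination rate constant by log-linear regression.

    ``best_fit`` (default) scans contiguous terminal windows of at least
    ``min_points`` positive post-peak observations (excluding Cmax itself)
    and keeps the window with the best adjusted R^2, ties going to the
    longer window.  ``last_n`` uses exactly the last ``n_points`` positive
    observations.  A non-negative slope or too few usable points is flagged
    as failure and downstream extrapolations are withheld.
    """
    t, c = profile.times, profile.concentrations
    pos = c > 0
    if pos.sum() < min_points:
        return LambdaZFit(math.nan, math.nan, 0, math.nan, False, "fewer than 3 positive points")
    i_cmax = int(np.argmax(c))
    # candidate terminal points: positive observations after (not at) Cmax
    cand = np.nonzero(pos & (np.arange(t.size) > i_cmax))[0]
    if cand.size < min_points:
        return LambdaZFit(
            math.nan, math.nan, 0, math.nan, False, "fewer than 3 positive post-peak points"
        )
    if rule == "last_n":
        windows = [cand[-n_points:]] if cand.size >= n_points else []
    elif rule == "best_fit":
        windows = [cand[-k:] for k in range(min_points, cand.size + 1)]
    else:
        raise ValueError(f"unknown rule {rule!r}")
    best = None
    for w in windows:
        slope, intercept, adj = _loglin_fit(t[w], c[w])
        if slope >= 0:
            continue
        # ties (within 1e-12) resolved toward more points; windows iterate
        # short -> long, so >= keeps the longer one
        if best is None or adj >= best[0] - 1e-12:
            best = (adj, slope, intercept, len(w))
    if best is None:
        return LambdaZFit(math.nan, math.nan, 0, math.nan, False, "no window with negative slope")
    adj, slope, intercept, npts = best
    return LambdaZFit(-slope, intercept, npts, adj, True)


def auc_aumc(times, concentrations) -> tuple:
    """(AUClast, AUMClast) by the linear-up/log-down trapezoid.

    Falling segments with both endpoints > 0 use the log trapezoid
    dt*(C1-C2)/ln(C1/C2) and its moment analogue
    (t1*C1 - t2*C2)/k + (C1-C2)/k^2 with k = ln(C1/C2)/dt; all other
    segments use the linear rule.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    auc = aumc = 0.0
    for i in range(t.size - 1):
        t1, t2, c1, c2 = t[i], t[i + 1], c[i], c[i + 1]
        dt = t2 - t1
        if c2 < c1 and c2 > 0:
            k = math.log(c1 / c2) / dt
            auc += (c1 - c2) / k
            aumc += (t1 * c1 - t2 * c2) / k + (c1 - c2) / k**2
        else:
            auc += 0.5 * dt * (c1 + c2)
            aumc += 0.5 * dt * (t1 * c1 + t2 * c2)
    return auc, aumc


def extrapolate(profile: SubjectProfile, fit: Optional[LambdaZFit] = None) -> NCAResult:
    """Full NCA parameter set for one profile.

    Extrapolated quantities are withheld (None) when the terminal fit
    failed.  If the last observation is zero, Tlast/Clast refer to the last
    positive observation and the observed zero tail contributes only its
    linear-trapezoid area up to that point (i.e. nothing beyond Tlast).
    """
    if fit is None:
        fit = lambda_z(profile)
    t, c = profile.times, profile.concentrations
    i_cmax = int(np.argmax(c))
    cmax, tmax = float(c[i_cmax]), float(t[i_cmax])
    pos = np.nonzero(c > 0)[0]
    if pos.size == 0:
        raise ValueError("profile has no positive concentrations")
    i_last = int(pos[-1])
    tlast, clast = float(t[i_last]), float(c[i_last])
    auc_last, aumc_last = auc_aumc(t[: i_last + 1], c[: i_last + 1])

    res = NCAResult(
        subject_id=profile.subject_id,
        dose=profile.dose,
        cmax=cmax,
        tmax=tmax,
        tlast=tlast,
        clast=clast,
        auc_last=auc_last,
        auc_inf=None,
        aumc_last=aumc_last,
        aumc_inf=None,
        mrt_inf=None,
        lambda_z=None,
        lambda_z_n_points=None,
        lambda_z_adj_r2=None,
        cl_nca=None,
        vz_nca=None,
        vss_nca=None,
        t_half_lambda_z=None,
        lambda_z_failed=not fit.success,
    )
    if not fit.success:
        return res
    lz = fit.lambda_z
    auc_inf = auc_last + clast / lz
    aumc_inf = aumc_last + tlast * clast / lz + clast / lz**2
    mrt_inf = aumc_inf / auc_inf - profile.infusion_duration / 2.0
    cl = profile.dose / auc_inf
    res.lambda_z = lz
    res.lambda_z_n_points = fit.n_points
    res.lambda_z_adj_r2 = fit.adj_r_squared
    res.auc_inf = auc_inf
    res.aumc_inf = aumc_inf
    res.mrt_inf = mrt_inf
    res.cl_nca = cl
    res.vz_nca = cl / lz
    res.vss_nca = mrt_inf * cl
    res.t_half_lambda_z = LOG2 / lz
    return res


def analyze_profile(profile: SubjectProfile, **lambda_z_kwargs) -> NCAResult:
    """lambda_z + trapezoids + extrapolation in one call."""
    return extrapolate(profile, lambda_z(profile, **lambda_z_kwargs))


_RESULT_COLUMNS = [
    "subject_id",
    "dose",
    "cmax",
    "tmax",
    "tlast",
    "clast",
    "auc_last",
    "auc_inf",
    "aumc_last",
    "aumc_inf",
    "mrt_inf",
    "lambda_z",
    "lambda_z_n_points",
    "lambda_z_adj_r2",
    "cl_nca",
    "vz_nca",
    "vss_nca",
    "t_half_lambda_z",
]


def analyze_dataset(
    profiles, *, weight_normalize: bool = False, **lambda_z_kwargs
) -> pd.DataFrame:
    """NCA per subject; one row per profile.

    With ``weight_normalize``, CL/Vz/Vss are additionally reported per kg
    (columns with a ``_per_kg`` suffix) for profiles carrying a weight.
    """
    rows = []
    for p in profiles:
        r = extrapolate(p, lambda_z(p, **lambda_z_kwargs))
        d = {k: getattr(r, k) for k in _RESULT_COLUMNS}
        if weight_normalize and p.weight:
            for k in ("cl_nca", "vz_nca", "vss_nca"):
                d[k + "_per_kg"] = None if d[k] is None else d[k] / p.weight
        rows.append(d)
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean, CV%, median and IQR of each numeric NCA parameter."""
    num = results.drop(columns=["subject_id"], errors="ignore").select_dtypes("number")
    out = pd.DataFrame(
        {
            "mean": num.mean(),
            "cv_percent": 100.0 * num.std(ddof=1) / num.mean(),
            "median": num.median(),
            "q1": num.quantile(0.25),
            "q3": num.quantile(0.75),
        }
    )
    out.index.name = "parameter"
    return out
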