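"""Closed-form two-compartment IV-infusion kinetics.

Central-compartment concentrations for zero-order (constant-rate) infusions
under linear, first-order disposition: single doses, finite multiple-dose
superposition, analytic steady state via per-exponential accumulation
factors, and continuous-infusion plateaus.  A numeric ODE integrator is
provided as an independent oracle for testing the closed forms.

Units throughout: time h, dose mg, volume L, clearance L/h, concentration
mg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PKParameters",
    "MicroConstants",
    "Regimen",
    "micro_constants",
    "disposition_arrays",
    "unit_infusion_conc",
    "unit_steady_state_conc",
    "concentration",
    "ode_oracle",
    "half_lives",
]

LOG2 = math.log(2.0)

# Relative gap below which the hybrid rate constants are treated as a
# repeated root and k21 is nudged; unreachable for physiological parameters.
_REPEATED_ROOT_RTOL = 1e-9
_NUDGE = 1e-9


@dataclass(frozen=True)
class PKParameters:
    """Individual two-compartment parameters.

    CL : total clearance (L/h); V1 : central volume (L);
    Q : intercompartmental clearance (L/h); V2 : peripheral volume (L).
    Q = 0 is accepted as the one-compartment limit.
    """

    CL: float
    V1: float
    Q: float
    V2: float

    def __post_init__(self) -> None:
        for name in ("CL", "V1", "V2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not (math.isfinite(self.Q) and self.Q >= 0):
            raise ValueError(f"Q must be non-negative, got {self.Q!r}")

    @property
    def vss(self) -> float:
        """Steady-state volume of distribution, V1 + V2 (L)."""
        return self.V1 + self.V2


@dataclass(frozen=True)
class MicroConstants:
    """Micro rate constants and hybrid disposition rates (all 1/h).

    k10 = CL/V1, k12 = Q/V1, k21 = Q/V2; lambda1 (alpha) and lambda2 (beta)
    are the roots of s^2 - (k10+k12+k21) s + k10*k21 = 0 with
    lambda1 >= lambda2 >= 0.
    """

    k10: float
    k12: float
    k21: float
    lambda1: float
    lambda2: float


@dataclass(frozen=True)
class Regimen:
    """A dosing regimen.

    Intermittent mode: `dose` mg infused over `infusion_duration` h every
    `interval` h.  Continuous mode: `dose` is the total daily amount and the
    infusion runs at dose/24 mg/h without interruption.
    """

    dose: float
    infusion_duration: float = 0.5
    interval: float = 8.0
    mode: Literal["intermittent", "continuous"] = "intermittent"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dose) and self.dose >= 0):
            raise ValueError(f"dose must be non-negative, got {self.dose!r}")
        if self.mode == "intermittent":
            if not (0 < self.infusion_duration <= self.interval):
                raise ValueError(
                    "need 0 < infusion_duration <= interval, got "
                    f"{self.infusion_duration!r} / {self.interval!r}"
                )
        elif self.mode != "continuous":
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h (dose/24 for continuous mode)."""
        if self.mode == "continuous":
            return self.dose / 24.0
        return self.dose / self.infusion_duration


def _disposition_raw(CL, V1, Q, V2):
    k10 = CL / V1
    k12 = Q / V1
    k21 = Q / V2
    s = k10 + k12 + k21
    p = k10 * k21
    disc = np.maximum(s * s - 4.0 * p, 0.0)
    root = np.sqrt(disc)
    lam1 = 0.5 * (s + root)
    lam2 = np.maximum(0.5 * (s - root), 0.0)
    return k10, k12, k21, lam1, lam2


def disposition_arrays(CL, V1, Q, V2):
    """Vectorized disposition: hybrid rates and unit-bolus coefficients.

    Returns ``(lam1, lam2, c1, c2)`` such that the central concentration
    after a unit IV bolus is ``c1*exp(-lam1*t) + c2*exp(-lam2*t)``.
    Broadcasts over array inputs.
    """
    CL, V1, Q, V2 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (CL, V1, Q, V2))
    )
    k10, k12, k21, lam1, lam2 = _disposition_raw(CL, V1, Q, V2)
    near = (lam1 - lam2) <= _REPEATED_ROOT_RTOL * lam1
    if np.any(near):
        k21n = np.where(near, k21 * (1.0 + _NUDGE) + (k21 == 0) * _NUDGE, k21)
        s = k10 + k12 + k21n
        root = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21n, 0.0))
        lam1 = np.where(near, 0.5 * (s + root), lam1)
        lam2 = np.where(near, np.maximum(0.5 * (s - root), 0.0), lam2)
        k21 = k21n
    gap = lam1 - lam2
    c1 = (lam1 - k21) / (V1 * gap)
    c2 = (k21 - lam2) / (V1 * gap)
    return lam1, lam2, c1, c2


def micro_constants(params: PKParameters) -> MicroConstants:
    """Micro constants and hybrid rates for a parameter set.

    lambda1*lambda2 = k10*k21 and lambda1+lambda2 = k10+k12+k21 (Vieta).
    """
    k10, k12, k21, lam1, lam2 = _disposition_raw(
        params.CL, params.V1, params.Q, params.V2
    )
    lam1, lam2 = float(lam1), float(lam2)
    if lam1 - lam2 <= _REPEATED_ROOT_RTOL * lam1:
        k21n = k21 * (1.0 + _NUDGE) if k21 > 0 else _NUDGE
        s = k10 + k12 + k21n
        root = math.sqrt(max(s * s - 4.0 * k10 * k21n, 0.0))
        lam1, lam2 = 0.5 * (s + root), max(0.5 * (s - root), 0.0)
        k21 = k21n
    return MicroConstants(
        k10=float(k10), k12=float(k12), k21=float(k21), lambda1=lam1, lambda2=lam2
    )


def _safe_per_lam(coef, lam):
    # coef/lam with the zero-amplitude (one-compartment limit) mode masked out
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(lam > 0, coef / np.where(lam > 0, lam, 1.0), 0.0)
    return out


def unit_infusion_conc(lam1, lam2, c1, c2, t_inf, t):
    """Central concentration for a unit dose infused over ``t_inf`` h.

    ``t`` is time since infusion start; negative times return 0.
    All arguments broadcast.
    """
    t = np.asarray(t, dtype=float)
    rate = 1.0 / t_inf
    out = np.zeros(np.broadcast_shapes(np.shape(lam1), t.shape))
    for lam, c in ((lam1, c1), (lam2, c2)):
        b = rate * _safe_per_lam(c, lam)
        during = b * (1.0 - np.exp(-lam * np.minimum(np.maximum(t, 0.0), t_inf)))
        decay = np.exp(-lam * np.maximum(t - t_inf, 0.0))
        out = out + np.where(t >= 0, during * decay, 0.0)
    return out


def unit_steady_state_conc(lam1, lam2, c1, c2, t_inf, tau, t):
    """Steady-state central concentration within one interval for unit dose.

    ``t`` is time since the start of the interval's infusion, wrapped into
    [0, tau).  Uses per-exponential accumulation factors
    1/(1 - exp(-lam*tau)).
    """
    t = np.asarray(t, dtype=float)
    tw = np.mod(t, tau)
    rate = 1.0 / t_inf
    out = np.zeros(np.broadcast_shapes(np.shape(lam1), tw.shape))
    for lam, c in ((lam1, c1), (lam2, c2)):
        b = rate * _safe_per_lam(c, lam)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = -np.expm1(-lam * tau)
            acc = np.where(denom > 0, 1.0 / np.where(denom > 0, denom, 1.0), 0.0)
        pulse = -np.expm1(-lam * t_inf)  # 1 - e^(-lam*t_inf)
        during = b * (
            -np.expm1(-lam * tw) + pulse * np.exp(-lam * (tw + tau - t_inf)) * acc
        )
        after = b * pulse * np.exp(-lam * (tw - t_inf)) * acc
        out = out + np.where(tw <= t_inf, during, after)
    return out


def concentration(
    params: PKParameters,
    regimen: Regimen,
    times,
    *,
    n_doses: int = 1,
    steady_state: bool = False,
) -> np.ndarray:
    """Central-compartment concentration (mg/L) on a time grid.

    For intermittent regimens, ``times`` are hours since the first dose;
    with ``steady_state=True`` they are interpreted within a steady-state
    interval (wrapped modulo the interval).  Finite ``n_doses`` uses exact
    superposition of single-dose solutions.  Continuous mode returns the
    rising infusion curve, or the analytic plateau rate/CL when
    ``steady_state=True``.

    The dose enters as a single terminal multiplication, so concentrations
    are exactly linear in dose (bit-for-bit under power-of-two scaling).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    lam1, lam2, c1, c2 = disposition_arrays(params.CL, params.V1, params.Q, params.V2)
    if regimen.mode == "continuous":
        if steady_state:
            return np.full(times.shape, regimen.dose * (1.0 / 24.0) / params.CL)
        unit = 0.0
        for lam, c in ((lam1, c1), (lam2, c2)):
            unit = unit + (1.0 / 24.0) * _safe_per_lam(c, lam) * (
                -np.expm1(-lam * times)
            )
        return regimen.dose * np.asarray(unit)
    if steady_state:
        unit = unit_steady_state_conc(
            lam1, lam2, c1, c2, regimen.infusion_duration, regimen.interval, times
        )
        return regimen.dose * np.asarray(unit)
    if n_doses < 1:
        raise ValueError("n_doses must be >= 1")
    unit = np.zeros(times.shape)
    for k in range(n_doses):
        unit = unit + unit_infusion_conc(
            lam1, lam2, c1, c2, regimen.infusion_duration, times - k * regimen.interval
        )
    return regimen.dose * unit


def ode_oracle(
    params: PKParameters,
    regimen: Regimen,
    times,
    *,
    n_doses: int = 1,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Concentration by direct numeric integration of the mass-balance ODEs.

    dA1/dt = rate_in(t) - (k10 + k12) A1 + k21 A2;
    dA2/dt = k12 A1 - k21 A2;  C = A1/V1.

    Integrates segment-by-segment between infusion on/off switch points so
    the right-hand side is smooth within each solver call.  Intended as an
    independent test oracle for :func:`concentration`; raises RuntimeError
    on integrator failure.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    mc = micro_constants(params)
    k10, k12, k21 = mc.k10, mc.k12, mc.k21

    if regimen.mode == "continuous":
        horizon = float(times[-1]) if times.size else 0.0
        breaks = np.array([0.0, max(horizon, 1e-9)])
        rates = np.array([regimen.rate])
    else:
        edges = set()
        for k in range(n_doses):
            edges.add(k * regimen.interval)
            edges.add(k * regimen.interval + regimen.infusion_duration)
        horizon = max(float(times[-1]) if times.size else 0.0, max(edges))
        edges.add(horizon)
        breaks = np.array(sorted(e for e in edges if e <= horizon + 1e-12))
        if breaks[-1] < horizon:
            breaks = np.append(breaks, horizon)
        rates = np.empty(len(breaks) - 1)
        for i, t0 in enumerate(breaks[:-1]):
            mid = 0.5 * (t0 + breaks[i + 1])
            k = int(mid // regimen.interval)
            in_inf = (k < n_doses) and (mid - k * regimen.interval) < regimen.infusion_duration
            rates[i] = regimen.rate if in_inf else 0.0

    def rhs(rate):
        def f(_t, y):
            a1, a2 = y
            return (rate - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2)

        return f

    conc = np.empty(times.shape)
    y = np.zeros(2)
    for i, t0 in enumerate(breaks[:-1]):
        t1 = breaks[i + 1]
        sel = (times >= t0) & (times <= t1 if i == len(breaks) - 2 else times < t1)
        t_eval = times[sel]
        # always evaluate the segment endpoint so the state carries over exactly
        append_end = t_eval.size == 0 or t_eval[-1] < t1
        t_all = np.append(t_eval, t1) if append_end else t_eval
        sol = solve_ivp(
            rhs(rates[i]),
            (t0, t1),
            y,
            method="DOP853",
            t_eval=t_all,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{t0}, {t1}]: {sol.message}")
        if t_eval.size:
            conc[sel] = sol.y[0][: t_eval.size] / params.V1
        y = sol.y[:, -1]
    return conc


def half_lives(params: PKParameters) -> dict:
    """Distribution (alpha) and terminal (beta) half-lives, h.

    In the one-compartment limit (Q = 0) the beta phase vanishes and
    ``t_half_beta`` is +inf; the single half-life is ln(2) * V1 / CL.
    """
    mc = micro_constants(params)
    return {
        "t_half_alpha": LOG2 / mc.lambda1,
        "t_half_beta": LOG2 / mc.lambda2 if mc.lambda2 > 0 else math.inf,
    }
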