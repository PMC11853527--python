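"""Standardized gating-kinetics comparison between channel variants.

Three statistics summarize how a mutation perturbs gating kinetics:

* perturbation energy  ddG = -RT ln(tau_WT / tau_mut), in kcal/mol, with
  tau_act compared at each channel's own half-activation voltage and
  tau_deact at -40 mV (both at dpH = 0).  Negative values mean the mutant's
  kinetic barrier is lower.
* U_tau, the voltage dependence of a time constant in mV per e-fold change,
  from a linear regression of ln tau on V (the "mV per e-fold" unit fixes
  the semilog reading of the tau-V plot).
* theta = U_tau,deact / U_tau,act, the deactivation/activation ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, R_KCAL

log = logging.getLogger(__name__)

__all__ = [
    "KineticsSummary",
    "UTauResult",
    "FittedChannel",
    "perturbation_energy",
    "voltage_dependence",
    "theta_ratio",
    "interpolate_tau",
    "standardized_summary",
]

#: Default voltage ranges (mV) for the tau-V regressions.
ACT_RANGE = (0.0, 100.0)
DEACT_RANGE = (-100.0, 20.0)


@dataclass
class UTauResult:
    """Voltage dependence of a time constant.

    ``U`` is mV per e-fold change (infinite when the regression slope is
    indistinguishable from zero, flagged by ``voltage_independent``).
    """

    U: float
    slope: float       # d ln tau / dV, 1/mV
    r2: float
    n_used: int
    voltage_independent: bool = False


@dataclass
class FittedChannel:
    """Per-variant fitted kinetics: tau-V points and the Boltzmann V_half."""

    label: str
    act_points: list[tuple[float, float]]    # (V mV, tau_act s)
    deact_points: list[tuple[float, float]]  # (V mV, tau_deact s)
    V_half: float


@dataclass
class KineticsSummary:
    tau_act_at_Vhalf: float
    tau_deact_at_minus40: float
    ddG_act: float
    ddG_deact: float
    U_act: float
    U_deact: float
    theta: float
    T: float = DEFAULT_TEMPERATURE_K


def perturbation_energy(tau_wt: float, tau_mut: float,
                        T: float = DEFAULT_TEMPERATURE_K) -> float:
    """ddG = -RT ln(tau_WT/tau_mut) in kcal/mol (R = 1.9872e-3)."""
    if tau_wt <= 0 or tau_mut <= 0:
        raise ValueError("time constants must be positive")
    return -R_KCAL * T * math.log(tau_wt / tau_mut)


def voltage_dependence(tau_points: list[tuple[float, float]],
                       V_range: tuple[float, float] | None = None,
                       r2_min: float = 0.95,
                       zero_slope_tol: float = 1e-4) -> UTauResult:
    """mV per e-fold change from a semilog regression of tau on V.

    Points outside ``V_range`` are excluded up front.  If the regression of
    the remaining points is poor (r^2 below ``r2_min``), endpoints are
    stripped greedily — dropping whichever end most improves r^2 — until the
    fit is linear or only 3 points remain, reproducing the practice of
    keeping only the voltage range that shows linearity.
    """
    pts = sorted(tau_points)
    if V_range is not None:
        pts = [(v, tau) for v, tau in pts if V_range[0] <= v <= V_range[1]]
    if len(pts) < 3:
        raise ValueError("need at least 3 tau-V points in range")
    V = np.array([p[0] for p in pts])
    lt = np.log([p[1] for p in pts])

    def regress(v, y):
        slope, icpt = np.polyfit(v, y, 1)
        pred = slope * v + icpt
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
        return slope, r2

    slope, r2 = regress(V, lt)
    while r2 < r2_min and V.size > 3:
        s_lo, r_lo = regress(V[1:], lt[1:])
        s_hi, r_hi = regress(V[:-1], lt[:-1])
        if r_lo >= r_hi:
            V, lt, slope, r2 = V[1:], lt[1:], s_lo, r_lo
        else:
            V, lt, slope, r2 = V[:-1], lt[:-1], s_hi, r_hi
    if abs(slope) < zero_slope_tol:
        log.warning("tau-V slope indistinguishable from zero: voltage independent")
        return UTauResult(U=math.inf, slope=float(slope), r2=r2,
                          n_used=int(V.size), voltage_independent=True)
    return UTauResult(U=abs(1.0 / float(slope)), slope=float(slope), r2=r2,
                      n_used=int(V.size))


def theta_ratio(U_deact: float, U_act: float) -> float:
    """theta = U_tau,deact / U_tau,act (propagates inf as a flagged inf)."""
    if U_act <= 0 or U_deact <= 0:
        raise ValueError("U values must be positive")
    if math.isinf(U_act):
        log.warning("activation voltage-independent: theta undefined, returning 0")
        return 0.0
    if math.isinf(U_deact):
        log.warning("deactivation voltage-independent: theta is infinite")
        return math.inf
    return U_deact / U_act


def interpolate_tau(points: list[tuple[float, float]], V: float) -> float:
    """Log-linear interpolation of tau at V between the bracketing voltages."""
    pts = sorted(points)
    Vs = np.array([p[0] for p in pts])
    taus = np.array([p[1] for p in pts])
    if not Vs.min() <= V <= Vs.max():
        raise ValueError(f"V={V:.1f} mV outside the fitted range "
                         f"[{Vs.min():.1f}, {Vs.max():.1f}]")
    return float(np.exp(np.interp(V, Vs, np.log(taus))))


def standardized_summary(wt: FittedChannel, mut: FittedChannel,
                         T: float = DEFAULT_TEMPERATURE_K) -> KineticsSummary:
    """Full kinetics comparison of a mutant against WT at dpH = 0.

    Activation time constants are interpolated at each channel's own V_half
    (same open probability); deactivation at -40 mV (same driving force).
    """
    tau_act_wt = interpolate_tau(wt.act_points, wt.V_half)
    tau_act_mut = interpolate_tau(mut.act_points, mut.V_half)
    tau_de_wt = interpolate_tau(wt.deact_points, -40.0)
    tau_de_mut = interpolate_tau(mut.deact_points, -40.0)
    u_act = voltage_dependence(mut.act_points, ACT_RANGE)
    u_deact = voltage_dependence(mut.deact_points, DEACT_RANGE)
    return KineticsSummary(
        tau_act_at_Vhalf=tau_act_mut,
        tau_deact_at_minus40=tau_de_mut,
        ddG_act=perturbation_energy(tau_act_wt, tau_act_mut, T),
        ddG_deact=perturbation_energy(tau_de_wt, tau_de_mut, T),
        U_act=u_act.U,
        U_deact=u_deact.U,
        theta=theta_ratio(u_deact.U, u_act.U),
        T=T,
    )
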