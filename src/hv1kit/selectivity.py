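"""Proton selectivity and closed-state leak analysis.

Selectivity is judged by comparing the measured reversal potential with the
proton Nernst potential E_H at the experimental pH gradient; a lower bound
on P_H/P_TMA follows from the bi-ionic GHK reversal potential.  Closed-state
proton leak is detected from driving-force-directed shifts of the holding
current when the external pH is exchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, nernst_slope_mv, rt_over_f_mv

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import LeakRecording

log = logging.getLogger(__name__)

__all__ = [
    "SelectivityResult",
    "LeakAssessment",
    "ExchangeShift",
    "nernst_potential",
    "vrev_zero_current",
    "vrev_tail",
    "ghk_vrev",
    "permeability_ratio_bound",
    "detect_leak",
]


@dataclass
class SelectivityResult:
    V_rev_measured: float
    E_H: float
    method: str  # "zero-current" | "tail"
    permeability_ratio_lower_bound: float | None = None

    @property
    def delta(self) -> float:
        return self.V_rev_measured - self.E_H


@dataclass
class ExchangeShift:
    time: float
    pH_o_before: float
    pH_o_after: float
    delta_I_hold: float
    predicted_sign: int
    se: float


@dataclass
class LeakAssessment:
    shifts: list[ExchangeShift]
    leak_detected: bool
    criterion_sd_multiple: float


def nernst_potential(pH_o: float, pH_i: float,
                     T: float = DEFAULT_TEMPERATURE_K) -> float:
    """Proton Nernst potential E_H = -(ln10 RT/F)(pH_o - pH_i) in mV."""
    for ph in (pH_o, pH_i):
        if not 0.0 <= ph <= 14.0:
            raise ValueError("pH outside [0, 14]")
    return -nernst_slope_mv(T) * (pH_o - pH_i)


def _zero_crossing(x: np.ndarray, y: np.ndarray) -> float:
    sign = np.sign(y)
    # a genuine sign change or an exact zero node both qualify
    idx = np.nonzero(sign[:-1] * sign[1:] <= 0)[0]
    for i in idx:
        if y[i] == 0.0:
            return float(x[i])
        if y[i] * y[i + 1] < 0:
            return float(x[i] - y[i] * (x[i + 1] - x[i]) / (y[i + 1] - y[i]))
    if y[-1] == 0.0:
        return float(x[-1])
    raise ValueError("no zero crossing in the sampled range")


def vrev_zero_current(iv_points: Sequence[tuple[float, float]]) -> float:
    """Reversal potential by interpolating the steady-state I-V zero
    crossing (usable when the channel conducts at the crossing)."""
    if len(iv_points) < 2:
        raise ValueError("need at least 2 I-V points")
    pts = sorted(iv_points)
    V = np.array([p[0] for p in pts], dtype=float)
    I = np.array([p[1] for p in pts], dtype=float)
    try:
        return _zero_crossing(V, I)
    except ValueError:
        raise ValueError("currents do not change sign: use the tail method")


def vrev_tail(tail_amplitudes: Sequence[tuple[float, float]]) -> float:
    """Reversal potential from instantaneous tail amplitudes after a fixed
    activating prepulse: zero-crossing interpolation of amplitude vs V."""
    if len(tail_amplitudes) < 2:
        raise ValueError("need at least 2 tail amplitudes")
    pts = sorted(tail_amplitudes)
    V = np.array([p[0] for p in pts], dtype=float)
    A = np.array([p[1] for p in pts], dtype=float)
    return _zero_crossing(V, A)


def ghk_vrev(p_ratio: float, pH_o: float, pH_i: float, c_TMA_mM: float,
             T: float = DEFAULT_TEMPERATURE_K) -> float:
    """Bi-ionic GHK reversal potential (mV) for H+ against TMA+ at
    permeability ratio ``p_ratio`` = P_H/P_TMA, with TMA at ``c_TMA_mM`` on
    both sides and the anion impermeant."""
    h_o = 10.0 ** (-pH_o)          # molar
    h_i = 10.0 ** (-pH_i)
    c = c_TMA_mM * 1e-3
    return rt_over_f_mv(T) * math.log((p_ratio * h_o + c) / (p_ratio * h_i + c))


def permeability_ratio_bound(epsilon: float, pH_o: float, pH_i: float,
                             c_TMA_mM: float = 100.0,
                             T: float = DEFAULT_TEMPERATURE_K) -> float:
    """Smallest P_H/P_TMA for which the GHK reversal potential sits within
    ``epsilon`` mV of E_H, by bisection on log10 of the ratio.

    |V_rev - E_H| decreases monotonically toward zero as the ratio grows,
    so a measured deviation bounded by epsilon implies the ratio is at least
    this value.  A bound below 1 is flagged as uninformative.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    E_H = nernst_potential(pH_o, pH_i, T)

    def dev(log_r: float) -> float:
        return abs(ghk_vrev(10.0 ** log_r, pH_o, pH_i, c_TMA_mM, T) - E_H)

    lo, hi = -6.0, 18.0
    if dev(lo) <= epsilon:
        log.warning("epsilon so large the bound is uninformative (< 1)")
        return 10.0 ** lo
    while dev(hi) > epsilon:  # pragma: no cover - huge epsilon only
        hi += 6.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if dev(mid) > epsilon:
            lo = mid
        else:
            hi = mid
    bound = 10.0 ** hi
    if bound < 1.0:
        log.warning("permeability-ratio bound below 1: uninformative")
    return bound


def _quiet_mask(t: np.ndarray, pulse_windows: Sequence[tuple[float, float]],
                pre_guard: float, post_guard: float) -> np.ndarray:
    mask = np.ones_like(t, dtype=bool)
    for start, end in pulse_windows:
        mask &= ~((t >= start - pre_guard) & (t <= end + post_guard))
    return mask


def detect_leak(recording: "LeakRecording", k_sd: float = 3.0,
                window: float = 10.0, settle: float = 0.5,
                pre_guard: float = 0.5, post_guard: float = 5.0,
                T: float = DEFAULT_TEMPERATURE_K) -> LeakAssessment:
    """Closed-state proton-leak assessment from holding-current shifts.

    For each exchange the holding current is averaged over quiet windows
    (test pulses excluded with a pre/post guard band; the post guard must
    outlast the tail relaxation) before and after the exchange.  An
    H+-selective leak predicts a shift of sign(E_H_before - E_H_after) *
    g_leak; the leak is called only when every exchange shift exceeds
    ``k_sd`` standard errors AND matches its predicted sign.
    """
    t, I = recording.trace.t, recording.trace.I
    quiet = _quiet_mask(t, recording.pulse_windows, pre_guard, post_guard)
    noise = recording.noise_sd
    if noise <= 0:
        # estimate from first differences of the quiet baseline
        dq = np.diff(I[quiet])
        noise = float(np.std(dq) / np.sqrt(2.0)) if dq.size > 10 else 1e-12

    pH_seq = [recording.initial_pH_o] + [e.new_pH_o for e in recording.exchanges]
    shifts: list[ExchangeShift] = []
    detected = True
    times = [e.time for e in recording.exchanges]
    for i, e in enumerate(recording.exchanges):
        lo = times[i - 1] + settle if i > 0 else 0.0
        hi = times[i + 1] if i + 1 < len(times) else t[-1]
        before = quiet & (t >= max(lo, e.time - window)) & (t < e.time)
        after = quiet & (t >= e.time + settle) & (t <= min(hi, e.time + settle + window))
        if before.sum() < 10 or after.sum() < 10:
            raise ValueError(f"no clean holding-current window around t={e.time} s")
        d = float(np.mean(I[after]) - np.mean(I[before]))
        se = noise * math.sqrt(1.0 / before.sum() + 1.0 / after.sum())
        eh_before = nernst_potential(pH_seq[i], recording.pH_i, T)
        eh_after = nernst_potential(e.new_pH_o, recording.pH_i, T)
        pred = int(np.sign(eh_before - eh_after))
        shifts.append(ExchangeShift(time=e.time, pH_o_before=pH_seq[i],
                                    pH_o_after=e.new_pH_o, delta_I_hold=d,
                                    predicted_sign=pred, se=se))
        if pred == 0:
            log.info("exchange at t=%.1f s to identical pH: no prediction", e.time)
            continue
        if not (abs(d) > k_sd * se and int(np.sign(d)) == pred):
            detected = False
    if not recording.exchanges:
        raise ValueError("at least one exchange event is required")
    return LeakAssessment(shifts=shifts, leak_detected=detected,
                          criterion_sd_multiple=k_sd)
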