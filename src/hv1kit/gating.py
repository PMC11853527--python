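"""Conductance-voltage analysis: g-V assembly, Boltzmann fits, the
limiting-slope gating-charge estimator, and tail-based threshold detection.

The gating charge is never taken from a Boltzmann fit.  It comes from the
limiting-slope method: at low open probability the log-conductance slope
approaches q/(RT/F), so a linear regression of ln g on V over the most
negative conductance decade, multiplied by RT/F (mV), estimates the charge
in elementary units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import lmfit

from .constants import DEFAULT_TEMPERATURE_K, rt_over_f_mv
from .traces import ConductancePoint, ExpFitResult, TraceFamily, conductance

log = logging.getLogger(__name__)

__all__ = [
    "GVCurve",
    "BoltzmannFit",
    "GatingChargeResult",
    "ThresholdResult",
    "build_gv",
    "fit_boltzmann",
    "limiting_slope_charge",
    "detect_vthres",
]


@dataclass
class GVCurve:
    points: list[ConductancePoint]
    pH_o: float = np.nan
    pH_i: float = np.nan
    T: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        vs = [p.V for p in self.points]
        if len(set(vs)) != len(vs):
            raise ValueError("duplicate voltages in g-V curve")

    @property
    def V(self) -> np.ndarray:
        return np.array([p.V for p in self.points])

    @property
    def g(self) -> np.ndarray:
        return np.array([p.g_H for p in self.points])


@dataclass
class BoltzmannFit:
    V_half: float
    k: float
    g_max: float
    rss: float
    well_constrained: bool = True

    def predict(self, V) -> np.ndarray:
        return self.g_max / (1.0 + np.exp((self.V_half - np.asarray(V)) / self.k))


@dataclass
class GatingChargeResult:
    e0: float
    V_window: tuple[float, float]
    slope: float          # d ln g / dV, 1/mV
    r2: float
    method: str


@dataclass
class ThresholdResult:
    V_thres: float
    criterion_sd_multiple: float


def build_gv(fits: list[tuple[float, ExpFitResult]], V_rev: float,
             pH_o: float = np.nan, pH_i: float = np.nan,
             T: float = DEFAULT_TEMPERATURE_K) -> GVCurve:
    """Chord-conductance curve from per-voltage activation fits.

    Each point divides the extrapolated steady-state current by the driving
    force; points with under 1 mV of driving force are dropped with a log
    record.  Non-monotonicity is only warned about, never corrected.
    """
    if len(fits) < 3:
        raise ValueError("need at least 3 voltages for a g-V curve")
    pts = []
    for V, fit in sorted(fits):
        if abs(V - V_rev) < 1.0:
            log.warning("dropping g-V point at V=%.1f mV: driving force < 1 mV", V)
            continue
        pts.append(ConductancePoint(V=V, g_H=conductance(fit.steady_state, V, V_rev),
                                    I_ss=fit.steady_state, V_rev_used=V_rev))
    g = np.array([p.g_H for p in pts])
    if g.size >= 2 and np.any(np.diff(g) < -1e-9 * max(1.0, g.max())):
        log.warning("g-V curve is not monotone non-decreasing")
    return GVCurve(points=pts, pH_o=pH_o, pH_i=pH_i, T=T)


def fit_boltzmann(gv: GVCurve) -> BoltzmannFit:
    """Fit g(V) = g_max / (1 + exp((V_half - V)/k)) by nonlinear least
    squares on the unnormalized conductances (g_max free).

    ``well_constrained`` is False when the sampled voltages do not bracket
    the fitted inflection or the plateau is unreached, emulating the
    poorly-fitted shallow-curve case.
    """
    V, g = gv.V, gv.g
    if V.size < 4:
        log.warning("fewer than 4 g-V points: Boltzmann fit poorly constrained")
    pars = lmfit.Parameters()
    pars.add("g_max", value=float(g.max()) or 1.0, min=0.0)
    pars.add("V_half", value=float(V[np.argmin(np.abs(g - 0.5 * g.max()))]))
    pars.add("k", value=8.0, min=1e-3)

    def resid(p):
        return p["g_max"] / (1.0 + np.exp((p["V_half"] - V) / p["k"])) - g

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = lmfit.minimize(resid, pars, method="leastsq")
    if not res.success:
        raise RuntimeError(f"Boltzmann fit did not converge: {res.message}")
    p = res.params
    vh, k = float(p["V_half"]), float(p["k"])
    constrained = bool(V.min() <= vh <= V.max()) and g.max() >= 0.8 * float(p["g_max"])
    if p["k"].stderr is not None and k > 0 and p["k"].stderr / k > 0.5:
        constrained = False
    if not constrained:
        log.warning("Boltzmann fit poorly constrained (V_half=%.1f, k=%.1f)", vh, k)
    return BoltzmannFit(V_half=vh, k=k, g_max=float(p["g_max"]),
                        rss=float(np.sum(res.residual ** 2)),
                        well_constrained=constrained)


def _lowest_decade(V: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Mask of the most negative contiguous factor-10 conductance band."""
    pos = g > 0
    if not pos.any():
        return pos
    order = np.argsort(V)
    anchor = None
    for i in order:
        if pos[i]:
            anchor = g[i]
            break
    mask = np.zeros_like(pos)
    for i in order:
        if pos[i] and anchor <= g[i] <= 10.0 * anchor:
            mask[i] = True
        elif mask.any() and g[i] > 10.0 * anchor:
            break
    return mask


def limiting_slope_charge(gv: GVCurve, T: float | None = None,
                          window: tuple[float, float] | None = None
                          ) -> GatingChargeResult:
    """Gating charge from the limiting slope of ln g versus V.

    The default window is the most negative contiguous conductance decade
    (g within [g_min_pos, 10 g_min_pos]); an explicit (V_lo, V_hi) window
    overrides it, matching 2 mV-step protocols near threshold.
    """
    if T is None:
        T = gv.T
    V, g = gv.V, gv.g
    if window is not None:
        mask = (V >= window[0]) & (V <= window[1]) & (g > 0)
        method = "explicit-window"
    else:
        mask = _lowest_decade(V, g)
        method = "lowest-decade"
    if mask.sum() < 3:
        raise ValueError("fewer than 3 positive-conductance points in window")
    Vw, gw = V[mask], g[mask]
    slope, intercept = np.polyfit(Vw, np.log(gw), 1)
    pred = slope * Vw + intercept
    ss_res = float(np.sum((np.log(gw) - pred) ** 2))
    ss_tot = float(np.sum((np.log(gw) - np.log(gw).mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    e0 = float(slope) * rt_over_f_mv(T)
    if e0 <= 0:
        raise ValueError("non-positive limiting-slope charge: check curve")
    return GatingChargeResult(e0=e0, V_window=(float(Vw.min()), float(Vw.max())),
                              slope=float(slope), r2=r2, method=method)


def detect_vthres(family: TraceFamily, noise_sd: float, k_sd: float = 3.0,
                  ) -> ThresholdResult:
    """Most negative test voltage whose instantaneous tail current exceeds
    ``k_sd`` noise standard deviations.

    The tail amplitude is the mean of the first few tail samples minus the
    settled tail baseline (last 10% of the tail).
    """
    if k_sd <= 0:
        log.warning("k_sd <= 0: every trace passes the criterion (degenerate)")
    for tr in family.sorted_by_v():
        tail = tr.tail_segment()
        n = tail.I.size
        if n < 10:
            continue
        head = float(np.mean(tail.I[: max(3, n // 50)]))
        base = float(np.mean(tail.I[int(0.9 * n):]))
        if abs(head - base) > k_sd * noise_sd:
            return ThresholdResult(V_thres=tr.V_test, criterion_sd_multiple=k_sd)
    raise ValueError("no activation detected: no tail exceeds criterion")
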