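"""Current-trace containers and exponential fitting.

Rising proton currents and decaying tails are both fitted with the decaying
basis ``I(t) = C + A * exp(-(t - t0)/tau)`` (one component) or its
two-component sum; rising fits simply have A < 0, and the extrapolated
steady-state current is the offset C.  The initial sigmoidal delay of
activation is disregarded by starting the fit window where the current has
covered a configurable fraction (default 10%) of its total excursion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

log = logging.getLogger(__name__)

__all__ = [
    "CurrentTrace",
    "TraceFamily",
    "ExpFitResult",
    "ConductancePoint",
    "FitError",
    "NoKineticsError",
    "fit_exponential",
    "activation_taus",
    "deactivation_taus",
    "conductance",
    "conductance_density",
]


class FitError(RuntimeError):
    """Exponential fit failed to converge or was ill-posed."""


class NoKineticsError(FitError):
    """Trace is flat relative to its noise floor; no kinetics resolvable."""


@dataclass
class CurrentTrace:
    """Sampled current versus time with its voltage/pH metadata.

    ``t_repol`` (if set) marks the repolarization instant within the sweep:
    samples before it belong to the test step at ``V_test``, samples after
    to the tail at ``V_repol``.
    """

    t: np.ndarray
    I: np.ndarray
    V_test: float
    V_hold: float
    pH_o: float
    pH_i: float
    C_m: float = np.nan
    label: str = ""
    t_repol: float | None = None
    V_repol: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.t.size != self.I.size:
            raise ValueError("t and I must have equal length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")

    def step_segment(self) -> "CurrentTrace":
        """The depolarizing-step portion of the sweep."""
        if self.t_repol is None or self.t_repol <= self.t[0]:
            return self
        m = self.t < self.t_repol
        return CurrentTrace(self.t[m], self.I[m], self.V_test, self.V_hold,
                            self.pH_o, self.pH_i, self.C_m, self.label,
                            t_repol=None, V_repol=self.V_repol)

    def tail_segment(self) -> "CurrentTrace":
        """The tail portion (time rebased to repolarization)."""
        if self.t_repol is None:
            raise ValueError(f"trace {self.label!r} has no tail marker")
        m = self.t >= self.t_repol
        if not m.any():
            raise ValueError(f"trace {self.label!r} has no samples after t_repol")
        return CurrentTrace(self.t[m] - self.t_repol, self.I[m],
                            self.V_repol if self.V_repol is not None else self.V_test,
                            self.V_hold, self.pH_o, self.pH_i, self.C_m,
                            self.label + "/tail")


@dataclass
class TraceFamily:
    """An ordered collection of sweeps from one cell/protocol."""

    traces: list[CurrentTrace]
    family_id: str = "family"

    def __iter__(self):
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)

    def sorted_by_v(self) -> "TraceFamily":
        return TraceFamily(sorted(self.traces, key=lambda tr: tr.V_test),
                           self.family_id)


@dataclass
class ExpFitResult:
    """Result of a one- or two-exponential fit.

    For two components ``(A, tau)`` is the fast pair and ``second_component``
    the slow pair ``(A2, tau2)`` with tau2 > tau.  ``C`` is the offset, i.e.
    the extrapolated steady-state current for rising fits.
    """

    A: float
    tau: float
    C: float
    fit_window: tuple[float, float]
    rss: float
    n_components: int = 1
    second_component: tuple[float, float] | None = None

    @property
    def tau_slow(self) -> float:
        return self.second_component[1] if self.second_component else self.tau

    @property
    def steady_state(self) -> float:
        return self.C

    @property
    def amplitude_fractions(self) -> tuple[float, float]:
        """(fast, slow) fractions of the total decay amplitude."""
        if self.second_component is None:
            return (0.0, 1.0)
        a1, a2 = abs(self.A), abs(self.second_component[0])
        tot = a1 + a2
        return (a1 / tot, a2 / tot) if tot > 0 else (0.0, 1.0)


@dataclass
class ConductancePoint:
    V: float
    g_H: float
    I_ss: float
    V_rev_used: float


def _select_window(trace: CurrentTrace, window: tuple[float, float] | None,
                   delay_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    t, I = trace.t, trace.I
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, I = t[m], I[m]
    if t.size >= 10 and delay_fraction > 0:
        # skip the initial delay: start where the current has covered
        # `delay_fraction` of its total excursion
        i0, i1 = I[0], np.mean(I[max(1, int(0.9 * I.size)):])
        if abs(i1 - i0) > 0:
            frac = np.abs((I - i0) / (i1 - i0))
            idx = np.argmax(frac >= delay_fraction)
            t, I = t[idx:], I[idx:]
    return t, I


def _guess_tau(t: np.ndarray, I: np.ndarray, C0: float) -> float:
    """Log-linear regression of the detrended decay for a tau seed."""
    resid = np.abs(I - C0)
    m = resid > 1e-3 * resid.max()
    if m.sum() >= 3:
        slope = np.polyfit(t[m], np.log(resid[m]), 1)[0]
        if slope < 0:
            return float(-1.0 / slope)
    return float((t[-1] - t[0]) / 3.0)


def fit_exponential(trace: CurrentTrace, window: tuple[float, float] | None = None,
                    n_components: int = 1, delay_fraction: float = 0.1,
                    noise_sd: float | None = None) -> ExpFitResult:
    """Least-squares exponential fit of a current trace.

    Raises :class:`NoKineticsError` for flat traces and :class:`FitError`
    on non-convergence; never returns silent NaNs.
    """
    t, I = _select_window(trace, window, delay_fraction)
    if t.size < 10:
        raise FitError(f"window holds {t.size} samples; at least 10 required")
    t0 = t[0]
    dt = float(np.median(np.diff(t)))
    span = float(t[-1] - t[0])
    excursion = float(np.ptp(I))
    floor = noise_sd if noise_sd is not None else 0.0
    if excursion <= max(3.0 * floor, 1e-12):
        raise NoKineticsError("no kinetics resolvable: trace flat at noise floor")

    C0 = float(np.mean(I[max(1, int(0.9 * I.size)):]))
    A0 = float(I[0] - C0)
    tau0 = min(max(_guess_tau(t, I, C0), 2 * dt), 10 * span)

    pars = lmfit.Parameters()
    pars.add("C", value=C0)
    pars.add("A", value=A0)
    pars.add("tau", value=tau0, min=2 * dt, max=10 * span)
    if n_components == 2:
        pars.add("A2", value=0.5 * A0)
        pars.add("tau2", value=min(5 * tau0, 10 * span), min=2 * dt, max=10 * span)
        pars["A"].set(value=0.5 * A0)
        pars["tau"].set(value=max(tau0 / 5, 2 * dt))

    def model(p, tt):
        out = p["C"] + p["A"] * np.exp(-(tt - t0) / p["tau"])
        if n_components == 2:
            out = out + p["A2"] * np.exp(-(tt - t0) / p["tau2"])
        return out

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = lmfit.minimize(lambda p: model(p, t) - I, pars, method="leastsq")
    if not res.success:
        raise FitError(f"exponential fit did not converge: {res.message}")
    p = res.params
    rss = float(np.sum(res.residual ** 2))
    if n_components == 1:
        return ExpFitResult(A=float(p["A"]), tau=float(p["tau"]), C=float(p["C"]),
                            fit_window=(float(t0), float(t[-1])), rss=rss)
    # order components fast -> slow
    comps = sorted([(float(p["tau"]), float(p["A"])),
                    (float(p["tau2"]), float(p["A2"]))])
    (tau_f, A_f), (tau_s, A_s) = comps
    return ExpFitResult(A=A_f, tau=tau_f, C=float(p["C"]),
                        fit_window=(float(t0), float(t[-1])), rss=rss,
                        n_components=2, second_component=(A_s, tau_s))


def activation_taus(family: TraceFamily, delay_fraction: float = 0.1,
                    noise_sd: float | None = None
                    ) -> list[tuple[float, ExpFitResult]]:
    """Per-voltage single-exponential rising fits of the depolarizing steps.

    Traces whose fit fails are skipped with a log record; results are sorted
    by ascending test voltage.
    """
    out = []
    for tr in family.sorted_by_v():
        try:
            fit = fit_exponential(tr.step_segment(), n_components=1,
                                  delay_fraction=delay_fraction,
                                  noise_sd=noise_sd)
        except FitError as exc:
            log.warning("activation fit skipped at V=%.1f mV (%s): %s",
                        tr.V_test, tr.label, exc)
            continue
        out.append((tr.V_test, fit))
    return out


def deactivation_taus(tails: TraceFamily, noise_sd: float | None = None,
                      degenerate_tau_ratio: float = 0.8
                      ) -> list[tuple[float, ExpFitResult]]:
    """Per-voltage tail fits; the slow component is the reported tau.

    A two-component fit is attempted first and demoted to one component when
    degenerate: tau_fast/tau_slow above ``degenerate_tau_ratio`` or either
    amplitude below twice the noise SD.
    """
    out = []
    for tr in tails.sorted_by_v():
        seg = tr.tail_segment() if tr.t_repol not in (None, 0.0) else tr
        if not -100.0 <= seg.V_test <= 0.0:
            log.warning("tail at %.1f mV outside the customary -100..0 mV range",
                        seg.V_test)
        try:
            fit2 = fit_exponential(seg, n_components=2, delay_fraction=0.0,
                                   noise_sd=noise_sd)
            degenerate = fit2.tau / fit2.tau_slow > degenerate_tau_ratio
            if noise_sd:
                a_s = abs(fit2.second_component[0])
                degenerate = degenerate or min(abs(fit2.A), a_s) < 2 * noise_sd
            fit = (fit_exponential(seg, n_components=1, delay_fraction=0.0,
                                   noise_sd=noise_sd) if degenerate else fit2)
        except FitError:
            try:
                fit = fit_exponential(seg, n_components=1, delay_fraction=0.0,
                                      noise_sd=noise_sd)
            except FitError as exc:
                log.warning("tail fit skipped at V=%.1f mV: %s", seg.V_test, exc)
                continue
        out.append((seg.V_test, fit))
    return out


def conductance(I_ss: float, V: float, V_rev: float) -> float:
    """Chord conductance g = I_ss / (V - V_rev) in nS (pA/mV)."""
    if abs(V - V_rev) < 1.0:
        raise ValueError("driving force below 1 mV: conductance unstable")
    return I_ss / (V - V_rev)


def conductance_density(g_max: float, C_m: float) -> float:
    """Maximal conductance normalized by cell capacitance (nS/pF)."""
    if C_m <= 0:
        raise ValueError("C_m must be > 0")
    return g_max / C_m
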