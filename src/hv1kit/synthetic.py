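"""Synthetic data generators: voltage-clamp simulator, somatic-mutation
tables, and toy structural ensembles.

The voltage-clamp simulator is a two-state (closed/open) gating model.  The
open probability at steady state is a single Boltzmann of the total gating
charge ``q_total``; relaxation toward it is a single exponential after an
explicit activation delay.  The sigmoidal onset produced by dimer
cooperativity in the real channel is represented only by that delay, because
the downstream fitting procedure disregards the initial delay anyway.  Tail
currents optionally carry a fast second component, mirroring the
two-component tails seen in the S4 mutants.

Currents are Ohmic::

    I(t) = (g_leak + g_max * Po(t)) * (V - E_H) + noise

with ``E_H`` the proton Nernst potential at the protocol's pH pair, so the
simulated channel is perfectly proton-selective by construction.  Noise is
additive white Gaussian; no 1/f or seal drift is modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, nernst_slope_mv, rt_over_f_mv
from .selectivity import nernst_potential
from .traces import CurrentTrace, TraceFamily
from .hotspot import MutationRecord
from .geometry import StructureEnsemble

__all__ = [
    "ChannelModelParams",
    "VoltageProtocol",
    "ExchangeEvent",
    "LeakRecording",
    "WaterSpec",
    "simulate_family",
    "simulate_tail_family",
    "simulate_leak_experiment",
    "generate_mutation_table",
    "generate_toy_ensemble",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_SYNTH_DBS = ("synthdb_primary", "synthdb_alt1", "synthdb_alt2")
_SYNTH_TISSUES = ("skin", "large_intestine", "endometrium", "lung", "liver")


@dataclass
class ChannelModelParams:
    """Generative parameters of the two-state channel model.

    Defaults emulate a WT-like channel: g_max = 32 nS (1.6 nS/pF on a 20 pF
    cell), q_total = 6.2 e0, V_half = +21 mV at dpH = 0, tau_act(V_half)
    around 2 s and tau_deact(-40 mV) around 0.6 s with 40 mV/e-fold voltage
    dependence on both.
    """

    g_max: float = 32.0            # nS
    q_total: float = 6.2           # elementary charges
    V_half_ref: float = 21.0       # mV at dpH = 0
    pH_shift_slope: float = 40.0   # mV per dpH unit; V_half = V_half_ref - slope*dpH
    tau_act0: float = 3.4          # s at 0 mV
    U_act_true: float = 40.0       # mV per e-fold
    tau_deact0: float = 1.6        # s at 0 mV
    U_deact_true: float = 40.0     # mV per e-fold
    delay: float = 0.05            # s, activation delay
    tail_fast_fraction: float = 0.0
    tail_fast_ratio: float = 0.1   # tau_fast / tau_slow
    g_leak: float = 0.0            # nS, closed-state proton leak
    C_m: float = 20.0              # pF
    noise_sd: float = 0.0          # pA
    T_K: float = DEFAULT_TEMPERATURE_K
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        if self.q_total <= 0:
            raise ValueError("q_total must be > 0")
        if not 0.0 <= self.tail_fast_fraction <= 1.0:
            raise ValueError("tail_fast_fraction must be in [0, 1]")
        if self.C_m <= 0:
            raise ValueError("C_m must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def k_gen(self) -> float:
        """Boltzmann slope factor RT/(q_total*F) in mV."""
        return rt_over_f_mv(self.T_K) / self.q_total

    def v_half(self, pH_o: float, pH_i: float) -> float:
        """Half-activation voltage at the given pH pair.

        Lowering pH_o (dpH more negative) shifts the curve positively along
        the voltage axis; raising it shifts negatively.
        """
        dpH = pH_o - pH_i
        return self.V_half_ref - self.pH_shift_slope * dpH

    def po_inf(self, V, pH_o: float, pH_i: float):
        """Steady-state open probability at voltage V (mV)."""
        vh = self.v_half(pH_o, pH_i)
        return 1.0 / (1.0 + np.exp((vh - np.asarray(V, dtype=float)) / self.k_gen))

    def tau_act(self, V: float) -> float:
        return self.tau_act0 * np.exp(-V / self.U_act_true)

    def tau_deact(self, V: float) -> float:
        return self.tau_deact0 * np.exp(V / self.U_deact_true)


@dataclass
class VoltageProtocol:
    """A depolarizing pulse family: hold, test steps, repolarizing tails."""

    steps: Sequence[tuple[float, float]]  # (V_test mV, duration s)
    V_hold: float = -40.0
    V_repol: float = -40.0
    tail_duration: float = 1.0
    interpulse_interval: float = 30.0
    pH_o: float = 6.5
    pH_i: float = 6.5
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("protocol needs at least one step")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.tail_duration <= 0 or any(d <= 0 for _, d in self.steps):
            raise ValueError("durations must be > 0")


@dataclass(frozen=True)
class ExchangeEvent:
    """External-solution exchange at ``time`` (s) to ``new_pH_o``."""

    time: float
    new_pH_o: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("exchange time must be >= 0")


@dataclass
class LeakRecording:
    """Continuous holding-current recording with periodic test pulses.

    ``pulse_windows`` are (start, end) times of the test pulses so leak
    analysis can exclude them; ``exchanges`` carry the solution history.
    """

    trace: CurrentTrace
    exchanges: list[ExchangeEvent]
    pulse_windows: list[tuple[float, float]]
    V_hold: float
    pH_i: float
    initial_pH_o: float
    noise_sd: float


def _relax(po_start: float, po_target: float, t: np.ndarray, tau: float,
           delay: float = 0.0) -> np.ndarray:
    po = np.full_like(t, po_start, dtype=float)
    after = t >= delay
    po[after] = po_target + (po_start - po_target) * np.exp(-(t[after] - delay) / tau)
    return po


def _step_po(params: ChannelModelParams, proto: VoltageProtocol,
             V: float, t: np.ndarray) -> np.ndarray:
    po0 = float(params.po_inf(proto.V_hold, proto.pH_o, proto.pH_i))
    po_inf = float(params.po_inf(V, proto.pH_o, proto.pH_i))
    if po_inf >= po0:
        tau, delay = params.tau_act(V), params.delay
    else:
        tau, delay = params.tau_deact(V), 0.0
    return _relax(po0, po_inf, t, tau, delay)


def _tail_po(params: ChannelModelParams, proto: VoltageProtocol,
             po_start: float, t: np.ndarray) -> np.ndarray:
    """Two-exponential deactivation toward Po_inf(V_repol)."""
    po_inf = float(params.po_inf(proto.V_repol, proto.pH_o, proto.pH_i))
    tau_slow = params.tau_deact(proto.V_repol)
    tau_fast = params.tail_fast_ratio * tau_slow
    f = params.tail_fast_fraction
    decay = f * np.exp(-t / tau_fast) + (1.0 - f) * np.exp(-t / tau_slow)
    return po_inf + (po_start - po_inf) * decay


def simulate_family(params: ChannelModelParams, protocol: VoltageProtocol,
                    family_id: str = "fam0") -> TraceFamily:
    """Simulate one depolarizing pulse family.

    Each trace covers the test step followed by the tail at ``V_repol``;
    ``t_repol`` on the trace marks the repolarization instant.
    """
    dt = 1.0 / protocol.sample_rate
    if any(d < 3 * dt for _, d in protocol.steps):
        raise ValueError("step duration below 3 sample intervals is unresolvable")
    rng = np.random.default_rng(params.seed)
    E_H = nernst_potential(protocol.pH_o, protocol.pH_i, params.T_K)
    traces = []
    for i, (V, dur) in enumerate(protocol.steps):
        t_step = np.arange(0.0, dur, dt)
        t_tail = np.arange(0.0, protocol.tail_duration, dt)
        po_step = _step_po(params, protocol, V, t_step)
        po_tail = _tail_po(params, protocol, float(po_step[-1]), t_tail)
        I_step = (params.g_leak + params.g_max * po_step) * (V - E_H)
        I_tail = (params.g_leak + params.g_max * po_tail) * (protocol.V_repol - E_H)
        t = np.concatenate([t_step, dur + t_tail])
        I = np.concatenate([I_step, I_tail])
        if params.noise_sd > 0:
            I = I + rng.normal(0.0, params.noise_sd, size=I.size)
        traces.append(CurrentTrace(
            t=t, I=I, V_test=V, V_hold=protocol.V_hold,
            pH_o=protocol.pH_o, pH_i=protocol.pH_i, C_m=params.C_m,
            label=f"{family_id}/step{i}", t_repol=dur, V_repol=protocol.V_repol,
        ))
    return TraceFamily(traces=traces, family_id=family_id)


def simulate_tail_family(params: ChannelModelParams, V_repols: Sequence[float],
                         V_act: float = 60.0, act_duration: float | None = None,
                         pH_o: float = 6.5, pH_i: float = 6.5,
                         sample_rate: float = 1000.0,
                         family_id: str = "tails") -> TraceFamily:
    """Tail-current series: a fixed activating prepulse, then repolarization
    to each voltage in ``V_repols``.

    Traces contain the tail only (t = 0 at repolarization) with ``V_test``
    set to the tail voltage, which is what the deactivation fits consume.
    Tail durations scale with the slow time constant at each voltage.
    """
    rng = np.random.default_rng(params.seed)
    E_H = nernst_potential(pH_o, pH_i, params.T_K)
    if act_duration is None:
        act_duration = 4.0 * params.tau_act(V_act) + params.delay
    proto0 = VoltageProtocol(steps=[(V_act, act_duration)], pH_o=pH_o, pH_i=pH_i,
                             sample_rate=sample_rate)
    t_act = np.arange(0.0, act_duration, 1.0 / sample_rate)
    po_end = float(_step_po(params, proto0, V_act, t_act)[-1])
    traces = []
    for i, Vr in enumerate(V_repols):
        tau_s = params.tau_deact(Vr)
        dur = max(6.0 * tau_s, 0.5)
        t = np.arange(0.0, dur, 1.0 / sample_rate)
        proto = dataclasses.replace(proto0, V_repol=Vr)
        po = _tail_po(params, proto, po_end, t)
        I = (params.g_leak + params.g_max * po) * (Vr - E_H)
        if params.noise_sd > 0:
            I = I + rng.normal(0.0, params.noise_sd, size=I.size)
        traces.append(CurrentTrace(
            t=t, I=I, V_test=Vr, V_hold=params.v_half(pH_o, pH_i),
            pH_o=pH_o, pH_i=pH_i, C_m=params.C_m,
            label=f"{family_id}/tail{i}", t_repol=0.0, V_repol=Vr,
        ))
    return TraceFamily(traces=traces, family_id=family_id)


def simulate_leak_experiment(params: ChannelModelParams,
                             protocol: VoltageProtocol,
                             exchanges: Sequence[ExchangeEvent],
                             n_pulses: int | None = None) -> LeakRecording:
    """Continuous recording at ``V_hold`` with periodic 1 s-style test pulses
    and external-solution exchanges.

    The first protocol step defines the repeated test pulse; pulses recur at
    ``interpulse_interval``.  At each exchange the proton reversal potential
    recomputes and the holding current steps to
    ``g_leak * (V_hold - E_H_new)`` (plus any open-channel component, which
    is negligible when ``V_hold`` is below activation).
    """
    times = sorted(e.time for e in exchanges)
    if len(set(times)) != len(times):
        raise ValueError("overlapping exchange times")
    exchanges = sorted(exchanges, key=lambda e: e.time)
    V_pulse, pulse_dur = protocol.steps[0]
    period = protocol.interpulse_interval
    if n_pulses is None:
        t_end = (max(times) if times else 0.0) + period
        n_pulses = int(np.ceil(t_end / period)) + 1
    total = n_pulses * period
    dt = 1.0 / protocol.sample_rate
    t = np.arange(0.0, total, dt)
    rng = np.random.default_rng(params.seed)

    # piecewise pH_o history
    pH_o = np.full_like(t, protocol.pH_o)
    for e in exchanges:
        pH_o[t >= e.time] = e.new_pH_o
    E_H = -nernst_slope_mv(params.T_K) * (pH_o - protocol.pH_i)

    # voltage command: hold with pulses centred in each period
    V = np.full_like(t, protocol.V_hold)
    pulse_windows: list[tuple[float, float]] = []
    for k in range(n_pulses):
        start = k * period + 0.5 * period
        pulse_windows.append((start, start + pulse_dur))
        V[(t >= start) & (t < start + pulse_dur)] = V_pulse

    # gate dynamics: relax toward po_inf(V) piecewise (single exponential)
    po = np.empty_like(t)
    po_prev = float(params.po_inf(protocol.V_hold, float(pH_o[0]), protocol.pH_i))
    seg_start = 0
    for k in range(1, t.size + 1):
        if k == t.size or V[k] != V[seg_start] or pH_o[k] != pH_o[seg_start]:
            Vs = float(V[seg_start])
            po_inf = float(params.po_inf(Vs, float(pH_o[seg_start]), protocol.pH_i))
            tau = params.tau_act(Vs) if po_inf >= po_prev else params.tau_deact(Vs)
            ts = t[seg_start:k] - t[seg_start]
            po[seg_start:k] = po_inf + (po_prev - po_inf) * np.exp(-ts / tau)
            po_prev = float(po[k - 1])
            seg_start = k

    I = (params.g_leak + params.g_max * po) * (V - E_H)
    if params.noise_sd > 0:
        I = I + rng.normal(0.0, params.noise_sd, size=I.size)
    trace = CurrentTrace(t=t, I=I, V_test=V_pulse, V_hold=protocol.V_hold,
                         pH_o=protocol.pH_o, pH_i=protocol.pH_i,
                         C_m=params.C_m, label="leak_assay")
    return LeakRecording(trace=trace, exchanges=list(exchanges),
                         pulse_windows=pulse_windows, V_hold=protocol.V_hold,
                         pH_i=protocol.pH_i, initial_pH_o=protocol.pH_o,
                         noise_sd=params.noise_sd)


def generate_mutation_table(length: int, n_background: int,
                            hotspots: Sequence[tuple[int, int, int]] = (),
                            class_probs: tuple[float, float, float] = (0.68, 0.26, 0.06),
                            seed: int | None = None) -> list[MutationRecord]:
    """Somatic-mutation table: uniform background plus hotspot enrichment.

    ``hotspots`` are (center, halfwidth, n_mut) triples; positions are drawn
    uniformly within [center - halfwidth, center + halfwidth] clipped to the
    protein.  ``class_probs`` are (missense, silent, stop) and must sum to 1.
    The default class mix mirrors a realistic somatic screen dominated by
    missense changes.
    """
    if abs(sum(class_probs) - 1.0) > 1e-9:
        raise ValueError("class_probs must sum to 1")
    rng = np.random.default_rng(seed)
    positions: list[int] = list(rng.integers(1, length + 1, size=n_background))
    for center, halfwidth, n_mut in hotspots:
        lo = max(1, center - halfwidth)
        hi = min(length, center + halfwidth)
        if not 1 <= center <= length:
            raise ValueError("hotspot center outside protein")
        positions.extend(rng.integers(lo, hi + 1, size=n_mut))
    records = []
    for i, pos in enumerate(positions):
        ref = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        cls = rng.choice(3, p=class_probs)
        if cls == 0:
            alt = ref
            while alt == ref:
                alt = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        elif cls == 1:
            alt = "="
        else:
            alt = "*"
        records.append(MutationRecord(
            position=int(pos), ref_aa=ref, alt_aa=alt,
            source_db=_SYNTH_DBS[rng.integers(len(_SYNTH_DBS))],
            tissue=_SYNTH_TISSUES[rng.integers(len(_SYNTH_TISSUES))],
            sample_id=f"S{i:05d}",
        ))
    return records


@dataclass
class WaterSpec:
    """Water placement for the toy pore: uniform along z at ``density_per_A``
    (waters per Angstrom of axis) within ``z_extent`` of the gasket plane,
    excluding the slab |z| < exclusion_halfwidth.  x, y scatter within
    ``lateral_radius`` of the axis.

    The default density puts two waters in each 0.5 A axial bin, so the
    "water number = 1" contour sits at half the bulk plateau and linear
    interpolation localizes the slab edge to a fraction of a bin.
    """

    density_per_A: float = 4.0
    z_extent: float = 12.0
    exclusion_halfwidth: float | None = None
    lateral_radius: float = 2.0


def _disk_xy(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def generate_toy_ensemble(n_frames: int, displacement_z: float = 0.0,
                          waters: WaterSpec | None = None,
                          jitter_sd: float = 0.05,
                          marker_residues: dict[int, tuple[str, float]] | None = None,
                          seed: int | None = None,
                          ) -> tuple[StructureEnsemble, StructureEnsemble]:
    """Paired deactivated/activated toy channel ensembles.

    The mimic has four gasket residues (VAL109, PHE150, VAL178, VAL179) whose
    C-alpha atoms define the z = 0 reference plane, a straight "S4" helix of
    C-alpha atoms rising along z, marker charged residues (default ARG208
    with CA and a CZ side-chain tip), and optional water oxygens.  In the
    activated copy the helix and markers are translated ``+displacement_z``
    along z; gasket and waters stay put.  Per-frame Gaussian jitter of
    ``jitter_sd`` A per coordinate is applied to protein atoms; waters are
    re-drawn independently each frame.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if marker_residues is None:
        marker_residues = {208: ("ARG", -2.0)}
    rng = np.random.default_rng(seed)

    names: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    base: list[list[float]] = []
    movable: list[bool] = []

    gasket = [(109, "VAL", (5.0, 0.0, 0.0)), (150, "PHE", (0.0, 5.0, 0.0)),
              (178, "VAL", (-5.0, 0.0, 0.0)), (179, "VAL", (0.0, -5.0, 0.0))]
    for resid, resname, xyz in gasket:
        names.append("CA"); resnames.append(resname); resids.append(resid)
        base.append(list(xyz)); movable.append(False)

    helix_resids = [r for r in range(199, 219) if r not in marker_residues]
    for k, resid in enumerate(range(199, 219)):
        z = -10.5 + 1.5 * (resid - 199) - 3.0
        if resid in marker_residues:
            resname, zmark = marker_residues[resid]
            names.append("CA"); resnames.append(resname); resids.append(resid)
            base.append([8.0, 0.0, zmark]); movable.append(True)
            if resname == "ARG":
                names.append("CZ"); resnames.append(resname); resids.append(resid)
                base.append([6.5, 0.0, zmark - 0.5]); movable.append(True)
            elif resname == "LYS":
                names.append("NZ"); resnames.append(resname); resids.append(resid)
                base.append([6.5, 0.0, zmark - 0.5]); movable.append(True)
        else:
            names.append("CA"); resnames.append("LEU"); resids.append(resid)
            base.append([8.0, 0.0, z]); movable.append(True)
    del helix_resids

    base_arr = np.asarray(base)
    movable_arr = np.asarray(movable)
    n_prot = base_arr.shape[0]

    def protein_frames(shift: float, rng: np.random.Generator) -> np.ndarray:
        coords = np.repeat(base_arr[None, :, :], n_frames, axis=0)
        coords[:, movable_arr, 2] += shift
        if jitter_sd > 0:
            coords = coords + rng.normal(0.0, jitter_sd, size=coords.shape)
        return coords

    def water_frames(rng: np.random.Generator) -> tuple[np.ndarray, int]:
        if waters is None:
            return np.zeros((n_frames, 0, 3)), 0
        w = waters
        if w.exclusion_halfwidth:
            seg = [(-w.z_extent, -w.exclusion_halfwidth),
                   (w.exclusion_halfwidth, w.z_extent)]
        else:
            seg = [(-w.z_extent, w.z_extent)]
        lengths = np.array([b - a for a, b in seg])
        n_w = int(round(w.density_per_A * lengths.sum()))
        frames = np.empty((n_frames, n_w, 3))
        for f in range(n_frames):
            picks = rng.choice(len(seg), size=n_w, p=lengths / lengths.sum())
            z = np.array([rng.uniform(*seg[p]) for p in picks])
            xy = _disk_xy(rng, n_w, w.lateral_radius)
            frames[f] = np.column_stack([xy, z])
        return frames, n_w

    ensembles = []
    for label, shift in (("deactivated", 0.0), ("activated", displacement_z)):
        prot = protein_frames(shift, rng)
        wat, n_w = water_frames(rng)
        coords = np.concatenate([prot, wat], axis=1)
        all_names = names + ["OW"] * n_w
        all_resnames = resnames + ["HOH"] * n_w
        all_resids = resids + list(range(1000, 1000 + n_w))
        ensembles.append(StructureEnsemble(
            names=all_names, resnames=all_resnames, resids=all_resids,
            coords=coords, label=label))
    return ensembles[0], ensembles[1]
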