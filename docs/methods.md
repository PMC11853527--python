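# Methods

`hv1kit` analyzes the biophysics of the human voltage-gated proton channel
(hHv1, gene *HVCN1*) and its variants at three levels: whole-cell
voltage-clamp electrophysiology, protein-level somatic-mutation statistics,
and geometry statistics over structural (MD-style) ensembles. Because raw
patch-clamp recordings for this problem are not publicly archived, the
package ships a first-class synthetic-data generator whose statistical
structure matches what the analyses assume; every estimator is validated by
round-tripping through that generator.

## The gating model behind the simulator

The voltage-clamp simulator (`hv1kit.synthetic`) is a deterministic
two-state (closed/open) Hodgkin–Huxley-type model with additive recording
noise. The steady-state open probability is a single Boltzmann of the total
gating charge `q_total`:

    Po_inf(V) = 1 / (1 + exp((V_half - V) / k)),   k = RT / (q_total F)

and the current is Ohmic through a perfectly proton-selective pore:

    I(t) = (g_leak + g_max * Po(t)) * (V - E_H) + noise,

with `E_H` the proton Nernst potential of the protocol's pH pair. `Po`
relaxes exponentially toward `Po_inf(V)` with

    tau_act(V)   = tau_act0   * exp(-V / U_act),
    tau_deact(V) = tau_deact0 * exp(+V / U_deact),

choosing the activation law (and applying the explicit activation delay)
when `Po_inf` lies above the starting value and the deactivation law
otherwise. Tails optionally carry a fast second exponential: a fraction
`tail_fast_fraction` of the decay amplitude relaxes with
`tail_fast_ratio * tau_deact(V)`. The dimer cooperativity that produces the
sigmoidal current onset in the real channel is represented *only* by the
delay parameter, because the downstream fitting procedure explicitly
disregards the initial delay; a Markov multi-state model would add nothing
the fits could see.

pH dependence enters in two places: `E_H = -(ln10 RT/F)(pH_o - pH_i)`, and
a rigid shift of the activation curve, `V_half = V_half_ref -
pH_shift_slope * dpH` with `dpH = pH_o - pH_i`. The default slope of
+40 mV per unit reproduces the canonical behaviour of proton channels
(curves shift positively when the bath is acidified, negatively when it is
alkalinized); the literature gives the direction but no sharp number, so
the slope is a configurable parameter. Proton depletion/accumulation during
large currents is not modelled; the simulated protocols are the short-pulse
designs that minimize it. Noise is white Gaussian per sample — no 1/f
component, seal drift, or series-resistance artifact — so passing the
recovery tests shows estimator correctness under ideal-amplifier
conditions, not robustness to every instrumental pathology.

Default parameters describe a WT-like channel: `g_max` 32 nS on a 20 pF
cell (1.6 nS/pF), `q_total` 6.2 e0, `V_half` +21 mV at symmetric pH,
`tau_act` about 2 s at `V_half`, `tau_deact(-40 mV)` about 0.6 s, and
40 mV per e-fold voltage dependence of both time constants. Temperature
defaults to 294 K (the midpoint of typical 19–22 °C recording conditions)
everywhere RT appears; it is defined once in `hv1kit.constants`.

## Exponential fitting (`hv1kit.traces`)

All current relaxations are fitted with the decaying basis
`I(t) = C + A exp(-(t - t0)/tau)` (plus a second component on request) by
bounded nonlinear least squares (lmfit/Levenberg–Marquardt), with initial
guesses from a log-linear regression of the detrended decay and `tau`
bounded to [2 sample intervals, 10 x window]. Rising fits simply have
`A < 0`, and the extrapolated steady-state current is the offset `C`. The
activation delay is disregarded operationally: the fit window starts at the
first sample where the current has covered 10% (configurable) of its total
excursion. Two-component tail fits are demoted to a single component when
degenerate (`tau_fast/tau_slow > 0.8`, or either amplitude under twice the
noise SD); the slow component is the reported deactivation time constant.
Flat traces (excursion below three noise SDs) raise an explicit
"no kinetics resolvable" error rather than returning NaNs.

## Conductance, Boltzmann and gating charge (`hv1kit.gating`)

Chord conductance is `g = I_ss / (V - V_rev)`; points with under 1 mV of
driving force are dropped (the quotient is numerically meaningless there).
The Boltzmann fit runs on unnormalized conductances with `g_max` free, and
flags itself as poorly constrained when the sampled voltages do not bracket
the fitted inflection or never approach the plateau — the situation that
arises for very shallow curves.

The gating charge is estimated **only** by the limiting-slope method, never
from the Boltzmann slope factor: `e0 = (RT/F) * d ln g / dV` over a window
of low open probability, implemented as a linear regression of `ln g` on V.
The default window is the most negative contiguous factor-10 band of
conductance ("lowest decade", anchored at the smallest positive g); an
explicit window argument supports 2 mV-step protocols near threshold. For a
two-state channel the log-slope is `(1 - Po)/k`, so the estimator is biased
low by roughly the mean open probability in the window: restricting to
Po < 0.01 keeps the bias under 1%, and the test suite demonstrates the
monotone convergence of the estimate toward `q_total` as the window moves
negative. When the conductances in the limiting decade are of order
10 pS, a one-unit pH gradient is the practical way to keep a usable driving
force (tens of mV) across the fit window; the noisy-recovery test uses that
design.

The activation threshold `V_thres` is the most negative test potential
whose instantaneous tail amplitude (first tail samples minus the settled
tail baseline) exceeds `k_sd` noise standard deviations; `k_sd = 3` is a
configurable stand-in for the visual "first tail current" call.

## Kinetics comparison (`hv1kit.kinetics`)

Perturbation energies use `ddG = -RT ln(tau_WT / tau_mut)` with
R = 1.9872e-3 kcal/(mol K); negative values mean the mutation lowered the
kinetic barrier. Activation time constants are compared at each channel's
own `V_half` (equal open probability) and deactivation at -40 mV (equal
driving force), both at symmetric pH; `tau` at the standard potential is
obtained by log-linear interpolation between the bracketing voltages. The
voltage dependence `U_tau` (mV per e-fold) is the reciprocal slope of a
regression of `ln tau` on V — the "per e-fold" unit fixes the semilog
reading of the tau–V plot — over default ranges 0..+100 mV (activation) and
-100..+20 mV (deactivation). Where the relation bends (near the reversal
potential, where resolution degrades), endpoints are stripped greedily
until r² >= 0.95 or three points remain. A slope indistinguishable from
zero returns an infinite-U sentinel flagged `voltage_independent`, which
propagates through `theta = U_deact / U_act`. The summary compares the
ratio of the two channels' interpolated mean time constants; per-cell
pairing is not reconstructable from summary data and is out of scope.

## Selectivity and closed-state leak (`hv1kit.selectivity`)

`E_H = -(ln10 RT/F)(pH_o - pH_i)` (58.33 mV per pH unit at 294 K).
Reversal potentials are interpolated zero crossings, of the steady-state
I–V relation when the channel conducts at the crossing, or of instantaneous
tail amplitudes after a fixed activating prepulse otherwise. The
permeability-ratio bound inverts the bi-ionic GHK reversal potential for H+
against TMA+ (TMA at the same concentration on both sides, anion treated as
impermeant): `|V_rev - E_H|` decreases monotonically to zero as P_H/P_TMA
grows, so a measured deviation no larger than epsilon implies a lower bound
on the ratio, found by bisection on log10(ratio). Epsilon is an argument —
the experimental deviation it represents is a property of each dataset, not
a constant of the method.

Closed-state leak detection averages the holding current over quiet windows
before and after each bath exchange. Test pulses are excluded with a 0.5 s
pre-pulse and a 5 s post-pulse guard: the post-pulse guard must outlast the
tail relaxation (about 8 time constants at `tau_deact(-40 mV) ~ 0.6 s`),
otherwise decaying tail current contaminates the baseline. An H+-selective
leak predicts a shift of sign `sign(E_H_before - E_H_after)` (the Ohmic
prediction for a conductance that follows the proton driving force); a leak
is called only when *every* exchange shift exceeds `k` standard errors of
the window-mean difference *and* matches its predicted sign. The criterion
scale is the standard error — `noise_sd * sqrt(1/n_before + 1/n_after)` —
not the raw sample SD: the detector works on averaged windows, and the SE
is what makes k = 3 deliver the intended operating characteristics
(sensitivity above 95% for a 0.05 nS leak, false-positive rate below 1%,
both verified over hundreds of seeded simulations).

## Mutation hotspots (`hv1kit.hotspot`)

Coordinates are 1-based protein positions throughout. The merge keeps the
primary database in full — recurrent entries are distinct mutation events —
and admits a secondary record only when its (position, ref, alt) key is
new; the protein-level change is the only deduplication key that can be
reconstructed from summary data. Classification is purely syntactic:
`*` stop, `=` (or alt == ref) silent, otherwise missense. The hotspot
profile counts selected-class records in a centered 7-residue window
(position ± 3), clipped at the termini without shrinking the denominator —
the profile reports counts, not densities. Candidate hotspot intervals are
flagged where the windowed count reaches twice the protein-wide mean; this
threshold is an explicit stand-in for a visual call and is configurable.

## Structure geometry (`hv1kit.geometry`)

Ensembles are multi-model PDB trajectories (read/written via MDAnalysis)
with constant topology. Superposition is the Kabsch SVD solution; the test
suite cross-checks it against an independently implemented quaternion
(Kearsley) eigenvalue oracle to 1e-6 Å. RMSF superposes all frames onto the
iteratively refined mean structure and reports per-residue fluctuations.

Salt bridges: a frame is "in contact" when the minimum distance between any
basic side-chain nitrogen (Arg NE/NH1/NH2, Lys NZ, His ND1/NE2 — His counts
both ring nitrogens regardless of protonation) and any carboxylate oxygen
(Asp OD1/OD2, Glu OE1/OE2) is at most 4.0 Å. Occupancy is the contact
fraction of frames, classified strong at >= 0.65 and weak at >= 0.25. All
three numbers are configuration keys: they are field-typical values, and
the packaged reference interaction table (a glyph matrix with per-column
strong/weak sums) — not a recomputation — is the fixture against which the
table machinery is verified.

Axial geometry uses the hydrophobic gasket (V109, F150, V178, V179): the
mean of their C-alpha atoms defines z = 0 and the pore axis (x, y). The
membrane normal is assumed to be the z axis of the input coordinates; no
axis inference is attempted. Axial shifts between deactivated and activated
ensembles are differences of gasket-relative mean z (C-alpha, or the
side-chain tip CZ/NZ for Arg/Lys), averaged over frames and, for helix
ranges, over the residues of the range.

The water profile counts water oxygens per axial bin (default 0.5 Å)
inside a cylinder (default radius 8 Å) about the pore axis, averaged over
frames. The dewetted width is the contiguous interval around the lowest
minimum where the mean water number is below 1.0, with endpoints linearly
interpolated at the level crossings. The toy generator places waters at a
bulk density of two per bin, which puts the level-1 contour at half the
bulk plateau; for a step-like exclusion slab, linear interpolation then
localizes each edge to within a quarter bin, so constructed slab widths are
recovered to about 0.1–0.2 Å. The toy ensembles are geometric mimics —
a four-residue gasket ring, a straight S4-like helix, marker charged
residues, Gaussian frame jitter — and deliberately contain no protein
physics; what the passing tests show is that the *measurement* operations
are correct, not that any MD observation is reproduced.

## Problem sizes and numerical choices

Simulated families use 500 Hz sampling with per-step durations of about
five activation time constants; limiting-slope protocols use eight 2 mV
steps; leak assays run at 100 Hz with 30 s inter-pulse intervals; toy
ensembles use 50–300 frames. These sizes make every estimator's error
budget comfortably smaller than the tolerances asserted in the tests while
keeping the whole suite fast. Degenerate inputs fail loudly: flat traces,
empty windows, missing gasket residues, inverted regions and unknown table
glyphs all raise typed errors with actionable messages.

## Known limitations

* Two-state gating only: no Cole–Moore shift, no gating currents, no
  single-channel stochasticity, no temperature dependence of kinetics.
* Leak-free baselines are drift-free by construction; real seal-leak drift
  would require detrending before the window comparison.
* The hotspot caller is a threshold rule, not an enrichment test with a
  null model.
* Salt-bridge criteria (4.0 Å, 0.65/0.25) are conventional defaults, not
  fitted to any reference trajectory.
* The GHK bound treats TMA+ as the only competing permeant species and
  ignores liquid-junction corrections, matching the solution design it
  models.
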