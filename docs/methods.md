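# Methods

`atrialsim` reimplements a multiscale in-silico analysis of human atrial
electrophysiology: how the nine major sarcolemmal currents (I_Na, I_to,
I_CaL, I_Kur, I_Kr, I_Ks, I_K1, I_NCX, I_NaK) shape single-cell
repolarization and tissue-level reentrant spiral waves, in two established
human atrial cardiomyocyte models, and how interventions on the chronic-AF
electrically remodeled substrate behave when applied chronically versus
acutely.

## Cell models

**Courtemanche-1998** (21 states) and **Grandi-2011** (38 states,
sinus-rhythm parameterization: AF and isoproterenol flags off,
right-atrium flag off) were transcribed from their original publications /
published code; `src/atrialsim/models/PROVENANCE` records lineage and
every local choice. Both expose the same kernel contract: a plain RHS for
adaptive solvers, a fixed-step in-place update, a workspace ("no
allocation") reaction step for the tissue kernel, and an instantaneous
per-current evaluator. Each of the nine currents carries one dimensionless
multiplier on its maximal conductance (whole-flux multiplier for the
pump/exchanger and for the voltage-dependent I_Kur conductance);
multiplier 1 is identity, 0 a full block, and composition of scalings is
element-wise multiplication. The chronic-AF electrical remodeling set is
I_Na x0.90, I_to x0.20, I_CaL x0.50, I_Kur x0.45, I_Ks x2.0, I_K1 x2.0,
I_NCX x1.4 (I_Kr, I_NaK untouched).

Numerics. Single-cell protocols default to LSODA (rtol 1e-6, atol 1e-8),
integrating each stimulus segment separately. The fixed-step scheme is
exponential: Rush–Larsen for Hodgkin–Huxley gates and, in the Grandi
model, an exact exponential update of every reaction whose rate is linear
in its own state (Ca2+/Na+ buffers, calsequestrin, RyR states, with the
dominant linear sink split off for the compartment concentrations) — this
is what makes the stiff junctional-cleft buffering integrable at dt =
0.01 ms. Gates are clamped to [0,1] after every fixed step. The split
scheme converges first order against LSODA; the cross-integrator
consistency test runs Courtemanche at dt 0.02 ms and Grandi at dt 0.0005
ms, where both meet <1 mV RMS / <2 ms APD90 agreement over five beats. A
voltage lookup table (0.05 mV grid over -95..65 mV, storing gate steady
states, per-gate Rush–Larsen factors for the run's dt, and six current
factors) accelerates the Courtemanche tissue kernel ~3x; it reproduces the
exact algebra to ~3e-5 mV RMS over a beat and is regression-tested against
it.

The model-independent stimulus charge is booked against intracellular K+
wherever the model integrates [K+]i (Courtemanche; Grandi holds K+
fixed), so the K+ and Ca2+ budgets close to <1% per 100 beats at the
pacing steady state. Intracellular Na+ is *not* drift-free at beat 100:
its own equilibration takes minutes of pacing in these models, so the
conservation test checks the K+ flux budget directly and the K/Ca drift,
not Na+.

A two-variable Aliev–Panfilov surrogate (V = 100u - 80 mV, time scale
calibrated so one beat has a configurable APD90) runs under the same
contract. It exists so tissue machinery is testable in seconds; it is not
one of the study's models, and only its I_Na (excitation) and I_Kr/I_K1
(repolarization) scaling entries act. Its effective excitability falls as
the configured APD grows (the time scale divides the reaction rates), so
tissue tests with a 200 ms surrogate use a stronger stimulus (60 pA/pF)
than the 120 ms variant (30 pA/pF).

## Single-cell protocols and biomarkers

Quasi-steady state = 100 beats at BCL 1000 ms; biomarkers from the final
beat. The stimulus is a 2 ms rectangular pulse at twice the diastolic
threshold; the threshold is bisected once per model as the smallest
amplitude sustaining 1:1 capture of a ten-beat 1 Hz train (single-pulse
capture from rest is insufficient for the Grandi model, whose Na+
availability at its ~-74 mV diastole is far below full-rest availability)
and is then reused unchanged under every perturbation. Measured values:
Courtemanche 11.0 pA/pF, Grandi 5.25 pA/pF.

APD_x runs from AP onset (maximal dV/dt within 10 ms of the stimulus) to
the first downward crossing of V_peak - x%(V_peak - V_onset), linearly
interpolated, with V_onset the pre-stimulus potential. Repolarization
failure (plateau arrest) is flagged when the 90% level is never crossed
before the next stimulus, or when the beat starts from a non-resting
diastole (V_onset > -55 mV), which is how an arrested plateau presents on
subsequent beats.

Conductance scans re-pace each multiplier value with the full protocol.
Because a perturbation that merely attenuates the Na+ spike lowers V_peak
and thereby shifts every relative repolarization level, scans (and the
direction-of-effect analysis) anchor the x% levels to the reference
condition's AP; `measure_biomarkers` keeps the per-beat reference as its
default. The direction-of-effect analysis applies each 50% block for ten
beats on top of the baseline pre-paced state: long enough for every gate
to equilibrate, short enough that the slow secondary Na+-load adaptation
(~+1% APD90 per extra 100 beats under I_Na block) does not contaminate a
G_max sensitivity.

With these conventions the package reproduces the study's cellular
endpoints (the acceptance script prints them): Courtemanche APD90 ~290 ms
baseline / ~265 ms at 50% I_to; Grandi ~307 ms baseline / ~335 ms at 50%
I_to (prolongation, the signature model difference); I_Kr/I_Ks block moves
Grandi APD90 less than a third as much as Courtemanche's; I_Na block
changes APD90 by <2%. One boundary lands one grid step away from the
published one: the largest fully-repolarizing Grandi I_CaL scale computes
to 175% rather than 150%, with the 175% row already near arrest (final
beat repolarizes at ~590 ms, against ~350 ms at 150%, and every scale from
200% up arrests). The boundary sits on a fold bifurcation and is sensitive
to encoding details the source does not pin down; we report the computed
value rather than tuning toward the printed one.

## Tissue model

Monodomain, homogeneous and isotropic: dV/dt = D lap(V) - I_ion/C_m +
I_stim on a 200 x 200 grid with dx = 0.02 cm (4 x 4 cm) and no-flux
(mirror) boundaries; 5-point Laplacian, operator splitting with the
reaction advanced by the fixed-step kernels (dt defaults 0.02 ms
Courtemanche, 0.01 ms Grandi; the configured dt is checked against the
diffusion stability bound). Activation times (upward -40 mV crossings,
re-armed below -60 mV) are logged in-kernel. Tissue stimuli default to 4x
the 0D diastolic threshold — the 0D twice-threshold pulse cannot charge
the 2-column stimulus band against diffusive loading.

CV calibration bisects D on a 200 x 15-node strip (sensors at 25% and 75%
of length on the mid-row, activation-time difference), seeded by the
CV ~ sqrt(D) scaling law; baseline Courtemanche lands at D ~ 1.12e-3
cm^2/ms, CV 48 cm/s, inside the 45-50 cm/s band. At the production
resolution the discretization is not fully converged: halving dx changes
the measured Courtemanche CV by ~7% and halving dt by ~1.5% — the
ordinary coarse-grid slowing of a sharp-upstroke model at dx = 0.02 cm.
The convergence test asserts the tighter 3%/1% bounds and is expected to
fail at this resolution; it is kept as an honest record of the
discretization error rather than relaxed.

S1S2: all nodes start from the 0D 100-beat pre-paced state of the same
model and scaling (one S1 beat in tissue); S1 drives the leftmost two
columns at t = 0, S2 the upper-left quadrant (shared edges included) at
the onset-to-onset coupling interval. Runs stop at the horizon or once
the whole tissue stays below -70 mV for 100 ms. Recordings (voltage
frames on a fixed stride + activation log) persist to HDF5, with CSV
export for activation times.

## Vulnerability, rotors, interventions

Outcome classes per S1S2 run: NO_CAPTURE if no node inside the S2 region
activates during the pulse (+10 ms latency; activations elsewhere cannot
serve as the criterion because at short coupling intervals the S1 wave is
still crossing the tissue); NO_REENTRY if S2's wave propagates but no
node is activated twice after the pulse; TRANSIENT_REENTRY with duration
= last activation - S2 onset; STABLE_REENTRY if activity persists into
the final 200 ms before the stability horizon (12 s at full scale).
Truncated recordings are refused rather than guessed. The vulnerable
window over an interval grid reports min/max reentrant interval, size
(max - min, 0 if none) and the per-interval duration profile; scans may
run a 3 s default horizon with stability follow-ups for reentrant rows.

Phase maps use the time-delay embedding theta = atan2(V(t) - V*,
V(t - tau) - V*) with tau = 5 ms and per-node V* at the voltage-range
midpoint; nodes with <5 mV range are masked. Singularities are detected
by the topological-charge (plaquette winding) method with a +-0.2 pi
tolerance, plus a 3x3-loop pass that catches a core sitting exactly on a
node. Cores are linked frame to frame (same chirality, <=0.3 cm per
stride, two-stride gap tolerance); trajectories are boxcar-smoothed over
~50 ms to flatten the node-quantization staircase, and path length is
resampled at ~20 ms so detection jitter does not accumulate as a random
walk — on an analytic drifting-spiral fixture the recovered path length is
within ~1% of drift speed x lifetime. Meander extent is the maximum
pairwise core distance.

Interventions on the AF substrate: recovery of the I_to remodeling
(multiplier reset to 1), recovery of the I_CaL remodeling, and 80% I_Kr
block (x0.20). CHRONIC applies the modified scaling from t = 0 including
the 0D pre-pacing; ACUTE runs the untreated substrate until t_switch
(default 1000 ms after S2; established reentry is verified from the
activation log, else the run is refused) and then switches every node's
scaling instantaneously — the state array is untouched, so a no-op switch
is bit-identical to no switch.

## Scaled-down reentry suite

Full-scale vulnerable-window scans (200 x 200 nodes, 12 s horizons) are
supported but cost hours on one core, so the qualitative reentry claims
are exercised at reduced scale: 100 x 100 nodes over the same 4 x 4 cm
(dx 0.04 cm), dt 0.04 ms (0D APD90 shifts by ~1.6 ms vs dt 0.02), and
D = 5e-4 cm^2/ms giving CV ~ 30 cm/s. Lowering CV shortens the reentrant
wavelength (CV x APD) and thereby keeps the wavelength-to-domain ratio of
the scaled-down run close to the full-scale study's; with the calibrated
45-50 cm/s the AF-remodeled wavelength (~7 cm) so far exceeds the 4 cm
domain that induced reentry self-terminates within a rotation — the
expected consequence of limited excitable area relative to the
wavelength. Under these
conditions the suite reproduces the substrate orderings: AF remodeling
and 300% I_K1 sustain reentry at coupling intervals where the baseline
substrate is not even captured. The acute-intervention ordering (80%
I_Kr block terminating before I_CaL recovery, which at full scale
preserves the rotor) does **not** survive this scale reduction: in a
domain this small relative to the wavelength, *any* acute intervention
that prolongs the wavelength extinguishes the rotor, and I_CaL recovery
terminates no later than the I_Kr block (checked at 100x100, 120x120 and
140x140 nodes). The corresponding test asserts the full-scale ordering
and is expected to fail at reduced scale; we keep it failing rather than
assert the scale artifact. These are ordering assertions only; window
positions and durations at this scale are not comparable to full-scale
values.

## Known limitations

- Tissue is homogeneous and isotropic: no fibrosis, anisotropy, bidomain
  effects or 3D geometry; no atrial-specific currents beyond the source
  models (no I_KACh, I_SK, I_K2P); no Ca2+-handling or structural AF
  remodeling; no state-dependent drug kinetics.
- The Grandi fixed-step tissue integration at dt 0.01 ms carries a ~+20 ms
  first-order APD bias relative to the adaptive reference; Grandi tissue
  results are therefore treated as qualitative. All quantitative cellular
  endpoints use the adaptive path.
- The synthetic fixtures (triangle AP, analytic spiral/planar phase
  movies, surrogate reentry) validate measurement and tracking machinery
  exactly, but they contain none of the restitution, alternans or memory
  behavior of the ionic models — passing fixture tests says the analysis
  is correct, not that the physiology is.
- Published figure-level quantities that depend on the exact CellML
  exposure, solver and stimulus of the original study can differ within a
  few percent here; the acceptance script reports what this implementation
  computes.
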