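# atrialsim

Multiscale in-silico electrophysiology of the human atrium: how individual
ionic currents shape action-potential repolarization and reentrant spiral
waves, and how interventions on the chronic-AF-remodeled substrate behave
when applied chronically versus acutely.

The package is aimed at cardiac electrophysiology modelers who want a
reproducible, scriptable pipeline for conductance-sensitivity studies:

- **Cell models.** The Courtemanche-1998 (21-state) and Grandi-2011
  (38-state, sinus-rhythm) human atrial cardiomyocyte models, transcribed
  from their original publications, behind one right-hand-side contract.
  Each of the nine major currents — I_Na, I_to, I_CaL, I_Kur, I_Kr, I_Ks,
  I_K1, I_NCX, I_NaK — carries a dimensionless multiplier on its maximal
  conductance (G_max) or whole flux; the chronic-AF electrical remodeling
  set (I_Na −10%, I_to −80%, I_CaL −50%, I_Kur −55%, I_Ks +100%, I_K1
  +100%, I_NCX +40%) ships as `af_variant()`. A fast two-variable
  surrogate cell makes tissue machinery testable in seconds.
- **Single-cell protocols.** 1 Hz pacing to quasi-steady state (100
  beats), APD20/50/90, RMP, amplitude and dV/dt_max extraction with
  plateau-arrest detection, and 0–400% G_max scans.
- **Tissue.** A monodomain solver, ∂V/∂t = D∇²V − I_ion/C_m + I_stim, on a
  4 × 4 cm sheet (200 × 200 nodes) with no-flux boundaries, compiled
  per-model reaction kernels, conduction-velocity calibration by bisection
  of D, and the S1 planar / S2 upper-left-quadrant cross-field induction
  protocol.
- **Analysis.** Reentry outcome classification (vulnerable windows:
  inducibility = window size, stability = reentry duration; stable =
  persisting at 12 s), time-delay phase mapping, topological-charge
  phase-singularity detection, rotor-core trajectories and meander.
- **Interventions.** Recovery of I_to or I_CaL remodeling and 80% I_Kr
  block, applied chronically (before induction, including the pre-pacing)
  or acutely (switched instantaneously during established reentry).

## Worked example

```python
from atrialsim import courtemanche_model, grandi_model, ConductanceScaling
from atrialsim.protocols0d import PacingProtocol, pace, measure_biomarkers

protocol = PacingProtocol()          # BCL 1000 ms, 100 beats, 2 ms pulse
for model in (courtemanche_model(), grandi_model()):
    base = measure_biomarkers(pace(model, None, protocol))
    ito = measure_biomarkers(pace(model, ConductanceScaling({"Ito": 0.5}),
                                  protocol))
    print(f"{model.name:13s} APD90 baseline {base.apd90:6.1f} ms | "
          f"50% Ito {ito.apd90:6.1f} ms")
```

prints

```
courtemanche  APD90 baseline  289.8 ms | 50% Ito  265.1 ms
grandi        APD90 baseline  307.5 ms | 50% Ito  335.0 ms
```

— the signature model dependence: halving I_to *shortens* the
Courtemanche action potential by ~9% but *prolongs* the Grandi action
potential by ~9%, because the two models resolve the early-repolarization
notch against different plateau-current balances.

Calibrating tissue conduction and probing reentry:

```python
from atrialsim.tissue import calibrate_cv, TissueGeometry, run_s1s2
from atrialsim.vulnerability import classify_outcome
from atrialsim import af_variant

crn = courtemanche_model()
steady = pace(crn, None, protocol).final_state
cal = calibrate_cv(crn, None, (45.0, 50.0), initial_state=steady)
print(cal)   # CVCalibration(D=1.1230e-03 cm^2/ms, cv=48.2 cm/s, target=(45.0, 50.0))

af_steady = pace(crn, af_variant(), protocol).final_state
geom = TissueGeometry(nx=100, ny=100, dx=0.04, diffusion=5e-4)
rec = run_s1s2(crn, af_variant(), geom, s1s2_interval=200.0,
               duration=1000.0, initial_state=af_steady, dt=0.04)
print(classify_outcome(rec, horizon=1000.0))
# (<OutcomeClass.STABLE_REENTRY: 'STABLE_REENTRY'>, 800.0)
```

The same S1S2 premature stimulus that the baseline substrate does not even
capture (`NO_CAPTURE`) induces a reentrant spiral wave on the AF-remodeled
substrate that persists to the horizon.

A command-line layer wraps the same calls:

```bash
atrialsim scan0d --model courtemanche --current Ito --scales 0.5,1.0
atrialsim calibrate-cv --model courtemanche
atrialsim s1s2 --model courtemanche --scaling "IK1=3.0" --interval 190
atrialsim intervene --name AF_IKr_block80 --timing acute --interval 200
atrialsim make-fixture --kind archimedean_spiral
```

Every command writes CSV tables (with a units row), HDF5 recordings and a
plain-text run log carrying the configuration hash.

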