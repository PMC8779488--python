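Model provenance
================

courtemanche
  Source: Courtemanche M, Ramirez RJ, Nattel S. "Ionic mechanisms underlying
  human atrial action potential properties: insights from a mathematical
  model." Am J Physiol Heart Circ Physiol 275:H301-H321 (1998).
  Encoding: equations, parameter values and resting initial conditions
  transcribed directly from the publication's equation set. No CellML file
  was consulted; the transcription is validated against the publication's
  printed biomarkers (resting potential, 1 Hz APD90) and by cross-integrator
  consistency (adaptive LSODA vs fixed-step Rush-Larsen).
  Local choices: stimulus charge booked against intracellular K+; gates
  clamped to [0,1] after each fixed step; IKur scaled as a whole-current
  multiplier because its conductance is voltage-dependent.

grandi
  Source: Grandi E, Pandit SV, Voigt N, et al. "Human atrial action
  potential and Ca2+ model: sinus rhythm and chronic atrial fibrillation."
  Circ Res 109:1055-1066 (2011).
  Encoding: equations and parameters transcribed from the published code of
  the original article, sinus-rhythm parameterization (AF = 0, ISO = 0,
  right-atrium flag off). Intracellular K+ and Cl- are fixed parameters.
  Local choices: the cytosolic Ca2+ buffering flux sums the Ca2+-binding
  reaction rates only (the Mg2+-binding states of troponin and myosin evolve
  but do not enter the Ca2+ balance); fixed-step integration uses an
  exponential linear-split update (exact for the buffer reactions) instead
  of a stiff adaptive solver.

surrogate
  Aliev RR, Panfilov AV. "A simple two-variable model of cardiac
  excitation." Chaos Solitons Fractals 7:293-301 (1996), rescaled to mV/ms
  with a tunable APD90. Synthetic testing surrogate only; not one of the
  study's atrial models.
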