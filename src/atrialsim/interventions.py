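"""AF-remodeling interventions: chronic vs acute application.

The chronic-AF electrical remodeling set (INa -10%, Ito -80%, ICaL -50%,
IKur -55%, IKs +100%, IK1 +100%, INCX +40%) forms the diseased substrate.
Three hypothetical treatments are modeled as conductance modifications:
recovery of the Ito remodeling (Ito multiplier reset to 1), recovery of
the ICaL remodeling (ICaL reset to 1), and 80% IKr block (IKr x 0.20, the
class III antiarrhythmic effect).

CHRONIC timing applies the modified scaling from t = 0 *including* the 0D
pre-pacing, modeling a treatment present before arrhythmia induction.
ACUTE timing runs the untreated AF substrate until reentry is established
and then switches the scaling instantaneously and uniformly at t_switch
(default 1000 ms after S2), carrying the tissue state over exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .currents import ConductanceScaling, CurrentID, af_variant
from .models import ModelDefinition
from .recording import Recording
from .tissue import TissueGeometry, run_s1s2
from .vulnerability import OutcomeClass, classify_outcome

__all__ = [
    "InterventionSpec",
    "build_intervention",
    "run_intervention",
    "NoReentryToTreat",
    "INTERVENTION_NAMES",
    "DEFAULT_T_SWITCH_AFTER_S2",
]

INTERVENTION_NAMES = ("AF", "AF_recover_Ito", "AF_recover_ICaL",
                      "AF_IKr_block80", "SR")
DEFAULT_T_SWITCH_AFTER_S2 = 1000.0  # ms; >= 2 rotations to establish reentry


class NoReentryToTreat(RuntimeError):
    """Acute intervention refused: no reentrant activity at t_switch."""


@dataclass(frozen=True)
class InterventionSpec:
    """A substrate scaling plus its treated modification and timing."""

    name: str
    base: ConductanceScaling       # substrate before treatment (e.g. AF)
    modified: ConductanceScaling   # substrate with the treatment applied
    timing: str = "chronic"        # "chronic" | "acute"
    t_switch_after_s2: float = DEFAULT_T_SWITCH_AFTER_S2

    def __post_init__(self) -> None:
        if self.timing not in ("chronic", "acute"):
            raise ValueError(f"timing must be chronic|acute, got {self.timing!r}")
        if self.timing == "acute" and self.t_switch_after_s2 <= 0:
            raise ValueError("acute t_switch must fall after S2 onset")

    def with_timing(self, timing: str,
                    t_switch_after_s2: float | None = None) -> "InterventionSpec":
        return InterventionSpec(
            self.name, self.base, self.modified, timing,
            self.t_switch_after_s2 if t_switch_after_s2 is None
            else float(t_switch_after_s2))


def build_intervention(name: str, timing: str = "chronic",
                       t_switch_after_s2: float = DEFAULT_T_SWITCH_AFTER_S2
                       ) -> InterventionSpec:
    """Named intervention on the AF-remodeled substrate.

    ``AF`` (untreated substrate) and ``SR`` (sinus rhythm, identity
    scaling) are included as controls; for both, base == modified.
    """
    af = af_variant()
    if name == "AF":
        base = modified = af
    elif name == "SR":
        base = modified = ConductanceScaling()
    elif name == "AF_recover_Ito":
        base, modified = af, af.with_current(CurrentID.Ito, 1.0)
    elif name == "AF_recover_ICaL":
        base, modified = af, af.with_current(CurrentID.ICaL, 1.0)
    elif name == "AF_IKr_block80":
        base, modified = af, af.compose({CurrentID.IKr: 0.20})
    else:
        raise KeyError(
            f"unknown intervention {name!r}; available: {INTERVENTION_NAMES}")
    return InterventionSpec(name, base, modified, timing,
                            float(t_switch_after_s2))


def run_intervention(model: ModelDefinition,
                     spec: InterventionSpec,
                     s1s2_interval: float,
                     geometry: TissueGeometry,
                     horizon: float = 3000.0,
                     initial_state: np.ndarray | None = None,
                     pre_paced_states: dict | None = None,
                     **s1s2_kwargs) -> tuple[Recording, OutcomeClass, float]:
    """Run one S1S2 intervention experiment; returns (recording, outcome,
    reentry_duration_ms).

    CHRONIC: the modified scaling is applied throughout, including the 0D
    pre-pacing that supplies the tissue initial state.  ACUTE: the base
    (untreated) scaling applies until t_switch = S2 onset +
    ``spec.t_switch_after_s2``, then the modified scaling applies to every
    node instantaneously; the run is refused if no reentrant activity
    (activations in the 250 ms before t_switch) exists to treat.

    ``initial_state`` (or entries of ``pre_paced_states`` keyed by scaling
    repr) can supply cached 0D pre-paced states; otherwise a 100-beat 1 Hz
    pre-pacing run is performed here.
    """
    from .protocols0d import PacingProtocol, pace

    scaling_run = spec.modified if spec.timing == "chronic" else spec.base
    if initial_state is None:
        key = repr(scaling_run)
        if pre_paced_states is not None and key in pre_paced_states:
            initial_state = pre_paced_states[key]
        else:
            initial_state = pace(model, scaling_run,
                                 PacingProtocol()).final_state
            if pre_paced_states is not None:
                pre_paced_states[key] = initial_state

    schedule = None
    if spec.timing == "acute":
        t_switch = float(s1s2_interval) + spec.t_switch_after_s2
        if t_switch >= horizon:
            raise ValueError("t_switch beyond the simulation horizon")
        schedule = [(t_switch, spec.modified)]

    rec = run_s1s2(model, scaling_run, geometry, s1s2_interval,
                   duration=horizon, initial_state=initial_state,
                   scaling_schedule=schedule, **s1s2_kwargs)
    rec.meta.update({
        "intervention": spec.name,
        "timing": spec.timing,
        "t_switch_ms": (None if schedule is None else schedule[0][0]),
    })

    if spec.timing == "acute":
        t_switch = schedule[0][0]
        _, times = rec.activation_after(t_switch - 250.0)
        if not np.any(times <= t_switch):
            raise NoReentryToTreat(
                f"{spec.name}: no reentry to treat — no activation in the "
                f"250 ms before t_switch={t_switch:.0f} ms "
                f"(S1S2={s1s2_interval:.0f} ms)")

    outcome, duration = classify_outcome(rec, horizon=horizon)
    return rec, outcome, duration
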