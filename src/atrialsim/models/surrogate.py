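"""Two-variable activator–recovery excitable cell (testing surrogate).

An Aliev–Panfilov-type model: an activation variable u (mapped to membrane
potential as V = 100*u - 80 mV) and a recovery variable w,

    du/dt = [ k u (u - a)(1 - u) - u w ] / ts + i_stim / 100
    dw/dt = [ (e0 + mu1 w / (u + mu2)) (-w - k u (u - a - 1)) ] / ts

with the time scale ts (ms per dimensionless unit) chosen so that a single
stimulated beat has the configured APD90.  This is NOT one of the study's
atrial cardiomyocyte models: it exists so tissue-level machinery (pacing,
S1S2, reentry classification, rotor tracking) is testable in seconds.

The nine-current scaling contract is honoured minimally: the INa entry
scales the excitation term (upstroke/CV) and the IKr and IK1 entries both
scale the repolarizing u*w term (APD); the remaining entries have no
effect, which the model definition documents.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numba import njit

from ..currents import CurrentID
from .base import ModelDefinition

N_STATE = 2
V_INDEX = 0
STATE_NAMES = ("V", "w")

K = 8.0
A = 0.15
E0 = 0.002
MU1 = 0.2
MU2 = 0.3
#: dimensionless APD90 of a single beat at these kinetics (measured once by
#: high-accuracy adaptive integration of the dimensionless system)
DIMENSIONLESS_APD90 = 26.391
V_REST = -80.0
V_SCALE = 100.0


@lru_cache(maxsize=8)
def _kernels(ts: float):
    @njit(cache=False)
    def rhs(t, y, scale, i_stim):
        dy = np.empty(2)
        u = (y[0] - V_REST) / V_SCALE
        w = y[1]
        excite = scale[0] * K * u * (u - A) * (1.0 - u)
        repol = scale[4] * scale[6] * u * w
        dy[0] = V_SCALE * (excite - repol) / ts + i_stim
        dy[1] = (E0 + MU1 * w / (u + MU2)) * (-w - K * u * (u - A - 1.0)) / ts
        return dy

    @njit(cache=False)
    def step_rl(y, dt, scale, i_stim):
        dy = rhs(0.0, y, scale, i_stim)
        y[0] += dt * dy[0]
        y[1] += dt * dy[1]
        if y[1] < 0.0:
            y[1] = 0.0

    @njit(cache=False)
    def reaction_rl(y, dt, scale, i_stim):
        dy = rhs(0.0, y, scale, i_stim)
        y[1] += dt * dy[1]
        if y[1] < 0.0:
            y[1] = 0.0
        return dy[0]

    @njit(cache=False)
    def reaction_ws(y, dt, scale, i_stim, w1, w2, w3, aux):
        return reaction_rl(y, dt, scale, i_stim)

    @njit(cache=False)
    def currents(y, scale):
        u = (y[0] - V_REST) / V_SCALE
        w = y[1]
        out = np.zeros(9)
        out[0] = -scale[0] * K * u * (u - A) * (1.0 - u) * V_SCALE / ts
        rep = scale[4] * scale[6] * u * w * V_SCALE / ts
        out[4] = rep * 0.5
        out[6] = rep * 0.5
        return out

    return rhs, step_rl, reaction_rl, reaction_ws, currents


@lru_cache(maxsize=8)
def build(apd_ms: float = 200.0) -> ModelDefinition:
    """Surrogate model definition with the requested single-beat APD90."""
    ts = float(apd_ms) / DIMENSIONLESS_APD90
    rhs, step_rl, reaction_rl, reaction_ws, currents = _kernels(round(ts, 9))
    return ModelDefinition(
        name="surrogate",
        state_names=STATE_NAMES,
        default_initial_state=np.array([V_REST, 0.0]),
        constants={"k": K, "a": A, "e0": E0, "mu1": MU1, "mu2": MU2,
                   "time_scale_ms": ts, "apd90_ms": float(apd_ms)},
        scalable_currents={
            CurrentID.INa: K, CurrentID.Ito: 0.0, CurrentID.ICaL: 0.0,
            CurrentID.IKur: 0.0, CurrentID.IKr: 1.0, CurrentID.IKs: 0.0,
            CurrentID.IK1: 1.0, CurrentID.INCX: 0.0, CurrentID.INaK: 0.0,
        },
        v_index=V_INDEX,
        gate_indices=np.empty(0, dtype=np.int64),
        rhs=rhs,
        step_rl=step_rl,
        reaction_rl=reaction_rl,
        reaction_ws=reaction_ws,
        currents=currents,
        dt_default=0.1,
        provenance=(
            "Aliev-Panfilov two-variable excitable cell; synthetic testing "
            "surrogate, not an atrial cardiomyocyte model from the study. "
            "Only the INa (excitation) and IKr/IK1 (repolarization) scaling "
            "entries act; Ito, ICaL, IKur, IKs, INCX and INaK entries are "
            "inert by construction."
        ),
    )
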