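"""Common contract for ionic cell models.

A :class:`ModelDefinition` bundles a model's state layout, initial
conditions, scalable-current registry and its compiled kernels behind one
interface, so that pacing drivers and the tissue solver are model-agnostic.

Kernel contract (all numba-compiled, operating on float64 arrays):

``rhs(t, y, scale, i_stim) -> dy``
    plain time derivatives (unit/ms), for adaptive solvers;
``step_rl(y, dt, scale, i_stim)``
    in-place fixed-step update, Rush–Larsen (exponential) for gates,
    forward Euler otherwise, gates clamped to [0, 1];
``reaction_rl(y, dt, scale, i_stim) -> dV/dt``
    like ``step_rl`` but leaves V untouched and returns dV/dt, so a tissue
    kernel can combine it with a diffusion term;
``currents(y, scale) -> ndarray(9)``
    instantaneous values of the nine scalable currents (pA/pF) in the fixed
    :data:`atrialsim.currents.CURRENT_ORDER`.

``scale`` is always the 9-vector produced by
:meth:`atrialsim.currents.ConductanceScaling.as_vector`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from ..currents import CURRENT_ORDER, ConductanceScaling, CurrentID

__all__ = ["ModelDefinition", "IntegrationError"]


class IntegrationError(RuntimeError):
    """Raised when an integration produces a non-finite state component."""

    def __init__(self, message: str, component: str | None = None,
                 beat: int | None = None):
        super().__init__(message)
        self.component = component
        self.beat = beat


@dataclass(frozen=True)
class ModelDefinition:
    """A cell model: state layout, constants, kernels, scalable currents."""

    name: str
    state_names: tuple[str, ...]
    default_initial_state: np.ndarray
    constants: Mapping[str, float]
    scalable_currents: Mapping[CurrentID, float]  # baseline G_max / flux values
    v_index: int
    gate_indices: np.ndarray
    rhs: Callable
    step_rl: Callable
    reaction_rl: Callable
    reaction_ws: Callable
    currents: Callable
    dt_default: float              # ms; fixed-step default validated per model
    #: optional builder of a dt-specific lookup table consumed by reaction_ws
    tissue_aux: Callable | None = None
    provenance: str = ""
    stimulus_sign_convention: str = "positive stimulus depolarizes (pA/pF)"
    #: diastolic threshold cache {(): amplitude} filled lazily by protocols
    _threshold_cache: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.state_names) != len(self.default_initial_state):
            raise ValueError("state_names and initial state length mismatch")
        missing = [c for c in CURRENT_ORDER if c not in self.scalable_currents]
        if missing:
            raise ValueError(f"{self.name}: unregistered scalable currents {missing}")
        extra = [c for c in self.scalable_currents if c not in CURRENT_ORDER]
        if extra:
            raise ValueError(f"{self.name}: unknown scalable currents {extra}")

    @property
    def n_state(self) -> int:
        return len(self.state_names)

    def initial_state(self) -> np.ndarray:
        return self.default_initial_state.copy()

    def state_index(self, name: str) -> int:
        return self.state_names.index(name)

    def check_state(self, y: np.ndarray, context: str = "") -> None:
        """Raise :class:`IntegrationError` naming the first bad component."""
        bad = np.flatnonzero(~np.isfinite(y))
        if bad.size:
            comp = self.state_names[int(bad[0])]
            raise IntegrationError(
                f"{self.name}: non-finite state component {comp!r} {context}".strip(),
                component=comp,
            )

    def scale_vector(self, scaling: ConductanceScaling | None) -> np.ndarray:
        if scaling is None:
            scaling = ConductanceScaling()
        return scaling.as_vector()

    def __repr__(self) -> str:
        return f"<ModelDefinition {self.name!r}, {self.n_state} states>"
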