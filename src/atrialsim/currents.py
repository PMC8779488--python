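"""Scalable ionic currents and conductance-scaling maps.

Nine sarcolemmal currents are exposed for maximal-conductance (or, for the
pumps/exchangers, whole-flux) scaling in every atrial cell model: the fast
Na+ current, the transient-outward K+ current, the L-type Ca2+ current, the
ultra-rapid / rapid / slow delayed-rectifier K+ currents, the inward-rectifier
K+ current, the Na+/Ca2+ exchanger and the Na+/K+ pump.  A
:class:`ConductanceScaling` maps each current to a dimensionless multiplier
applied to its maximal conductance; 1.0 is identity, 0.0 is a full block.
"""

from __future__ import annotations

import enum
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CurrentID", "ConductanceScaling", "AF_REMODELING"]


class CurrentID(str, enum.Enum):
    """Identifiers of the nine scalable sarcolemmal currents."""

    INa = "INa"
    Ito = "Ito"
    ICaL = "ICaL"
    IKur = "IKur"
    IKr = "IKr"
    IKs = "IKs"
    IK1 = "IK1"
    INCX = "INCX"
    INaK = "INaK"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.value


#: Fixed ordering used for the scale vectors handed to compiled kernels.
CURRENT_ORDER: tuple[CurrentID, ...] = tuple(CurrentID)

#: Chronic-AF electrical remodeling of transmembrane current densities:
#: INa -10%, Ito -80%, ICaL -50%, IKur -55%, IKs +100%, IK1 +100%, INCX +40%.
AF_REMODELING: dict[CurrentID, float] = {
    CurrentID.INa: 0.90,
    CurrentID.Ito: 0.20,
    CurrentID.ICaL: 0.50,
    CurrentID.IKur: 0.45,
    CurrentID.IKs: 2.0,
    CurrentID.IK1: 2.0,
    CurrentID.INCX: 1.4,
}


@dataclass(frozen=True)
class ConductanceScaling:
    """Map from :class:`CurrentID` to a nonnegative G_max multiplier.

    Missing entries default to 1.0 (identity).  Composition of two scalings
    is element-wise multiplication, so applying a perturbation twice squares
    its multipliers.
    """

    factors: Mapping[CurrentID, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[CurrentID, float] = {}
        for key, value in dict(self.factors).items():
            cid = CurrentID(key)
            value = float(value)
            if not np.isfinite(value) or value < 0.0:
                raise ValueError(
                    f"scaling for {cid} must be finite and >= 0, got {value!r}"
                )
            clean[cid] = value
        object.__setattr__(self, "factors", clean)

    def __getitem__(self, current: CurrentID | str) -> float:
        return self.factors.get(CurrentID(current), 1.0)

    def compose(self, other: "ConductanceScaling | Mapping") -> "ConductanceScaling":
        """Element-wise product with ``other`` (order-independent)."""
        if not isinstance(other, ConductanceScaling):
            other = ConductanceScaling(other)
        keys = set(self.factors) | set(other.factors)
        return ConductanceScaling({k: self[k] * other[k] for k in keys})

    def with_current(self, current: CurrentID | str, value: float) -> "ConductanceScaling":
        """Return a copy with one current's multiplier replaced (not composed)."""
        factors = dict(self.factors)
        factors[CurrentID(current)] = float(value)
        return ConductanceScaling(factors)

    def as_vector(self) -> np.ndarray:
        """Multipliers in the fixed :data:`CURRENT_ORDER`, for compiled kernels."""
        return np.array([self[c] for c in CURRENT_ORDER], dtype=np.float64)

    def to_dict(self) -> dict[str, float]:
        return {c.value: self[c] for c in CURRENT_ORDER}

    def __repr__(self) -> str:
        inner = ", ".join(f"{c}={self[c]:g}" for c in CURRENT_ORDER if self[c] != 1.0)
        return f"ConductanceScaling({inner or 'identity'})"


def af_variant(base: ConductanceScaling | None = None) -> ConductanceScaling:
    """Compose ``base`` (default identity) with the chronic-AF remodeling set.

    IKr and INaK are not remodeled and keep their base multipliers.
    """
    base = base if base is not None else ConductanceScaling()
    return base.compose(AF_REMODELING)
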