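"""Ionic cell models behind one right-hand-side contract."""

from __future__ import annotations

from ..currents import CurrentID
from .base import IntegrationError, ModelDefinition

__all__ = [
    "ModelDefinition",
    "IntegrationError",
    "courtemanche_model",
    "grandi_model",
    "surrogate_model",
    "get_model",
    "MODEL_NAMES",
]

MODEL_NAMES = ("courtemanche", "grandi", "surrogate")

_CACHE: dict[str, ModelDefinition] = {}


def courtemanche_model() -> ModelDefinition:
    """Courtemanche-1998 human atrial cardiomyocyte model."""
    if "courtemanche" not in _CACHE:
        from . import courtemanche as cm

        _CACHE["courtemanche"] = ModelDefinition(
            name="courtemanche",
            state_names=cm.STATE_NAMES,
            default_initial_state=cm.Y0.copy(),
            constants={
                "Cm_pF": cm.CM, "T_K": cm.T, "Ko_mM": cm.KO,
                "Nao_mM": cm.NAO, "Cao_mM": cm.CAO,
            },
            scalable_currents={
                CurrentID.INa: cm.G_NA, CurrentID.Ito: cm.G_TO,
                CurrentID.ICaL: cm.G_CAL, CurrentID.IKur: 1.0,
                CurrentID.IKr: cm.G_KR, CurrentID.IKs: cm.G_KS,
                CurrentID.IK1: cm.G_K1, CurrentID.INCX: cm.I_NACA_MAX,
                CurrentID.INaK: cm.I_NAK_MAX,
            },
            v_index=cm.V_INDEX,
            gate_indices=cm.GATE_INDICES,
            rhs=cm.rhs,
            step_rl=cm.step_rl,
            reaction_rl=cm.reaction_rl,
            reaction_ws=cm.reaction_ws,
            currents=cm.currents,
            dt_default=0.02,
            tissue_aux=cm.tissue_aux,
            provenance=(
                "Courtemanche, Ramirez & Nattel 1998 human atrial action "
                "potential model; equations and initial conditions transcribed "
                "from the original publication. IKur has a voltage-dependent "
                "conductance, so its registry entry is the whole-current "
                "multiplier 1.0."
            ),
        )
    return _CACHE["courtemanche"]


def grandi_model() -> ModelDefinition:
    """Grandi-2011 human atrial cardiomyocyte model (sinus-rhythm variant)."""
    if "grandi" not in _CACHE:
        from . import grandi as gr

        _CACHE["grandi"] = ModelDefinition(
            name="grandi",
            state_names=gr.STATE_NAMES,
            default_initial_state=gr.Y0.copy(),
            constants={
                "Cm_pF": gr.CMEM * 1e12, "T_K": gr.TEMP, "Ko_mM": gr.KO,
                "Nao_mM": gr.NAO, "Cao_mM": gr.CAO, "Ki_mM": gr.KI,
            },
            scalable_currents={
                CurrentID.INa: gr.G_NA, CurrentID.Ito: gr.G_TO_FAST,
                CurrentID.ICaL: gr.P_CA, CurrentID.IKur: gr.G_KUR,
                CurrentID.IKr: gr.G_KR, CurrentID.IKs: gr.G_KS,
                CurrentID.IK1: gr.G_K1, CurrentID.INCX: gr.IBAR_NCX,
                CurrentID.INaK: gr.IBAR_NAK,
            },
            v_index=gr.V_INDEX,
            gate_indices=gr.GATE_INDICES,
            rhs=gr.rhs,
            step_rl=gr.step_rl,
            reaction_rl=gr.reaction_rl,
            reaction_ws=gr.reaction_ws,
            currents=gr.currents,
            dt_default=0.01,
            provenance=(
                "Grandi, Pandit, Voigt et al. 2011 human atrial model, "
                "sinus-rhythm parameterization (AF = ISO = 0, right-atrium "
                "flag off); equations transcribed from the published code of "
                "the original article. Intracellular K+ is a fixed parameter "
                "in this model."
            ),
        )
    return _CACHE["grandi"]


def surrogate_model(apd_ms: float = 200.0) -> ModelDefinition:
    """Two-variable activator–recovery excitable cell (testing surrogate).

    NOT one of the study's atrial models: a minimal Aliev–Panfilov-type cell
    with a tunable action-potential duration, registered under the same RHS
    contract so tissue-level machinery can be exercised in seconds.
    """
    from . import surrogate as su

    return su.build(apd_ms=apd_ms)


def get_model(name: str, **kwargs) -> ModelDefinition:
    """Look a model up by name: courtemanche | grandi | surrogate."""
    name = name.lower()
    if name == "courtemanche":
        return courtemanche_model()
    if name == "grandi":
        return grandi_model()
    if name == "surrogate":
        return surrogate_model(**kwargs)
    raise KeyError(f"unknown model {name!r}; available: {MODEL_NAMES}")
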