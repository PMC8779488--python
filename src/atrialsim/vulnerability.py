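"""S1S2 outcome classification and vulnerable-window profiles.

An S1S2 run is classified from its activation log:

NO_CAPTURE
    no propagated activation outside the S2 region after S2 (the S1 wave
    has left the tissue by the time S2 is delivered, so any later
    activation is S2-caused);
NO_REENTRY
    S2 captures and its primary wave propagates, but no node is activated
    more than once afterwards — the wave extinguishes at the boundaries;
TRANSIENT_REENTRY
    at least one node is re-excited (activated >= 2 times after S2), and
    the tissue is quiescent before the stability horizon; the reentry
    duration is the last activation time minus S2 onset;
STABLE_REENTRY
    reentrant activity persists at the horizon (12 s by convention):
    any activation falls in the final 200 ms before the horizon.

The vulnerable window over a grid of S1S2 coupling intervals summarizes
inducibility (window size, max - min reentrant interval) and stability
(the per-interval reentry-duration profile).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .currents import ConductanceScaling
from .models import ModelDefinition
from .models.base import IntegrationError
from .recording import Recording
from .tissue import TissueGeometry, run_s1s2

__all__ = [
    "OutcomeClass",
    "VWRecord",
    "VulnerableWindow",
    "classify_outcome",
    "scan_vulnerable_window",
    "STABILITY_HORIZON_MS",
]

STABILITY_HORIZON_MS = 12_000.0
STABLE_TAIL_MS = 200.0
CAPTURE_LATENCY_MS = 10.0

REENTRY_CLASSES = ("TRANSIENT_REENTRY", "STABLE_REENTRY")


class OutcomeClass(str, enum.Enum):
    NO_CAPTURE = "NO_CAPTURE"
    NO_REENTRY = "NO_REENTRY"
    TRANSIENT_REENTRY = "TRANSIENT_REENTRY"
    STABLE_REENTRY = "STABLE_REENTRY"

    @property
    def is_reentry(self) -> bool:
        return self.value in REENTRY_CLASSES


class TruncatedRecording(ValueError):
    """Recording neither reaches quiescence nor the stability horizon."""


def classify_outcome(recording: Recording,
                     horizon: float = STABILITY_HORIZON_MS
                     ) -> tuple[OutcomeClass, float]:
    """Classify an S1S2 recording; returns (outcome, reentry_duration_ms).

    The recording's metadata must carry the S2 onset and S2 region bounds
    (written by :func:`atrialsim.tissue.run_s1s2`).  A recording that is
    neither quiescent nor long enough to reach ``horizon`` is refused.
    """
    meta = recording.meta
    try:
        s2_onset = float(meta["s2_onset_ms"])
        stim_dur = float(meta.get("stim_duration_ms", 2.0))
        x_max = int(meta["s2_mask_x_max"])
        y_max = int(meta["s2_mask_y_max"])
    except KeyError as exc:
        raise ValueError(f"recording lacks S1S2 metadata ({exc})") from exc

    quiescent = bool(meta.get("quiescent", False))
    t_end = recording.t_end
    if not quiescent and t_end + 1e-6 < horizon:
        raise TruncatedRecording(
            f"recording ends at {t_end:.0f} ms, neither quiescent nor "
            f"reaching the {horizon:.0f} ms horizon")

    s2_end = s2_onset + stim_dur
    # capture: some node inside the S2 region activates during the pulse
    # (+ a short latency margin).  Activations elsewhere cannot be used as
    # the capture criterion because at short coupling intervals the S1
    # wave may still be crossing the tissue when S2 is delivered.
    xy_c, t_c = recording.activation_after(s2_onset)
    window = t_c <= s2_end + CAPTURE_LATENCY_MS
    in_mask = (xy_c[:, 0] <= x_max) & (xy_c[:, 1] <= y_max)
    if not np.any(window & in_mask):
        return OutcomeClass.NO_CAPTURE, 0.0
    xy, times = recording.activation_after(s2_end)
    if times.size == 0:
        return OutcomeClass.NO_CAPTURE, 0.0

    # re-excitation: any node activated at least twice after S2
    flat = xy[:, 1].astype(np.int64) * (recording.shape[1] + 1) + xy[:, 0]
    _, counts = np.unique(flat, return_counts=True)
    reentry = bool((counts >= 2).any())
    if not reentry:
        return OutcomeClass.NO_REENTRY, 0.0

    if not quiescent and times.max() >= horizon - STABLE_TAIL_MS:
        return OutcomeClass.STABLE_REENTRY, float(t_end - s2_onset)
    return OutcomeClass.TRANSIENT_REENTRY, float(times.max() - s2_onset)


@dataclass(frozen=True)
class VWRecord:
    """One S1S2 coupling interval's outcome."""

    interval: float               # ms
    outcome: OutcomeClass | None
    reentry_duration: float = 0.0  # ms
    error: str = ""


@dataclass
class VulnerableWindow:
    """Reentry outcomes over an S1S2 interval grid."""

    records: list[VWRecord]
    model_name: str = ""
    scaling: dict = field(default_factory=dict)
    horizon: float = STABILITY_HORIZON_MS

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.interval)

    @property
    def reentrant_intervals(self) -> np.ndarray:
        return np.array([r.interval for r in self.records
                         if r.outcome is not None and r.outcome.is_reentry])

    @property
    def window_start(self) -> float:
        iv = self.reentrant_intervals
        return float(iv.min()) if iv.size else np.nan

    @property
    def window_end(self) -> float:
        iv = self.reentrant_intervals
        return float(iv.max()) if iv.size else np.nan

    @property
    def size(self) -> float:
        """max - min reentrant coupling interval; 0 when none is reentrant."""
        iv = self.reentrant_intervals
        return float(iv.max() - iv.min()) if iv.size else 0.0

    @property
    def n_stable(self) -> int:
        return sum(1 for r in self.records
                   if r.outcome is OutcomeClass.STABLE_REENTRY)

    def max_duration(self) -> float:
        return max((r.reentry_duration for r in self.records), default=0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "s1s2_interval_ms": r.interval,
            "outcome": r.outcome.value if r.outcome else "ERROR",
            "reentry_duration_ms": r.reentry_duration,
            "error": r.error,
        } for r in self.records]).set_index("s1s2_interval_ms")


def scan_vulnerable_window(model: ModelDefinition,
                           scaling: ConductanceScaling | None,
                           interval_grid,
                           geometry: TissueGeometry,
                           initial_state: np.ndarray | None = None,
                           duration: float = 3000.0,
                           horizon: float = STABILITY_HORIZON_MS,
                           stability_follow_up: bool = False,
                           **s1s2_kwargs) -> VulnerableWindow:
    """One S1S2 run per coupling interval; outcomes summarized.

    Runs are independent and order-insensitive; per-interval failures are
    recorded as error rows rather than dropped.  ``duration`` is the scan
    horizon (3 s default); with ``stability_follow_up`` every reentrant
    interval is re-run to the full stability ``horizon`` so that
    STABLE_REENTRY claims refer to the 12 s definition.
    """
    grid = np.asarray(sorted(interval_grid), dtype=float)
    if grid.size and np.any(np.diff(grid) <= 0):
        raise ValueError("interval grid must be strictly increasing")
    records = []
    for interval in grid:
        try:
            rec = run_s1s2(model, scaling, geometry, interval,
                           duration=duration, initial_state=initial_state,
                           **s1s2_kwargs)
            outcome, dur = classify_outcome(rec, horizon=duration)
            if (outcome is OutcomeClass.STABLE_REENTRY and
                    stability_follow_up and horizon > duration):
                rec = run_s1s2(model, scaling, geometry, interval,
                               duration=horizon, initial_state=initial_state,
                               **s1s2_kwargs)
                outcome, dur = classify_outcome(rec, horizon=horizon)
            records.append(VWRecord(float(interval), outcome, dur))
        except (IntegrationError, TruncatedRecording) as exc:
            records.append(VWRecord(float(interval), None, 0.0, str(exc)))
    return VulnerableWindow(
        records=records,
        model_name=model.name,
        scaling=(scaling.to_dict() if scaling is not None
                 else ConductanceScaling().to_dict()),
        horizon=horizon if stability_follow_up else duration,
    )
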