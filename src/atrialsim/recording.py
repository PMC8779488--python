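"""Voltage-frame recordings: the common output format of tissue runs.

A :class:`Recording` holds voltage snapshots on a regular time stride, the
per-node activation log (upward -40 mV crossings), and run metadata.  Both
the tissue solver and the synthetic fixture generators emit this format,
so the analysis modules (vulnerability classification, phase mapping,
rotor tracking) cannot distinguish a fixture from a simulation.

Persistence is HDF5: one ``frames`` dataset (T, ny, nx float32), frame
times, the activation log, and metadata as root attributes.  Activation
times can also be exported as CSV (x, y, t_act).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = ["Recording"]


@dataclass
class Recording:
    frames: np.ndarray            # (T, ny, nx) float32, membrane potential mV
    frame_times: np.ndarray       # (T,) ms
    activation_xy: np.ndarray     # (N, 2) int32, node indices (x, y)
    activation_times: np.ndarray  # (N,) ms
    activation_counts: np.ndarray  # (ny, nx) int32
    dx: float                     # cm
    dt: float                     # ms (solver step)
    model_name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.shape[0] != self.frame_times.size:
            raise ValueError("frames and frame_times length mismatch")

    # -- geometry helpers ------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]  # (ny, nx)

    @property
    def stride_ms(self) -> float:
        if self.frame_times.size < 2:
            return float("nan")
        return float(np.median(np.diff(self.frame_times)))

    @property
    def t_end(self) -> float:
        return float(self.meta.get("ended_at_ms",
                                   self.frame_times[-1] if
                                   self.frame_times.size else 0.0))

    def activation_after(self, t0: float):
        """(xy, times) of activations at or after ``t0`` ms."""
        sel = self.activation_times >= t0
        return self.activation_xy[sel], self.activation_times[sel]

    # -- persistence -----------------------------------------------------
    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=self.frames, compression="gzip",
                             compression_opts=1)
            f.create_dataset("frame_times", data=self.frame_times)
            f.create_dataset("activation_xy", data=self.activation_xy)
            f.create_dataset("activation_times", data=self.activation_times)
            f.create_dataset("activation_counts", data=self.activation_counts)
            f.attrs["dx_cm"] = self.dx
            f.attrs["dt_ms"] = self.dt
            f.attrs["model"] = self.model_name
            f.attrs["meta_json"] = json.dumps(self.meta, default=float)
        return path

    @classmethod
    def load(cls, path) -> "Recording":
        with h5py.File(path, "r") as f:
            return cls(
                frames=f["frames"][...],
                frame_times=f["frame_times"][...],
                activation_xy=f["activation_xy"][...],
                activation_times=f["activation_times"][...],
                activation_counts=f["activation_counts"][...],
                dx=float(f.attrs["dx_cm"]),
                dt=float(f.attrs["dt_ms"]),
                model_name=str(f.attrs.get("model", "")),
                meta=json.loads(f.attrs.get("meta_json", "{}")),
            )

    def activation_csv(self, path) -> Path:
        """Write the activation log as CSV columns x, y, t_act_ms."""
        import pandas as pd

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame({
            "x": self.activation_xy[:, 0],
            "y": self.activation_xy[:, 1],
            "t_act_ms": self.activation_times,
        })
        df.to_csv(path, index=False)
        return path

    def export_frames_png(self, directory, stride: int = 1,
                          vmin: float = -90.0, vmax: float = 30.0) -> list:
        """Optional PNG export of voltage frames (one file per frame)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for k in range(0, self.frames.shape[0], stride):
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.imshow(self.frames[k], origin="lower", vmin=vmin, vmax=vmax,
                      cmap="turbo")
            ax.set_title(f"t = {self.frame_times[k]:.0f} ms")
            ax.set_xticks([]), ax.set_yticks([])
            out = directory / f"frame_{k:05d}.png"
            fig.savefig(out, dpi=100)
            plt.close(fig)
            written.append(out)
        return written
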