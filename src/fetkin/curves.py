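"""Core domain types for dynamic PET kinetic analysis.

Time-activity data are stored per acquisition frame.  Frame schedules are
kept in seconds (the natural unit of acquisition metadata); all kinetic rate
constants are in min^-1 and conversion happens once at the model boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "InputFunction",
    "TissueCurve",
    "KineticParams",
    "MODEL_N_PARAMS",
    "clinical_schedule",
    "read_curve_csv",
    "write_curve_csv",
]

#: number of free parameters per model (K1,k2 | +VB | +k3,k4)
MODEL_N_PARAMS = {"s1TCM": 2, "1TCM": 3, "2TCM": 5}


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, non-overlapping acquisition frames in seconds."""

    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=float)
        ends = np.asarray(self.ends, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if starts.ndim != 1 or starts.shape != ends.shape or starts.size == 0:
            raise ValueError("starts/ends must be equal-length 1-D arrays")
        if starts[0] < 0:
            raise ValueError("first frame must start at t >= 0")
        if not np.all(ends > starts):
            raise ValueError("each frame must end after it starts")
        if starts.size > 1 and not np.all(starts[1:] >= ends[:-1] - 1e-9):
            raise ValueError("frames must be non-overlapping and increasing")

    @property
    def n(self) -> int:
        return self.starts.size

    @property
    def durations_s(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints_s(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    # minute-based views used at the model boundary
    @property
    def starts_min(self) -> np.ndarray:
        return self.starts / 60.0

    @property
    def ends_min(self) -> np.ndarray:
        return self.ends / 60.0

    @property
    def midpoints_min(self) -> np.ndarray:
        return self.midpoints_s / 60.0

    @property
    def total_end_s(self) -> float:
        return float(self.ends[-1])

    def to_json(self) -> str:
        return json.dumps(
            {"frame_start_s": self.starts.tolist(), "frame_end_s": self.ends.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "FrameSchedule":
        d = json.loads(text)
        return cls(np.asarray(d["frame_start_s"]), np.asarray(d["frame_end_s"]))


def clinical_schedule() -> FrameSchedule:
    """The 40-min dynamic acquisition: 6 x 20 s, 8 x 60 s, 6 x 300 s (n = 20 frames)."""
    durations = np.concatenate([np.full(6, 20.0), np.full(8, 60.0), np.full(6, 300.0)])
    ends = np.cumsum(durations)
    starts = ends - durations
    return FrameSchedule(starts, ends)


@dataclass(frozen=True)
class InputFunction:
    """Arterial input function C_a: per-frame tracer concentration in blood.

    ``state`` records whether the curve is whole-blood or plasma; kinetic
    models expect the plasma curve.
    """

    schedule: FrameSchedule
    values: np.ndarray
    state: str = "plasma"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.schedule.n,):
            raise ValueError("values length must match schedule")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("input function values must be finite and >= 0")
        if values.max() <= 0:
            raise ValueError("input function peak must be positive")
        if self.state not in ("whole_blood", "plasma"):
            raise ValueError("state must be 'whole_blood' or 'plasma'")

    @property
    def peak(self) -> float:
        return float(self.values.max())

    def to_plasma(self, plasma_factor: float = 0.10) -> "InputFunction":
        """Whole-blood -> plasma conversion by a fixed fractional factor."""
        if self.state == "plasma":
            return self
        return replace(self, values=self.values * (1.0 + plasma_factor), state="plasma")


@dataclass(frozen=True)
class TissueCurve:
    """Measured or simulated total tissue activity C_T per frame."""

    schedule: FrameSchedule
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.schedule.n,):
            raise ValueError("values length must match schedule")
        if not np.all(np.isfinite(values)):
            raise ValueError("tissue values must be finite")


@dataclass(frozen=True)
class KineticParams:
    """Transfer constants of a compartment model.

    Rates are in min^-1 and constrained to [0, 1] (the fitting search box);
    VB is the fractional blood volume (dimensionless; reported clinically as
    ml/100 ml, i.e. x100).  The simplified one-tissue model fixes VB = 0.
    """

    model: str
    K1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    VB: float = 0.0

    def __post_init__(self):
        if self.model not in MODEL_N_PARAMS:
            raise ValueError(f"unknown model {self.model!r}")
        for name in ("K1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside the [0, 1] min^-1 constraint")
        if not (0.0 <= self.VB < 1.0):
            raise ValueError(f"VB = {self.VB} outside [0, 1)")
        if self.model == "s1TCM" and self.VB != 0.0:
            raise ValueError("s1TCM assumes VB = 0")
        if self.model != "2TCM" and (self.k3 != 0.0 or self.k4 != 0.0):
            raise ValueError("k3/k4 are 2TCM parameters")

    @property
    def free_names(self) -> tuple:
        return {
            "s1TCM": ("K1", "k2"),
            "1TCM": ("K1", "k2", "VB"),
            "2TCM": ("K1", "k2", "k3", "k4", "VB"),
        }[self.model]

    @property
    def n_params(self) -> int:
        return MODEL_N_PARAMS[self.model]

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self.free_names], dtype=float)

    @classmethod
    def from_array(cls, model: str, x: np.ndarray) -> "KineticParams":
        names = {
            "s1TCM": ("K1", "k2"),
            "1TCM": ("K1", "k2", "VB"),
            "2TCM": ("K1", "k2", "k3", "k4", "VB"),
        }[model]
        return cls(model=model, **dict(zip(names, np.asarray(x, dtype=float))))


# ---------------------------------------------------------------------------
# curve exchange format: CSV (frame_start_s, frame_end_s, value) + JSON sidecar

def write_curve_csv(path, curve, units: str = "kBq/ml") -> None:
    """Write a TAC/AIF to CSV with a JSON sidecar for units and blood state."""
    path = Path(path)
    sched = curve.schedule
    pd.DataFrame(
        {
            "frame_start_s": sched.starts,
            "frame_end_s": sched.ends,
            "value": curve.values,
        }
    ).to_csv(path, index=False)
    meta = {"units": units}
    if isinstance(curve, InputFunction):
        meta["state"] = curve.state
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_curve_csv(path, kind: str = "tissue"):
    """Read a curve CSV; ``kind`` is 'tissue' or 'input'."""
    path = Path(path)
    df = pd.read_csv(path)
    sched = FrameSchedule(df["frame_start_s"].to_numpy(), df["frame_end_s"].to_numpy())
    values = df["value"].to_numpy()
    if kind == "input":
        state = "plasma"
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            state = json.loads(sidecar.read_text()).get("state", "plasma")
        return InputFunction(sched, values, state=state)
    return TissueCurve(sched, values)
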