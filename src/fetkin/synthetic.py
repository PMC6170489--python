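"""Synthetic study data: bolus AIFs, noisy tissue curves, the simulation
parameter grid, and small dynamic phantoms.

No measured arterial curves are distributed with clinical FET studies, so
the arterial input is emulated by a gamma-variate bolus with a slow washout
tail — the standard parametric family for first-pass tracer boluses.  Two
variants reproduce the two sampling situations seen in image-derived AIFs:

* type I  — the bolus arrives after the first frame, so the first frame is
  exactly zero;
* type II — the bolus is already under way when acquisition starts, so the
  first frame contains substantial activity.

Acquisition noise is additive i.i.d. Gaussian with SD sigma = AIF_peak/SNR
(SNR = 100 by default, matching patient data quality); noisy frames may go
negative and are kept that way unless clipping is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import FrameSchedule, InputFunction, KineticParams, TissueCurve, clinical_schedule
from .models import TACModel, frame_average

__all__ = [
    "NoiseModel",
    "AIFShape",
    "SimulationSpec",
    "make_aif",
    "simulate_tac",
    "table3_combinations",
    "simulation_grid",
    "Phantom",
    "make_phantom",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian acquisition noise calibrated to the AIF peak.

    ``snr`` = peak of the AIF divided by the noise SD, so
    ``sigma = aif_peak / snr``.
    """

    snr: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    def sigma(self, aif_peak: float) -> float:
        return aif_peak / self.snr


@dataclass(frozen=True)
class AIFShape:
    """Gamma-variate bolus + washout tail, in minutes.

    Defaults put the bolus peak inside the 20-s frames and leave a tail of
    roughly 10-20% of peak at 40 min.
    """

    alpha: float = 2.0            # gamma-variate sharpness
    beta_min: float = 0.12        # gamma-variate time scale (peak at alpha*beta after onset)
    tail_fraction: float = 0.18   # recirculation plateau relative to bolus peak
    tail_rise_min: float = 0.5
    tail_decay_per_min: float = 0.01

    def __post_init__(self):
        for name in ("alpha", "beta_min", "tail_fraction", "tail_rise_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tail_decay_per_min < 0:
            raise ValueError("tail_decay_per_min must be >= 0")

    def evaluate(self, t_min: np.ndarray, onset_min: float) -> np.ndarray:
        """Continuous curve, unit bolus peak, zero before onset."""
        u = np.asarray(t_min, dtype=float) - onset_min
        out = np.zeros_like(u)
        pos = u > 0
        up = u[pos]
        bolus = (up / (self.alpha * self.beta_min)) ** self.alpha * np.exp(
            self.alpha - up / self.beta_min
        )
        tail = (
            self.tail_fraction
            * (1.0 - np.exp(-up / self.tail_rise_min))
            * np.exp(-self.tail_decay_per_min * up)
        )
        out[pos] = bolus + tail
        return out


#: bolus onset in seconds for the two AIF variants
AIF_ONSETS_S = {"I": 25.0, "II": -3.0}


def make_aif(aif_type: str = "I", peak: float = 100.0,
             schedule: FrameSchedule | None = None,
             shape: AIFShape | None = None,
             onset_s: float | None = None,
             state: str = "plasma") -> InputFunction:
    """Frame-averaged synthetic AIF of type I (zero first frame) or II.

    The curve is normalized so that its maximum *frame* value equals
    ``peak`` exactly.
    """
    if aif_type not in AIF_ONSETS_S:
        raise ValueError("aif_type must be 'I' or 'II'")
    if peak <= 0:
        raise ValueError("peak must be positive")
    schedule = schedule or clinical_schedule()
    shape = shape or AIFShape()
    onset = (AIF_ONSETS_S[aif_type] if onset_s is None else onset_s) / 60.0
    if aif_type == "I" and onset * 60.0 < schedule.ends[0]:
        raise ValueError("type I requires bolus onset at or after the first frame end")
    vals = frame_average(lambda t: shape.evaluate(t, onset), schedule, n_nodes=64)
    vals = np.clip(vals, 0.0, None) * (peak / vals.max())
    return InputFunction(schedule, vals, state=state)


def simulate_tac(params: KineticParams, input_fn: InputFunction,
                 schedule: FrameSchedule | None = None,
                 noise: NoiseModel | None = None,
                 rng=None, clip_negative: bool = False) -> TissueCurve:
    """Model tissue curve plus optional Gaussian acquisition noise.

    ``rng`` may be a seed or Generator; by default ``noise.seed`` is used.
    With ``noise=None`` the exact solver output is returned.
    """
    schedule = schedule or input_fn.schedule
    ctx = TACModel(input_fn, schedule)
    y = ctx.curve(params)
    if noise is not None:
        if rng is None:
            rng = noise.seed
        rng = np.random.default_rng(rng)
        y = y + rng.normal(0.0, noise.sigma(input_fn.peak), size=y.size)
        if clip_negative:
            y = np.clip(y, 0.0, None)
    return TissueCurve(schedule, y)


#: simulation grid: (K1, k2, k3, k4) in 1e-2 min^-1, VB in ml/100 ml
_GRID_RAW = [
    (10, 20, 2.5, 5, 5),
    (10, 20, 7.5, 5, 5),
    (10, 60, 12.5, 5, 5),
    (10, 45, 7.5, 5, 5),
    (10, 20, 12.5, 5, 5),
    (20, 20, 2.5, 5, 5),
    (20, 20, 7.5, 10, 5),
    (20, 60, 12.5, 5, 5),
    (40, 45, 2.5, 20, 5),
    (40, 60, 7.5, 5, 5),
]


def table3_combinations() -> list[KineticParams]:
    """The ten 2TCM parameter combinations of the simulation grid,
    converted to internal units (min^-1; VB as a fraction)."""
    return [
        KineticParams("2TCM", K1=k1 / 100, k2=k2 / 100, k3=k3 / 100,
                      k4=k4 / 100, VB=vb / 100)
        for (k1, k2, k3, k4, vb) in _GRID_RAW
    ]


simulation_grid = table3_combinations  # descriptive alias


@dataclass
class SimulationSpec:
    """Full specification of the Monte-Carlo robustness experiment."""

    combinations: list = field(default_factory=table3_combinations)
    aif_types: tuple = ("I", "II")
    n_replicates: int = 1000
    schedule: FrameSchedule = field(default_factory=clinical_schedule)
    noise: NoiseModel = field(default_factory=NoiseModel)
    aif_peak: float = 100.0
    aif_shape: AIFShape = field(default_factory=AIFShape)

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.combinations:
            raise ValueError("combinations must be non-empty")


# ---------------------------------------------------------------------------
# dynamic phantom


@dataclass
class Phantom:
    dynamic: np.ndarray          # (x, y, z, n_frames)
    masks: dict                  # region name -> bool array
    schedule: FrameSchedule
    input_fn: InputFunction
    truth: dict                  # region name -> KineticParams


def make_phantom(shape=(12, 12, 4),
                 lesion_params: KineticParams | None = None,
                 background_params: KineticParams | None = None,
                 input_fn: InputFunction | None = None,
                 schedule: FrameSchedule | None = None,
                 noise: NoiseModel | None = None,
                 lesion_center=(6, 6, 2), lesion_radius: float = 3.0,
                 artery_voxels=((0, 0, 0), (0, 0, 1), (0, 0, 2)),
                 rng=None) -> Phantom:
    """Small dynamic phantom: a hot lesion in background tissue plus a few
    artery voxels carrying the AIF, with ground-truth masks."""
    if max(shape) > 32:
        raise ValueError("phantom limited to 32 voxels per axis")
    schedule = schedule or clinical_schedule()
    input_fn = input_fn or make_aif("I", peak=100.0, schedule=schedule)
    lesion_params = lesion_params or KineticParams(
        "2TCM", K1=0.20, k2=0.20, k3=0.075, k4=0.05, VB=0.05)
    background_params = background_params or KineticParams(
        "2TCM", K1=0.05, k2=0.25, k3=0.01, k4=0.05, VB=0.03)

    idx = np.indices(shape)
    center = np.asarray(lesion_center, dtype=float)
    dist2 = sum((idx[d] - center[d]) ** 2 for d in range(3))
    lesion = dist2 <= lesion_radius**2
    if not lesion.any() or np.any((center < 0) | (center >= np.array(shape))):
        raise ValueError("lesion must lie inside the phantom")
    artery = np.zeros(shape, dtype=bool)
    for v in artery_voxels:
        artery[tuple(v)] = True
    if (artery & lesion).any():
        raise ValueError("overlapping region labels: artery inside lesion")
    background = ~(lesion | artery)

    ctx = TACModel(input_fn, schedule)
    curves = {
        "lesion": ctx.curve(lesion_params),
        "background": ctx.curve(background_params),
    }
    dyn = np.empty(shape + (schedule.n,))
    dyn[background] = curves["background"]
    dyn[lesion] = curves["lesion"]
    dyn[artery] = input_fn.values
    if noise is not None:
        rng = np.random.default_rng(noise.seed if rng is None else rng)
        dyn = dyn + rng.normal(0.0, noise.sigma(input_fn.peak), size=dyn.shape)
    return Phantom(
        dynamic=dyn,
        masks={"lesion": lesion, "background": background, "artery": artery},
        schedule=schedule,
        input_fn=input_fn,
        truth={"lesion": lesion_params, "background": background_params},
    )
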