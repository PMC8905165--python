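"""Core parameter and ground-truth containers for the motility simulator.

Units are fixed package-wide: positions and run lengths in nm, times in s,
microtubule lengths in µm, landing rates in events·µm⁻¹·min⁻¹, velocities
in nm/s. Image coordinates are 0-based (row, col) pixels, row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "VelocityComponent",
    "MotorModel",
    "OpticsModel",
    "MTSegment",
    "MicrotubuleField",
    "Landing",
    "TrajectoryTruth",
    "Movie",
]


@dataclass(frozen=True)
class VelocityComponent:
    """One Gaussian component of the per-motor velocity mixture."""

    weight: float
    mean: float  # nm/s
    sd: float  # nm/s

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"component weight must be in [0,1], got {self.weight}")
        if self.sd < 0:
            raise ValueError(f"component sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class MotorModel:
    """Generative parameters of one motor construct.

    The model mirrors the quantities the analysis layer estimates: a
    homogeneous Poisson landing process along each microtubule, a Gaussian
    mixture of per-motor speeds, exponential run lengths (per-distance
    detachment) or residencies (per-time detachment), an optional two-state
    pause process, exponential dwell for non-processive (static) binders, and
    independent single-exponential photobleaching of each fluorophore.
    """

    name: str
    landing_rate_total: float  # events per µm per min
    processive_fraction: float
    velocity_components: tuple[VelocityComponent, ...]
    run_length_mean: float  # nm, exponential scale
    residency_mean: float  # s, exponential scale
    pause_entry_rate: float = 0.0  # per s, while moving
    pause_exit_rate: float = 0.0  # per s, while paused
    static_dwell_mean: float = 1.0  # s
    detach_mode: Literal["per_distance", "per_time"] = "per_distance"
    n_fluorophores: int = 4
    bleach_rate: float = 0.0  # per s per fluorophore

    def __post_init__(self) -> None:
        comps = tuple(
            c if isinstance(c, VelocityComponent) else VelocityComponent(*c)
            for c in self.velocity_components
        )
        object.__setattr__(self, "velocity_components", comps)
        if not comps:
            raise ValueError("velocity_components must be non-empty")
        wsum = sum(c.weight for c in comps)
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {wsum}")
        if not (0.0 <= self.processive_fraction <= 1.0):
            raise ValueError(
                f"processive_fraction must be in [0,1], got {self.processive_fraction}"
            )
        for attr in (
            "landing_rate_total",
            "run_length_mean",
            "residency_mean",
            "pause_entry_rate",
            "pause_exit_rate",
            "static_dwell_mean",
            "bleach_rate",
        ):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.n_fluorophores not in range(1, 9):
            raise ValueError(
                f"n_fluorophores must be in 1..8, got {self.n_fluorophores}"
            )
        if self.detach_mode not in ("per_distance", "per_time"):
            raise ValueError(f"unknown detach_mode {self.detach_mode!r}")


@dataclass(frozen=True)
class OpticsModel:
    """Acquisition parameters of the simulated TIRF microscope."""

    pixel_size: float = 160.0  # nm per pixel
    frame_interval: float = 0.12  # s
    exposure: float = 0.1  # s
    psf_sigma: float = 120.0  # nm
    photons_per_fluorophore_per_frame: float = 200.0
    background_mean: float = 100.0  # counts
    read_noise_sd: float = 2.0  # counts
    duration: float = 120.0  # s
    image_shape: tuple[int, int] = (128, 128)  # (rows, cols)

    def __post_init__(self) -> None:
        if not (self.frame_interval >= self.exposure > 0):
            raise ValueError("require frame_interval >= exposure > 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.duration / self.frame_interval < 5:
            raise ValueError("duration must cover at least 5 frames")
        object.__setattr__(self, "image_shape", tuple(int(s) for s in self.image_shape))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class MTSegment:
    """One immobilized microtubule, a straight segment in the image plane.

    ``endpoint_a`` is the minus end when ``polarity`` is +1, the plus end
    when −1; ground-truth positions are measured in nm from the minus end.
    """

    endpoint_a: tuple[float, float]  # (row, col) px
    endpoint_b: tuple[float, float]
    length_um: float
    polarity: int = 1

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("microtubule length must be > 0")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")

    @property
    def length_nm(self) -> float:
        return self.length_um * 1000.0

    def minus_end(self) -> tuple[float, float]:
        return self.endpoint_a if self.polarity == 1 else self.endpoint_b

    def plus_end(self) -> tuple[float, float]:
        return self.endpoint_b if self.polarity == 1 else self.endpoint_a

    def point_at(self, position_nm: float) -> tuple[float, float]:
        """Image coordinates (row, col) of a position measured from the minus end."""
        f = position_nm / self.length_nm
        (r0, c0), (r1, c1) = self.minus_end(), self.plus_end()
        return (r0 + f * (r1 - r0), c0 + f * (c1 - c0))


@dataclass(frozen=True)
class MicrotubuleField:
    """A set of immobilized microtubule segments inside one field of view."""

    segments: tuple[MTSegment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def lengths_um(self) -> np.ndarray:
        return np.array([s.length_um for s in self.segments])

    def total_length_um(self) -> float:
        return float(self.lengths_um.sum())


@dataclass(frozen=True)
class Landing:
    """One motor landing event drawn from the Poisson landing process."""

    mt_id: int
    t_land: float  # s
    position_nm: float  # along the microtubule, from the minus end
    cls: Literal["processive", "static"]


@dataclass
class TrajectoryTruth:
    """Ground truth for one motor: frame-grid path, states and lifetimes.

    ``frames_t`` / ``positions_nm`` / ``states`` sample the continuous
    trajectory on the acquisition frame grid; ``t_detach``, ``run_length_true``
    and ``residency_true`` are the exact (off-grid) values the estimators
    should recover on average.
    """

    motor_id: int
    mt_id: int
    t_land: float
    cls: Literal["processive", "static"]
    frames_t: np.ndarray  # s, frame-grid times with t_land <= t <= t_detach
    positions_nm: np.ndarray
    states: np.ndarray  # 'moving' | 'paused'
    t_detach: float
    bleach_times: np.ndarray  # absolute s, one per fluorophore
    velocity_draw: float  # nm/s, instantaneous moving-state speed

    def __post_init__(self) -> None:
        if self.t_detach <= self.t_land:
            raise ValueError("t_detach must exceed t_land")

    @property
    def residency_true(self) -> float:
        return self.t_detach - self.t_land

    @property
    def run_length_true(self) -> float:
        if self.cls == "static":
            return 0.0
        # exact net displacement: moving time x instantaneous speed
        return self._moving_distance

    _moving_distance: float = field(default=0.0, repr=False)

    def n_unbleached(self, t: float | np.ndarray) -> np.ndarray:
        """Number of fluorophores still fluorescent at absolute time(s) t."""
        t = np.asarray(t, dtype=float)
        return (self.bleach_times[None, :] > t[..., None]).sum(axis=-1)


@dataclass
class Movie:
    """A rendered time-lapse: data indexed (frame, row, col)."""

    data: np.ndarray
    optics: OpticsModel

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("movie data must be 3-D (T, Y, X)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def as_motor_model(obj: "MotorModel | dict") -> MotorModel:
    """Coerce a config mapping into a validated MotorModel."""
    if isinstance(obj, MotorModel):
        return obj
    d = dict(obj)
    comps = tuple(VelocityComponent(*c) for c in d.pop("velocity_components"))
    return MotorModel(velocity_components=comps, **d)


def as_optics_model(obj: "OpticsModel | dict") -> OpticsModel:
    if isinstance(obj, OpticsModel):
        return obj
    d = dict(obj)
    if "image_shape" in d:
        d["image_shape"] = tuple(d["image_shape"])
    return OpticsModel(**d)
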