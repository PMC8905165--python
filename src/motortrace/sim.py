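"""Generative simulator: microtubule fields, motor landing, stepping,
pausing, detachment, photobleaching and TIRF movie rendering.

The simulator produces data with exactly the statistical structure the
analysis layer assumes — homogeneous Poisson landings along each
microtubule, Gaussian-mixture per-motor speeds, exponential run lengths or
residencies, two-state pausing, and independent exponential photobleaching
of 1–8 fluorophores — so every estimator can be validated by parameter
recovery without external data.

All sampling is reproducible bit-for-bit given (parameters, seed); child
random streams are derived deterministically per motor with
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .models import (
    Landing,
    MicrotubuleField,
    MotorModel,
    Movie,
    MTSegment,
    OpticsModel,
    TrajectoryTruth,
)

__all__ = [
    "sample_field",
    "sample_landings",
    "sample_trajectory",
    "sample_trajectories",
    "render_movie",
    "sample_bleach_trace",
    "sample_velocities",
    "sample_run_lengths",
    "sample_residencies",
    "BleachTraceTruth",
]


class PlacementError(RuntimeError):
    """Raised when a microtubule segment cannot be placed in the image."""


class RenderError(RuntimeError):
    """Raised when a trajectory falls outside the image during rendering."""


# ---------------------------------------------------------------------------
# distribution samplers (the generative marginals the estimators recover)


def _mixture_rvs(model: MotorModel, n: int, rng: np.random.Generator) -> np.ndarray:
    comps = model.velocity_components
    weights = np.array([c.weight for c in comps])
    idx = rng.choice(len(comps), size=n, p=weights)
    means = np.array([c.mean for c in comps])[idx]
    sds = np.array([c.sd for c in comps])[idx]
    return rng.normal(means, sds)


def sample_velocities(
    model: MotorModel, n: int, seed: int | np.random.Generator, truncate: bool = False
) -> np.ndarray:
    """Draw n per-motor speeds (nm/s) from the model's Gaussian mixture.

    With ``truncate=True`` non-positive draws are redrawn (used for
    trajectory simulation, where a processive speed must be positive); the
    default returns the raw mixture, matching the distribution the velocity
    histogram fit assumes.
    """
    rng = np.random.default_rng(seed)
    v = _mixture_rvs(model, n, rng)
    if truncate:
        while True:
            bad = v <= 0
            if not bad.any():
                break
            v[bad] = _mixture_rvs(model, int(bad.sum()), rng)
    return v


def sample_run_lengths(model: MotorModel, n: int, seed) -> np.ndarray:
    """Exponential run-length draws (nm) at the model's generative scale."""
    if model.run_length_mean <= 0:
        raise ValueError("run_length_mean must be > 0 to sample run lengths")
    return np.random.default_rng(seed).exponential(model.run_length_mean, n)


def sample_residencies(model: MotorModel, n: int, seed) -> np.ndarray:
    """Exponential residency draws (s) at the model's generative scale."""
    if model.residency_mean <= 0:
        raise ValueError("residency_mean must be > 0 to sample residencies")
    return np.random.default_rng(seed).exponential(model.residency_mean, n)


# ---------------------------------------------------------------------------
# field and landing sampling


def sample_field(
    n_mts: int,
    length_mean: float,
    length_sd: float,
    optics: OpticsModel,
    seed: int | np.random.Generator,
    margin_px: float = 2.0,
) -> MicrotubuleField:
    """Place n_mts straight microtubule segments in the field of view.

    Lengths (µm) are Gaussian truncated at >= 1 µm (degenerate at the mean
    when sd = 0); orientation and position are uniform; overlap is allowed,
    as on a real coverslip.
    """
    if n_mts < 1:
        raise ValueError("n_mts must be >= 1")
    rng = np.random.default_rng(seed)
    rows, cols = optics.image_shape
    segments = []
    for i in range(n_mts):
        if length_sd > 0:
            length = 0.0
            while length < 1.0:
                length = rng.normal(length_mean, length_sd)
        else:
            length = max(length_mean, 1.0)
        half_px = length * 1000.0 / optics.pixel_size / 2.0
        placed = False
        for _ in range(1000):
            theta = rng.uniform(0, np.pi)
            cr = rng.uniform(margin_px, rows - 1 - margin_px)
            cc = rng.uniform(margin_px, cols - 1 - margin_px)
            dr, dc = half_px * np.sin(theta), half_px * np.cos(theta)
            a = (cr - dr, cc - dc)
            b = (cr + dr, cc + dc)
            if all(
                margin_px <= p[0] <= rows - 1 - margin_px
                and margin_px <= p[1] <= cols - 1 - margin_px
                for p in (a, b)
            ):
                polarity = int(rng.choice([-1, 1]))
                segments.append(MTSegment(a, b, length, polarity))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"segment {i} (length {length:.1f} um) does not fit in a "
                f"{rows}x{cols} px image at {optics.pixel_size} nm/px"
            )
    return MicrotubuleField(tuple(segments))


def sample_landings(
    field: MicrotubuleField,
    model: MotorModel,
    duration: float,
    seed: int | np.random.Generator,
) -> list[Landing]:
    """Draw motor landing events as a homogeneous Poisson process per microtubule.

    The count on microtubule i is Poisson(rate x L_i x duration_min) with the
    rate in events·µm⁻¹·min⁻¹; landing times are uniform over the movie,
    positions uniform along the segment, and each event is independently
    processive with probability ``model.processive_fraction``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    duration_min = duration / 60.0
    landings: list[Landing] = []
    for mt_id, seg in enumerate(field.segments):
        lam = model.landing_rate_total * seg.length_um * duration_min
        count = rng.poisson(lam) if lam > 0 else 0
        for _ in range(count):
            t = rng.uniform(0.0, duration)
            pos = rng.uniform(0.0, seg.length_nm)
            cls = "processive" if rng.random() < model.processive_fraction else "static"
            landings.append(Landing(mt_id, t, pos, cls))
    landings.sort(key=lambda ev: ev.t_land)
    return landings


# ---------------------------------------------------------------------------
# trajectory simulation


def _simulate_state_path(
    model: MotorModel, rng: np.random.Generator, v: float
) -> tuple[list[tuple[float, float, str]], float, float]:
    """Event-driven two-state (moving/paused) path of one processive motor.

    Returns (breakpoints, total_duration, moving_distance): breakpoints are
    (t_rel, position_nm, state-entered) with t_rel measured from landing.
    In per_distance mode the motor detaches when its cumulative moving
    distance reaches an Exp(run_length_mean) draw; in per_time mode it
    detaches at an Exp(residency_mean) time after landing.
    """
    if model.detach_mode == "per_distance":
        if model.run_length_mean <= 0:
            raise ValueError(
                "degenerate model: per_distance detachment requires run_length_mean > 0"
            )
        run_target = rng.exponential(model.run_length_mean)
        t_end = np.inf
    else:
        run_target = np.inf
        t_end = rng.exponential(model.residency_mean)

    t, x, dist = 0.0, 0.0, 0.0
    state = "moving"
    points: list[tuple[float, float, str]] = [(0.0, 0.0, state)]
    while True:
        if state == "moving":
            hold = (
                rng.exponential(1.0 / model.pause_entry_rate)
                if model.pause_entry_rate > 0
                else np.inf
            )
            # detachment by distance happens mid-hold if the run target is hit
            t_to_target = (run_target - dist) / v if np.isfinite(run_target) else np.inf
            dt = min(hold, t_to_target, t_end - t)
            t += dt
            x += v * dt
            dist += v * dt
            if dt == t_to_target or t >= t_end:
                points.append((t, x, "detached"))
                return points, t, dist
            state = "paused"
        else:
            hold = (
                rng.exponential(1.0 / model.pause_exit_rate)
                if model.pause_exit_rate > 0
                else np.inf
            )
            dt = min(hold, t_end - t)
            t += dt
            if t >= t_end:
                points.append((t, x, "detached"))
                return points, t, dist
            state = "moving"
        points.append((t, x, state))


def sample_trajectory(
    model: MotorModel,
    landing: Landing,
    optics: OpticsModel,
    seed: int | np.random.Generator,
    motor_id: int = 0,
    mt_length_um: float | None = None,
) -> TrajectoryTruth:
    """Simulate one motor's ground-truth path from landing to detachment.

    Static motors dwell Exp(static_dwell_mean) at a fixed position.
    Processive motors draw one instantaneous speed from the velocity mixture
    and alternate moving/paused states with exponential holding times.
    Bleach times are i.i.d. Exp(bleach_rate) per fluorophore, clocked from
    landing. Positions are reported on the acquisition frame grid; when
    ``mt_length_um`` is given the trajectory is truncated at the plus end.
    """
    rng = np.random.default_rng(seed)
    if model.bleach_rate > 0:
        bleach = landing.t_land + rng.exponential(
            1.0 / model.bleach_rate, model.n_fluorophores
        )
    else:
        bleach = np.full(model.n_fluorophores, np.inf)

    if landing.cls == "static":
        dwell = rng.exponential(model.static_dwell_mean)
        t_detach = landing.t_land + max(dwell, 1e-9)
        grid = optics.frame_times
        sel = (grid >= landing.t_land) & (grid <= t_detach)
        ts = grid[sel]
        return TrajectoryTruth(
            motor_id=motor_id,
            mt_id=landing.mt_id,
            t_land=landing.t_land,
            cls="static",
            frames_t=ts,
            positions_nm=np.full(ts.size, landing.position_nm),
            states=np.full(ts.size, "paused", dtype=object),
            t_detach=t_detach,
            bleach_times=bleach,
            velocity_draw=0.0,
            _moving_distance=0.0,
        )

    v = float(sample_velocities(model, 1, rng, truncate=True)[0])
    points, total, moving_dist = _simulate_state_path(model, rng, v)
    t_detach = landing.t_land + max(total, 1e-9)

    # truncate at the plus end if the microtubule length is known
    max_disp = np.inf
    if mt_length_um is not None:
        max_disp = mt_length_um * 1000.0 - landing.position_nm
        if moving_dist > max_disp:
            # walk the breakpoints to the crossing time
            for (t0, x0, _s0), (t1, x1, _s1) in zip(points, points[1:]):
                if x1 >= max_disp:
                    frac = (max_disp - x0) / (x1 - x0) if x1 > x0 else 0.0
                    t_detach = landing.t_land + t0 + frac * (t1 - t0)
                    moving_dist = max_disp
                    break

    grid = optics.frame_times
    sel = (grid >= landing.t_land) & (grid <= t_detach)
    ts = grid[sel]
    rel = ts - landing.t_land
    bp_t = np.array([p[0] for p in points])
    bp_x = np.array([p[1] for p in points])
    pos_rel = np.interp(rel, bp_t, bp_x)
    pos = np.minimum(landing.position_nm + pos_rel, landing.position_nm + max_disp)
    # state at each frame: the state entered at the latest breakpoint <= t
    idx = np.clip(np.searchsorted(bp_t, rel, side="right") - 1, 0, len(points) - 1)
    states = np.array(
        [points[i][2] if points[i][2] != "detached" else "paused" for i in idx],
        dtype=object,
    )
    return TrajectoryTruth(
        motor_id=motor_id,
        mt_id=landing.mt_id,
        t_land=landing.t_land,
        cls="processive",
        frames_t=ts,
        positions_nm=pos,
        states=states,
        t_detach=t_detach,
        bleach_times=bleach,
        velocity_draw=v,
        _moving_distance=float(moving_dist),
    )


def sample_trajectories(
    model: MotorModel,
    landings: list[Landing],
    optics: OpticsModel,
    seed: int,
    field: MicrotubuleField | None = None,
) -> list[TrajectoryTruth]:
    """Simulate every landing with an independent child random stream."""
    children = np.random.SeedSequence(seed).spawn(len(landings))
    out = []
    for i, (landing, child) in enumerate(zip(landings, children)):
        length = field.segments[landing.mt_id].length_um if field is not None else None
        out.append(
            sample_trajectory(
                model,
                landing,
                optics,
                np.random.default_rng(child),
                motor_id=i,
                mt_length_um=length,
            )
        )
    return out


# ---------------------------------------------------------------------------
# rendering


def _gaussian_spot(
    shape: tuple[int, int], center: tuple[float, float], sigma_px: float
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Pixel-integrated unit-flux Gaussian on a +/-6 sigma window.

    The window kernel is renormalized to unit sum so that (away from image
    edges) photometry is exact: the spot contributes exactly its integrated
    intensity to the frame.
    """
    r0, c0 = center
    half = max(int(np.ceil(6 * sigma_px)), 2)
    rlo, rhi = int(np.floor(r0)) - half, int(np.floor(r0)) + half + 1
    clo, chi = int(np.floor(c0)) - half, int(np.floor(c0)) + half + 1
    rlo_c, rhi_c = max(rlo, 0), min(rhi, shape[0])
    clo_c, chi_c = max(clo, 0), min(chi, shape[1])
    rows = np.arange(rlo_c, rhi_c)
    cols = np.arange(clo_c, chi_c)
    s = sigma_px * np.sqrt(2.0)
    fr = 0.5 * (erf((rows + 0.5 - r0) / s) - erf((rows - 0.5 - r0) / s))
    fc = 0.5 * (erf((cols + 0.5 - c0) / s) - erf((cols - 0.5 - c0) / s))
    kern = np.outer(fr, fc)
    total = kern.sum()
    if total > 0.5:  # fully (or nearly) inside: renormalize for exact photometry
        kern = kern / total
    return kern, (slice(rlo_c, rhi_c), slice(clo_c, chi_c))


def render_movie(
    field: MicrotubuleField,
    trajectories: list[TrajectoryTruth],
    optics: OpticsModel,
    seed: int | np.random.Generator,
    noise: bool = True,
) -> Movie:
    """Render trajectories into a time-lapse movie.

    Each motor with >= 1 unbleached fluorophore contributes a 2-D Gaussian
    spot of integrated intensity photons_per_fluorophore_per_frame x
    (unbleached count). With ``noise=True`` pixel values are
    Poisson(signal + background) + Gaussian read noise, clipped at zero and
    quantized to 16-bit; with ``noise=False`` the noiseless float signal
    plus background is returned.
    """
    rng = np.random.default_rng(seed)
    shape = optics.image_shape
    sigma_px = optics.psf_sigma / optics.pixel_size
    times = optics.frame_times
    signal = np.zeros((times.size,) + shape, dtype=float)

    for traj in trajectories:
        if traj.frames_t.size == 0:
            continue
        seg = field.segments[traj.mt_id]
        frame_idx = np.rint(traj.frames_t / optics.frame_interval).astype(int)
        counts = traj.n_unbleached(traj.frames_t)
        for k, t, pos, n_fl in zip(frame_idx, traj.frames_t, traj.positions_nm, counts):
            if n_fl < 1 or k < 0 or k >= times.size:
                continue
            center = seg.point_at(pos)
            if not (
                -0.5 <= center[0] <= shape[0] - 0.5
                and -0.5 <= center[1] <= shape[1] - 0.5
            ):
                raise RenderError(
                    f"motor {traj.motor_id} at {center} outside {shape} image"
                )
            kern, sl = _gaussian_spot(shape, center, sigma_px)
            signal[k][sl] += optics.photons_per_fluorophore_per_frame * n_fl * kern

    if not noise:
        return Movie(signal + optics.background_mean, optics)
    data = rng.poisson(signal + optics.background_mean).astype(float)
    if optics.read_noise_sd > 0:
        data += rng.normal(0.0, optics.read_noise_sd, data.shape)
    data = np.clip(np.rint(data), 0, 2**16 - 1).astype(np.uint16)
    return Movie(data, optics)


# ---------------------------------------------------------------------------
# photobleaching traces


@dataclass
class BleachTraceTruth:
    """Ground truth for one surface-adsorbed motor's bleaching staircase."""

    intensity: np.ndarray  # counts per frame (noisy)
    noiseless: np.ndarray  # counts per frame before noise
    bleach_times: np.ndarray  # s, one per initially active fluorophore
    n_active_start: int  # fluorophores fluorescent at frame 0
    true_step_count: int  # downward steps visible within the trace
    frame_interval: float


def sample_bleach_trace(
    model: MotorModel,
    unit_intensity: float,
    noise_sd: float,
    n_frames: int,
    seed: int | np.random.Generator,
    frame_interval: float = 0.12,
    pre_bleached_prob: float = 0.0,
) -> BleachTraceTruth:
    """Simulate the intensity staircase of one adsorbed motor.

    Each of the model's fluorophores is independently dark from the start
    with probability ``pre_bleached_prob`` (bleached during handling or
    before acquisition); the rest bleach as i.i.d. Exp(bleach_rate). The
    noiseless trace is unit_intensity x (active count at frame time), and
    Gaussian noise of s.d. ``noise_sd`` is added.
    """
    if n_frames < 5:
        raise ValueError("n_frames must be >= 5")
    rng = np.random.default_rng(seed)
    active = rng.random(model.n_fluorophores) >= pre_bleached_prob
    n_active = int(active.sum())
    if model.bleach_rate > 0:
        btimes = rng.exponential(1.0 / model.bleach_rate, n_active)
    else:
        btimes = np.full(n_active, np.inf)
    t = np.arange(n_frames) * frame_interval
    counts = (btimes[None, :] > t[:, None]).sum(axis=1)
    noiseless = unit_intensity * counts.astype(float)
    noisy = noiseless + (rng.normal(0.0, noise_sd, n_frames) if noise_sd > 0 else 0.0)
    visible_steps = int(np.sum((btimes >= 0) & (btimes < t[-1])))
    return BleachTraceTruth(
        intensity=noisy,
        noiseless=noiseless,
        bleach_times=np.sort(btimes),
        n_active_start=n_active,
        true_step_count=visible_steps,
        frame_interval=frame_interval,
    )
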