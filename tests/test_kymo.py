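"""Kymograph building, event extraction, measurement definitions and the
five-frame filter."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from motortrace import kymo, sim
from motortrace.kymo import (
    Kymograph,
    RunEvent,
    build_kymograph,
    classify_motile,
    events_from_truth,
    extract_events,
    filter_events,
    gliding_velocities,
)
from motortrace.models import Landing, MicrotubuleField, MTSegment


def _truth_frame(motor_id, times, positions, mt_id=0, dt=0.12):
    return pd.DataFrame({
        "motor_id": motor_id,
        "mt_id": mt_id,
        "frame": np.round(np.asarray(times) / dt).astype(int),
        "t": times,
        "position_nm": positions,
    })


def _make_event(n_frames, positions, dt=0.12):
    pos = np.asarray(positions, float)
    ev = RunEvent(
        motor_id=0, mt_id=0, t_start=0.0, t_end=(n_frames - 1) * dt,
        n_frames=n_frames, x_start=pos[0], x_end=pos[-1],
        path_positions=pos, frame_interval=dt,
    )
    return ev


# ---------------------------------------------------------------------------
# kymograph geometry


def test_static_spot_gives_constant_bright_row(cfg754, single_mt_field, small_optics):
    model = dataclasses.replace(cfg754.motor, bleach_rate=0.0, static_dwell_mean=1e6)
    land = Landing(0, 0.0, 3000.0, "static")
    tr = sim.sample_trajectory(model, land, small_optics, seed=1)
    movie = sim.render_movie(single_mt_field, [tr], small_optics, seed=2, noise=False)
    k = build_kymograph(movie, single_mt_field.segments[0])
    rows = k.intensity.argmax(axis=0)
    assert np.all(rows == rows[0])
    assert abs(rows[0] * k.pixel_size - 3000.0) <= k.pixel_size


def test_moving_spot_slope_matches_velocity(cfg754, single_mt_field, small_optics):
    """A constant-speed motor draws a line of slope v/(px per frame)."""
    model = dataclasses.replace(
        cfg754.motor, bleach_rate=0.0, velocity_components=((1.0, 800.0, 0.0),),
        run_length_mean=1e9,
    )
    land = Landing(0, 0.0, 500.0, "processive")
    tr = sim.sample_trajectory(model, land, small_optics, seed=3,
                               mt_length_um=single_mt_field.segments[0].length_um)
    movie = sim.render_movie(single_mt_field, [tr], small_optics, seed=4, noise=False)
    k = build_kymograph(movie, single_mt_field.segments[0])
    present = np.arange(tr.frames_t.size)  # columns with the motor on screen
    rows = k.intensity.argmax(axis=0).astype(float)[present]
    slope_px = np.polyfit(present, rows, 1)[0]
    expected = 800.0 * k.frame_interval / k.pixel_size
    assert slope_px == pytest.approx(expected, rel=0.05)


def test_zero_length_segment_raises(cfg754, single_mt_field, small_optics):
    movie = sim.render_movie(single_mt_field, [], small_optics, seed=1, noise=False)
    bad = MTSegment((10.0, 10.0), (10.0, 10.0 + 1e-12), 1.0, 1)
    with pytest.raises(ValueError, match="zero-length"):
        build_kymograph(movie, bad)


# ---------------------------------------------------------------------------
# measurement definitions (truth mode)


def test_truth_event_velocity_is_exact_for_uniform_motion():
    times = np.arange(0, 10.01, 0.12)
    df = _truth_frame(0, times, 100.0 * times)
    (ev,) = events_from_truth(df)
    assert ev.velocity == pytest.approx(100.0)
    assert ev.run_length == pytest.approx(100.0 * (times[-1] - times[0]))


def test_truth_event_velocity_averages_over_pauses():
    """5 s at 200 nm/s then 5 s paused: whole-run velocity is 100 nm/s."""
    dt = 0.12
    times = np.arange(0, 10.0 + dt / 2, dt)
    pos = np.where(times <= 5.0, 200.0 * times, 1000.0)
    df = _truth_frame(0, times, pos)
    (ev,) = events_from_truth(df)
    # endpoints define it: 1000 nm over ~10 s
    assert ev.velocity == pytest.approx(1000.0 / (times[-1] - times[0]), rel=1e-9)
    assert ev.velocity == pytest.approx(100.0, rel=0.02)


def test_truth_events_conserve_motor_count(cfg754, small_optics, tmp_path):
    field = sim.sample_field(4, 8.0, 1.0, small_optics, seed=5)
    landings = sim.sample_landings(field, cfg754.motor, 120.0, seed=6)
    trajectories = sim.sample_trajectories(cfg754.motor, landings, small_optics, 7, field=field)
    from motortrace import io as mio
    frames_path, _ = mio.write_truth(str(tmp_path / "truth_test"), trajectories)
    truth = mio.read_truth(frames_path)
    events = events_from_truth(truth)
    n_with_frames = sum(t.frames_t.size > 0 for t in trajectories)
    assert len(events) == n_with_frames


def test_truth_table_schema_mismatch_raises():
    with pytest.raises(ValueError, match="missing columns"):
        events_from_truth(pd.DataFrame({"motor_id": [0], "t": [0.0]}))


# ---------------------------------------------------------------------------
# filtering and classification


@pytest.mark.parametrize("n_frames,kept", [(4, False), (5, True), (6, True)])
def test_five_frame_filter_boundary(n_frames, kept):
    ev = _make_event(n_frames, np.linspace(0, 500, n_frames))
    assert (len(filter_events([ev])) == 1) is kept


def test_filter_removal_fraction_matches_exponential_cdf(cfg483, small_optics):
    """At residency scale 5.41 s and 0.12 s frames, roughly a fraction
    1 - exp(-0.6/5.41) of events span fewer than five frames."""
    model = dataclasses.replace(cfg483.motor, detach_mode="per_time",
                                processive_fraction=1.0)
    optics = dataclasses.replace(small_optics, duration=1e4)
    rng = np.random.default_rng(11)
    n = 3000
    short = 0
    children = np.random.SeedSequence(12).spawn(n)
    for c in children:
        land = Landing(0, rng.uniform(0, 9000.0), 0.0, "processive")
        tr = sim.sample_trajectory(model, land, optics, np.random.default_rng(c))
        if tr.frames_t.size < 5:
            short += 1
    expected = 1 - np.exp(-0.6 / 5.41)
    assert short / n == pytest.approx(expected, abs=0.03)


def test_classify_static_not_motile():
    ev = _make_event(10, np.full(10, 1000.0))
    assert not classify_motile(ev)


def test_classify_long_unidirectional_run_motile():
    ev = _make_event(10, np.linspace(0, 700, 10))
    assert classify_motile(ev)


def test_classify_rejects_direction_inconsistent_tracks():
    # net displacement 400 nm but half the steps go backwards
    pos = np.array([0, 200, 50, 250, 100, 300, 150, 350, 200, 400], float)
    ev = _make_event(10, pos)
    assert not classify_motile(ev)


def test_event_velocity_residency_product_invariant(cfg754, small_optics, tmp_path):
    """velocity x residency == run_length for every constructed event."""
    field = sim.sample_field(3, 8.0, 1.0, small_optics, seed=13)
    landings = sim.sample_landings(field, cfg754.motor, 120.0, seed=14)
    trajectories = sim.sample_trajectories(cfg754.motor, landings, small_optics, 15, field=field)
    from motortrace import io as mio
    frames_path, _ = mio.write_truth(str(tmp_path / "truth_inv"), trajectories)
    events = events_from_truth(mio.read_truth(frames_path))
    assert events, "fixture produced no events"
    for ev in events:
        assert ev.velocity * ev.residency == pytest.approx(ev.run_length, rel=1e-9)


# ---------------------------------------------------------------------------
# extraction from rendered kymographs


def test_blank_kymograph_yields_no_events(small_optics):
    movie = sim.render_movie(MicrotubuleField(()), [], small_optics, seed=16)
    seg = MTSegment((32.0, 5.0), (32.0, 55.0), 8.0, 1)
    k = build_kymograph(movie, seg)
    assert extract_events(k) == [] or all(e.n_frames < 5 for e in extract_events(k))


def test_crossing_tracks_stay_separate():
    """Two constructed tracks crossing faster than max_jump remain two events."""
    n_pos, n_frames = 60, 40
    img = np.zeros((n_pos, n_frames))
    rows_a = np.clip(5 + 1.2 * np.arange(n_frames), 0, n_pos - 1).astype(int)
    rows_b = np.clip(52 - 1.2 * np.arange(n_frames), 0, n_pos - 1).astype(int)
    for k in range(n_frames):
        img[rows_a[k], k] += 100.0
        img[rows_b[k], k] += 100.0
    kg = Kymograph(img, 160.0, 0.12, n_pos * 0.16)
    events = [e for e in extract_events(kg, max_jump=4.0) if e.n_frames >= 5]
    assert len(events) == 2
    slopes = sorted(np.sign(e.x_end - e.x_start) for e in events)
    assert slopes == [-1.0, 1.0]


def test_dense_fixture_event_recovery(cfg754, small_optics):
    """On a rendered movie at the configured landing density, >= 90% of
    filterable truth events are recovered with velocity within 10%."""
    model = dataclasses.replace(cfg754.motor, bleach_rate=0.0, processive_fraction=1.0)
    optics = dataclasses.replace(
        small_optics, duration=300.0, image_shape=(64, 64),
        photons_per_fluorophore_per_frame=400.0,
    )
    seg = MTSegment((32.0, 4.0), (32.0, 60.0), 56 * 160 / 1000, 1)
    field = MicrotubuleField((seg,))
    landings = sim.sample_landings(field, model, optics.duration, seed=17)
    trajectories = sim.sample_trajectories(model, landings, optics, 18, field=field)
    movie = sim.render_movie(field, trajectories, optics, 19)
    k = build_kymograph(movie, seg)
    found = [e for e in extract_events(k) if e.n_frames >= 5]

    truth_events = [t for t in trajectories if t.frames_t.size >= 5]
    matched = 0
    for tr in truth_events:
        v_true = np.ptp(tr.positions_nm) / max(np.ptp(tr.frames_t), optics.frame_interval)
        # best candidate: overlapping event with smallest median path distance
        best, best_d = None, np.inf
        for ev in found:
            lo = max(ev.t_start, tr.frames_t[0])
            hi = min(ev.t_end, tr.frames_t[-1])
            if hi - lo < 0.5 * np.ptp(tr.frames_t):
                continue
            ev_t = ev.t_start + np.arange(ev.n_frames) * optics.frame_interval
            common = (tr.frames_t >= lo - 1e-9) & (tr.frames_t <= hi + 1e-9)
            d = np.median(np.abs(
                np.interp(tr.frames_t[common], ev_t, ev.path_positions)
                - tr.positions_nm[common]
            ))
            if d < best_d:
                best, best_d = ev, d
        if best is not None and best_d < 2 * optics.pixel_size and v_true > 0:
            matched += abs(best.velocity - v_true) / v_true < 0.10
    assert len(truth_events) >= 8, "fixture too sparse to be meaningful"
    assert matched / len(truth_events) >= 0.9


def test_extraction_is_deterministic(cfg754, single_mt_field, small_optics):
    landings = sim.sample_landings(single_mt_field, cfg754.motor, 12.0, seed=20)
    trajectories = sim.sample_trajectories(cfg754.motor, landings, small_optics, 21,
                                           field=single_mt_field)
    movie = sim.render_movie(single_mt_field, trajectories, small_optics, seed=22)
    k = build_kymograph(movie, single_mt_field.segments[0])
    e1 = extract_events(k)
    e2 = extract_events(k)
    assert len(e1) == len(e2)
    for a, b in zip(e1, e2):
        np.testing.assert_array_equal(a.path_positions, b.path_positions)


def test_truth_and_extraction_agree_on_noise_free_movie(cfg754, small_optics):
    """Velocity from tracking matches the truth-table definition within the
    pixelation bound pixel_size / residency."""
    model = dataclasses.replace(
        cfg754.motor, bleach_rate=0.0, velocity_components=((1.0, 250.0, 0.0),),
        run_length_mean=1e9,
    )
    optics = dataclasses.replace(small_optics, duration=24.0)
    seg = MTSegment((32.0, 4.0), (32.0, 60.0), 56 * 160 / 1000, 1)
    field = MicrotubuleField((seg,))
    land = Landing(0, 0.0, 800.0, "processive")
    tr = sim.sample_trajectory(model, land, optics, seed=23, mt_length_um=seg.length_um)
    movie = sim.render_movie(field, [tr], optics, seed=24, noise=False)
    k = build_kymograph(movie, seg)
    (ev,) = [e for e in extract_events(k) if e.n_frames >= 5]
    v_truth = np.ptp(tr.positions_nm) / np.ptp(tr.frames_t)
    bound = k.pixel_size / np.ptp(tr.frames_t)
    assert abs(ev.velocity - v_truth) <= bound


# ---------------------------------------------------------------------------
# gliding


def _gliding_kymograph(v_nm_s, n_px=40, n_frames=101, mt_px=12, start=3.1):
    """Rigid translocation of a bright segment; frame interval chosen so the
    total displacement is an integer number of pixels."""
    disp_px = 10
    elapsed = disp_px * 160.0 / v_nm_s if v_nm_s > 0 else 12.0
    dt = elapsed / (n_frames - 1)
    img = np.zeros((n_px, n_frames))
    for k in range(n_frames):
        edge = start + (disp_px * k / (n_frames - 1) if v_nm_s > 0 else 0.0)
        lo = int(np.floor(edge)) - mt_px
        img[max(lo, 0): int(np.floor(edge)) + 1, k] = 100.0
    return Kymograph(img, 160.0, dt, mt_px * 0.16)


def test_stationary_microtubule_glides_at_zero():
    k = _gliding_kymograph(0.0)
    assert gliding_velocities([k])[0] == 0.0


def test_rigid_translocation_velocity_identity():
    k = _gliding_kymograph(115.7)
    (v,) = gliding_velocities([k])
    assert v == pytest.approx(115.7, rel=1e-6)


def test_gliding_population_mean_recovery(cfgfl):
    """n=93 gliding speeds drawn at the configured mean are recovered by a
    single-Gaussian fit."""
    from motortrace import stats

    g = cfgfl.gliding
    rng = np.random.default_rng(25)
    vs = []
    for _ in range(g["n"]):
        v = max(rng.normal(g["velocity_mean"], g["velocity_sd"]), 20.0)
        k = _gliding_kymograph(v, start=3.0 + rng.uniform(0, 1))
        vs.append(gliding_velocities([k])[0])
    fit = stats.histogram_gaussian_fit(np.array(vs), n_components=1, bin_width=20.0)
    sem = g["velocity_sd"] / np.sqrt(g["n"])
    assert fit.means[0] == pytest.approx(g["velocity_mean"], abs=3 * max(sem, fit.sem_of_means[0]))
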