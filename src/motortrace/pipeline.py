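"""End-to-end analysis: events → filters → fits → report.

The report aggregates, per construct, everything a motility figure legend
carries: event counts, the velocity Gaussian fit (1 or 2 components), the
run-length and residency survival fits with CI95, landing rates (total and
processive) when a microtubule field is supplied, and the motile fraction.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import stats
from .kymo import RunEvent, filter_events
from .models import MicrotubuleField

__all__ = ["analyze_events", "summarize_bleach"]


def _fit_or_error(fn, *args, **kwargs):
    try:
        return dataclasses.asdict(fn(*args, **kwargs)), None
    except (ValueError, stats.FitError) as exc:
        return None, str(exc)


def analyze_events(
    events: Sequence[RunEvent],
    construct: str = "",
    n_velocity_components: int = 1,
    bin_width: float = 20.0,
    field: MicrotubuleField | None = None,
    duration_min: float | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    min_frames: int = 5,
) -> dict:
    """Run the full statistical pipeline on measured events.

    Events are first filtered (>= ``min_frames`` frames); velocity, run
    length and residency statistics use motile events only, as static
    binders have no run to measure. Every estimate carries its n and, where
    defined, a CI95 or s.e.m. Fits that cannot run on the data at hand are
    reported as structured errors, not exceptions.
    """
    events = list(events)
    kept = filter_events(events, min_frames=min_frames)
    motile = [ev for ev in kept if ev.motile]
    velocities = np.array([ev.velocity for ev in motile])
    run_lengths = np.array([ev.run_length for ev in motile])
    residencies = np.array([ev.residency for ev in motile])

    report: dict = {
        "construct": construct,
        "seed": seed,
        "n_events_raw": len(events),
        "n_events_filtered": len(kept),
        "n_events_motile": len(motile),
    }

    if kept:
        mf = stats.motile_fraction(kept)
        report["motile_fraction"] = dataclasses.asdict(mf)
    else:
        report["motile_fraction"] = None

    if velocities.size:
        fit, err = _fit_or_error(
            stats.histogram_gaussian_fit, velocities,
            n_components=n_velocity_components, bin_width=bin_width,
        )
        report["velocity_fit"] = fit
        if err:
            report["velocity_fit_error"] = err
    else:
        report["velocity_fit"] = None

    for label, sample in (("run_length_fit", run_lengths), ("residency_fit", residencies)):
        if sample.size:
            fit, err = _fit_or_error(
                stats.survival_exponential_fit, sample, n_boot=n_boot, seed=seed
            )
            report[label] = fit
            if err:
                report[label + "_error"] = err
        else:
            report[label] = None

    if field is not None and duration_min is not None:
        # landing rates count every landing, before the frame filter
        total = stats.landing_rate(events, field, duration_min, processive_only=False)
        proc = stats.landing_rate(events, field, duration_min, processive_only=True)
        report["landing_rate_total"] = dataclasses.asdict(total)
        report["landing_rate_processive"] = dataclasses.asdict(proc)
    else:
        report["landing_rate_total"] = None
        report["landing_rate_processive"] = None
    return report


def summarize_bleach(step_counts: Sequence[int], initial_intensities: Sequence[float]) -> dict:
    """Histogram summary of photobleaching step counts and initial intensities."""
    counts = np.asarray(list(step_counts), dtype=int)
    init = np.asarray(list(initial_intensities), dtype=float)
    hist = np.bincount(counts, minlength=1) if counts.size else np.array([0])
    return {
        "n_traces": int(counts.size),
        "step_histogram": {int(k): int(v) for k, v in enumerate(hist) if v or k <= counts.max(initial=0)},
        "step_mode": int(np.argmax(hist)) if counts.size else None,
        "initial_intensity_mean": float(init.mean()) if init.size else None,
        "initial_intensity_median": float(np.median(init)) if init.size else None,
    }
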