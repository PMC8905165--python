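"""The statistical layer: velocity histogram Gaussian fits, survival-curve
exponential fits, bootstrap confidence intervals, per-microtubule landing
rates, Welch's t-test and motile fractions.

These are the estimators the motility literature applies to kymograph
event tables: velocities are histogrammed and fitted with one or two
Gaussians by least squares; run lengths and residency times are summarized
as the decay constant tau of A*exp(-x/tau) fitted to the empirical survival
curve 1 - ECDF; landing rates are events per µm of microtubule per minute,
averaged over microtubules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit
from statsmodels.stats.proportion import proportion_confint

from .models import MicrotubuleField

__all__ = [
    "GaussianFitResult",
    "SurvivalFitResult",
    "LandingRateResult",
    "WelchResult",
    "MotileFractionResult",
    "FitError",
    "histogram_gaussian_fit",
    "survival_exponential_fit",
    "bootstrap_ci95",
    "landing_rate",
    "welch_t_test",
    "motile_fraction",
]


class FitError(RuntimeError):
    """A fit failed or is not defined for the given data."""


@dataclass
class GaussianFitResult:
    n_components: int
    means: np.ndarray  # nm/s, ascending for 2 components
    sds: np.ndarray
    amplitudes: np.ndarray  # histogram counts at the mode
    sem_of_means: np.ndarray  # from the fit covariance
    r_squared: float
    n: int
    bin_width: float

    def __post_init__(self) -> None:
        if self.n_components == 2 and self.means[0] > self.means[1]:
            raise AssertionError("two-component means must be sorted ascending")


@dataclass
class SurvivalFitResult:
    decay_constant: float  # nm or s
    amplitude: float
    ci95: tuple[float, float]
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.decay_constant <= 0:
            raise AssertionError("decay constant must be > 0")


@dataclass
class LandingRateResult:
    per_mt_rates: np.ndarray  # events per µm per min
    mean_rate: float
    sem: float
    n_mts: int
    processive_only: bool


@dataclass
class WelchResult:
    t_statistic: float
    df: float
    p_value: float


@dataclass
class MotileFractionResult:
    fraction: float
    ci95: tuple[float, float]  # Wilson 95% interval
    n_motile: int
    n_total: int


# ---------------------------------------------------------------------------
# Gaussian histogram fits


def _two_means_split(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1-D 2-means: the split of the sorted sample minimizing total
    within-group sum of squares. Ties broken toward larger separation."""
    xs = np.sort(x)
    n = xs.size
    c = np.cumsum(xs)
    c2 = np.cumsum(xs**2)
    best_ss, best_i, best_sep = np.inf, 1, -np.inf
    for i in range(1, n):
        s1, s2 = c[i - 1], c[-1] - c[i - 1]
        ss = (c2[i - 1] - s1**2 / i) + (c2[-1] - c2[i - 1] - s2**2 / (n - i))
        sep = abs(s2 / (n - i) - s1 / i)
        if ss < best_ss - 1e-12 or (abs(ss - best_ss) <= 1e-12 and sep > best_sep):
            best_ss, best_i, best_sep = ss, i, sep
    return xs[:best_i], xs[best_i:]


def _gauss_sum(x: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    for a, m, s in zip(params[::3], params[1::3], params[2::3]):
        out += a * np.exp(-((x - m) ** 2) / (2 * s**2))
    return out


def histogram_gaussian_fit(
    values: Sequence[float], n_components: int = 1, bin_width: float = 20.0
) -> GaussianFitResult:
    """Least-squares fit of a sum of Gaussians to a binned histogram.

    Mirrors the standard velocity-histogram workflow: raw values are binned
    at ``bin_width`` (default 20 nm/s), and amplitude/mean/sd per component
    are fitted to counts vs bin centers. Standard errors of the means come
    from the fit covariance; r² is computed on the histogram counts. For two
    components, initialization uses an exact 1-D 2-means split of the raw
    values and the means are reported in ascending order.
    """
    v = np.asarray(values, dtype=float)
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    min_n = 20 if n_components == 1 else 40
    if v.size < min_n:
        raise ValueError(f"need >= {min_n} values for a {n_components}-component fit")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")

    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil(v.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(v, edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    n_params = 3 * n_components
    occupied = int((counts > 0).sum())
    if occupied < 2:
        raise FitError("degenerate histogram: a single occupied bin cannot be fitted")
    if occupied < n_params:
        raise FitError(
            f"{occupied} occupied bins cannot constrain {n_params} fit parameters"
        )

    span = max(v.max() - v.min(), bin_width)
    amax = counts.max()
    if n_components == 1:
        p0 = [amax, float(v.mean()), max(float(v.std()), bin_width / 2)]
    else:
        g1, g2 = _two_means_split(v)
        p0 = [
            amax, float(g1.mean()), max(float(g1.std()), bin_width / 2),
            max(amax / 3.0, 0.5), float(g2.mean()), max(float(g2.std()), bin_width / 2),
        ]
    lower = [0.0, v.min(), bin_width / 4] * n_components
    upper = [2.0 * amax + 1, v.max(), span] * n_components
    p0 = np.clip(p0, lower, upper)
    try:
        popt, pcov = curve_fit(
            _gauss_sum, centers, counts, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"Gaussian histogram fit did not converge: {exc}") from exc

    fitted = _gauss_sum(centers, *popt)
    ss_res = float(((counts - fitted) ** 2).sum())
    ss_tot = float(((counts - counts.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    perr = np.sqrt(np.diag(pcov))
    amps = popt[0::3]
    means = popt[1::3]
    sds = popt[2::3]
    sems = perr[1::3]
    order = np.argsort(means)
    return GaussianFitResult(
        n_components=n_components,
        means=means[order],
        sds=sds[order],
        amplitudes=amps[order],
        sem_of_means=sems[order],
        r_squared=r2,
        n=v.size,
        bin_width=bin_width,
    )


# ---------------------------------------------------------------------------
# survival-curve exponential fit


def _survival_points(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical survival curve evaluated at the sorted sample.

    Uses the Hazen plotting position S_i = 1 - (i - 0.5)/n, the standard
    convention for least-squares fits to probability curves; it avoids the
    S = 0 endpoint that would otherwise bias the decay constant low.
    """
    x = np.sort(v)
    n = x.size
    s = 1.0 - (np.arange(1, n + 1) - 0.5) / n
    return x, s


def survival_exponential_fit(
    values: Sequence[float],
    n_boot: int = 0,
    seed: int | None = None,
) -> SurvivalFitResult:
    """Fit A*exp(-x/tau) to the empirical survival curve 1 - ECDF.

    tau is the decay constant reported for run lengths and residency times.
    The amplitude A is a free parameter (initialized at 1) because the
    finite minimum detectable run depresses the early part of real survival
    curves. The 95% CI is the Wald interval from the fit covariance by
    default; with ``n_boot`` > 0 a seeded percentile bootstrap of the whole
    refit is used instead.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 20:
        raise ValueError("need >= 20 values for a survival fit")
    if np.any(v <= 0):
        raise ValueError("survival fit requires strictly positive values")

    def _fit(sample: np.ndarray) -> tuple[float, float]:
        x, s = _survival_points(sample)
        popt, pcov = curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau),
            x, s,
            p0=[1.0, float(sample.mean())],
            bounds=([0.0, 1e-12], [2.0, np.inf]),
            maxfev=20000,
        )
        return popt, pcov

    try:
        popt, pcov = _fit(v)
    except RuntimeError as exc:
        raise FitError(f"survival exponential fit did not converge: {exc}") from exc
    a, tau = float(popt[0]), float(popt[1])
    x, s = _survival_points(v)
    resid = s - a * np.exp(-x / tau)
    ss_tot = float(((s - s.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")

    if n_boot > 0:
        lo, hi = bootstrap_ci95(
            v, lambda sample: float(_fit(np.asarray(sample))[0][1]),
            n_boot=n_boot, seed=0 if seed is None else seed,
        )
    else:
        se = float(np.sqrt(pcov[1, 1]))
        lo, hi = tau - 1.96 * se, tau + 1.96 * se
    return SurvivalFitResult(
        decay_constant=tau, amplitude=a, ci95=(lo, hi), r_squared=r2, n=v.size
    )


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_ci95(
    values: Sequence[float],
    estimator: Callable[[np.ndarray], float],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap 95% interval of an estimator, seeded.

    Resamples with replacement ``n_boot`` times (>= 200) and returns the
    (2.5, 97.5) percentiles of the estimator's bootstrap distribution.
    Raises if the estimator fails on more than 5% of resamples.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    v = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    failures = 0
    for b in range(n_boot):
        sample = v[rng.integers(0, v.size, v.size)]
        try:
            est[b] = estimator(sample)
        except Exception:
            est[b] = np.nan
            failures += 1
    if failures > 0.05 * n_boot:
        raise FitError(
            f"estimator failed on {failures}/{n_boot} bootstrap resamples"
        )
    ok = est[~np.isnan(est)]
    return float(np.percentile(ok, 2.5)), float(np.percentile(ok, 97.5))


# ---------------------------------------------------------------------------
# landing rates, Welch's t-test, motile fraction


def landing_rate(
    events: "Iterable | pd.DataFrame",
    field: MicrotubuleField,
    duration_min: float,
    processive_only: bool = False,
) -> LandingRateResult:
    """Per-microtubule landing rates in events·µm⁻¹·min⁻¹.

    For microtubule i, rate_i = count_i / (L_i x duration); the result
    reports the mean and s.e.m. over microtubules (microtubules with no
    events contribute zero rates). With ``processive_only`` only motile
    events are counted.
    """
    if duration_min <= 0:
        raise ValueError("duration must be > 0")
    lengths = field.lengths_um
    if np.any(lengths <= 0):
        raise ValueError("microtubule of zero length")
    if isinstance(events, pd.DataFrame):
        mt_ids = events["mt_id"].to_numpy(int)
        motile = events["motile"].to_numpy(bool) if "motile" in events else np.ones(len(events), bool)
    else:
        evs = list(events)
        mt_ids = np.array([ev.mt_id for ev in evs], dtype=int)
        motile = np.array([bool(getattr(ev, "motile", True)) for ev in evs], dtype=bool)
    if processive_only and mt_ids.size:
        mt_ids = mt_ids[motile]
    if mt_ids.size and (mt_ids.min() < 0 or mt_ids.max() >= len(field)):
        raise ValueError("event references a microtubule not in the field")
    counts = np.bincount(mt_ids, minlength=len(field)).astype(float)
    rates = counts / (lengths * duration_min)
    sem = float(rates.std(ddof=1) / np.sqrt(len(rates))) if len(rates) > 1 else 0.0
    return LandingRateResult(
        per_mt_rates=rates,
        mean_rate=float(rates.mean()),
        sem=sem,
        n_mts=len(field),
        processive_only=processive_only,
    )


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Two-sided Welch's t-test with Welch–Satterthwaite degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise FitError("undefined statistic: zero variance in both samples")
    res = sps.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return WelchResult(
        t_statistic=float(res.statistic), df=float(df), p_value=float(res.pvalue)
    )


def motile_fraction(events: Sequence) -> MotileFractionResult:
    """Fraction of events classified motile, with a Wilson 95% interval."""
    evs = list(events)
    if not evs:
        raise ValueError("motile_fraction requires a non-empty event list")
    n_motile = sum(bool(getattr(ev, "motile")) for ev in evs)
    n = len(evs)
    lo, hi = proportion_confint(n_motile, n, alpha=0.05, method="wilson")
    return MotileFractionResult(
        fraction=n_motile / n, ci95=(float(lo), float(hi)),
        n_motile=n_motile, n_total=n,
    )
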