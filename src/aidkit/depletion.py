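"""Depletion kinetics: rates, completeness, variability, mother/daughter lag.

All estimators expect baseline-normalized trajectories (pre-auxin mean 1)
so that the autofluorescence floor and the complete-depletion band are on a
shared scale across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .preprocess import SmoothTrajectory, fit_smoothing_spline
from .trajectory import PopulationSample, Trajectory

__all__ = [
    "DepletionSummary",
    "DoseResponseFit",
    "FloorEstimate",
    "floor_band",
    "max_depletion_rate",
    "time_to_floor",
    "estimate_floor",
    "completeness_ratio",
    "cohort_completeness",
    "fit_rate_dose_response",
    "fit_completeness_dose_response",
    "variability_slope",
    "compare_mother_daughter",
    "summarize_depletion",
]

BEFORE_WINDOW = (0.0, 240.0)
AFTER_WINDOW = (500.0, 740.0)


@dataclass
class DepletionSummary:
    """Per-cell depletion statistics."""

    cell_id: str
    min_slope: float
    time_to_floor: float | None
    completeness_ratio: float | None


@dataclass
class FloorEstimate:
    """Bootstrap estimate of the complete-depletion signal ratio."""

    mean_ratio: float
    ci95_low: float
    ci95_high: float
    n_boot: int


@dataclass
class DoseResponseFit:
    """A fitted dose-response model with its parameters and residual."""

    model: str  # "two_phase_decay" | "log_logistic"
    params: dict
    rss: float
    converged: bool = True
    message: str = ""

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.model == "two_phase_decay":
            return p["plateau"] * (
                1.0 - p["fast_fraction"] * np.exp(-p["k_fast"] * x)
                - (1.0 - p["fast_fraction"]) * np.exp(-p["k_slow"] * x)
            )
        if self.model == "log_logistic":
            return p["base"] + (p["top"] - p["base"]) / (
                1.0 + 10.0 ** ((p["log_ec50"] - np.log10(x)) * p["hill"])
            )
        raise ValueError(f"unknown model {self.model!r}")


def floor_band(floor_mean: float, noise_sd: float) -> tuple[float, float]:
    """Complete-depletion band: floor mean +/- 2 noise SD."""
    return floor_mean - 2.0 * noise_sd, floor_mean + 2.0 * noise_sd


def max_depletion_rate(traj, t_add: float) -> tuple[float, float]:
    """Most negative signal slope after auxin addition.

    Accepts a :class:`SmoothTrajectory` (spline derivative, single-cell
    analyses) or a ``(times, values)`` pair (finite differences on the
    sampling grid, used for cohort mean traces); slopes are assigned to
    the left edge of their interval. Returns ``(min_slope, t_at_min)``;
    ties resolve to the earliest time.
    """
    if isinstance(traj, SmoothTrajectory):
        times, slopes = traj.times, traj.derivative
    else:
        times, values = (np.asarray(a, dtype=float) for a in traj)
        slopes = np.diff(values) / np.diff(times)
        times = times[:-1]
    mask = times >= t_add
    if not mask.any():
        raise ValueError("no samples at or after t_add")
    slopes, times = slopes[mask], times[mask]
    i = int(np.argmin(slopes))  # argmin takes the earliest tie
    return min(float(slopes[i]), 0.0), float(times[i])


def time_to_floor(traj: Trajectory, t_add: float, band: tuple[float, float]) -> float | None:
    """Minutes from auxin addition to first entry into the floor band."""
    mask = traj.times >= t_add
    if not mask.any():
        raise ValueError("no samples at or after t_add")
    below = traj.signal[mask] <= band[1]
    if not below.any():
        return None
    return float(traj.times[mask][int(np.argmax(below))] - t_add)


def estimate_floor(
    wildtype_cell_means,
    reporter_cell_means,
    n_boot: int = 100,
    rng=None,
) -> FloorEstimate:
    """Complete-depletion ratio: mean wild-type autofluorescence over mean
    pre-depletion reporter signal, with a percentile bootstrap CI over cells.
    """
    wt = np.asarray(wildtype_cell_means, dtype=float)
    rep = np.asarray(reporter_cell_means, dtype=float)
    if wt.size == 0 or rep.size == 0:
        raise ValueError("both cell groups must be nonempty")
    if rep.mean() == 0:
        raise ValueError("zero reporter mean")
    rng = np.random.default_rng(rng)
    ratio = float(wt.mean() / rep.mean())
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = (
            rng.choice(wt, size=wt.size, replace=True).mean()
            / rng.choice(rep, size=rep.size, replace=True).mean()
        )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return FloorEstimate(ratio, float(lo), float(hi), n_boot)


def completeness_ratio(
    traj: Trajectory,
    before: tuple[float, float] = BEFORE_WINDOW,
    after: tuple[float, float] = AFTER_WINDOW,
) -> float:
    """mean(after-window signal) / mean(before-window signal) for one cell."""
    b = traj.window_values(before)
    a = traj.window_values(after)
    if b.size == 0 or a.size == 0:
        raise ValueError("both windows must contain samples")
    return float(a.mean() / b.mean())


def cohort_completeness(
    sample: PopulationSample,
    before: tuple[float, float] = BEFORE_WINDOW,
    after: tuple[float, float] = AFTER_WINDOW,
    confidence: float = 0.95,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Cohort mean completeness ratio with a t-based CI across cells."""
    ratios = np.array([completeness_ratio(t, before, after) for t in sample])
    mean = float(ratios.mean())
    if ratios.size > 1:
        sem = ratios.std(ddof=1) / np.sqrt(ratios.size)
        tq = stats.t.ppf(0.5 + confidence / 2, df=ratios.size - 1)
        ci = (mean - tq * sem, mean + tq * sem)
    else:
        ci = (mean, mean)
    return mean, ci, ratios


def _two_phase(x, plateau, fast_fraction, k_fast, k_slow):
    return plateau * (
        1.0 - fast_fraction * np.exp(-k_fast * x)
        - (1.0 - fast_fraction) * np.exp(-k_slow * x)
    )


def fit_rate_dose_response(conc_mM, rates) -> DoseResponseFit:
    """Two-phase exponential decay fit of min slope vs concentration.

    y(x) = P (1 - f e^{-K1 x} - (1-f) e^{-K2 x}) with the intercept
    constrained to 0 by construction (the exponential fractions sum to 1).
    The label-swap symmetry is broken by reporting K1 >= K2 (swapping the
    phases and replacing f by 1-f leaves the curve unchanged).
    """
    x = np.asarray(conc_mM, dtype=float)
    y = np.asarray(rates, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 concentrations")
    if np.allclose(y, 0.0):
        return DoseResponseFit(
            "two_phase_decay",
            {"plateau": 0.0, "fast_fraction": 0.5, "k_fast": 1.0, "k_slow": 0.0},
            rss=0.0,
        )
    scale = 1.0 / max(np.median(x[x > 0]), 1e-12)
    p0 = (y[np.argmax(x)], 0.6, 5.0 * scale, 0.5 * scale)
    try:
        popt, _ = optimize.curve_fit(
            _two_phase, x, y, p0=p0,
            bounds=([-np.inf, 0.0, 0.0, 0.0], [np.inf, 1.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        return DoseResponseFit("two_phase_decay", {}, rss=np.inf,
                               converged=False, message=str(err))
    plateau, f, k1, k2 = popt
    if k1 < k2:
        k1, k2, f = k2, k1, 1.0 - f
    params = {"plateau": float(plateau), "fast_fraction": float(f),
              "k_fast": float(k1), "k_slow": float(k2)}
    fit = DoseResponseFit("two_phase_decay", params, rss=0.0)
    fit.rss = float(np.sum((fit.predict(x) - y) ** 2))
    return fit


def fit_completeness_dose_response(conc_mM, ratios, base: float) -> DoseResponseFit:
    """Log-dose response with variable slope, top fixed at 1 and base fixed.

    ratio(x) = base + (1 - base) / (1 + 10^{(log10 EC50 - log10 x) h}).
    """
    x = np.asarray(conc_mM, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 concentrations")
    if not 0 < base < 1:
        raise ValueError("base must lie in (0, 1)")
    if np.any(x <= 0):
        raise ValueError("concentrations must be > 0 for a log-dose fit")

    def model(logx, log_ec50, hill):
        return base + (1.0 - base) / (1.0 + 10.0 ** ((log_ec50 - logx) * hill))

    logx = np.log10(x)
    p0 = (float(np.median(logx)), -1.0)
    try:
        popt, _ = optimize.curve_fit(model, logx, y, p0=p0, maxfev=20000)
    except RuntimeError as err:
        return DoseResponseFit("log_logistic", {}, rss=np.inf,
                               converged=False, message=str(err))
    params = {"top": 1.0, "base": float(base),
              "log_ec50": float(popt[0]), "hill": float(popt[1])}
    fit = DoseResponseFit("log_logistic", params, rss=0.0)
    fit.rss = float(np.sum((fit.predict(x) - y) ** 2))
    return fit


def variability_slope(
    sample: PopulationSample,
    t_add: float,
    window_min: float = 120.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Change of the cell-to-cell SD per time interval during depletion.

    Computes the pointwise SD of the normalized signals over
    ``[t_add, t_add + window_min]`` and its finite differences on the
    sampling grid.  Returns ``(interval_times, dSD/dt, mean_slope)``:
    a positive mean marks a variable (desynchronized) response, a negative
    mean a uniform one.
    """
    if len(sample) < 2:
        raise ValueError("need at least 2 cells")
    times = sample.common_grid()
    mat = np.vstack([t.signal for t in sample])
    mask = (times >= t_add) & (times <= t_add + window_min)
    if mask.sum() < 2:
        raise ValueError("variability window must cover at least 2 samples")
    sd = mat[:, mask].std(axis=0, ddof=1)
    tt = times[mask]
    slopes = np.diff(sd) / np.diff(tt)
    return tt[:-1], slopes, float(slopes.mean())


def _half_depletion_time(
    traj: Trajectory, t_add: float, floor: float
) -> float | None:
    """First crossing of the baseline/floor midpoint, linearly interpolated."""
    threshold = 0.5 * (1.0 + floor)
    mask = traj.times >= t_add
    t = traj.times[mask]
    s = traj.signal[mask]
    below = s <= threshold
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(t[0] - t_add)
    frac = (s[i - 1] - threshold) / (s[i - 1] - s[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]) - t_add)


def compare_mother_daughter(
    sample: PopulationSample,
    t_add: float,
    floor: float = 0.288,
) -> dict:
    """Mother/daughter depletion asymmetry.

    Computes each cell's time-to-half-depletion (first crossing of the
    midpoint between the normalized baseline 1 and the floor) and returns
    the Hodges-Lehmann median daughter-minus-mother difference with a
    rank-sum (Mann-Whitney) p-value.
    """
    groups = {}
    for role in ("mother", "daughter"):
        ts = [
            _half_depletion_time(t, t_add, floor)
            for t in sample.by_role(role)
        ]
        ts = [t for t in ts if t is not None]
        if len(ts) < 3:
            raise ValueError(f"need at least 3 {role} cells with a half-depletion crossing")
        groups[role] = np.asarray(ts)
    diffs = groups["daughter"][:, None] - groups["mother"][None, :]
    stat = stats.mannwhitneyu(groups["daughter"], groups["mother"], alternative="two-sided")
    return {
        "median_delay_min": float(np.median(diffs)),
        "p_value": float(stat.pvalue),
        "mother_times": groups["mother"],
        "daughter_times": groups["daughter"],
    }


def summarize_depletion(
    sample: PopulationSample,
    t_add: float,
    band: tuple[float, float],
    before: tuple[float, float] = BEFORE_WINDOW,
    after: tuple[float, float] | None = AFTER_WINDOW,
    lam: float | None = None,
) -> pd.DataFrame:
    """Per-cell depletion summaries (spline min slope, time-to-floor, ratio)."""
    rows = []
    for traj in sample:
        smooth = fit_smoothing_spline(traj, lam=lam)
        slope, _ = max_depletion_rate(smooth, t_add)
        ttf = time_to_floor(traj, t_add, band)
        ratio = None
        if after is not None and traj.window_values(after).size:
            ratio = completeness_ratio(traj, before, after)
        rows.append({
            "cell_id": traj.cell_id,
            "role": traj.role,
            "min_slope": slope,
            "time_to_floor": ttf,
            "completeness_ratio": ratio,
        })
    return pd.DataFrame(rows)
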