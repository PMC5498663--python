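"""Background subtraction, normalization, smoothing and cohort statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline, make_smoothing_spline

from .trajectory import PopulationSample, Trajectory

__all__ = [
    "SmoothTrajectory",
    "subtract_background",
    "normalize_baseline",
    "fit_smoothing_spline",
    "population_stats",
    "mean_trace",
]

#: Default baseline window (min): the pre-auxin acquisition period.
BASELINE_WINDOW = (0.0, 240.0)


@dataclass
class SmoothTrajectory:
    """A smoothing-spline fit of one trajectory and its first derivative.

    ``smooth_values`` and ``derivative`` (signal units / min) are the spline
    and its analytic derivative evaluated on the source time grid; the
    underlying spline is kept for evaluation at arbitrary times.
    """

    source: Trajectory
    smooth_values: np.ndarray
    derivative: np.ndarray
    smoothing_parameter: float | None
    spline: BSpline

    @property
    def times(self) -> np.ndarray:
        return self.source.times

    def __call__(self, t):
        return self.spline(t)

    def derivative_at(self, t):
        return self.spline.derivative()(t)


def subtract_background(raw_frame_values, cell_values):
    """Subtract the modal grey value of the field of view from cell signals.

    The mode of the frame-pixel distribution (histogram with
    Freedman-Diaconis bins; ties resolved to the lowest modal bin center)
    estimates the background fluorescence. Simulated trajectories are
    already background-free, so this step applies to raw imaging data.
    """
    frame = np.asarray(raw_frame_values, dtype=float).ravel()
    if frame.size == 0:
        raise ValueError("empty frame sample")
    counts, edges = np.histogram(frame, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = centers[int(np.argmax(counts))]  # argmax takes the lowest tied bin
    return np.asarray(cell_values, dtype=float) - mode


def normalize_baseline(traj: Trajectory, window: tuple[float, float] = BASELINE_WINDOW) -> Trajectory:
    """Divide a trajectory by its mean signal over the baseline window.

    After normalization the window mean is exactly 1, which makes the
    operation idempotent.
    """
    vals = traj.window_values(window)
    if vals.size < 2:
        raise ValueError("baseline window must cover at least 2 samples")
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError("non-positive baseline mean signals corrupt input")
    return traj.with_signal(traj.signal / mean)


def fit_smoothing_spline(traj: Trajectory, lam: float | None = None) -> SmoothTrajectory:
    """Fit a cubic smoothing spline and evaluate its first derivative.

    ``lam=None`` selects the smoothing parameter by generalized
    cross-validation; a fixed value may be supplied for reproducibility
    (``lam=0`` interpolates).
    """
    if traj.times.size < 8:
        raise ValueError("need at least 8 samples for spline smoothing")
    spl = make_smoothing_spline(traj.times, traj.signal, lam=lam)
    return SmoothTrajectory(
        source=traj,
        smooth_values=spl(traj.times),
        derivative=spl.derivative()(traj.times),
        smoothing_parameter=lam,
        spline=spl,
    )


def population_stats(sample: PopulationSample, confidence: float = 0.95) -> pd.DataFrame:
    """Pointwise cohort statistics on a common time grid.

    Returns a frame with columns ``time_min, mean, sd, sem, ci_low,
    ci_high`` (CI via the t-quantile with n-1 degrees of freedom).
    """
    if len(sample) < 2:
        raise ValueError("need at least 2 trajectories")
    times = sample.common_grid()
    mat = np.vstack([t.signal for t in sample])
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    sem = sd / np.sqrt(n)
    tq = stats.t.ppf(0.5 + confidence / 2, df=n - 1)
    return pd.DataFrame({
        "time_min": times,
        "mean": mean,
        "sd": sd,
        "sem": sem,
        "ci_low": mean - tq * sem,
        "ci_high": mean + tq * sem,
    })


def mean_trace(sample: PopulationSample) -> tuple[np.ndarray, np.ndarray]:
    """(times, cohort mean signal) on the common grid."""
    times = sample.common_grid()
    mat = np.vstack([t.signal for t in sample])
    return times, mat.mean(axis=0)
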