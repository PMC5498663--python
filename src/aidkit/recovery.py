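"""Cycle-resolved protein recovery after auxin removal.

During recovery the reporter rises in a sawtooth: synthesis within each
division cycle, an abrupt concentration drop at each budding.  The peak
(MAX) of each cycle and the drop to the following trough (DIFF = MAX -
next MIN) obey DIFF = (1 - 1/DIL) MAX for a constant per-division
dilution factor DIL, so the slope of the origin-constrained regression of
DIFF on MAX converts to DIL = 1 / (1 - SLOPE).

The regression is meaningful on the protein component of the signal: the
additive autofluorescence floor would otherwise make DIFF/MAX depend on
expression level.  Use :func:`protein_component` (baseline-normalized
signal minus the measured floor, rescaled) before segmenting cycles.

Because divisions are observed events at which the concentration drops
discontinuously, smoothing is done per inter-budding segment (a single
spline across a division would smear the drop and shrink DIFF), and the
peak/trough flanking each division are evaluated at the division time by
short local-linear extrapolation from either side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .preprocess import fit_smoothing_spline, mean_trace
from .trajectory import PopulationSample, Trajectory

__all__ = [
    "CycleStats",
    "DilutionEstimate",
    "protein_component",
    "segment_cycles",
    "fit_max_diff_regression",
    "dilution_factor",
    "estimate_dilution",
    "fraction_recovered",
    "time_to_full_recovery",
    "minimum_pulse_for_depletion",
]


@dataclass
class CycleStats:
    """Per-division-cycle peak/trough statistics and derivative integrals."""

    cell_id: str
    cycle_index: int  # 1-based, counted from the first budding after removal
    t_start: float
    t_end: float
    max_signal: float
    min_signal: float | None
    diff: float | None
    synthesis_integral: float
    dilution_integral: float


@dataclass
class DilutionEstimate:
    """Origin-constrained DIFF-vs-MAX slope and the derived dilution factor."""

    slope: float
    slope_ci95: tuple[float, float]
    dil: float
    dil_ci95: tuple[float, float]
    n_oscillations: int
    n_cells: int


def protein_component(traj: Trajectory, floor: float) -> Trajectory:
    """Autofluorescence-corrected, rescaled protein signal.

    Maps a baseline-normalized signal s to (s - floor) / (1 - floor), so
    the pre-depletion level stays ~1 and complete depletion sits at ~0.
    Values are clipped at 0.
    """
    if not 0 <= floor < 1:
        raise ValueError("floor must lie in [0, 1)")
    return traj.with_signal(np.clip((traj.signal - floor) / (1.0 - floor), 0.0, None))


class _SegmentFit:
    """Smooth representation of one inter-budding segment.

    Samples exactly at a (grid-snapped) budding time are excluded: they
    cannot be assigned to either side of the drop.  The values at the
    flanking division times are obtained by local-linear extrapolation
    from the nearest ``n_edge`` samples, which evaluates the pre-drop peak
    and post-drop trough at the division itself instead of at the nearest
    sample.
    """

    def __init__(self, times: np.ndarray, values: np.ndarray,
                 t_left: float, t_right: float,
                 lam: float | None, n_edge: int = 4) -> None:
        eps = 1e-9
        mask = (times > t_left + eps) & (times < t_right - eps)
        self.t = times[mask]
        self.v = values[mask]
        self.t_left, self.t_right = t_left, t_right
        self.ok = self.t.size >= 2
        if not self.ok:
            return
        if self.t.size >= 8:
            spl = make_smoothing_spline(self.t, self.v, lam=lam)
            self.dense_t = np.linspace(self.t[0], self.t[-1],
                                       max(int(self.t[-1] - self.t[0]), 4) + 1)
            self.dense_v = np.asarray(spl(self.dense_t), dtype=float)
        else:
            self.dense_t, self.dense_v = self.t, self.v
        k = min(n_edge, self.t.size)
        self.value_at_left = self._linfit(self.t[:k], self.v[:k], t_left)
        self.value_at_right = self._linfit(self.t[-k:], self.v[-k:], t_right)

    @staticmethod
    def _linfit(t: np.ndarray, v: np.ndarray, t0: float) -> float:
        if t.size == 1:
            return float(v[0])
        b1, b0 = np.polyfit(t, v, 1)
        return float(b0 + b1 * t0)

    def sign_run_integrals(self) -> tuple[float, float]:
        """Positive / negative variation of the within-segment smooth trace.

        Computed from value differences (fundamental theorem of calculus),
        so the two parts sum exactly to the net change across the segment
        including the extrapolated boundary values.
        """
        vv = np.concatenate(([self.value_at_left], self.dense_v,
                             [self.value_at_right]))
        dv = np.diff(vv)
        return float(dv[dv > 0].sum()), float(dv[dv < 0].sum())


def segment_cycles(
    traj: Trajectory,
    t_removal: float,
    max_cycles: int | None = None,
    lam: float | None = None,
) -> list[CycleStats]:
    """Split a trajectory into post-removal division cycles.

    Cycles are delimited by consecutive budding events after auxin removal
    (cycle 1 starts at the first budding).  Each inter-budding segment is
    smoothed separately.  During recovery the trace rises monotonically
    within a cycle and drops at the division, so the cycle peak (MAX) is
    the pre-drop value at the closing division and the following trough
    (MIN) the post-drop value, both evaluated at the division time by
    local-linear extrapolation; the last cycle, with no following
    segment, carries no MIN/DIFF.  The synthesis integral is the positive
    variation of the within-cycle smooth trace; the dilution integral the
    negative variation plus the drop at the cycle-ending division.
    Returns an empty list when fewer than two post-removal buddings exist.
    """
    buds = traj.budding_times[traj.budding_times >= t_removal]
    if max_cycles is not None:
        buds = buds[: max_cycles + 2]
    if buds.size < 2:
        return []

    segments = [
        _SegmentFit(traj.times, traj.signal, float(a), float(b), lam)
        for a, b in zip(buds[:-1], buds[1:])
    ]

    n_cycles = len(segments) if max_cycles is None else min(len(segments), max_cycles)
    cycles: list[CycleStats] = []
    for j in range(n_cycles):
        seg = segments[j]
        if not seg.ok:
            continue
        max_sig = seg.value_at_right
        min_sig = diff = None
        if j + 1 < len(segments) and segments[j + 1].ok:
            min_sig = segments[j + 1].value_at_left
            diff = max_sig - min_sig
        syn, neg = seg.sign_run_integrals()
        dil = neg
        if min_sig is not None:
            dil += min_sig - seg.value_at_right  # drop at the closing division
        cycles.append(CycleStats(
            cell_id=traj.cell_id,
            cycle_index=j + 1,
            t_start=seg.t_left,
            t_end=seg.t_right,
            max_signal=max_sig,
            min_signal=min_sig,
            diff=diff,
            synthesis_integral=syn,
            dilution_integral=dil,
        ))
    return cycles


def fit_max_diff_regression(
    max_values,
    diff_values,
    n_boot: int = 1000,
    rng=None,
    through_origin: bool = True,
) -> tuple[float, tuple[float, float]]:
    """Linear regression of per-cycle DIFF on MAX with a bootstrap slope CI.

    The intercept is constrained to 0 by default, consistent with the
    algebra SLOPE = DIFF / MAX; a free-intercept variant is available for
    sensitivity analysis.  The 95% CI is a percentile bootstrap over
    oscillations.
    """
    x = np.asarray(max_values, dtype=float)
    y = np.asarray(diff_values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 (MAX, DIFF) pairs")

    def slope_of(xi, yi):
        if through_origin:
            sxx = float(np.sum(xi * xi))
            if sxx == 0:
                raise ValueError("degenerate MAX values (all zero)")
            return float(np.sum(xi * yi) / sxx)
        if np.var(xi) == 0:
            raise ValueError("degenerate MAX variance")
        return float(np.polyfit(xi, yi, 1)[0])

    slope = slope_of(x, y)
    rng = np.random.default_rng(rng)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, x.size, size=x.size)
        boots[b] = slope_of(x[idx], y[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return slope, (float(lo), float(hi))


def dilution_factor(slope: float) -> float:
    """Per-division dilution factor DIL = 1 / (1 - SLOPE); requires slope < 1."""
    if slope >= 1:
        raise ValueError("slope >= 1 implies non-physical (infinite) dilution")
    return 1.0 / (1.0 - slope)


def estimate_dilution(
    sample: PopulationSample,
    floor: float,
    t_removal: float,
    n_boot: int = 1000,
    rng=None,
    max_cycles: int | None = None,
    through_origin: bool = True,
    lam: float | None = None,
) -> tuple[DilutionEstimate, list[CycleStats]]:
    """End-to-end dilution-factor estimate from a recovery cohort.

    Trajectories must be baseline-normalized; the autofluorescence floor is
    removed, each cell is smoothed, cycles are segmented, and the pooled
    (MAX, DIFF) pairs feed the origin-constrained regression.
    """
    all_cycles: list[CycleStats] = []
    n_cells = 0
    for traj in sample:
        cycles = segment_cycles(
            protein_component(traj, floor), t_removal,
            max_cycles=max_cycles, lam=lam,
        )
        if cycles:
            n_cells += 1
        all_cycles.extend(cycles)
    pairs = [(c.max_signal, c.diff) for c in all_cycles if c.diff is not None]
    if len(pairs) < 5:
        raise ValueError("too few oscillations with a following trough")
    mx, df = map(np.asarray, zip(*pairs))
    slope, slope_ci = fit_max_diff_regression(
        mx, df, n_boot=n_boot, rng=rng, through_origin=through_origin
    )
    est = DilutionEstimate(
        slope=slope,
        slope_ci95=slope_ci,
        dil=dilution_factor(slope),
        dil_ci95=(dilution_factor(slope_ci[0]), dilution_factor(slope_ci[1])),
        n_oscillations=len(pairs),
        n_cells=n_cells,
    )
    return est, all_cycles


def fraction_recovered(
    sample: PopulationSample,
    t_removal: float,
    t_after_removal: float,
    floor: float,
    confidence: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Fraction of baseline protein recovered at a time after removal.

    Per cell: (normalized signal at t - floor) / (1 - floor), clipped at 0,
    evaluated at the grid sample nearest to ``t_removal + t_after_removal``.
    Returns the cohort mean and a t-based CI across cells.
    """
    if t_after_removal < 0:
        raise ValueError("t_after_removal must be >= 0")
    t_eval = t_removal + t_after_removal
    fracs = []
    for traj in sample:
        if t_eval > traj.times[-1]:
            raise ValueError("evaluation time beyond the trajectory horizon")
        i = int(np.argmin(np.abs(traj.times - t_eval)))
        fracs.append(max((traj.signal[i] - floor) / (1.0 - floor), 0.0))
    fracs = np.asarray(fracs)
    mean = float(fracs.mean())
    if fracs.size > 1:
        sem = fracs.std(ddof=1) / np.sqrt(fracs.size)
        tq = stats.t.ppf(0.5 + confidence / 2, df=fracs.size - 1)
        ci = (mean - tq * sem, mean + tq * sem)
    else:
        ci = (mean, mean)
    return mean, ci


def time_to_full_recovery(
    sample: PopulationSample,
    t_removal: float,
    band: tuple[float, float] = (0.95, 1.05),
) -> float | None:
    """Minutes after removal until the cohort mean re-enters the baseline band.

    A cohort whose mean is already inside the band at removal returns 0;
    returns None if the band is never reached within the horizon.
    """
    times, mean = mean_trace(sample)
    mask = times >= t_removal
    inside = (mean[mask] >= band[0]) & (mean[mask] <= band[1])
    if not inside.any():
        return None
    return float(times[mask][int(np.argmax(inside))] - t_removal)


def minimum_pulse_for_depletion(
    samples_by_duration: dict[float, PopulationSample],
    t_add: float,
    band: tuple[float, float],
    lam: float | None = None,
) -> float | None:
    """Shortest auxin pulse achieving complete cohort depletion.

    A pulse counts as complete when the cohort mean of per-cell nadirs
    (the minimum of each cell's smoothed normalized trace after auxin
    addition) lies inside the floor band.  The per-cell nadir is used
    because onset delays desynchronize the cells: each cell's deepest
    depletion, not the pointwise cohort mean, measures completeness.
    Returns None when no tested pulse reaches the band.
    """
    if len(samples_by_duration) < 2:
        raise ValueError("need at least 2 pulse durations")
    complete = []
    for duration, sample in samples_by_duration.items():
        nadirs = []
        for traj in sample:
            smooth = fit_smoothing_spline(traj, lam=lam)
            mask = traj.times >= t_add
            nadirs.append(float(np.min(smooth.smooth_values[mask])))
        if float(np.mean(nadirs)) <= band[1]:
            complete.append(duration)
    return min(complete) if complete else None
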