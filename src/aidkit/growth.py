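"""Single-cell growth rates, recovery fits, and group comparisons.

Growth is quantified per budding cycle: the single-cell doubling time
DT_sc is the interval between consecutive budding events and the growth
rate is GR_sc = ln(2) / DT_sc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GrowthRecord",
    "RecoveryFit",
    "growth_rates_from_budding",
    "pool_growth_rates",
    "fit_growth_recovery",
    "time_to_plateau",
    "compare_groups",
    "growth_reduction_summary",
    "significance_stars",
]

LN2 = math.log(2.0)


@dataclass
class GrowthRecord:
    """Per-cycle doubling times and growth rates of one cell.

    ``times`` are the midpoints of each budding interval, used as the time
    registration when fitting recovery curves.
    """

    cell_id: str
    doubling_times: np.ndarray
    growth_rates: np.ndarray
    times: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.doubling_times = np.asarray(self.doubling_times, dtype=float)
        self.growth_rates = np.asarray(self.growth_rates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.doubling_times <= 0):
            raise ValueError("doubling times must be > 0")

    @property
    def n_cycles(self) -> int:
        return self.doubling_times.size


@dataclass
class RecoveryFit:
    """One-phase exponential association fit of recovering growth rates.

    GR(t) = plateau + (y0 - plateau) e^{-K t} with the plateau fixed to
    the mean growth rate of unperturbed control cells.
    """

    K: float
    K_se: float
    y0: float
    plateau: float
    rss: float
    converged: bool = True
    message: str = ""

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.plateau + (self.y0 - self.plateau) * np.exp(-self.K * t)


def growth_rates_from_budding(
    budding_times, cell_id: str = "cell", condition: str = ""
) -> GrowthRecord:
    """Per-cycle DT/GR pairs from consecutive budding events.

    Fewer than two events yield an empty record.
    """
    b = np.sort(np.asarray(budding_times, dtype=float))
    if b.size < 2:
        return GrowthRecord(cell_id, np.empty(0), np.empty(0), np.empty(0), condition)
    dt = np.diff(b)
    if np.any(dt <= 0):
        raise ValueError("budding events must be distinct")
    return GrowthRecord(
        cell_id=cell_id,
        doubling_times=dt,
        growth_rates=LN2 / dt,
        times=0.5 * (b[:-1] + b[1:]),
        condition=condition,
    )


def pool_growth_rates(records) -> pd.DataFrame:
    """Pool per-cycle growth rates across cells into one long frame."""
    rows = []
    for rec in records:
        for t, dt, gr in zip(rec.times, rec.doubling_times, rec.growth_rates):
            rows.append({
                "cell_id": rec.cell_id,
                "condition": rec.condition,
                "time_min": t,
                "dt_min": dt,
                "gr_per_min": gr,
            })
    return pd.DataFrame(rows, columns=["cell_id", "condition", "time_min", "dt_min", "gr_per_min"])


def fit_growth_recovery(times, growth_rates, plateau: float) -> RecoveryFit:
    """Least-squares one-phase association with a fixed plateau.

    Flags (rather than fails on) degenerate data: non-convergence or a
    start already at the plateau, where K is unidentifiable.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(growth_rates, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")

    def model(tt, y0, k):
        return plateau + (y0 - plateau) * np.exp(-k * tt)

    p0 = (float(y[np.argmin(t)]), 0.005)
    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=p0,
            bounds=([-np.inf, 1e-8], [np.inf, 1.0]),
            maxfev=20000,
        )
    except RuntimeError as err:
        return RecoveryFit(np.nan, np.nan, np.nan, plateau, np.inf,
                           converged=False, message=str(err))
    y0, k = (float(v) for v in popt)
    k_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    rss = float(np.sum((model(t, *popt) - y) ** 2))
    fit = RecoveryFit(k, k_se, y0, plateau, rss)
    if abs(y0 - plateau) < 0.02 * abs(plateau):
        fit.converged = False
        fit.message = "data start at the plateau; K unidentifiable"
    return fit


def time_to_plateau(fit: RecoveryFit, frac: float = 0.05) -> float:
    """Time at which the fitted curve is within ``frac`` of the plateau."""
    gap = abs(fit.y0 - fit.plateau)
    target = frac * abs(fit.plateau)
    if gap <= target:
        return 0.0
    return math.log(gap / target) / fit.K


def _dunn_all_pairs(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post-test on pooled ranks with tie correction and Bonferroni
    adjustment over all pairs."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks, sizes, i0 = {}, {}, 0
    for g in names:
        n = groups[g].size
        mean_ranks[g] = float(ranks[i0:i0 + n].mean())
        sizes[g] = n
        i0 += n

    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = min(2.0 * stats.norm.sf(abs(z)) * m, 1.0)
        rows.append({
            "group_a": a, "group_b": b, "z": z,
            "p_adjusted": p, "stars": significance_stars(p),
        })
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(growth_rates_by_group: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis omnibus test with Dunn's all-pairs post-test.

    ``growth_rates_by_group`` maps condition labels to pooled per-cycle
    growth rates; each group needs at least 3 cycles.
    """
    if len(growth_rates_by_group) < 2:
        raise ValueError("need at least 2 groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in growth_rates_by_group.items()}
    for name, vals in groups.items():
        if vals.size < 3:
            raise ValueError(f"group {name!r} needs at least 3 cycles")
    if all(np.array_equal(v, next(iter(groups.values()))) for v in groups.values()):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups.values())
    return {
        "kruskal_h": float(h),
        "kruskal_p": float(p),
        "pairwise": _dunn_all_pairs(groups),
    }


def growth_reduction_summary(
    growth_rates_by_condition: dict[str, np.ndarray],
    reference: str,
) -> dict[str, float]:
    """Percent reduction of mean growth rate relative to a reference group."""
    if reference not in growth_rates_by_condition:
        raise ValueError(f"reference group {reference!r} missing")
    ref = np.asarray(growth_rates_by_condition[reference], dtype=float)
    if ref.size == 0 or ref.mean() == 0:
        raise ValueError("reference group empty or zero")
    out = {}
    for name, vals in growth_rates_by_condition.items():
        vals = np.asarray(vals, dtype=float)
        out[name] = 100.0 * (1.0 - vals.mean() / ref.mean())
    return out
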