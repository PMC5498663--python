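"""End-to-end experiment recipes: simulate a cohort, run the estimators.

These functions reproduce the study designs the estimators were built
for -- step depletion at a given dose, the wild-type/reporter floor
calibration, auxin pulses with recovery, and growth-rate comparisons --
and are shared by the command-line ``report`` command and the acceptance
checks.  Auxin is added at 240 min by convention, so the standard
before-depletion [0, 240] and after-depletion [500, 740] windows apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import depletion, growth, recovery
from .config import AuxinSchedule, Segment, SimConfig
from .preprocess import normalize_baseline
from .trajectory import PopulationSample
from .simulate import (
    _as_seedseq,
    simulate_autofluorescence_cells,
    simulate_experiment,
)

__all__ = [
    "RunConfig",
    "step_schedule",
    "pulse_schedule",
    "growth_schedule",
    "normalized",
    "run_floor_experiment",
    "run_depletion_experiment",
    "run_pulse_experiment",
    "run_mother_daughter_experiment",
    "run_growth_experiment",
    "run_growth_recovery_experiment",
    "run_report",
]

T_ADD = 240.0


@dataclass
class RunConfig:
    """Windows, sizes, seeds and flags of one full analysis run."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    t_add: float = T_ADD
    before_window: tuple[float, float] = (0.0, 240.0)
    after_window: tuple[float, float] = (500.0, 740.0)
    n_boot_floor: int = 100
    n_boot_slope: int = 1000
    n_depletion_cells: int = 20
    n_wildtype_cells: int = 13
    n_reporter_cells: int = 15
    n_recovery_cells: int = 19
    n_growth_cells: int = 20
    pulse_durations: tuple[float, ...] = (10.0, 20.0, 120.0)
    pulse_conc: float = 0.5
    through_origin: bool = True
    smoothing_lam: float | None = None

    def __post_init__(self) -> None:
        if self.n_boot_floor < 1 or self.n_boot_slope < 1:
            raise ValueError("bootstrap iteration counts must be >= 1")
        if self.before_window[1] > self.after_window[0]:
            raise ValueError("before/after windows must not overlap")


def step_schedule(
    conc_mM: float,
    t_add: float = T_ADD,
    t_end: float = 740.0,
    delivery: str = "instant",
    compound: str = "IAA",
    ph: float = 5.1,
    light_on: bool = True,
    schedule_id: str | None = None,
) -> AuxinSchedule:
    """Step exposure: auxin from t_add to the end of the experiment."""
    segs = () if conc_mM == 0 else (Segment(t_add, t_end, conc_mM, compound),)
    return AuxinSchedule(
        segments=segs, delivery=delivery, ph=ph, light_on=light_on, t_end=t_end,
        schedule_id=schedule_id or f"step_{compound}_{conc_mM:g}mM",
    )


def pulse_schedule(
    pulse_min: float,
    conc_mM: float = 0.5,
    t_add: float = T_ADD,
    t_end: float = 2880.0,
    delivery: str = "fast",
    compound: str = "IAA",
) -> AuxinSchedule:
    """Auxin pulse of a given duration followed by recovery medium."""
    return AuxinSchedule(
        segments=(Segment(t_add, t_add + pulse_min, conc_mM, compound),),
        delivery=delivery, t_end=t_end,
        schedule_id=f"pulse_{pulse_min:g}min_{conc_mM:g}mM",
    )


def growth_schedule(
    conc_mM: float,
    compound: str = "IAA",
    light_on: bool = True,
    t_end: float = 720.0,
) -> AuxinSchedule:
    """Constant-condition growth experiment from t = 0."""
    segs = () if conc_mM == 0 else (Segment(0.0, t_end, conc_mM, compound),)
    label = "control" if conc_mM == 0 else f"{compound}_{conc_mM:g}mM"
    return AuxinSchedule(
        segments=segs, light_on=light_on, t_end=t_end,
        schedule_id=f"growth_{label}{'_light' if light_on else '_dark'}",
    )


def normalized(sample: PopulationSample, window=(0.0, 240.0)) -> PopulationSample:
    return sample.map_signal(lambda t: normalize_baseline(t, window))


def run_floor_experiment(cfg: RunConfig, seed=None) -> depletion.FloorEstimate:
    """Wild-type / reporter floor calibration with a bootstrap CI.

    Simulates non-fluorescent and pre-depletion reporter cohorts over the
    baseline window and takes the bootstrap ratio of group mean signals.
    """
    ss = _as_seedseq(self_seed(cfg, seed))
    s_wt, s_rep, s_boot = ss.spawn(3)
    wt = simulate_autofluorescence_cells(
        cfg.sim, cfg.n_wildtype_cells, seed=s_wt, t_end=cfg.before_window[1]
    )
    rep = simulate_experiment(
        cfg.sim, step_schedule(0.0, t_end=cfg.before_window[1]),
        n_mothers=cfg.n_reporter_cells, seed=s_rep,
    )
    wt_means = [float(t.signal.mean()) for t in wt]
    rep_means = [float(t.signal.mean()) for t in rep]
    return depletion.estimate_floor(
        wt_means, rep_means, n_boot=cfg.n_boot_floor,
        rng=np.random.default_rng(s_boot),
    )


def run_depletion_experiment(
    cfg: RunConfig,
    conc_mM: float,
    seed=None,
    n_mothers: int | None = None,
    n_daughters: int = 0,
    delivery: str = "instant",
    t_end: float = 740.0,
) -> PopulationSample:
    """Simulate a step-depletion cohort and return it baseline-normalized."""
    sample = simulate_experiment(
        cfg.sim,
        step_schedule(conc_mM, t_add=cfg.t_add, t_end=t_end, delivery=delivery),
        n_mothers=n_mothers if n_mothers is not None else cfg.n_depletion_cells,
        n_daughters=n_daughters,
        seed=self_seed(cfg, seed),
    )
    return normalized(sample, cfg.before_window)


def run_pulse_experiment(
    cfg: RunConfig,
    pulse_min: float,
    seed=None,
    n_cells: int | None = None,
    t_end: float = 2880.0,
) -> PopulationSample:
    """Simulate an auxin-pulse recovery cohort, baseline-normalized."""
    sample = simulate_experiment(
        cfg.sim,
        pulse_schedule(pulse_min, conc_mM=cfg.pulse_conc, t_add=cfg.t_add, t_end=t_end),
        n_mothers=n_cells if n_cells is not None else cfg.n_recovery_cells,
        seed=self_seed(cfg, seed),
    )
    return normalized(sample, cfg.before_window)


def run_mother_daughter_experiment(
    cfg: RunConfig,
    seed=None,
    n_mothers: int = 21,
    n_daughters: int = 7,
    conc_mM: float = 0.5,
) -> dict:
    """Mother/daughter depletion-delay comparison at saturating auxin."""
    sample = simulate_experiment(
        cfg.sim,
        step_schedule(conc_mM, t_add=cfg.t_add),
        n_mothers=n_mothers, n_daughters=n_daughters,
        seed=self_seed(cfg, seed),
    )
    sample = normalized(sample, cfg.before_window)
    return depletion.compare_mother_daughter(
        sample, cfg.t_add, floor=cfg.sim.af_floor
    )


def _pooled_growth(sample: PopulationSample, condition: str) -> np.ndarray:
    records = [
        growth.growth_rates_from_budding(t.budding_times, t.cell_id, condition)
        for t in sample
    ]
    pooled = growth.pool_growth_rates(records)
    return pooled["gr_per_min"].to_numpy()


def run_growth_experiment(
    cfg: RunConfig,
    conditions: dict[str, AuxinSchedule],
    seed=None,
    n_cells: int | None = None,
) -> dict[str, np.ndarray]:
    """Pooled per-cycle growth rates for each named condition."""
    n = n_cells if n_cells is not None else cfg.n_growth_cells
    ss = _as_seedseq(self_seed(cfg, seed))
    out = {}
    for (name, schedule), s in zip(conditions.items(), ss.spawn(len(conditions))):
        sample = simulate_experiment(cfg.sim, schedule, n_mothers=n, seed=s)
        out[name] = _pooled_growth(sample, name)
    return out


def run_growth_recovery_experiment(
    cfg: RunConfig,
    seed=None,
    n_cells: int = 24,
    conc_mM: float = 0.1,
    t_removal: float = 240.0,
    t_end: float = 1440.0,
) -> growth.RecoveryFit:
    """Growth-rate recovery after auxin removal, fitted against a control
    plateau measured in an unperturbed cohort."""
    ss = _as_seedseq(self_seed(cfg, seed))
    s_ctrl, s_rec = ss.spawn(2)
    ctrl = simulate_experiment(
        cfg.sim, growth_schedule(0.0, t_end=t_end), n_mothers=n_cells, seed=s_ctrl
    )
    plateau = float(np.mean(_pooled_growth(ctrl, "control")))

    schedule = AuxinSchedule(
        segments=(Segment(0.0, t_removal, conc_mM, "IAA"),),
        light_on=True, t_end=t_end,
        schedule_id=f"growth_recovery_{conc_mM:g}mM",
    )
    sample = simulate_experiment(cfg.sim, schedule, n_mothers=n_cells, seed=s_rec)
    times, grs = [], []
    for traj in sample:
        rec = growth.growth_rates_from_budding(traj.budding_times, traj.cell_id)
        mask = rec.times >= t_removal
        times.extend(rec.times[mask] - t_removal)
        grs.extend(rec.growth_rates[mask])
    return growth.fit_growth_recovery(np.asarray(times), np.asarray(grs), plateau)


def self_seed(cfg: RunConfig, seed) -> int:
    return cfg.seed if seed is None else seed


def run_report(cfg: RunConfig) -> dict:
    """Full simulated study: floor, depletion, recovery, dilution, growth.

    Returns a JSON-serializable summary; deterministic for a fixed seed.
    """
    if cfg.n_depletion_cells < 1 or cfg.n_recovery_cells < 1:
        raise ValueError("empty cohort")
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.spawn(8)

    floor = run_floor_experiment(cfg, seed=seeds[0])

    sat = run_depletion_experiment(cfg, 0.5, seed=seeds[1])
    band = depletion.floor_band(
        floor.mean_ratio, cfg.sim.noise_cv * floor.mean_ratio
    )
    ttf = [depletion.time_to_floor(t, cfg.t_add, band) for t in sat]
    ttf = [t for t in ttf if t is not None]
    completeness, completeness_ci, _ = depletion.cohort_completeness(
        sat, cfg.before_window, cfg.after_window
    )

    pulses = {
        d: run_pulse_experiment(cfg, d, seed=s)
        for d, s in zip(cfg.pulse_durations, seeds[2].spawn(len(cfg.pulse_durations)))
    }
    min_pulse = recovery.minimum_pulse_for_depletion(
        pulses, cfg.t_add, band, lam=cfg.smoothing_lam
    )
    longest = pulses[max(cfg.pulse_durations)]
    t_removal = cfg.t_add + max(cfg.pulse_durations)
    frac60, frac60_ci = recovery.fraction_recovered(
        longest, t_removal, 60.0, floor.mean_ratio
    )
    t_full = recovery.time_to_full_recovery(longest, t_removal)
    dil_est, cycles = recovery.estimate_dilution(
        longest, floor.mean_ratio, t_removal,
        n_boot=cfg.n_boot_slope, rng=np.random.default_rng(seeds[3]),
        max_cycles=5, through_origin=cfg.through_origin, lam=cfg.smoothing_lam,
    )

    md = run_mother_daughter_experiment(cfg, seed=seeds[4])

    rates = run_growth_experiment(cfg, {
        "control": growth_schedule(0.0),
        "IAA_0.0005mM_light": growth_schedule(0.0005),
    }, seed=seeds[5])
    reduction = growth.growth_reduction_summary(rates, "control")
    rec_fit = run_growth_recovery_experiment(cfg, seed=seeds[6])

    return {
        "seed": cfg.seed,
        "floor": {
            "mean_ratio": floor.mean_ratio,
            "ci95": [floor.ci95_low, floor.ci95_high],
            "n_boot": floor.n_boot,
        },
        "depletion": {
            "mean_time_to_floor_min": float(np.mean(ttf)) if ttf else None,
            "n_cells_reaching_floor": len(ttf),
            "completeness_ratio": completeness,
            "completeness_ci95": list(completeness_ci),
        },
        "recovery": {
            "min_pulse_min": min_pulse,
            "fraction_recovered_60min": frac60,
            "fraction_recovered_ci95": list(frac60_ci),
            "time_to_full_recovery_min": t_full,
        },
        "dilution": {
            "slope": dil_est.slope,
            "slope_ci95": list(dil_est.slope_ci95),
            "dil": dil_est.dil,
            "dil_ci95": list(dil_est.dil_ci95),
            "n_oscillations": dil_est.n_oscillations,
            "n_cells": dil_est.n_cells,
        },
        "mother_daughter": {
            "median_delay_min": md["median_delay_min"],
            "p_value": md["p_value"],
        },
        "growth": {
            "reduction_pct": {k: v for k, v in reduction.items() if k != "control"},
            "recovery_K_per_min": rec_fit.K,
            "recovery_time_to_plateau_min": growth.time_to_plateau(rec_fit),
        },
    }
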