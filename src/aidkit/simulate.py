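"""Forward simulator of single-cell degron reporter trajectories.

Between divisions the protein concentration C obeys the linear ODE

    dC/dt = k_syn_max * (1 - C / c_cap) - k_deg(A_eff(t - tau)) * C

which is solved in closed form on every interval of constant coefficients
(lambda = k_syn_max / c_cap + k_deg, C_inf = k_syn_max / lambda).  Each
division divides C by the dilution factor.  The emitted signal is

    (af_floor + (1 - af_floor) * C) * lognormal noise

sampled on a fixed grid.  Auxin reaches each cell after a dose-dependent
random onset delay tau (plus a fixed extra delay for newborn daughters):
the delay models slow uptake/accumulation, so it postpones the start of
degradation but not its end -- degradation ceases as soon as external
auxin is withdrawn (protein recovery begins almost immediately after a
medium switch).  The medium pH rescales the effective auxin concentration
through the protonated (membrane-permeant) fraction of the acid.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .config import AuxinSchedule, Segment, SimConfig
from .trajectory import PopulationSample, Trajectory

__all__ = [
    "effective_auxin",
    "degradation_rate",
    "growth_reduction",
    "auxin_profile",
    "cycle_fixed_point",
    "simulate_cell",
    "simulate_experiment",
    "simulate_autofluorescence_cells",
]

# sub-step (min) used inside concentration ramps, where the piecewise
# constant-coefficient closed form is only a midpoint approximation
_RAMP_SUBSTEP = 0.5


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def effective_auxin(conc_mM: float, ph: float, config: SimConfig) -> float:
    """Auxin concentration corrected for pH-dependent uptake.

    Only the protonated acid crosses the membrane efficiently, so the
    effective concentration is rescaled by the Henderson-Hasselbalch
    protonated fraction f(pH) = 1 / (1 + 10^(pH - pKa)) relative to the
    reference pH: at ``ph_ref`` the concentration is returned unchanged,
    and raising the pH strictly lowers it.
    """
    conc = np.asarray(conc_mM, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    if not 0 < ph < 14:
        raise ValueError("ph must lie in (0, 14)")
    f = lambda p: 1.0 / (1.0 + 10.0 ** (p - config.pka_iaa))
    out = conc * (f(ph) / f(config.ph_ref))
    return float(out) if np.isscalar(conc_mM) else out


def degradation_rate(eff_conc_mM: float, config: SimConfig) -> float:
    """Hill dose response of the degradation rate constant (min^-1)."""
    a = np.asarray(eff_conc_mM, dtype=float)
    if np.any(a < 0):
        raise ValueError("concentration must be >= 0")
    ah = a ** config.hill_h
    out = config.k_deg_max * ah / (config.ec50_deg ** config.hill_h + ah)
    return float(out) if np.isscalar(eff_conc_mM) else out


def growth_reduction(conc_mM: float, light_on: bool, compound: str, config: SimConfig) -> float:
    """Fractional growth-rate reduction caused by auxin in [0, 1).

    IAA photo-degrades under blue (GFP excitation) light into cytotoxic
    derivatives, so the defect saturates at ``photo_r_max`` under light and
    at the weaker ``dark_r_max`` without it.  NAA, the indole-free
    substitute, causes no growth defect.
    """
    if compound not in ("IAA", "NAA"):
        raise ValueError(f"unknown compound {compound!r}")
    if conc_mM < 0:
        raise ValueError("concentration must be >= 0")
    if conc_mM == 0 or compound == "NAA":
        return 0.0
    if light_on:
        return config.photo_r_max * conc_mM / (config.photo_a50 + conc_mM)
    return config.dark_r_max * conc_mM / (config.dark_a50 + conc_mM)


def auxin_profile(schedule: AuxinSchedule, t_min, config: SimConfig | None = None):
    """Concentration seen by the cells at time ``t_min`` (vectorized).

    Instant delivery is an ideal step; fast delivery a 3.5-min linear
    ramp at each transition; pump delivery shifts the whole program by
    the realized delivery lag and ramps over 10 min.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any((t < 0) | (t > schedule.t_end)):
        raise ValueError("time outside the experiment horizon")
    lag, ramp = schedule.lag, schedule.ramp
    conc = np.zeros_like(t)
    for seg in schedule.segments:
        s, e = seg.start_min + lag, seg.end_min + lag
        if ramp == 0:
            c = np.where((t >= s) & (t < e), seg.conc_mM, 0.0)
        else:
            up = np.clip((t - s) / ramp, 0.0, 1.0)
            down = np.clip((t - e) / ramp, 0.0, 1.0)
            c = seg.conc_mM * (up - down)
        conc = np.maximum(conc, c)
    return float(conc) if t.ndim == 0 else conc


def cycle_fixed_point(config: SimConfig, t_div: float | None = None) -> tuple[float, float]:
    """(MIN*, MAX*) of the periodic no-auxin division cycle.

    With synthesis k_syn_max (1 - C/c_cap) between divisions and a
    dil_factor drop at each division, the post-division concentration
    fixed point is MIN* = c_cap (1 - e^{-kT}) / (dil - e^{-kT}) with
    k = k_syn_max / c_cap; MAX* = dil * MIN*.
    """
    T = config.t_div_median if t_div is None else t_div
    k = config.k_syn_max / config.c_cap if config.c_cap > 0 else 0.0
    if k == 0.0:
        return 0.0, 0.0
    e = math.exp(-k * T)
    min_star = config.c_cap * (1.0 - e) / (config.dil_factor - e)
    return min_star, config.dil_factor * min_star


def _reduction_at(t: float, schedule: AuxinSchedule, config: SimConfig) -> float:
    """Growth-rate reduction at time t, relaxing after each exposure.

    While a segment is active the reduction is its dose response; after it
    ends the defect decays exponentially at ``growth_recovery_k``.  The
    maximum over segments is taken.
    """
    lag = schedule.lag
    r = 0.0
    for seg in schedule.segments:
        s, e = seg.start_min + lag, seg.end_min + lag
        if t < s:
            continue
        r_seg = growth_reduction(seg.conc_mM, schedule.light_on, seg.compound, config)
        if t < e:
            r = max(r, r_seg)
        else:
            r = max(r, r_seg * math.exp(-config.growth_recovery_k * (t - e)))
    return r


def _draw_interval(t_now: float, schedule: AuxinSchedule, config: SimConfig, rng) -> float:
    """Draw one inter-budding interval (lognormal, growth-adjusted median)."""
    r = _reduction_at(t_now, schedule, config)
    median = config.t_div_median / max(1.0 - r, 1e-6)
    sigma = math.sqrt(math.log(1.0 + config.t_div_cv ** 2))
    return float(rng.lognormal(math.log(median), sigma))


def _onset_delay(schedule: AuxinSchedule, role: str, config: SimConfig, rng) -> float:
    a = schedule.max_concentration()
    if a == 0:
        return 0.0
    mean = config.onset_m_max * config.onset_ec50 / (a + config.onset_ec50)
    tau = float(rng.gamma(2.0, mean / 2.0)) if mean > 0 else 0.0
    if role == "daughter":
        tau += config.daughter_delay
    return tau


def _auxin_breakpoints(schedule: AuxinSchedule, tau: float) -> list[float]:
    """Times at which the (onset-delayed) degradation input changes regime."""
    lag, ramp = schedule.lag, schedule.ramp
    pts: list[float] = []
    for seg in schedule.segments:
        for edge in (seg.start_min + lag, seg.end_min + lag):
            for shift in (0.0, tau):
                pts.append(edge + shift)
                if ramp > 0:
                    # subdivide the ramp for the midpoint approximation
                    n = max(1, int(math.ceil(ramp / _RAMP_SUBSTEP)))
                    pts.extend(edge + shift + ramp * i / n for i in range(1, n + 1))
    return pts


def simulate_cell(
    config: SimConfig,
    schedule: AuxinSchedule,
    role: str = "mother",
    rng=None,
    cell_id: str = "cell",
    t_start: float = 0.0,
    initial_c: float | None = None,
    initial_phase: float | None = None,
) -> Trajectory:
    """Simulate one cell's fluorescence trajectory under a schedule.

    Mothers start at a uniformly random phase of the periodic no-auxin
    cycle; daughters (or ``initial_phase=0``) start freshly divided at
    MIN*.  ``t_start`` is the birth / tracking-start time; samples are
    emitted on the global grid from the first grid point >= t_start to the
    schedule horizon.
    """
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    dt = config.sample_period
    horizon = schedule.t_end

    k_syn = config.k_syn_max
    k_dil = k_syn / config.c_cap if config.c_cap > 0 else 0.0
    min_star, _ = cycle_fixed_point(config)

    # initial phase and concentration on the baseline periodic orbit
    if initial_phase is None:
        phase = 0.0 if role == "daughter" else float(rng.uniform(0.0, 1.0))
    else:
        phase = float(initial_phase)
    if initial_c is None:
        c = config.c_cap + (min_star - config.c_cap) * math.exp(
            -k_dil * phase * config.t_div_median
        ) if k_dil > 0 else 0.0
    else:
        c = float(initial_c)

    # division (budding) event times
    divisions: list[float] = []
    t_next = t_start + (1.0 - phase) * _draw_interval(t_start, schedule, config, rng)
    while t_next <= horizon:
        divisions.append(t_next)
        t_next += _draw_interval(t_next, schedule, config, rng)

    tau = _onset_delay(schedule, role, config, rng)

    # sample grid
    first = math.ceil(round(t_start / dt, 9)) * dt
    times = np.arange(first, horizon + dt / 2, dt)
    if times.size == 0:
        raise ValueError("no sample times within the horizon")

    # merged event grid: samples, divisions, degradation-input breakpoints
    events: dict[float, int] = {}  # time -> bitmask: 1 sample, 2 division
    for t in times:
        events[round(float(t), 9)] = events.get(round(float(t), 9), 0) | 1
    for d in divisions:
        key = round(float(d), 9)
        events[key] = events.get(key, 0) | 2
    for b in _auxin_breakpoints(schedule, tau):
        if t_start < b < horizon:
            key = round(float(b), 9)
            events.setdefault(key, 0)
    grid = sorted(t for t in events if t_start <= t <= horizon)

    def kdeg_at(t: float) -> float:
        # onset-only delay: accumulation lags by tau, washout is immediate
        t_delayed = min(max(t - tau, 0.0), horizon)
        a = min(auxin_profile(schedule, t_delayed),
                auxin_profile(schedule, min(max(t, 0.0), horizon)))
        return degradation_rate(effective_auxin(a, schedule.ph, config), config)

    c_samples = np.empty(times.size)
    i_sample = 0
    t_prev = t_start
    for t in grid:
        if t > t_prev:
            kd = kdeg_at(0.5 * (t_prev + t))
            lam = k_dil + kd
            if lam > 0:
                c_inf = k_syn / lam
                c = c_inf + (c - c_inf) * math.exp(-lam * (t - t_prev))
            else:
                c = c + k_syn * (t - t_prev)
            t_prev = t
        mask = events.get(t, 0)
        if mask & 1:
            c_samples[i_sample] = c
            i_sample += 1
        if mask & 2:
            c /= config.dil_factor
    assert i_sample == times.size

    signal = config.af_floor + (1.0 - config.af_floor) * c_samples
    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2))
        signal = signal * rng.lognormal(-0.5 * sigma ** 2, sigma, size=signal.shape)

    budding = np.unique(np.round(np.asarray(divisions) / dt) * dt) if divisions else np.empty(0)
    budding = budding[(budding >= times[0]) & (budding <= times[-1])]

    return Trajectory(
        cell_id=cell_id,
        role=role,
        times=times,
        signal=np.maximum(signal, 0.0),
        budding_times=budding,
        schedule_id=schedule.schedule_id,
        schedule=schedule,
    )


def simulate_experiment(
    config: SimConfig,
    schedule: AuxinSchedule,
    n_mothers: int,
    n_daughters: int = 0,
    seed=None,
) -> PopulationSample:
    """Simulate an independent cohort sharing one schedule.

    Daughters are born one sample period before auxin arrival (newborns
    observed just prior to auxin appearance); with no auxin they are
    tracked from t = 0.  Reproducible for a fixed seed.
    """
    if n_mothers + n_daughters < 1:
        raise ValueError("need at least one cell")
    ss = _as_seedseq(seed if seed is not None else config.seed)
    exp_ss, *cell_ss = ss.spawn(1 + n_mothers + n_daughters)
    schedule = schedule.with_pump_lag(np.random.default_rng(exp_ss))

    arrival = schedule.arrival_time()
    t_birth = max(0.0, arrival - config.sample_period) if arrival is not None else 0.0

    cells: list[Trajectory] = []
    for i in range(n_mothers):
        cells.append(simulate_cell(
            config, schedule, role="mother",
            rng=np.random.default_rng(cell_ss[i]),
            cell_id=f"mother_{i:03d}",
        ))
    for j in range(n_daughters):
        cells.append(simulate_cell(
            config, schedule, role="daughter",
            rng=np.random.default_rng(cell_ss[n_mothers + j]),
            cell_id=f"daughter_{j:03d}",
            t_start=t_birth,
        ))
    return PopulationSample(cells, config=config, schedule=schedule)


def simulate_autofluorescence_cells(
    config: SimConfig,
    n_cells: int,
    seed=None,
    t_end: float = 240.0,
) -> PopulationSample:
    """Simulate non-fluorescent (wild-type) cells: autofluorescence only.

    Implemented as reporter cells with zero synthesis and zero initial
    protein, so the emitted signal is the autofluorescence floor times
    measurement noise.
    """
    wt_config = config.with_(k_syn_max=0.0)
    schedule = AuxinSchedule(segments=(), t_end=t_end, schedule_id="wildtype")
    ss = _as_seedseq(seed if seed is not None else config.seed)
    cells = [
        simulate_cell(
            wt_config, schedule, role="mother",
            rng=np.random.default_rng(s),
            cell_id=f"wt_{i:03d}", initial_c=0.0,
        )
        for i, s in enumerate(ss.spawn(n_cells))
    ]
    return PopulationSample(cells, config=wt_config, schedule=schedule)
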