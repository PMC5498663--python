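"""Simulation configuration and auxin delivery schedules.

The forward model describes a fluorescent degron reporter (mGFP-AID) in
budding yeast: auxin triggers TIR1-mediated degradation of the tagged
protein, cell divisions dilute it, and synthesis restores it after auxin
removal.  All times are minutes from acquisition start, concentrations in
mM, and signals in baseline-normalized fluorescence units where the
pre-depletion cycle average is ~1 and cellular autofluorescence sits at
``af_floor``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = ["SimConfig", "Segment", "AuxinSchedule", "FAST_RAMP_MIN", "PUMP_RAMP_MIN"]

#: Duration of the linear concentration ramp for a fast medium switch
#: (complete switch within 3-4 minutes; the midpoint is used).
FAST_RAMP_MIN = 3.5

#: Ramp duration following the syringe-pump delivery lag.
PUMP_RAMP_MIN = 10.0

COMPOUNDS = ("IAA", "NAA")
DELIVERIES = ("instant", "fast", "pump")


@dataclass(frozen=True)
class SimConfig:
    """Kinetic, noise and delivery parameters of the single-cell forward model.

    Defaults are calibrated so that, on a 100-min division cycle with a
    1.2-fold per-division dilution, the no-auxin protein concentration has a
    periodic steady state with cycle average ~1.0, recovery from complete
    depletion reaches ~20% of baseline within 60 min, and saturating auxin
    (>= 0.25 mM) drives the signal into the autofluorescence floor band
    within tens of minutes.

    Parameters
    ----------
    k_deg_max
        Maximal auxin-induced degradation rate constant (min^-1).
    ec50_deg
        Auxin concentration of half-maximal degradation (mM).
    hill_h
        Hill coefficient of the degradation dose response.
    k_syn_max
        Maximal protein synthesis rate (normalized concentration / min).
    c_cap
        Synthesis-repression capacity: synthesis is
        ``k_syn_max * (1 - C / c_cap)``.
    dil_factor
        Fold drop of protein concentration at each division (>= 1).
    t_div_median, t_div_cv
        Median and CV of the lognormal inter-budding interval (min).
    af_floor
        Autofluorescence level in normalized signal units (ratio of
        wild-type autofluorescence to pre-depletion reporter signal).
    noise_cv
        CV of multiplicative (lognormal, mean-1) measurement noise.
    pka_iaa, ph_ref
        Acid dissociation constant of the auxin and reference medium pH;
        auxin uptake scales with its protonated fraction.
    onset_m_max, onset_ec50
        Dose dependence of the per-cell depletion onset delay: the Gamma
        (shape 2) delay has mean ``onset_m_max * onset_ec50 / (A + onset_ec50)``.
    daughter_delay
        Extra onset delay of newborn daughter cells (min).
    photo_r_max, photo_a50
        Saturating growth-rate reduction for IAA combined with GFP
        excitation light (fraction, mM).
    dark_r_max, dark_a50
        Weaker growth-rate reduction for IAA without excitation light.
    growth_recovery_k
        Exponential rate at which the growth defect relaxes after auxin
        removal (min^-1).
    sample_period
        Fluorescence sampling period (min).
    seed
        Default RNG seed for simulations (overridable per call).
    """

    k_deg_max: float = 0.25
    ec50_deg: float = 0.05
    hill_h: float = 2.0
    k_syn_max: float = 0.00333
    c_cap: float = 2.24
    dil_factor: float = 1.2
    t_div_median: float = 100.0
    t_div_cv: float = 0.15
    af_floor: float = 0.288
    noise_cv: float = 0.05
    pka_iaa: float = 4.75
    ph_ref: float = 5.1
    onset_m_max: float = 60.0
    onset_ec50: float = 0.04
    daughter_delay: float = 20.0
    photo_r_max: float = 0.7
    photo_a50: float = 0.0005
    dark_r_max: float = 0.3
    dark_a50: float = 0.3
    growth_recovery_k: float = 0.006
    sample_period: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        rates = (
            "k_deg_max", "ec50_deg", "hill_h", "k_syn_max", "c_cap",
            "t_div_median", "t_div_cv", "noise_cv", "onset_m_max",
            "onset_ec50", "daughter_delay", "growth_recovery_k",
            "photo_r_max", "photo_a50", "dark_r_max", "dark_a50",
        )
        for name in rates:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.dil_factor < 1:
            raise ValueError(f"dil_factor must be >= 1, got {self.dil_factor}")
        if not 0 <= self.af_floor < 1:
            raise ValueError(f"af_floor must be in [0, 1), got {self.af_floor}")
        if self.sample_period <= 0:
            raise ValueError("sample_period must be > 0")
        if not 0 < self.ph_ref < 14:
            raise ValueError("ph_ref must be a valid pH")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class Segment:
    """One constant-concentration auxin exposure window."""

    start_min: float
    end_min: float
    conc_mM: float
    compound: str = "IAA"

    def __post_init__(self) -> None:
        if self.end_min <= self.start_min:
            raise ValueError("segment end must be after start")
        if self.conc_mM < 0:
            raise ValueError("concentration must be >= 0")
        if self.compound not in COMPOUNDS:
            raise ValueError(f"unknown compound {self.compound!r}; expected one of {COMPOUNDS}")


@dataclass(frozen=True)
class AuxinSchedule:
    """Auxin exposure program for one experiment.

    ``delivery`` controls how a nominal segment translates into the
    concentration seen by the cells: ``instant`` is an ideal step, ``fast``
    a 3.5-min linear ramp (fast perfusion switch), and ``pump`` a
    per-experiment lag drawn from Normal(50, 5) min followed by a 10-min
    ramp (syringe-pump medium switch).  For pump delivery the lag must be
    realized (``with_pump_lag``) before the profile can be evaluated.
    """

    segments: tuple[Segment, ...] = ()
    delivery: str = "instant"
    ph: float = 5.1
    light_on: bool = True
    t_end: float = 740.0
    schedule_id: str = "schedule"
    pump_lag: float | None = None

    def __post_init__(self) -> None:
        if self.delivery not in DELIVERIES:
            raise ValueError(f"unknown delivery {self.delivery!r}; expected one of {DELIVERIES}")
        if not 0 < self.ph < 14:
            raise ValueError("ph must be a valid pH")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        segs = tuple(sorted(self.segments, key=lambda s: s.start_min))
        for a, b in zip(segs, segs[1:]):
            if b.start_min < a.end_min:
                raise ValueError("segments must be non-overlapping and ordered")
        object.__setattr__(self, "segments", segs)

    @property
    def lag(self) -> float:
        """Delivery lag between nominal and effective segment times."""
        if self.delivery != "pump":
            return 0.0
        if self.pump_lag is None:
            raise ValueError("pump delivery requires a realized pump_lag (use with_pump_lag)")
        return self.pump_lag

    @property
    def ramp(self) -> float:
        return {"instant": 0.0, "fast": FAST_RAMP_MIN, "pump": PUMP_RAMP_MIN}[self.delivery]

    def with_pump_lag(self, rng) -> "AuxinSchedule":
        """Realize the syringe-pump delivery lag (Normal(50, 5) min)."""
        if self.delivery != "pump":
            return self
        lag = float(rng.normal(50.0, 5.0))
        return replace(self, pump_lag=max(lag, 0.0))

    def arrival_time(self) -> float | None:
        """Time at which auxin first reaches the cells, or None if never."""
        if not self.segments:
            return None
        return self.segments[0].start_min + self.lag

    def max_concentration(self) -> float:
        return max((s.conc_mM for s in self.segments), default=0.0)

    def to_dict(self) -> dict:
        d = {
            "delivery": self.delivery,
            "ph": self.ph,
            "light_on": self.light_on,
            "t_end": self.t_end,
            "schedule_id": self.schedule_id,
            "pump_lag": self.pump_lag,
            "n_segments": len(self.segments),
        }
        for i, s in enumerate(self.segments):
            d[f"segment{i}_start_min"] = s.start_min
            d[f"segment{i}_end_min"] = s.end_min
            d[f"segment{i}_conc_mM"] = s.conc_mM
            d[f"segment{i}_compound"] = s.compound
        return d
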