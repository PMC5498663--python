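"""Single-cell trajectory containers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import AuxinSchedule, SimConfig

__all__ = ["Trajectory", "PopulationSample", "ROLES"]

ROLES = ("mother", "daughter")


@dataclass
class Trajectory:
    """One cell's time-stamped fluorescence signal and budding events.

    ``times`` lie on a fixed grid (multiples of the sampling period);
    ``signal`` is raw fluorescence (autofluorescence + protein component +
    noise) or a normalized version of it. ``budding_times`` are the observed
    budding events, snapped to the sampling grid.
    """

    cell_id: str
    role: str
    times: np.ndarray
    signal: np.ndarray
    budding_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    schedule_id: str = "schedule"
    schedule: AuxinSchedule | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.budding_times = np.asarray(self.budding_times, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have the same length")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0]):
                raise ValueError("times must lie on a fixed grid")
        if np.any(self.signal < 0):
            raise ValueError("signal must be >= 0")
        if self.budding_times.size:
            lo, hi = self.times[0], self.times[-1]
            if np.any((self.budding_times < lo) | (self.budding_times > hi)):
                raise ValueError("budding_times must lie within the observed time span")

    @property
    def sample_period(self) -> float:
        if self.times.size < 2:
            raise ValueError("need at least two samples to define a period")
        return float(self.times[1] - self.times[0])

    def window_values(self, window: tuple[float, float]) -> np.ndarray:
        """Signal values with window[0] <= t <= window[1]."""
        lo, hi = window
        return self.signal[(self.times >= lo) & (self.times <= hi)]

    def with_signal(self, signal: np.ndarray) -> "Trajectory":
        return replace(self, signal=np.asarray(signal, dtype=float))


@dataclass
class PopulationSample:
    """A cohort of trajectories sharing one auxin schedule."""

    trajectories: list[Trajectory]
    config: SimConfig | None = None
    schedule: AuxinSchedule | None = None

    def __post_init__(self) -> None:
        periods = {t.sample_period for t in self.trajectories if t.times.size >= 2}
        if len(periods) > 1:
            raise ValueError("all trajectories must share one sampling period")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def by_role(self, role: str) -> "PopulationSample":
        return PopulationSample(
            [t for t in self.trajectories if t.role == role],
            config=self.config, schedule=self.schedule,
        )

    def map_signal(self, fn) -> "PopulationSample":
        """Apply a Trajectory -> Trajectory transform to every cell."""
        return PopulationSample(
            [fn(t) for t in self.trajectories],
            config=self.config, schedule=self.schedule,
        )

    def common_grid(self) -> np.ndarray:
        """The shared time grid, requiring identical times across cells."""
        if not self.trajectories:
            raise ValueError("empty sample")
        ref = self.trajectories[0].times
        for t in self.trajectories[1:]:
            if t.times.shape != ref.shape or not np.array_equal(t.times, ref):
                raise ValueError("trajectories are not on a common time grid")
        return ref
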