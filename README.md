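# aidkit

Quantitative single-cell analysis of the auxin-inducible degron (AID)
system in budding yeast: a forward simulator of degron-reporter
fluorescence trajectories under programmable auxin schedules, and the
estimators needed to characterize targeted protein depletion and
recovery from 5-min time-lapse data.

## Who this is for

The AID system makes a tagged protein degradable on demand: auxin (IAA,
or its indole-free substitute NAA) recruits the tagged protein to the
plant F-box protein TIR1 for ubiquitin-mediated destruction. Anyone
using AID as a conditional-depletion tool needs quantitative answers to:
how fast is depletion at a given dose, is it complete, how uniform is it
across cells, how quickly does the protein come back after washout, and
what side effects does auxin itself have on growth. `aidkit` packages
those estimators, together with a calibrated generative model of the
underlying single-cell kinetics for validating them.

## The model

Between divisions, the normalized protein concentration *C* of one cell
follows

    dC/dt = k_syn (1 − C / c_cap) − k_deg(A_eff(t)) · C

solved in closed form on every constant-coefficient interval. At each
budding event *C* drops by the dilution factor DIL (default 1.2).
Degradation follows a Hill dose response
k_deg = k_max A^h / (EC50^h + A^h); the effective auxin A_eff is the
scheduled concentration rescaled by the Henderson–Hasselbalch protonated
fraction (uptake falls as medium pH rises) and delayed per cell by a
Gamma-distributed uptake lag (newborn daughters add a fixed ≈20-min
delay). The emitted signal is autofluorescence plus the protein
component, times multiplicative lognormal measurement noise.

The analysis side implements the field's standard summary statistics:

- **Depletion** — minimum of ΔSignal/ΔTime after auxin addition,
  time-to-floor (entry into the autofluorescence band), completeness
  ratio mean(500–740 min)/mean(0–240 min), two-phase-exponential and
  log-logistic dose–response fits, cell-to-cell SD slopes, and the
  mother/daughter delay with a rank-sum test.
- **Recovery** — per-division-cycle peaks (MAX) and drops
  (DIFF = MAX − next MIN) of the recovering sawtooth; the
  origin-constrained regression of DIFF on MAX whose slope gives the
  dilution factor DIL = 1/(1 − SLOPE) with a bootstrap CI; fraction
  recovered at a given time and time to full recovery.
- **Growth** — per-cycle growth rates GR = ln 2 / DT from inter-budding
  intervals, one-phase exponential-association recovery fits with a
  fixed plateau, and Kruskal–Wallis/Dunn group comparisons.

## Worked example

Estimate the per-division dilution factor from a simulated recovery
experiment (19 mother cells, 120-min saturating pulse, fast medium
switch):

```python
import numpy as np
from aidkit import recovery
from aidkit.workflows import (
    RunConfig, run_floor_experiment, run_pulse_experiment,
)

cfg = RunConfig(seed=1)
floor = run_floor_experiment(cfg).mean_ratio   # complete-depletion ratio
sample = run_pulse_experiment(cfg, 120.0, n_cells=19)
est, cycles = recovery.estimate_dilution(
    sample, floor, t_removal=360.0,
    rng=np.random.default_rng(1), max_cycles=5,
)
print(f"floor ratio {floor:.3f}")
print(f"slope {est.slope:.3f}, DIL {est.dil:.3f} "
      f"(95% CI {est.dil_ci95[0]:.3f}-{est.dil_ci95[1]:.3f}), "
      f"{est.n_oscillations} oscillations from {est.n_cells} cells")
```

prints

```
floor ratio 0.287
slope 0.198, DIL 1.247 (95% CI 1.217-1.278), 95 oscillations from 19 cells
```

The floor ratio is the autofluorescence of non-fluorescent cells divided
by the pre-depletion reporter signal — the level a fully depleted cell
falls to. The regression slope says each division drops the protein
concentration to 1/1.25 of its peak, i.e. cell growth dilutes the
re-synthesized protein by ≈1.2-fold per cycle, which is why full
recovery takes several generations even though re-synthesis starts
within minutes of auxin washout.

The same pipelines run from the shell:

```
aidkit simulate --n-mothers 20 --seed 1 --out cohort.csv
aidkit deplete cohort.csv --t-add 240 --out summary.csv
aidkit recover cohort.csv --t-removal 360
aidkit report --seed 1 --out report.json
```

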