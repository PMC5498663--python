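# Methods

## The forward model

One cell carries a normalized protein concentration *C(t)*. Between
division events

    dC/dt = k_syn (1 − C / c_cap) − k_deg(A_eff(t)) · C

and at each budding event *C ← C / DIL*. The linear-repression synthesis
term is the simplest form that jointly produces (i) a periodic steady
state of the no-auxin division cycle at the pre-depletion level, (ii)
roughly 20% recovery within 60 min of auxin washout from a fully
depleted state, and (iii) full recovery only after several generations.
With DIL = 1.2 and a 100-min median cycle, the calibration
k_syn = 0.00333 min⁻¹, c_cap = 2.24 places the cycle fixed point at
MIN\* = 0.915, MAX\* = 1.098 (MAX\*/MIN\* = DIL exactly) with
cycle-averaged C ≈ 1.0, so normalized baselines sit at 1 by
construction. Because the coefficients are piecewise constant, the ODE
is solved exactly per interval (concentration ramps are subdivided into
0.5-min steps with midpoint coefficients); divisions are instantaneous
concentration drops, and continuous within-cycle dilution is folded into
the synthesis term.

The emitted signal is `(af_floor + (1 − af_floor) C) × lognormal noise`
with `af_floor = 0.288` — the measured ratio of wild-type
autofluorescence to pre-depletion reporter fluorescence — so a fully
depleted cell converges to the autofluorescence floor, never below it.

### Dose response and pH

Degradation follows a Hill curve, k_deg = k_max A^h/(EC50^h + A^h) with
k_max = 0.25 min⁻¹, EC50 = 0.05 mM, h = 2: depletion rate saturates
(>96% of k_max) at 0.25 mM and above. Only the protonated acid
permeates the membrane, so the effective concentration is rescaled by
f(pH)/f(pH_ref) with f(pH) = 1/(1 + 10^(pH − pKa)), pKa(IAA) = 4.75
(a literature constant), pH_ref = 5.1. Raising the medium to pH 6.8
multiplies the effective dose by ≈0.029, which reproduces the observed
slowdown of depletion in alkaline medium. NAA is modeled with identical
degradation kinetics (its depletion dynamics match IAA at ≥0.05 mM) and
no growth toxicity.

### Onset delay

Each cell starts degrading only after a random uptake lag
τ ~ Gamma(shape 2, mean m_max·EC50_onset/(A + EC50_onset)) with
m_max = 60 min and EC50_onset = 0.04 mM; daughters add a fixed 20-min
delay. Two modeling decisions matter here:

- **The lag delays onset only.** The degradation input is
  min(A(t), A(t − τ)): accumulation lags behind the schedule, but
  washout acts immediately, because depleted cells start re-synthesizing
  within minutes of a medium switch. Making the lag symmetric (shifting
  the whole profile) would also delay recovery by ~τ, which contradicts
  the observed immediate recovery and depresses the 60-min recovered
  fraction well below its measured ~20%.
- **The lag at saturating dose must be short.** A 20-min pulse at
  0.5 mM completely depletes the reporter while a 10-min pulse does
  not; with immediate washout this bounds the mean lag at 0.5 mM to a
  few minutes (default: 4.4 min). At low doses the lag is long and
  broad (mean 37 min at 0.025 mM), which is what makes sub-saturating
  depletion *variable* across cells: the cell-to-cell SD of the signal
  rises during depletion at ≤0.1 mM and falls at ≥0.25 mM.

Whether the daughter lag reflects uptake or degradation machinery is
biologically unresolved; the simulator encodes it as a pure onset delay.

### Growth and phototoxicity

Inter-budding intervals are lognormal with median
t_div / (1 − r) and CV 0.15, where r is the auxin growth-defect
fraction: r = r_max A/(A50 + A) with r_max = 0.7, A50 = 0.5 µM under
GFP-excitation light (IAA photo-degrades to cytotoxic products; the
defaults put a 35% defect at 0.5 µM), a weaker dark term (r_max = 0.3,
A50 = 0.3 mM, so only >0.1 mM slows growth without light), and zero for
NAA. After auxin removal the defect relaxes exponentially at
K = 0.006 min⁻¹, which brings the growth rate within 5% of the
unperturbed plateau in ≈7–10 h.

### Delivery modes

`instant` is an ideal step; `fast` ramps linearly over 3.5 min (fast
perfusion switch, below the 5-min sampling period); `pump` applies a
per-experiment lag drawn from Normal(50, 5) min followed by a 10-min
ramp (syringe-pump dead volume).

## Estimators

**Normalization.** Every trajectory is divided by its mean signal over
the pre-auxin window (0–240 min by the default time convention: auxin
at t = 240 min); the operation is idempotent. Modal-grey background
subtraction (Freedman–Diaconis-binned histogram mode of the field of
view) is available for raw imaging data; simulated data are
background-free.

**Depletion.** Min slope is the minimum of ΔSignal/ΔTime after
addition — finite differences on the 5-min grid for cohort mean traces,
the analytic derivative of a GCV-smoothed cubic spline for single
cells. The floor band is the floor ratio ± 2 measurement-noise SD; the
spec of "complete depletion" is entry into this band. Time-to-half uses
linear interpolation between samples; the mother/daughter delay is the
Hodges–Lehmann median of pairwise daughter-minus-mother differences with
a Mann–Whitney test. The rate dose response is a two-phase exponential
decay through the origin (the two exponential fractions sum to 1, so the
intercept constraint is structural; the label-swap symmetry is broken by
reporting the faster rate first). The completeness dose response is a
log-logistic with top fixed at 1 and base fixed at the measured floor.

**Cycle segmentation and the dilution factor.** Divisions are observed
events at which the trace is discontinuous, so smoothing is done per
inter-budding segment — a single spline fitted across a division smears
the drop and biases DIFF low (estimated DIL 1.14 at truth 1.2). Samples
falling exactly on a grid-snapped budding time are excluded (they cannot
be assigned to either side of the drop), and the pre-drop peak (MAX) and
post-drop trough (MIN) are evaluated *at the division time* by local
linear extrapolation from the nearest four samples on each side. On
noise-free sawtooths this estimator is exact; with 5% noise it recovers
DIL to within ~0.1% across DIL ∈ {1.1, 1.2, 1.5, 2.0}. Scanning
segment interiors for extrema was rejected: under-smoothed short
segments select noise excursions and inflate the slope.

The regression of DIFF on MAX is constrained through the origin, which
is what makes DIL = 1/(1 − SLOPE) an identity; a free-intercept variant
is exposed (`through_origin=False`) for sensitivity analysis. The
regression runs on the *protein component* (s − floor)/(1 − floor):
dilution acts on protein, not on the additive autofluorescence offset,
and leaving the offset in makes DIFF/MAX level-dependent and biases the
origin-constrained slope low. The slope CI is a percentile bootstrap
over oscillations (default 1000 resamples).

**Pulse completeness.** A pulse achieves complete depletion when the
cohort mean of per-cell nadirs (minimum of each cell's smoothed trace
after addition) is inside the floor band. The per-cell nadir is used
rather than the pointwise cohort mean because onset lags desynchronize
the cells: each cell's deepest depletion measures completeness, the
pointwise mean measures synchrony.

**Growth.** GR = ln 2/DT per budding interval, attached to the interval
midpoint when fitting recovery. Recovery is a one-phase exponential
association with the plateau fixed to the mean growth rate of an
unperturbed control cohort; a fit whose start is already at the plateau
is flagged as unidentifiable rather than failed. Group comparisons use
Kruskal–Wallis with Dunn's all-pairs post-test (rank sums with tie
correction, Bonferroni-adjusted), implemented in-package.

## Numerical and statistical choices

- GCV selects the smoothing parameter by default; a fixed value can be
  supplied for reproducibility (0 interpolates).
- The cell-to-cell variability slope is evaluated over the 120 min after
  auxin addition: once every cell has finished depleting, the SD returns
  to the noise floor regardless of dose, so only a window on the scale
  of the depletion transient discriminates uniform from variable
  responses.
- All simulations draw from `numpy` `SeedSequence` trees: one seed fixes
  the pump lag, every cell's phase, division intervals, onset lag and
  measurement noise, making every experiment bit-reproducible.
- Budding times are snapped to the sampling grid on output (the CSV
  stores a per-sample budding flag); internal division events use exact
  times.
- Degenerate inputs fail loudly: empty cohorts, windows without samples,
  non-positive baselines, slopes ≥ 1 in the dilution map, unknown
  compounds or delivery modes all raise instead of propagating NaNs.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the estimators
assume: sawtooth baselines with a stationary normalized level, Hill-dose
depletion into an autofluorescence floor, onset-lag-driven cell-to-cell
variability, constant per-division dilution during recovery, and
dose- and light-dependent growth defects with exponential relaxation.
It deliberately omits fluorophore maturation kinetics, mRNA dynamics,
TIR1 expression variation, cell-size and replicative-age effects,
segmentation/tracking artifacts and photobleaching. Tests passing on
synthetic cohorts therefore validate the estimators' correctness and
calibration under the stated model, not the biological completeness of
that model; on real data the same estimators should be read with those
additional noise sources in mind.

### Measurement-resolution caveats

Two properties are intrinsically resolution-limited at 5% multiplicative
noise and ~95 oscillations. First, the per-oscillation drop factor
MAX/MIN shares MAX's measurement error, so a direct Spearman correlation
between MAX and the drop factor fluctuates by |ρ| ≈ 0.1–0.3 even though
the generative dilution is exactly level-independent (verified
noise-free to 1%). Second, at the study's default of 100 bootstrap
iterations the CI percentile endpoints carry Monte-Carlo noise worth a
few points of coverage; the estimator itself is calibrated (92%
coverage at 1000 iterations over 200 replicates).

## Problem sizes

Default analyses use the study's cohort sizes: 20-cell depletion
cohorts, 13 + 15 cells for the floor calibration, 19 mothers × 5
recovery cycles (~95 oscillations) for the dilution factor, 21 + 7
mother/daughter cells, 38-cell pulse cohorts, and 20–24 cells per growth
condition; recovery experiments run to 48 simulated hours so the
sawtooth reaches its new equilibrium. A full end-to-end report takes
~15 s on one CPU.
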