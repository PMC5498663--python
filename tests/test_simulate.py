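"""Forward-simulator unit and property tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from aidkit import (
    AuxinSchedule,
    Segment,
    SimConfig,
    auxin_profile,
    cycle_fixed_point,
    degradation_rate,
    effective_auxin,
    growth_reduction,
    simulate_autofluorescence_cells,
    simulate_cell,
    simulate_experiment,
)
from aidkit.depletion import _half_depletion_time
from aidkit.preprocess import normalize_baseline


class TestEffectiveAuxin:
    def test_unchanged_at_reference_ph(self, config):
        assert effective_auxin(0.1, config.ph_ref, config) == pytest.approx(0.1)

    def test_protonated_fraction_half_at_pka(self, config):
        # Henderson-Hasselbalch midpoint: f(pKa) = 1/2
        f = 1.0 / (1.0 + 10.0 ** (config.pka_iaa - config.pka_iaa))
        assert f == 0.5

    def test_high_ph_suppresses_uptake(self, config):
        # f(6.8)/f(5.1) with pKa 4.75, computed independently from the
        # protonated-fraction formula
        expected = 0.1 * (1 + 10 ** (5.1 - 4.75)) / (1 + 10 ** (6.8 - 4.75))
        assert effective_auxin(0.1, 6.8, config) == pytest.approx(expected)
        assert effective_auxin(0.1, 6.8, config) == pytest.approx(0.0028610, rel=1e-4)

    def test_negative_concentration_rejected(self, config):
        with pytest.raises(ValueError):
            effective_auxin(-0.1, 5.1, config)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(ph=st.floats(1.0, 13.0), dph=st.floats(0.01, 3.0))
    def test_strictly_decreasing_in_ph(self, ph, dph):
        config = SimConfig()
        if ph + dph >= 14:
            return
        assert effective_auxin(1.0, ph + dph, config) < effective_auxin(1.0, ph, config)


class TestDegradationRate:
    def test_zero_without_auxin(self, config):
        assert degradation_rate(0.0, config) == 0.0

    def test_half_maximal_at_ec50(self, config):
        assert degradation_rate(config.ec50_deg, config) == pytest.approx(config.k_deg_max / 2)

    def test_saturated_at_quarter_millimolar(self, config):
        # 0.25 mM with ec50 = 0.05 mM, h = 2: 0.25^2/(0.05^2+0.25^2) = 0.9615
        assert degradation_rate(0.25, config) >= 0.96 * config.k_deg_max

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(a=st.floats(0.0, 10.0), da=st.floats(0.001, 5.0))
    def test_monotone_nondecreasing(self, a, da):
        config = SimConfig()
        assert degradation_rate(a + da, config) >= degradation_rate(a, config)


class TestGrowthReduction:
    def test_zero_without_auxin(self, config):
        assert growth_reduction(0.0, True, "IAA", config) == 0.0

    def test_naa_harmless_under_light(self, config):
        assert growth_reduction(0.1, True, "NAA", config) == 0.0

    def test_iaa_half_micromolar_under_light(self, config):
        # defaults calibrated to a 35% growth-rate reduction at 0.5 uM
        assert growth_reduction(0.0005, True, "IAA", config) == pytest.approx(0.35)

    def test_dark_defect_weaker(self, config):
        assert growth_reduction(0.1, False, "IAA", config) < growth_reduction(0.1, True, "IAA", config)

    def test_unknown_compound_rejected(self, config):
        with pytest.raises(ValueError):
            growth_reduction(0.1, True, "2,4-D", config)


class TestAuxinProfile:
    def test_instant_step(self):
        sch = AuxinSchedule(segments=(Segment(240, 740, 0.5),), delivery="instant")
        assert auxin_profile(sch, 239.9) == 0.0
        assert auxin_profile(sch, 240.0) == 0.5

    def test_fast_ramp_completes_in_three_and_a_half_minutes(self):
        sch = AuxinSchedule(segments=(Segment(240, 740, 0.5),), delivery="fast")
        assert auxin_profile(sch, 240.0) == 0.0
        assert auxin_profile(sch, 241.75) == pytest.approx(0.25)
        assert auxin_profile(sch, 243.5) == pytest.approx(0.5)

    def test_pump_lag_delays_arrival(self):
        sch = AuxinSchedule(
            segments=(Segment(240, 740, 0.5),), delivery="pump", pump_lag=50.0
        )
        assert auxin_profile(sch, 289.9) == 0.0
        assert auxin_profile(sch, 295.0) > 0.0
        assert auxin_profile(sch, 300.0) == pytest.approx(0.5)

    def test_unrealized_pump_lag_rejected(self):
        sch = AuxinSchedule(segments=(Segment(240, 740, 0.5),), delivery="pump")
        with pytest.raises(ValueError):
            auxin_profile(sch, 300.0)

    def test_time_outside_horizon_rejected(self):
        sch = AuxinSchedule(segments=(Segment(240, 740, 0.5),), t_end=740)
        with pytest.raises(ValueError):
            auxin_profile(sch, 741.0)


class TestSimulateCell:
    def test_closed_form_decay_oracle(self, quiet_config):
        """Under constant saturating auxin without divisions, the simulated
        protein matches C(t) = C_inf + (C0 - C_inf) e^{-lambda t} to 1e-9."""
        cfg = quiet_config.with_(t_div_median=1e9, onset_m_max=0.0)
        sch = AuxinSchedule(segments=(Segment(0, 740, 0.5),), t_end=740)
        traj = simulate_cell(cfg, sch, rng=3, initial_phase=0.0, initial_c=1.0)
        lam = cfg.k_syn_max / cfg.c_cap + degradation_rate(
            effective_auxin(0.5, sch.ph, cfg), cfg
        )
        c_inf = cfg.k_syn_max / lam
        analytic = c_inf + (1.0 - c_inf) * np.exp(-lam * traj.times)
        simulated = (traj.signal - cfg.af_floor) / (1.0 - cfg.af_floor)
        assert np.abs(simulated - analytic).max() < 1e-9

    def test_baseline_sawtooth_at_periodic_fixed_point(self, quiet_config):
        """Without auxin the noise-free cycle starts on its periodic orbit:
        the peak samples sit at MAX* = dil * MIN* from the first cycle."""
        cfg = quiet_config.with_(t_div_cv=0.0)
        sch = AuxinSchedule(segments=(), t_end=740)
        traj = simulate_cell(cfg, sch, role="daughter", rng=5, initial_phase=0.0)
        min_star, max_star = cycle_fixed_point(cfg)
        protein = (traj.signal - cfg.af_floor) / (1.0 - cfg.af_floor)
        # divisions every 100 min on the grid; the sample at each division
        # records the pre-drop peak
        peaks = protein[traj.times % cfg.t_div_median == 0][1:]
        assert peaks == pytest.approx(max_star, abs=1e-9)
        assert max_star / min_star == pytest.approx(cfg.dil_factor)

    def test_saturating_auxin_reaches_autofluorescence_floor(self, quiet_config):
        sch = AuxinSchedule(segments=(Segment(240, 740, 0.5),), t_end=740)
        traj = simulate_cell(quiet_config, sch, rng=6)
        tail = traj.signal[traj.times >= 500]
        assert np.all(tail < quiet_config.af_floor + 0.02)

    def test_signal_never_below_floor_without_noise(self, quiet_config):
        sch = AuxinSchedule(segments=(Segment(240, 740, 0.5),), t_end=740)
        traj = simulate_cell(quiet_config, sch, rng=7)
        assert np.all(traj.signal >= quiet_config.af_floor - 1e-12)

    def test_empty_schedule_gives_baseline_only(self, config):
        traj = simulate_cell(config, AuxinSchedule(segments=(), t_end=480), rng=8)
        assert traj.signal.min() > 0.5  # never approaches the floor


class TestSimulateExperiment:
    def test_deterministic_for_fixed_seed(self, config):
        sch = AuxinSchedule(segments=(Segment(240, 740, 0.5),), t_end=740)
        a = simulate_experiment(config, sch, n_mothers=3, n_daughters=2, seed=42)
        b = simulate_experiment(config, sch, n_mothers=3, n_daughters=2, seed=42)
        for ta, tb in zip(a, b):
            assert ta.cell_id == tb.cell_id
            np.testing.assert_array_equal(ta.signal, tb.signal)
            np.testing.assert_array_equal(ta.budding_times, tb.budding_times)

    def test_zero_cells_rejected(self, config):
        with pytest.raises(ValueError):
            simulate_experiment(config, AuxinSchedule(), n_mothers=0, n_daughters=0)

    def test_all_cells_reach_floor_at_saturation(self, saturating_cohort):
        floor_top = 0.288 + 2 * 0.05 * 0.288
        for traj in saturating_cohort:
            assert traj.signal[traj.times >= 400].min() <= floor_top

    def test_baseline_stationarity_of_normalized_signal(self, config):
        """With no auxin the cycle-averaged normalized signal stays at
        1.0 +/- 3% over any 240-min window (noise on, 20 cells)."""
        sample = simulate_experiment(
            config, AuxinSchedule(segments=(), t_end=720), n_mothers=20, seed=9
        )
        sample = sample.map_signal(lambda t: normalize_baseline(t, (0, 240)))
        mat = np.vstack([t.signal for t in sample])
        times = sample.common_grid()
        for lo in (0.0, 240.0, 480.0):
            window = mat[:, (times >= lo) & (times < lo + 240)]
            assert window.mean() == pytest.approx(1.0, abs=0.03)

    def test_daughters_depleted_later_than_mothers(self, config):
        sample = simulate_experiment(
            config,
            AuxinSchedule(segments=(Segment(240, 740, 0.5),), t_end=740),
            n_mothers=30, n_daughters=30, seed=10,
        )
        sample = sample.map_signal(lambda t: normalize_baseline(t, (0, 240)))
        halves = {
            role: np.array([
                _half_depletion_time(t, 240.0, config.af_floor)
                for t in sample.by_role(role)
            ])
            for role in ("mother", "daughter")
        }
        gap = np.median(halves["daughter"]) - np.median(halves["mother"])
        assert gap == pytest.approx(config.daughter_delay, abs=5.0)

    def test_naa_and_iaa_depletion_indistinguishable(self, config):
        """At >= 0.05 mM the synthetic substitute NAA depletes the reporter
        like IAA (non-significant two-sample comparison at n = 20)."""
        halves = {}
        for seed, compound in ((11, "IAA"), (13, "NAA")):
            sch = AuxinSchedule(
                segments=(Segment(240, 740, 0.05, compound),), t_end=740
            )
            sample = simulate_experiment(config, sch, n_mothers=20, seed=seed)
            sample = sample.map_signal(lambda t: normalize_baseline(t, (0, 240)))
            halves[compound] = [
                _half_depletion_time(t, 240.0, config.af_floor) for t in sample
            ]
        p = sps.mannwhitneyu(halves["IAA"], halves["NAA"]).pvalue
        assert p > 0.05

    def test_wildtype_cells_sit_at_autofluorescence(self, config):
        wt = simulate_autofluorescence_cells(config, 13, seed=12)
        means = [t.signal.mean() for t in wt]
        assert np.mean(means) == pytest.approx(config.af_floor, rel=0.05)
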