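import math

import numpy as np
import pytest
from scipy import stats as sps

from vta_omission.exceptions import ParameterError
from vta_omission.photometry_analysis import preprocess_trace, trial_dff, epoch_window_dff
from vta_omission.session_model import Epoch, ProtocolSpec, build_schedule
from vta_omission.spike_analysis import UnitType, classify_unit_type
from vta_omission.synthetic_cohort import (
    AnimalParams,
    CohortConfig,
    CSModulation,
    UnitParams,
    derive_seed_sequence,
    draw_cohort_params,
    draw_unit_params,
    expected_freezing_pct,
    generate_cohort,
    indicator_kernel,
    rate_at,
    simulate_behavior,
    simulate_photometry,
    simulate_unit,
)


class TestSimulateUnit:
    def test_seeded_determinism(self, ext10_schedule):
        p = UnitParams(unit_id="u", omission_amplitude_hz=12.0)
        a = simulate_unit(p, ext10_schedule, seed=5)
        b = simulate_unit(p, ext10_schedule, seed=5)
        np.testing.assert_array_equal(a.spike_times_s, b.spike_times_s)
        assert a.homecage_rate_hz == b.homecage_rate_hz

    def test_homecage_rate_within_three_se(self, ext10_schedule):
        rate = 6.0
        duration = 300.0
        se = math.sqrt(rate / duration)
        p = UnitParams(unit_id="u", baseline_rate_hz=rate)
        errs = [
            abs(simulate_unit(p, ext10_schedule, seed=s).homecage_rate_hz - rate)
            for s in range(20)
        ]
        assert np.mean([e <= 3 * se for e in errs]) >= 0.95

    def test_session_rate_matches_baseline(self, ext10_schedule):
        p = UnitParams(unit_id="u", baseline_rate_hz=5.0)
        rec = simulate_unit(p, ext10_schedule, seed=9)
        empirical = rec.spike_times_s.size / ext10_schedule.total_duration_s
        assert empirical == pytest.approx(5.0, rel=0.1)

    def test_omission_transient_adds_rate_after_offset(self, ext10_schedule):
        amp = 15.0
        p = UnitParams(unit_id="u", baseline_rate_hz=5.0, omission_amplitude_hz=amp)
        offsets = np.asarray(ext10_schedule.cs_offsets_s)
        inside = rate_at(offsets + 0.5, p, ext10_schedule)
        outside = rate_at(offsets + 1.5, p, ext10_schedule)
        np.testing.assert_allclose(inside, 5.0 + amp)  # decay is infinite by default
        np.testing.assert_allclose(outside, 5.0)

    def test_omission_decay_across_trials(self, ext10_schedule):
        p = UnitParams(
            unit_id="u", baseline_rate_hz=5.0,
            omission_amplitude_hz=10.0, omission_decay_trials=3.0,
        )
        offsets = np.asarray(ext10_schedule.cs_offsets_s)
        added = rate_at(offsets + 0.5, p, ext10_schedule) - 5.0
        expected = 10.0 * np.exp(-np.arange(10) / 3.0)
        np.testing.assert_allclose(added, expected, rtol=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            UnitParams(unit_id="u", baseline_rate_hz=0.0)
        with pytest.raises(ParameterError):
            UnitParams(unit_id="u", cs_gain=-0.5)
        with pytest.raises(ParameterError):
            UnitParams(unit_id="u", omission_amplitude_hz=-1.0)


class TestSimulatePhotometry:
    def _noiseless(self, **kw):
        defaults = dict(
            animal_id="a", noise_sd=0.0, drift_amplitude=0.0, omission_amp=0.3,
        )
        defaults.update(kw)
        return AnimalParams(**defaults)

    def _omission_dff(self, params, schedule, seed=0):
        trace = simulate_photometry(params, schedule, seed)
        trace10 = preprocess_trace(trace)
        trials = [
            trial_dff(trace10, onset, trial_index=i)
            for i, onset in enumerate(schedule.cs_onsets_s[:10])
        ]
        return epoch_window_dff(trials, "omission_5s")

    def test_gfp_has_null_omission_signal(self, ext10_schedule):
        params = AnimalParams(
            animal_id="g", fluorophore="GFP", omission_amp=0.0,
            noise_sd=0.003, drift_amplitude=0.0,
        )
        dff = self._omission_dff(params, ext10_schedule)
        # mean over 10 trials x 50 samples of ~iid noise: sd ~ noise/sqrt(eff n)
        assert abs(dff) < 2 * 0.003

    def test_linearity_in_omission_amplitude(self, ext10_schedule):
        base = self._omission_dff(self._noiseless(omission_amp=0.2), ext10_schedule)
        double = self._omission_dff(self._noiseless(omission_amp=0.4), ext10_schedule)
        assert double == pytest.approx(2 * base, rel=1e-6)
        assert base > 0

    def test_monotone_in_omission_amplitude(self, ext10_schedule):
        vals = [
            self._omission_dff(self._noiseless(omission_amp=a), ext10_schedule)
            for a in (0.1, 0.2, 0.4, 0.8)
        ]
        assert np.all(np.diff(vals) > 0)

    def test_slower_indicator_has_longer_tail(self):
        """Half-decay time of the kernel grows monotonically with tau_decay."""
        t = np.arange(0, 20, 1e-4)
        half_times = []
        for tau_d in (0.2, 0.4, 1.0, 2.0):
            h = indicator_kernel(t, 0.05, tau_d)
            peak_i = h.argmax()
            half_i = peak_i + np.argmax(h[peak_i:] < 0.5)
            half_times.append(t[half_i])
        assert np.all(np.diff(half_times) > 0)

    def test_gfp_with_amplitude_rejected(self):
        with pytest.raises(ParameterError):
            AnimalParams(animal_id="g", fluorophore="GFP", omission_amp=0.2)

    def test_nonpositive_baseline_rejected(self, ext10_schedule):
        with pytest.raises(ParameterError):
            simulate_photometry(self._noiseless(), ext10_schedule, 0, baseline_f=0.0)


class TestSimulateBehavior:
    def test_no_learning_when_tau_infinite(self, ext_schedule):
        params = AnimalParams(
            animal_id="a", omission_amp=0.3, freeze_start_pct=70.0,
            freeze_end_pct=10.0, learning_tau_trials=1e12, freeze_noise_conc=math.inf,
        )
        sim = simulate_behavior(params, ext_schedule, seed=0)
        np.testing.assert_allclose(sim.per_trial_pct, 70.0, rtol=1e-6)

    def test_noiseless_closed_form(self, ext_schedule):
        params = AnimalParams(
            animal_id="a", omission_amp=0.3, freeze_start_pct=80.0,
            freeze_end_pct=10.0, learning_tau_trials=5.0, freeze_noise_conc=math.inf,
        )
        sim = simulate_behavior(params, ext_schedule, seed=0)
        assert sim.per_trial_pct[0] == pytest.approx(80.0)
        assert np.all(np.diff(sim.per_trial_pct) < 0)
        k = np.arange(1, 26)
        expected = 10.0 + 70.0 * np.exp(-(k - 1) / 5.0)
        np.testing.assert_allclose(sim.per_trial_pct, expected, rtol=1e-9)

    def test_intervals_match_reported_percentages(self, ext_schedule):
        from vta_omission.behavior_analysis import percent_freezing

        params = AnimalParams(animal_id="a", omission_amp=0.3)
        sim = simulate_behavior(params, ext_schedule, seed=3)
        for onset, pct in zip(ext_schedule.cs_onsets_s, sim.per_trial_pct):
            measured = percent_freezing(sim.record, (onset, onset + 10.0))
            assert measured == pytest.approx(pct, abs=0.01)

    def test_seeded_determinism(self, ext_schedule):
        params = AnimalParams(animal_id="a", omission_amp=0.3)
        a = simulate_behavior(params, ext_schedule, seed=8)
        b = simulate_behavior(params, ext_schedule, seed=8)
        assert a.record.intervals == b.record.intervals


class TestCohort:
    def test_da_units_always_pass_type_criterion(self, rng):
        units = draw_unit_params(400, "ext", "m", 0.25, rng)
        for u in units:
            expected = UnitType.PUTATIVE_DA if u.cell_class == "DA" else UnitType.PUTATIVE_NON_DA
            assert classify_unit_type(u.baseline_rate_hz, u.width_us) is expected

    def test_zero_target_spearman_independent(self):
        cfg = CohortConfig(n_animals=200, n_gfp=0, target_spearman=0.0, master_seed=10)
        animals = draw_cohort_params(cfg)
        amps = [a.omission_amp for a in animals]
        taus = [a.learning_tau_trials for a in animals]
        assert abs(sps.spearmanr(amps, taus).statistic) < 0.15

    def test_degenerate_copula_config_rejected(self):
        with pytest.raises(ParameterError):
            CohortConfig(n_animals=2, target_spearman=1.0)
        with pytest.raises(ParameterError):
            CohortConfig(target_spearman=1.5)

    def test_seed_derivation_is_stable_and_distinct(self):
        a1 = derive_seed_sequence(3, "a01").generate_state(2)
        a2 = derive_seed_sequence(3, "a01").generate_state(2)
        b = derive_seed_sequence(3, "a02").generate_state(2)
        np.testing.assert_array_equal(a1, a2)
        assert not np.array_equal(a1, b)

    def test_manifest_bookkeeping(self, tmp_path):
        cfg = CohortConfig(
            n_animals=2, n_gfp=1, units_per_animal=2, master_seed=1,
            n_extinction_trials=20,
        )
        manifest = generate_cohort(cfg, tmp_path)
        assert len(manifest["animals"]) == 3
        for animal in manifest["animals"]:
            files = animal["files"]
            # one trace file and one spike file per animal
            assert (tmp_path / files["traces"]).exists()
            assert (tmp_path / files["spikes"]).exists()
            assert (tmp_path / files["events"]).exists()
            assert (tmp_path / files["freezing"]).exists()
        assert (tmp_path / "manifest.json").exists()
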