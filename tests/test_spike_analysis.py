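import numpy as np
import pytest
from hypothesis import given, strategies as st

from vta_omission.exceptions import StatisticsError, VtaOmissionError
from vta_omission.session_model import Epoch, SessionKind, SessionSchedule
from vta_omission.spike_analysis import (
    PSTH,
    ResponseLabel,
    UnitRecord,
    UnitType,
    ZScoredPSTH,
    classify_cs_response,
    classify_omission_response,
    classify_unit_type,
    compute_epoch_psth,
    estimate_homecage_rate,
    population_omission_test,
    zscore_psth,
)


def single_trial_schedule(onset=100.0, n=1, gap=60.0):
    onsets = tuple(onset + i * (10.0 + gap) for i in range(n))
    return SessionSchedule(
        cs_onsets_s=onsets, cs_duration_s=10.0, us_times_s=(),
        session_kind=SessionKind.EXTINCTION, total_duration_s=onsets[-1] + 60.0,
    )


def make_unit(spikes, unit_id="u1", rate=5.0, width=550.0):
    return UnitRecord(unit_id, np.asarray(spikes, dtype=float), rate, width)


def make_z(values, epoch=Epoch.E_EXT):
    z = np.asarray(values, dtype=float)
    return ZScoredPSTH(z=z, baseline_mean_hz=5.0, baseline_sd_hz=1.0, valid=True, epoch=epoch)


class TestUnitTypeCriterion:
    @pytest.mark.parametrize(
        "rate,width,expected",
        [
            (4.0, 550.0, UnitType.PUTATIVE_DA),
            (10.0, 550.0, UnitType.PUTATIVE_NON_DA),  # rate boundary is strict
            (4.0, 450.0, UnitType.PUTATIVE_NON_DA),   # width boundary is strict
            (9.99, 450.01, UnitType.PUTATIVE_DA),
            (25.0, 300.0, UnitType.PUTATIVE_NON_DA),
        ],
    )
    def test_rate_width_criterion(self, rate, width, expected):
        assert classify_unit_type(rate, width) is expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(VtaOmissionError):
            classify_unit_type(-1.0, 500.0)
        with pytest.raises(VtaOmissionError):
            classify_unit_type(5.0, 0.0)

    def test_homecage_rate_estimator(self):
        assert estimate_homecage_rate([1.0, 2.0, 3.0], 300.0) == pytest.approx(0.01)


class TestPSTH:
    def test_silent_unit_all_zero(self):
        sched = single_trial_schedule()
        psth = compute_epoch_psth(make_unit([]), sched, Epoch.ALL)
        assert psth.rate_hz.shape == (20,)
        assert np.all(psth.rate_hz == 0)

    def test_hand_counted_single_trial(self):
        """Spikes at onset+0.5 and onset+1.5 land in the [0,1) and [1,2) bins."""
        sched = single_trial_schedule(onset=100.0)
        psth = compute_epoch_psth(make_unit([100.5, 101.5]), sched, Epoch.ALL)
        expected = np.zeros(20)
        expected[5] = 1.0  # bin [0, 1)
        expected[6] = 1.0  # bin [1, 2)
        np.testing.assert_array_equal(psth.rate_hz, expected)

    def test_trial_averaging(self):
        """One spike on one of two trials averages to 0.5 Hz."""
        sched = single_trial_schedule(onset=100.0, n=2)
        psth = compute_epoch_psth(make_unit([100.2]), sched, Epoch.ALL)
        assert psth.rate_hz[5] == pytest.approx(0.5)
        assert psth.n_trials == 2

    def test_edge_spike_goes_to_right_open_bin(self):
        sched = single_trial_schedule(onset=100.0)
        psth = compute_epoch_psth(make_unit([100.0]), sched, Epoch.ALL)
        assert psth.rate_hz[5] == 1.0 and psth.rate_hz[4] == 0.0


class TestZScore:
    def test_degenerate_baseline_flagged_invalid(self):
        sched = single_trial_schedule()
        psth = compute_epoch_psth(make_unit([]), sched, Epoch.ALL)
        z = zscore_psth(psth)
        assert not z.valid
        assert classify_omission_response(z) is ResponseLabel.UNCLASSIFIABLE
        assert classify_cs_response(z) is ResponseLabel.UNCLASSIFIABLE

    def test_hand_calculation(self):
        """Baseline [1,2,3,2,2]: mu=2, sd=sqrt(0.5); a bin at 4 gives z=2.828."""
        rate = np.array([1, 2, 3, 2, 2] + [4] * 15, dtype=float)
        psth = PSTH(np.arange(-5, 16, dtype=float), rate, Epoch.E_EXT, 10)
        z = zscore_psth(psth)
        assert z.baseline_mean_hz == pytest.approx(2.0)
        assert z.baseline_sd_hz == pytest.approx(np.sqrt(0.5))
        assert z.z[5] == pytest.approx(2.0 * np.sqrt(2.0))

    def test_baseline_mean_zero_and_unnormalization(self, rng):
        rate = rng.poisson(5.0, size=20).astype(float)
        rate[:5] += np.arange(5) * 0.1  # ensure nonzero baseline spread
        psth = PSTH(np.arange(-5, 16, dtype=float), rate, Epoch.E_EXT, 10)
        z = zscore_psth(psth)
        assert z.valid
        assert np.mean(z.z[:5]) == pytest.approx(0.0, abs=1e-12)
        recovered = z.z * z.baseline_sd_hz + z.baseline_mean_hz
        np.testing.assert_allclose(recovered, rate, rtol=1e-12)

    def test_pooled_trial_convention_available(self, ext_schedule, rng):
        spikes = np.sort(rng.uniform(0, ext_schedule.total_duration_s, 2000))
        psth = compute_epoch_psth(make_unit(spikes), ext_schedule, Epoch.E_EXT)
        z_psth = zscore_psth(psth, baseline_sd="psth_bins")
        z_pool = zscore_psth(psth, baseline_sd="pooled_trials")
        assert z_psth.valid and z_pool.valid
        # pooled SD includes within-trial Poisson variance, so it is larger
        assert z_pool.baseline_sd_hz > z_psth.baseline_sd_hz


class TestResponseClassification:
    @pytest.mark.parametrize(
        "z_omit,z_last,expected",
        [
            (3.0, 0.5, ResponseLabel.EXCITED),
            (2.5, 1.0, ResponseLabel.NONRESPONSIVE),  # delta 1.5 < 2
            (2.0, -1.0, ResponseLabel.NONRESPONSIVE),  # threshold is strict
            (-3.0, 0.0, ResponseLabel.INHIBITED),
            (-2.0, 1.0, ResponseLabel.NONRESPONSIVE),
            (-3.0, -2.5, ResponseLabel.NONRESPONSIVE),  # delta 0.5 < 2
        ],
    )
    def test_omission_criteria(self, z_omit, z_last, expected):
        values = np.zeros(20)
        values[14] = z_last
        values[15] = z_omit
        assert classify_omission_response(make_z(values)) is expected

    @pytest.mark.parametrize(
        "mean_z,expected",
        [
            (2.5, ResponseLabel.EXCITED),
            (-2.5, ResponseLabel.INHIBITED),
            (0.0, ResponseLabel.NONRESPONSIVE),
            (2.0, ResponseLabel.NONRESPONSIVE),  # strict threshold
        ],
    )
    def test_cs_criteria(self, mean_z, expected):
        values = np.zeros(20)
        values[5:15] = mean_z
        assert classify_cs_response(make_z(values)) is expected

    def test_labels_invariant_to_time_shift(self, rng):
        """Shifting all spikes and onsets by a constant leaves labels unchanged."""
        sched = single_trial_schedule(onset=100.0, n=12)
        spikes = np.sort(rng.uniform(0, sched.total_duration_s, 800))
        unit = make_unit(spikes)
        shift = 37.5
        shifted_sched = SessionSchedule(
            cs_onsets_s=tuple(t + shift for t in sched.cs_onsets_s),
            cs_duration_s=sched.cs_duration_s,
            us_times_s=(),
            session_kind=sched.session_kind,
            total_duration_s=sched.total_duration_s + shift,
        )
        shifted_unit = make_unit(spikes + shift)
        for epoch in (Epoch.E_EXT, Epoch.ALL):
            z_a = zscore_psth(compute_epoch_psth(unit, sched, epoch))
            z_b = zscore_psth(compute_epoch_psth(shifted_unit, shifted_sched, epoch))
            assert classify_omission_response(z_a) is classify_omission_response(z_b)
            assert classify_cs_response(z_a) is classify_cs_response(z_b)


class TestPopulationTest:
    def _psth(self, omit, base):
        rate = np.full(20, float(base))
        rate[15] = omit
        return PSTH(np.arange(-5, 16, dtype=float), rate, Epoch.E_EXT, 10)

    def test_null_identical_pairs(self):
        psths = [self._psth(2.0, 2.0) for _ in range(5)]
        res = population_omission_test(psths)
        assert res.statistic == 0.0 and res.p_two_sided == 1.0

    def test_closed_form_t(self):
        psths = [self._psth(3, 1), self._psth(4, 1), self._psth(5, 1)]
        res = population_omission_test(psths)
        assert res.statistic == pytest.approx(3 * np.sqrt(3))
        assert res.df == 2

    def test_degrees_of_freedom_bookkeeping(self, rng):
        psths = [self._psth(rng.uniform(1, 5), rng.uniform(1, 5)) for _ in range(40)]
        assert population_omission_test(psths).df == 39

    def test_too_few_units(self):
        with pytest.raises(StatisticsError):
            population_omission_test([self._psth(1, 1)])
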