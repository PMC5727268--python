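import numpy as np
import pytest

import cmaplin as cml
from cmaplin import (
    AxonPopulation,
    InjuryModel,
    SimConfig,
    StimulusSchedule,
    fit_condition,
    generate_cohort,
    recruitment_amplitudes,
    simulate_amplitudes,
    simulate_recording,
)


@pytest.fixture
def schedule03():
    return StimulusSchedule(mt=0.3)


class TestSimulateAmplitudes:
    def test_saturated_population_is_flat(self, schedule03):
        pop = AxonPopulation(thresholds=tuple(np.full(50, 0.5)), amps=tuple(np.full(50, 3.0)))
        row = simulate_amplitudes(pop, InjuryModel(), 0, schedule03, seed=0, noise_sd=0.0)
        np.testing.assert_allclose(row, 150.0)

    def test_uniform_thresholds_linear_recruitment(self, schedule03):
        # thresholds evenly spread over (1.0, 1.4] MT, equal unit amplitudes:
        # the recruitment count grows linearly in intensity, and the fitted
        # slope equals the analytic recruitment density amp * n / 0.4 per MT
        n, amp = 400, 2.5
        thr = 1.0 + (np.arange(n) + 0.5) / n * 0.4
        pop = AxonPopulation(thresholds=tuple(thr), amps=tuple(np.full(n, amp)))
        row = simulate_amplitudes(pop, InjuryModel(), 0, schedule03, seed=0, noise_sd=0.0)
        intensities_mt = np.array(schedule03.levels_pct_mt) / 100.0
        m = cml.fit_linear_model(intensities_mt, row)
        density = amp * n / 0.4  # uV per MT unit
        assert m.a == pytest.approx(density, rel=1e-9)
        assert m.residual_ss == pytest.approx(0.0, abs=1e-12)

    def test_block_fraction_expectation(self, schedule03):
        # level 3 blocks 75% of axons: expected recruitable amplitude is 25%
        # of level 0 (amplitudes are independent of the block order)
        injury = InjuryModel()
        pop = AxonPopulation()
        sched_sat = StimulusSchedule(mt=0.3, levels_pct_mt=(100.0, 110.0, 120.0, 130.0, 1000.0))
        ratios = []
        for seed in range(500):
            full = recruitment_amplitudes(pop, injury, 0, sched_sat, seed)[-1]
            blocked = recruitment_amplitudes(pop, injury, 3, sched_sat, seed)[-1]
            ratios.append(blocked / full)
        ratios = np.array(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 0.25) < 2 * se

    def test_noise_truncated_at_zero(self, schedule03):
        pop = AxonPopulation(thresholds=(5.0,), amps=(1.0,))  # never recruited
        row = simulate_amplitudes(pop, InjuryModel(), 0, schedule03, seed=2, noise_sd=50.0)
        assert np.all(row >= 0.0)

    def test_vpp_monotone_nonincreasing_in_damage(self, schedule03):
        pop, injury = AxonPopulation(), InjuryModel()
        for seed in range(20):
            rows = [
                recruitment_amplitudes(pop, injury, lvl, schedule03, seed)
                for lvl in range(4)
            ]
            for lo, hi in zip(rows, rows[1:]):
                assert np.all(hi <= lo + 1e-12)

    def test_invalid_level(self, schedule03):
        with pytest.raises(ValueError):
            simulate_amplitudes(AxonPopulation(), InjuryModel(), 4, schedule03, seed=0)


class TestInjuryModelValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"block_fraction": (0.0, 0.5, 0.4, 0.6)},
            {"block_fraction": (0.0, 0.2, 0.5, 1.0)},
            {"threshold_shift": (1.0, 0.9, 1.0, 1.0)},
            {"block_order": "sideways"},
        ],
    )
    def test_rejects(self, kwargs):
        with pytest.raises(ValueError):
            InjuryModel(**kwargs)


class TestSimulateRecording:
    def test_trigger_count(self, schedule03):
        rec = simulate_recording(
            AxonPopulation(), InjuryModel(), 0, schedule03, SimConfig(seed=0)
        )
        assert len(rec.meta["trigger_indices"]) == schedule03.n_trains * 5

    def test_noiseless_recovery_exact(self, schedule03):
        rec = simulate_recording(
            AxonPopulation(), InjuryModel(), 1, schedule03, SimConfig(seed=6, noise_sd=0.0)
        )
        vpp = cml.process_recording(rec, schedule=schedule03)
        true = np.asarray(rec.meta["true_vpp_row"])
        np.testing.assert_allclose(vpp, true, rtol=1e-6)

    def test_noisy_recovery_close(self, schedule03):
        errs = []
        for seed in range(10):
            rec = simulate_recording(
                AxonPopulation(), InjuryModel(), 0, schedule03, SimConfig(seed=seed)
            )
            vpp = cml.process_recording(rec, schedule=schedule03)
            true = np.asarray(rec.meta["true_vpp_row"])
            errs.append(np.abs(vpp - true) / true)
        assert np.mean(errs) < 0.05


class TestGenerateCohort:
    def test_shape_and_determinism(self):
        cfg = SimConfig(seed=7, n_subjects=4)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert len(a) == 4
        for ma, mb in zip(a, b):
            assert ma.vpp.shape == (4, 5)
            np.testing.assert_array_equal(ma.vpp, mb.vpp)
            assert ma.subject_id == mb.subject_id

    def test_default_cohort_shape(self, cohort_seed1):
        assert len(cohort_seed1) == 16
        assert all(m.vpp.shape == (4, 5) for m in cohort_seed1)

    def test_per_trial_slope_medians_decrease(self, cohort_seed1):
        A = np.array(
            [
                [fit_condition(m, k, "per_trial").a for k in range(4)]
                for m in cohort_seed1
            ]
        )
        med = np.median(A, axis=0)
        assert np.all(np.diff(med) < 0)


class TestScaleInvarianceTrap:
    """Per-trial normalization sees injury only through recruitment *shape*.

    Blocking a random axon subset rescales the recruitment curve nearly
    uniformly, which Eq-5-style self-normalization cancels; blocking in
    descending-threshold order caps the curve and changes its shape.  The
    per-trial slope separation between the extreme conditions must collapse
    in the first configuration and survive in the second.
    """

    @staticmethod
    def _median_slope_gap(injury, n=24):
        sched = StimulusSchedule(mt=0.3)
        pop = AxonPopulation()
        gaps = []
        for seed in range(n):
            rows = np.vstack(
                [
                    simulate_amplitudes(pop, injury, lvl, sched, seed=seed, noise_sd=15.0)
                    for lvl in range(4)
                ]
            )
            m = cml.CmapMatrix(vpp=rows, schedule=sched)
            a0 = fit_condition(m, 0, "per_trial").a
            a3 = fit_condition(m, 3, "per_trial").a
            gaps.append(abs(a0 - a3))
        return float(np.median(gaps))

    def test_random_block_is_invisible_ordered_block_is_not(self):
        trap = self._median_slope_gap(
            InjuryModel(block_order="random", threshold_shift=(1.0,) * 4)
        )
        default = self._median_slope_gap(InjuryModel())
        assert trap < default / 3.0
        assert default > 0.5  # clear separation in slope units
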