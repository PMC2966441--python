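"""Tests of the cortical-sheet generator, forward model and run simulator."""

import numpy as np
import pytest

import utrocular as u
from utrocular.synthetic import SF_AXIS, _generate_trial_sequence


class TestOdMap:
    def test_bounded_and_near_zero_mean(self):
        grid = u.GridSpec()
        oc = u.generate_od_map(grid, seed=0)
        assert np.all(oc >= -1) and np.all(oc <= 1)
        assert abs(oc.mean()) < 0.05

    def test_sharpness_zero_is_rescaled_bandpass(self):
        grid = u.GridSpec()
        oc = u.generate_od_map(grid, sharpness=0, seed=3)
        assert np.isclose(np.abs(oc).max(), 1.0)
        assert abs(oc.mean()) < 0.05

    def test_deterministic_under_seed(self):
        grid = u.GridSpec()
        a = u.generate_od_map(grid, seed=7)
        b = u.generate_od_map(grid, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_rejects_grid_smaller_than_two_periods(self):
        with pytest.raises(ValueError, match="single column"):
            u.generate_od_map(u.GridSpec(extent_mm=(3.0, 3.0)), od_period_mm=1.6)

    @pytest.mark.parametrize("seed", range(50))
    def test_spectral_peak_at_columnar_period(self, seed):
        """Radial power spectrum peaks at 1/od_period_mm within half an octave."""
        grid = u.GridSpec()
        oc = u.generate_od_map(grid, od_period_mm=1.6, seed=seed)
        freqs, power = u.radial_power_spectrum(oc, grid.mm_per_px)
        peak = freqs[np.argmax(power)]
        f0 = 1.0 / 1.6
        assert f0 / np.sqrt(2) <= peak <= f0 * np.sqrt(2)


class TestSfMap:
    def test_bounded(self):
        oc = u.generate_od_map(u.GridSpec(), seed=0)
        sf = u.generate_sf_map(oc, 0.5, seed=1)
        assert sf.min() >= 0 and sf.max() <= 1

    def test_uncoupled_map_is_independent(self):
        oc = u.generate_od_map(u.GridSpec(), seed=0)
        sf = u.generate_sf_map(oc, 0.0, seed=1)
        r = np.corrcoef((1 - sf).ravel(), np.abs(oc).ravel())[0, 1]
        assert abs(r) < 0.1

    def test_full_coupling_strongly_correlated(self):
        oc = u.generate_od_map(u.GridSpec(), seed=0)
        sf = u.generate_sf_map(oc, 1.0, seed=1)
        r = np.corrcoef((1 - sf).ravel(), np.abs(oc).ravel())[0, 1]
        assert r > 0.8

    def test_coupling_monotone_over_seeds(self):
        """Mean corr(1 - sf_pref, |ocularity|) increases across rho 0, 0.5, 1."""
        grid = u.GridSpec(extent_mm=(12.0, 12.0))
        means = []
        for rho in (0.0, 0.5, 1.0):
            rs = []
            for seed in range(20):
                oc = u.generate_od_map(grid, seed=seed)
                sf = u.generate_sf_map(oc, rho, seed=1000 + seed)
                rs.append(np.corrcoef((1 - sf).ravel(), np.abs(oc).ravel())[0, 1])
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]

    def test_rejects_out_of_range_rho(self):
        oc = u.generate_od_map(u.GridSpec(), seed=0)
        with pytest.raises(ValueError):
            u.generate_sf_map(oc, 1.5)


class TestNeuralResponse:
    def _sheet(self, ocularity, sf_pref):
        grid = u.GridSpec(extent_mm=(0.3, 0.15), mm_per_px=0.15)
        return u.CorticalSheet(
            grid=grid,
            ocularity=np.asarray(ocularity, dtype=float),
            sf_pref=np.asarray(sf_pref, dtype=float),
            od_period_mm=1.6,
            coupling_rho=0.0,
            seed=0,
        )

    def test_no_selectivity_means_eyes_identical(self):
        sheet = u.make_cortical_sheet(u.GridSpec(extent_mm=(6.0, 6.0)), seed=0)
        model = u.ResponseModel(eye_selectivity=0.0, left_eye_offset_delta=0.0)
        np.testing.assert_array_equal(
            u.neural_response(sheet, "L", "low", model),
            u.neural_response(sheet, "R", "low", model),
        )

    def test_left_offset_is_purely_additive(self):
        sheet = u.make_cortical_sheet(u.GridSpec(extent_mm=(6.0, 6.0)), seed=0)
        model = u.ResponseModel(eye_selectivity=0.0, left_eye_offset_delta=0.25)
        rl = u.neural_response(sheet, "L", "high", model)
        rr = u.neural_response(sheet, "R", "high", model)
        assert np.isclose(rl.mean() - rr.mean(), 0.25)

    def test_matches_hand_evaluated_formula_on_two_pixels(self):
        sheet = self._sheet([[0.5, -0.4]], [[0.2, 0.9]])
        model = u.ResponseModel(
            base_gain=2.0,
            eye_selectivity=0.5,
            sf_tuning_width=0.3,
            left_eye_offset_delta=0.1,
            noise_sd=0.0,
        )
        got = u.neural_response(sheet, "L", "low", model)
        sf_stim = SF_AXIS["low"]
        expected = (
            2.0
            * np.exp(-((sf_stim - np.array([0.2, 0.9])) ** 2) / (2 * 0.3**2))
            * (1 + 0.5 * 1.0 * np.array([0.5, -0.4]))
            + 0.1
        )
        np.testing.assert_allclose(got.ravel(), expected, rtol=1e-12)

    def test_nonnegative_response(self):
        sheet = u.make_cortical_sheet(u.GridSpec(extent_mm=(6.0, 6.0)), seed=1)
        model = u.ResponseModel(eye_selectivity=1.0)
        for eye in ("L", "R"):
            for sf in ("low", "high"):
                assert np.all(u.neural_response(sheet, eye, sf, model) >= 0)

    def test_rejects_unknown_tokens(self):
        sheet = u.make_cortical_sheet(u.GridSpec(extent_mm=(6.0, 6.0)), seed=0)
        model = u.ResponseModel()
        with pytest.raises(ValueError):
            u.neural_response(sheet, "X", "low", model)
        with pytest.raises(ValueError):
            u.neural_response(sheet, "L", "mid", model)


class TestSampleVoxels:
    def test_constant_field_gives_constant_voxels(self):
        field = np.full((40, 40), 3.25)
        for fwhm in (0.0, 4.0):
            vox = u.sample_voxels(
                field, u.VoxelSamplingConfig(smoothing_fwhm_mm=fwhm), mm_per_px=0.15
            )
            np.testing.assert_allclose(vox, 3.25)

    def test_unsmoothed_voxel_is_pixel_mean(self, rng):
        # 1.0 mm voxels over 0.5 mm pixels: each voxel covers a 2x2 pixel patch
        field = rng.standard_normal((4, 4))
        vox = u.sample_voxels(
            field,
            u.VoxelSamplingConfig(voxel_mm=1.0, smoothing_fwhm_mm=0.0),
            mm_per_px=0.5,
        )
        expected = field.reshape(2, 2, 2, 2).mean(axis=(1, 3))
        np.testing.assert_allclose(vox, expected)

    def test_smoothing_contracts_variance(self, rng):
        field = rng.standard_normal((160, 160))
        cfg = lambda f: u.VoxelSamplingConfig(smoothing_fwhm_mm=f)
        variances = [
            u.sample_voxels(field, cfg(f), mm_per_px=0.15).var() for f in (0, 2, 4, 8)
        ]
        assert all(a >= b for a, b in zip(variances, variances[1:]))

    def test_rejects_subpixel_voxels(self, rng):
        field = rng.standard_normal((8, 8))
        with pytest.raises(ValueError):
            u.sample_voxels(
                field, u.VoxelSamplingConfig(voxel_mm=0.05), mm_per_px=0.15
            )


class TestSimulateRun:
    def _responses(self):
        rng = np.random.default_rng(0)
        return {c: rng.standard_normal(10) for c in u.CONDITIONS}

    def test_noise_free_boxcar_reproduces_condition_response(self):
        design = u.ExperimentDesign()
        resp = self._responses()
        model = u.ResponseModel(noise_sd=0.0)
        run = u.simulate_run(design, resp, model, 0, order_seed=1, hrf="boxcar")
        labels = np.array(run.volume_labels, dtype=object)
        for cond in u.CONDITIONS:
            block = run.data[:, labels == cond]
            assert block.shape[1] == 6
            np.testing.assert_allclose(
                block, np.tile(np.asarray(resp[cond])[:, None], (1, 6))
            )

    def test_default_design_block_structure(self):
        design = u.ExperimentDesign()
        assert design.volumes_per_block == 6
        run = u.simulate_run(design, self._responses(), u.ResponseModel(), 0)
        labels = np.array(run.volume_labels, dtype=object)
        stim = labels != u.FIXATION
        assert stim.sum() == 4 * 6
        for cond in u.CONDITIONS:
            assert (labels == cond).sum() == 6

    def test_noise_varies_order_fixed(self):
        design = u.ExperimentDesign()
        resp = self._responses()
        model = u.ResponseModel(noise_sd=0.5)
        a = u.simulate_run(design, resp, model, 0, order_seed=3, noise_seed=10)
        b = u.simulate_run(design, resp, model, 0, order_seed=3, noise_seed=11)
        assert a.volume_labels == b.volume_labels
        assert not np.allclose(a.data, b.data)

    def test_rejects_condition_mismatch(self):
        design = u.ExperimentDesign()
        resp = self._responses()
        resp.pop("L_low")
        with pytest.raises(ValueError, match="do not match"):
            u.simulate_run(design, resp, u.ResponseModel(), 0)


class TestSimulateExperiment:
    def test_default_design_counts(self, default_dataset):
        runs, gt = default_dataset
        assert len(runs) == 12
        n_blocks = sum(
            1
            for run in runs
            for a, b in zip([u.FIXATION] + list(run.volume_labels), run.volume_labels)
            if b != u.FIXATION and a != b
        )
        assert n_blocks == 48

    def test_null_construction_has_no_eye_information(self):
        sheet = u.make_cortical_sheet(u.GridSpec(extent_mm=(6.0, 6.0)), seed=0)
        model = u.ResponseModel(eye_selectivity=0.0, left_eye_offset_delta=0.0)
        _, gt = u.simulate_experiment(sheet=sheet, model=model, seed=0)
        for sf in u.SFS:
            np.testing.assert_array_equal(
                gt.condition_responses[f"L_{sf}"], gt.condition_responses[f"R_{sf}"]
            )

    def test_bit_identical_under_master_seed(self):
        grid = u.GridSpec(extent_mm=(6.0, 6.0))
        a, _ = u.simulate_experiment(sheet=u.make_cortical_sheet(grid, seed=2), seed=5)
        b, _ = u.simulate_experiment(sheet=u.make_cortical_sheet(grid, seed=2), seed=5)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.data, rb.data)
            assert ra.volume_labels == rb.volume_labels


class TestSimulateBehavior:
    def test_session_has_624_trials(self):
        session = u.simulate_behavior(seed=0)
        assert session.n_trials == 624

    def test_ordering_constraints_hold_exhaustively(self):
        for seed in range(5):
            session = u.simulate_behavior(seed=seed)
            conds = [
                f"{e}_{s}" for e, s in zip(session.stimulus_eye, session.sf)
            ]
            assert u.check_sequence_constraints(conds)
            # independent scan: no adjacent condition repeats, sf alternates
            assert all(a != b for a, b in zip(conds, conds[1:]))
            assert all(a != b for a, b in zip(session.sf, session.sf[1:]))

    def test_balanced_conditions(self):
        session = u.simulate_behavior(seed=1)
        conds = [f"{e}_{s}" for e, s in zip(session.stimulus_eye, session.sf)]
        counts = {c: conds.count(c) for c in u.CONDITIONS}
        assert all(v == 156 for v in counts.values())

    def test_chance_generator_accuracy_near_half(self):
        design = u.BehavioralDesign(
            dprime_per_sf={"low": 0.0, "high": 0.0},
            criterion_per_sf={"low": 0.0, "high": 0.0},
        )
        correct = []
        for seed in range(10):
            session = u.simulate_behavior(design, seed=seed)
            correct.append(session.correct.mean())
        n = 10 * 624
        margin = 2.576 * np.sqrt(0.25 / n)
        assert abs(np.mean(correct) - 0.5) < margin

    def test_deterministic_under_seed(self):
        a = u.simulate_behavior(seed=9)
        b = u.simulate_behavior(seed=9)
        assert list(a.stimulus_eye) == list(b.stimulus_eye)
        assert list(a.response_eye) == list(b.response_eye)

    def test_checker_detects_violations(self):
        assert not u.check_sequence_constraints(["L_low", "L_low", "R_high"])
        assert not u.check_sequence_constraints(["L_low", "R_low", "L_high"])

    def test_sequence_generator_validates(self, rng):
        conds = _generate_trial_sequence(48, rng)
        assert u.check_sequence_constraints(conds)
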