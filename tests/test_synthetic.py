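"""Synthetic data generator: geometry, photometry, dose response, reproducibility."""

import math

import numpy as np
import pytest

from locipair import (
    CometModel,
    DoseResponseModel,
    NucleusModel,
    SeparationInfeasibleError,
    elongation_model,
    generate_comet_image,
    generate_dose_panel,
    generate_nucleus_stack,
    generate_time_series,
    meristematic_model,
)
from locipair.stack import FOCI, NUCLEUS
from locipair.synthetic import DriftOutOfBoundsError


class TestModels:
    def test_nucleolus_must_fit_inside_nucleus(self):
        with pytest.raises(ValueError):
            NucleusModel(semi_axes_um=(1.0, 1.0, 1.0), nucleolus_radius_um=1.0)

    def test_lengths_positive(self):
        with pytest.raises(ValueError):
            NucleusModel(semi_axes_um=(0.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            NucleusModel(separation_mean_um=-1.0)

    def test_elongation_volume_exceeds_meristematic(self):
        assert elongation_model().volume_um3 > meristematic_model().volume_um3

    def test_dose_response_validation(self):
        with pytest.raises(ValueError):
            DoseResponseModel(shortening_um=5.0)  # exceeds baseline
        with pytest.raises(ValueError):
            DoseResponseModel(recovery_tau_h=0.0)


class TestNucleusStack:
    def test_zero_separation_gives_identical_coordinates(self):
        model = meristematic_model(noise=False)
        _, truth = generate_nucleus_stack(model, separation_override=0.0, seed=3)
        np.testing.assert_array_equal(truth.coordinates_um[0], truth.coordinates_um[1])
        assert truth.separation_um == 0.0

    def test_override_separation_is_exact(self):
        _, truth = generate_nucleus_stack(meristematic_model(), separation_override=3.5, seed=5)
        assert truth.separation_um == 3.5
        d = np.linalg.norm(truth.coordinates_um[0] - truth.coordinates_um[1])
        assert d == pytest.approx(3.5, abs=1e-9)

    def test_intensity_conservation_noiseless(self):
        model = meristematic_model(noise=False, size_jitter_sd=0.0)
        stack, _ = generate_nucleus_stack(model, separation_override=2.0, seed=8)
        signal = stack.channel(FOCI) - model.background
        assert signal.sum() == pytest.approx(2 * model.focus_amplitude, rel=0.01)

    def test_truth_respects_nucleoplasm_geometry(self):
        model = meristematic_model()
        for seed in range(15):
            _, truth = generate_nucleus_stack(model, seed=seed)
            rel = truth.coordinates_um - truth.nucleus_center_um
            axes = np.asarray(truth.semi_axes_um)
            assert np.all(np.sum((rel / axes) ** 2, axis=1) <= 1.0 + 1e-9)
            assert np.all(np.linalg.norm(rel, axis=1) > truth.nucleolus_radius_um)

    def test_nucleus_channel_is_filled_ellipsoid(self):
        model = meristematic_model(noise=False, size_jitter_sd=0.0)
        stack, truth = generate_nucleus_stack(model, separation_override=2.0, seed=8)
        nuc = stack.channel(NUCLEUS) - model.background
        voxvol = float(np.prod(stack.voxel_size))
        rendered = nuc.sum() / model.nucleus_intensity * voxvol
        assert rendered == pytest.approx(truth.volume_um3, rel=0.03)

    def test_impossible_separation_raises(self):
        model = meristematic_model()
        with pytest.raises(SeparationInfeasibleError):
            generate_nucleus_stack(model, separation_override=10.0, seed=1)

    def test_reproducibility_bit_identical(self):
        model = meristematic_model()
        stack_a, truth_a = generate_nucleus_stack(model, seed=99)
        stack_b, truth_b = generate_nucleus_stack(model, seed=99)
        np.testing.assert_array_equal(stack_a.data, stack_b.data)
        np.testing.assert_array_equal(truth_a.coordinates_um, truth_b.coordinates_um)
        stack_c, _ = generate_nucleus_stack(model, seed=100)
        assert not np.array_equal(stack_a.data, stack_c.data)

    def test_separation_distribution_matches_request(self):
        # geometry chosen so the normal law is not truncated by the nucleus
        model = meristematic_model(
            noise=False, separation_mean_um=2.0, separation_sd_um=0.5, size_jitter_sd=0.0
        )
        seps = np.array([
            generate_nucleus_stack(model, seed=s)[1].separation_um for s in range(500)
        ])
        se_mean = 0.5 / math.sqrt(500)
        assert abs(seps.mean() - 2.0) < 3 * se_mean
        se_sd = 0.5 / math.sqrt(2 * 499)
        assert abs(seps.std(ddof=1) - 0.5) < 3 * se_sd


class TestDoseResponse:
    def test_mean_nonincreasing_in_dose(self):
        dr = DoseResponseModel()
        means = [dr.predicted_mean_um(d, 0.0) for d in np.linspace(0, 300, 13)]
        assert all(b <= a + 1e-12 for a, b in zip(means, means[1:]))

    def test_zero_dose_is_baseline(self):
        dr = DoseResponseModel()
        assert dr.predicted_mean_um(0.0, 0.0) == pytest.approx(dr.baseline_um)

    def test_recovered_at_24h(self):
        dr = DoseResponseModel()
        assert abs(dr.predicted_mean_um(150.0, 24.0) - dr.baseline_um) < 0.05

    def test_panel_truth_shortens_with_dose(self):
        model = meristematic_model(noise=False)
        panel = generate_dose_panel(model, DoseResponseModel(), [0.0, 150.0], 15, seed=2)
        seps = {0.0: [], 150.0: []}
        for _, truth in panel:
            if not truth.paired:
                seps[truth.dose_gy].append(truth.separation_um)
        assert np.mean(seps[150.0]) < np.mean(seps[0.0])

    def test_panel_volumes_independent_of_dose(self):
        # same seed, different dose: element-wise identical volume draws
        model = meristematic_model(noise=False)
        p0 = generate_dose_panel(model, DoseResponseModel(), [0.0], 10, seed=4)
        p150 = generate_dose_panel(model, DoseResponseModel(), [150.0], 10, seed=4)
        v0 = [t.volume_um3 for _, t in p0]
        v150 = [t.volume_um3 for _, t in p150]
        np.testing.assert_allclose(v0, v150, rtol=1e-12)


class TestTimeSeries:
    def test_constant_separation_and_span(self):
        model = meristematic_model(noise=False)
        series = generate_time_series(model, 7, interval_min=10.0, drift_um_per_step=0.25, seed=6)
        assert len(series) == 7
        seps = {t.separation_um for _, t in series}
        assert len(seps) == 1
        assert series[-1][1].extra["time_min"] == 60.0

    def test_zero_drift_freezes_coordinates(self):
        model = meristematic_model(noise=False)
        series = generate_time_series(model, 3, drift_um_per_step=0.0, seed=6)
        ref = series[0][1].coordinates_um
        for _, truth in series[1:]:
            np.testing.assert_array_equal(truth.coordinates_um, ref)

    def test_large_drift_without_expansion_raises(self):
        model = meristematic_model(noise=False)
        with pytest.raises(DriftOutOfBoundsError):
            generate_time_series(model, 8, drift_um_per_step=2.0, seed=6, expand_stack=False)

    def test_needs_two_timepoints(self):
        with pytest.raises(ValueError):
            generate_time_series(meristematic_model(), 1)


class TestCometGenerator:
    @staticmethod
    def truth_masks(model):
        yy, xx = np.mgrid[0 : model.shape[0], 0 : model.shape[1]]
        cy, cx = model.head_center
        head = (yy - cy) ** 2 + (xx - cx) ** 2 <= model.head_radius_px**2
        tail = xx > cx + model.head_radius_px
        return head, tail

    def test_zero_tail_fraction_all_signal_in_head(self):
        model = CometModel(tail_fraction=0.0, noise=False)
        image, _ = generate_comet_image(model, seed=1)
        plane = image.data[0] - model.background
        head, tail = self.truth_masks(model)
        assert plane[tail].sum() == pytest.approx(0.0, abs=1e-9)
        assert plane[head].sum() == pytest.approx(model.intensity, rel=1e-6)

    def test_half_tail_fraction_pixel_sum_oracle(self):
        model = CometModel(tail_fraction=0.5, noise=False)
        image, _ = generate_comet_image(model, seed=1)
        plane = image.data[0] - model.background
        _, tail = self.truth_masks(model)
        assert plane[tail].sum() / plane.sum() == pytest.approx(0.5, abs=0.01)

    def test_full_tail_fraction_head_only_background(self):
        model = CometModel(tail_fraction=1.0, noise=False)
        image, _ = generate_comet_image(model, seed=1)
        plane = image.data[0] - model.background
        head, _ = self.truth_masks(model)
        assert plane[head].sum() == pytest.approx(0.0, abs=1e-9)

    def test_total_intensity_conserved_before_noise(self):
        for f in (0.0, 0.3, 0.7, 1.0):
            model = CometModel(tail_fraction=f, noise=False)
            image, _ = generate_comet_image(model, seed=1)
            total = (image.data[0] - model.background).sum()
            assert total == pytest.approx(model.intensity, rel=1e-6)

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            CometModel(tail_fraction=1.5)
        with pytest.raises(ValueError):
            CometModel(tail_length_px=10.0, head_radius_px=12.0)
        with pytest.raises(ValueError):
            CometModel(shape=(64, 64), tail_length_px=90.0)
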