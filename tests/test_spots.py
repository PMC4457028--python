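"""Focus detection, subvoxel localization and distance statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locipair import (
    FocusDetection,
    ImageStack,
    detect_foci,
    generate_nucleus_stack,
    generate_time_series,
    measure_pair,
    meristematic_model,
    pairing_frequency,
    summarize_distances,
    track_series,
)
from locipair.spots import pair_distance
from locipair.stack import FOCI
from locipair.synthetic import _render_foci


def det(z, y, x, score=1.0):
    return FocusDetection(position_um=(z, y, x), peak_intensity=1.0, score=score)


def foci_stack(positions_um, amplitudes, shape=(15, 69, 69), voxel=(0.5, 0.1, 0.1),
               background=10.0):
    img = background + _render_foci(shape, voxel, np.asarray(positions_um),
                                    amplitudes, (0.3, 0.125, 0.125))
    return ImageStack(data=img[None], voxel_size=voxel, channels=(FOCI,))


class TestDetection:
    def test_noiseless_localization_accuracy(self, clean_meristematic):
        _, stack, truth = clean_meristematic
        detections = detect_foci(stack)
        assert len(detections) == 2
        found = np.array([d.position_um for d in detections])
        # match detections to truth by nearest assignment
        d00 = np.linalg.norm(found[0] - truth.coordinates_um[0])
        d01 = np.linalg.norm(found[0] - truth.coordinates_um[1])
        pairing = [(0, 0), (1, 1)] if d00 < d01 else [(0, 1), (1, 0)]
        for fi, ti in pairing:
            err = np.abs(found[fi] - truth.coordinates_um[ti])
            assert err[0] < 0.25  # axial
            assert err[1] < 0.1 and err[2] < 0.1  # lateral

    def test_uniform_stack_yields_nothing(self):
        stack = ImageStack(
            data=np.full((1, 11, 41, 41), 10.0), voxel_size=(0.5, 0.1, 0.1), channels=(FOCI,)
        )
        assert detect_foci(stack) == []

    def test_brighter_focus_ranked_first(self):
        positions = [(3.5, 2.0, 2.0), (3.5, 4.5, 4.5)]
        stack = foci_stack(positions, amplitudes=[2000.0, 1000.0])
        detections = detect_foci(stack)
        assert len(detections) == 2
        top = np.array(detections[0].position_um)
        assert np.linalg.norm(top - np.array(positions[0])) < 0.15
        assert detections[0].score > detections[1].score

    def test_axial_voxel_size_scales_axial_distance(self):
        # same voxel grid content, axial voxel size doubled -> axial
        # component of the measured distance doubles
        positions = [(2.0, 3.0, 3.0), (4.0, 3.0, 3.0)]
        stack1 = foci_stack(positions, [2000.0, 2000.0], shape=(13, 61, 61))
        stack2 = ImageStack(data=stack1.data, voxel_size=(1.0, 0.1, 0.1), channels=(FOCI,))
        d1 = measure_pair(detect_foci(stack1, (0.3, 0.125))).distance_um
        d2 = measure_pair(detect_foci(stack2, (0.6, 0.125))).distance_um
        assert d2 / d1 == pytest.approx(2.0, rel=1e-3)

    @pytest.mark.parametrize("separation", [1.0, 2.0, 3.5])
    def test_unbiased_distance_recovery(self, separation):
        model = meristematic_model()
        measured = []
        for child in np.random.SeedSequence(int(separation * 10)).spawn(100):
            rng = np.random.default_rng(child)
            stack, _ = generate_nucleus_stack(model, separation_override=separation, seed=rng)
            pair = measure_pair(detect_foci(stack))
            if pair is not None and not pair.paired:
                measured.append(pair.distance_um)
        assert len(measured) >= 95
        assert abs(np.mean(measured) - separation) < 0.1


class TestMeasurePair:
    def test_identical_coordinates_paired(self):
        pair = measure_pair([det(1, 1, 1), det(1, 1, 1, score=0.5)])
        assert pair.distance_um == 0.0 and pair.paired

    def test_known_separation(self):
        pair = measure_pair([det(0, 0, 0), det(0, 0, 3.5, score=0.5)], pairing_threshold_um=0.4)
        assert pair.distance_um == pytest.approx(3.5)
        assert not pair.paired

    def test_below_threshold_paired(self):
        pair = measure_pair([det(0, 0, 0), det(0, 0.3, 0, score=0.5)], pairing_threshold_um=0.4)
        assert pair.distance_um == pytest.approx(0.3) and pair.paired

    def test_single_detection_is_merged_pair(self):
        pair = measure_pair([det(1, 2, 3)])
        assert pair.distance_um == 0.0 and pair.paired and pair.n_candidates == 1

    def test_no_detections_returns_none(self):
        assert measure_pair([]) is None

    def test_extra_candidates_counted(self):
        pair = measure_pair([det(0, 0, 0, 3.0), det(0, 0, 2.0, 2.0), det(0, 2, 0, 1.0)])
        assert pair.n_candidates == 3
        assert pair.distance_um == pytest.approx(2.0)

    @given(
        a=st.tuples(*[st.floats(0, 10) for _ in range(3)]),
        b=st.tuples(*[st.floats(0, 10) for _ in range(3)]),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_distance_symmetric_nonnegative(self, a, b):
        d_ab = pair_distance(det(*a), det(*b))
        d_ba = pair_distance(det(*b), det(*a))
        assert d_ab == d_ba >= 0
        assert (d_ab == 0) == (a == b)
        assert d_ab == pytest.approx(math.dist(a, b))


class TestSummaries:
    def make_pairs(self, distances, paired_flags, threshold=0.4):
        pairs = []
        for d, flag in zip(distances, paired_flags):
            b = det(0, 0, d, score=0.5)
            # construct distances consistent with the paired flag
            pairs.append(measure_pair([det(0, 0, 0), b], pairing_threshold_um=threshold))
            assert pairs[-1].paired == flag
        return pairs

    def test_exclusion_counts(self):
        pairs = self.make_pairs([3, 4, 5, 0.1] + [2] * 6, [False] * 3 + [True] + [False] * 6)
        summary = summarize_distances(pairs, exclude_paired=True)
        assert summary.n == 9 and summary.n_excluded_paired == 1

    def test_mean_and_sample_sd(self):
        pairs = self.make_pairs([3, 4, 5], [False] * 3)
        summary = summarize_distances(pairs)
        assert summary.mean_um == pytest.approx(4.0)
        assert summary.sd_um == pytest.approx(1.0)

    def test_all_paired_is_an_error(self):
        pairs = self.make_pairs([0.1, 0.2], [True, True])
        with pytest.raises(ValueError):
            summarize_distances(pairs)

    def test_pairing_and_distance_partition_nuclei(self):
        pairs = self.make_pairs([3, 0.1, 4, 0.2, 5], [False, True, False, True, False])
        summary = summarize_distances(pairs)
        assert summary.n + summary.n_excluded_paired == len(pairs)


class TestPairingFrequency:
    def test_fraction_per_root(self):
        pairs = [measure_pair([det(0, 0, 0), det(0, 0, 3, score=0.5)]) for _ in range(28)]
        pairs += [measure_pair([det(0, 0, 0)]) for _ in range(2)]
        out = pairing_frequency({"root1": pairs})
        assert out["per_root"]["root1"] == pytest.approx(2 / 30)

    def test_extremes(self):
        unpaired = [measure_pair([det(0, 0, 0), det(0, 0, 3, score=0.5)]) for _ in range(30)]
        paired = [measure_pair([det(0, 0, 0)]) for _ in range(30)]
        assert pairing_frequency({"r": unpaired})["mean"] == 0.0
        assert pairing_frequency({"r": paired})["mean"] == 1.0

    def test_small_root_warns_and_empty_errors(self):
        pairs = [measure_pair([det(0, 0, 0), det(0, 0, 3, score=0.5)])] * 5
        with pytest.warns(UserWarning, match="< 30"):
            pairing_frequency({"tiny": pairs})
        with pytest.raises(ValueError):
            pairing_frequency({})
        with pytest.raises(ValueError):
            pairing_frequency({"r": []})


class TestTrackSeries:
    def test_constant_truth_low_cv(self):
        model = meristematic_model()
        series = generate_time_series(model, 7, drift_um_per_step=0.2, seed=31)
        result = track_series([s for s, _ in series])
        assert len(result["distances_um"]) == 7
        assert result["n_missing"] == 0
        assert result["cv"] < 0.10

    def test_blank_frame_recorded_missing(self):
        model = meristematic_model()
        series = [s for s, _ in generate_time_series(model, 3, seed=32)]
        blank = ImageStack(
            data=np.full_like(series[0].data, 10.0),
            voxel_size=series[0].voxel_size,
            channels=series[0].channels,
        )
        result = track_series([series[0], blank, series[2]])
        assert result["n_missing"] == 1
        assert math.isnan(result["distances_um"][1])

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            track_series([])
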