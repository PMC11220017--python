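"""Spectral metric unit tests and invariant property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ewsfd import (
    ValidationError,
    box_count_profile,
    compute_metrics,
    count_spectral_boxes,
    entropy_weight,
    ew_sfd,
    possible_boxes,
    quantize_to_level,
    sfd_dsr,
    sfd_esr,
    shannon_entropy,
    spectral_histogram,
)
from oracle import brute_metrics

# small random frames at 4-bit depth, the workhorse strategy
frames_s4 = arrays(np.int64, (6, 6), elements=st.integers(0, 15))


class TestQuantize:
    @pytest.mark.parametrize(
        "S, j, values, expected",
        [
            (8, 8, [0, 37, 255], [0, 37, 255]),  # full level is the identity
            (8, 1, [200, 100], [1, 0]),
            (4, 2, [0, 5, 10, 15], [0, 1, 2, 3]),
        ],
    )
    def test_keeps_top_j_bits(self, S, j, values, expected):
        frame = np.array([values], dtype=np.int64)
        np.testing.assert_array_equal(quantize_to_level(frame, S, j)[0], expected)

    @pytest.mark.parametrize("j", [0, 9])
    def test_level_out_of_range(self, j):
        with pytest.raises(ValidationError):
            quantize_to_level(np.zeros((2, 2), int), 8, j)

    def test_value_exceeding_depth(self):
        with pytest.raises(ValidationError):
            quantize_to_level(np.full((2, 2), 16), 4, 2)


class TestShannonEntropy:
    def test_single_symbol_is_zero(self):
        frame = np.full((5, 5), 7)
        assert shannon_entropy(spectral_histogram(frame, 4, 3)) == 0.0

    @pytest.mark.parametrize("j", [1, 2, 3])
    def test_uniform_over_2j_symbols_is_j_bits(self, j):
        # one pixel in each level-j box
        frame = (np.arange(1 << j) << (4 - j)).reshape(1, -1)
        h = shannon_entropy(spectral_histogram(frame, 4, j))
        assert h == pytest.approx(j, abs=1e-12)

    def test_hand_computed_skewed_counts(self):
        # counts {3, 1} over 4 pixels: 0.75*log2(4/3) + 0.25*log2(4)
        assert shannon_entropy(np.array([3, 1])) == pytest.approx(
            0.75 * np.log2(4 / 3) + 0.25 * 2, abs=1e-12
        )

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValidationError):
            shannon_entropy(np.array([], dtype=int))


class TestBoxCounting:
    def test_constant_frame_occupies_one_box(self):
        assert count_spectral_boxes(np.full((4, 4), 9), 4, 2) == 1

    def test_eight_values_at_level_two(self):
        frame = np.arange(8).reshape(2, 4)
        assert count_spectral_boxes(frame, 3, 2) == 4

    def test_matches_exhaustive_enumeration(self, rng):
        from oracle import brute_box_histogram

        for _ in range(25):
            frame = rng.integers(0, 16, size=(6, 6))
            for j in (1, 2, 3):
                assert count_spectral_boxes(frame, 4, j) == len(
                    brute_box_histogram(frame, 4, j)
                )

    @pytest.mark.parametrize(
        "S, n, j, mode, expected",
        [
            (16, 1, 1, "esr", 65536),
            (8, 1, 3, "dsr", 8),
            (4, 3, 2, "dsr", 64),
            (4, 3, 2, "esr", 4096),
        ],
    )
    def test_possible_boxes(self, S, n, j, mode, expected):
        assert possible_boxes(S, n, j, mode) == expected


class TestSfd:
    def test_constant_frame_has_zero_dimension(self):
        frame = np.full((5, 5), 3)
        assert sfd_esr(frame, 4) == 0.0
        assert sfd_dsr(frame, 4) == 0.0
        assert ew_sfd(frame, 4) == 0.0

    def test_esr_two_level_frame(self):
        # S=2, both level-1 boxes occupied: 1 * [log 2 / log 4] / 1
        frame = np.array([[0, 2]])
        assert sfd_esr(frame, 2) == pytest.approx(0.5, abs=1e-12)

    def test_dsr_full_occupancy_is_one(self):
        frame = np.arange(16).reshape(4, 4)
        assert sfd_dsr(frame, 4) == pytest.approx(1.0, abs=1e-12)

    def test_depth_below_two_rejected(self):
        for fn in (sfd_esr, sfd_dsr, ew_sfd):
            with pytest.raises(ValidationError):
                fn(np.zeros((2, 2), int), 1)

    def test_exhaustive_2x2_frames_match_oracle(self):
        """All 256 single-band 2x2 frames at S=2 agree with brute force."""
        for code in range(256):
            vals = [(code >> (2 * k)) & 3 for k in range(4)]
            frame = np.array(vals).reshape(2, 2)
            want = brute_metrics(frame, 2)
            assert sfd_esr(frame, 2) == pytest.approx(want["sfd_esr"], abs=1e-12)
            assert sfd_dsr(frame, 2) == pytest.approx(want["sfd_dsr"], abs=1e-12)
            assert ew_sfd(frame, 2) == pytest.approx(want["ew_sfd"], abs=1e-12)

    def test_multiband_matches_oracle(self, rng):
        for _ in range(10):
            frame = rng.integers(0, 8, size=(4, 4, 2))
            want = brute_metrics(frame, 3)
            r = compute_metrics(frame, 3)
            assert r.sfd_esr == pytest.approx(want["sfd_esr"], abs=1e-12)
            assert r.sfd_dsr == pytest.approx(want["sfd_dsr"], abs=1e-12)
            assert r.ew_sfd == pytest.approx(want["ew_sfd"], abs=1e-12)
            assert r.entropy_bits == pytest.approx(want["entropy_bits"], abs=1e-12)


class TestEntropyWeight:
    def test_constant_frame_weight_zero(self):
        assert entropy_weight(np.full((3, 3), 5), 4, 2) == 0.0

    def test_uniform_histogram_weight_one(self):
        frame = (np.arange(4) << 2).reshape(2, 2)  # one pixel per level-2 box
        assert entropy_weight(frame, 4, 2) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_weight(self):
        # quantized level-2 counts {2, 1, 1} over 4 pixels -> H = 1.5, f = 0.75
        frame = np.array([[0, 1, 4, 8]])
        assert entropy_weight(frame, 4, 2) == pytest.approx(0.75, abs=1e-12)


class TestEwSfd:
    def test_equals_dsr_when_histograms_uniform(self):
        frame = np.arange(16).reshape(4, 4)  # every level histogram uniform
        assert ew_sfd(frame, 4) == pytest.approx(sfd_dsr(frame, 4), abs=1e-12)

    def test_floored_levels_reported(self):
        r = compute_metrics(np.full((3, 3), 2), 4)
        assert r.floored_levels == 3  # constant frame floors every level
        assert r.ew_sfd == 0.0


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

@settings(max_examples=150, derandomize=True, deadline=None)
@given(frames_s4)
def test_metric_ordering_and_ranges(frame):
    """0 <= ew_sfd <= sfd_dsr <= n and 0 <= H <= S*n on arbitrary frames."""
    r = compute_metrics(frame, 4)
    assert 0.0 <= r.ew_sfd <= r.sfd_dsr + 1e-12
    assert r.sfd_dsr <= r.n + 1e-12
    assert 0.0 <= r.sfd_esr
    assert 0.0 <= r.entropy_bits <= r.S * r.n + 1e-12


@settings(max_examples=100, derandomize=True, deadline=None)
@given(frames_s4)
def test_box_counts_non_decreasing_in_level(frame):
    """Refining the spectral grid never merges occupied boxes."""
    profile = box_count_profile(frame, 4)
    assert np.all(np.diff(profile.sbm) >= 0)
    assert np.all(profile.sbm <= profile.sbt_dsr)
    assert np.all((0.0 <= profile.f) & (profile.f <= 1.0))


@settings(max_examples=100, derandomize=True, deadline=None)
@given(frames_s4, st.randoms(use_true_random=False))
def test_permutation_invariance(frame, pyrandom):
    """All four metrics depend only on the value histogram, not positions."""
    flat = list(frame.ravel())
    pyrandom.shuffle(flat)
    shuffled = np.array(flat).reshape(frame.shape)
    a, b = compute_metrics(frame, 4), compute_metrics(shuffled, 4)
    assert a == b


@settings(max_examples=100, derandomize=True, deadline=None)
@given(frames_s4)
def test_relabeling_within_boxes_preserves_counts(frame):
    """A bijective value shuffle inside each level-j box keeps SBM_j and f_j."""
    j = 2
    # swap the two halves of every level-2 box (xor the bit below the kept ones)
    relabeled = frame ^ 0b10
    assert count_spectral_boxes(frame, 4, j) == count_spectral_boxes(relabeled, 4, j)
    assert entropy_weight(frame, 4, j) == pytest.approx(
        entropy_weight(relabeled, 4, j), abs=1e-12
    )


def test_depth_choice_only_changes_level_range(rng):
    """Analysing 4-bit data at container depth 8 rescales, never corrupts."""
    frame = rng.integers(0, 16, size=(6, 6))
    # at depth 8 the same values sit in the low bits; box counts at level j+4
    # of depth 8 equal counts at level j of depth 4
    for j in (1, 2, 3):
        assert count_spectral_boxes(frame, 4, j) == count_spectral_boxes(
            frame, 8, j + 4
        )
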