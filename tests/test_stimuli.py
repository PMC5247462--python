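"""Stimulus geometry, timing and mirror identities."""

import numpy as np
import pytest

from bodyn.stimuli import (
    GRAY,
    AttentionCue,
    StimulusSequence,
    build_protocol_sequence,
    crf_boundary,
    make_ambiguous_edge,
    make_blank,
    make_random_block,
    make_square,
    mirror_frame,
)
from bodyn.v1 import GaborBank, extract_contrast


class TestSquares:
    def test_geometry_and_levels(self):
        fr = make_square("left", "white", 40, 100)
        lum = fr.luminance
        assert lum.shape == (100, 100)
        assert lum[50, 49] == 1.0 and lum[50, 50] == GRAY  # edge on midline
        assert lum[50, 9] == GRAY and lum[5, 49] == GRAY  # just outside
        assert set(np.unique(lum)) == {GRAY, 1.0}

    def test_mirror_identity(self):
        left = make_square("left", "white", 40, 100)
        right = make_square("right", "white", 40, 100)
        assert np.array_equal(mirror_frame(left).luminance, right.luminance)

    @pytest.mark.parametrize("size", [41, 0, 60])
    def test_invalid_sizes(self, size):
        with pytest.raises(ValueError):
            make_square("left", "white", size, 100)

    def test_unknown_side_or_polarity(self):
        with pytest.raises(ValueError):
            make_square("up", "white", 40)
        with pytest.raises(ValueError):
            make_square("left", "red", 40)


class TestAmbiguousEdge:
    def test_halfplane_layout(self):
        fr = make_ambiguous_edge("left", "white", 100)
        assert np.all(fr.luminance[:, :50] == 1.0)
        assert np.all(fr.luminance[:, 50:] == GRAY)

    def test_local_patch_matches_square(self):
        sq = make_square("left", "white", 40, 100)
        amb = make_ambiguous_edge("left", "white", 100)
        assert np.array_equal(sq.luminance[45:55, 45:55], amb.luminance[45:55, 45:55])

    def test_gabor_response_at_crf_identical(self):
        bank = GaborBank()
        sq = extract_contrast(make_square("left", "white", 40, 100), bank)
        amb = extract_contrast(make_ambiguous_edge("left", "white", 100), bank)
        assert sq.values[:, 48:52, 48:52] == pytest.approx(
            amb.values[:, 48:52, 48:52], abs=1e-6
        )


class TestSequences:
    def test_tiling_validation(self):
        fr = make_blank(50)
        with pytest.raises(ValueError):
            StimulusSequence([(fr, 0.0, 400.0), (fr, 500.0, 1000.0)], 1000.0)
        with pytest.raises(ValueError):
            StimulusSequence([(fr, 0.0, 400.0)], 1000.0)

    def test_duration_sweep_onset(self):
        seq, _ = build_protocol_sequence("duration_sweep", grid=50, duration=125.0)
        assert seq.epochs[1][1] == 375.0 and seq.epochs[1][2] == 500.0
        assert seq.epochs[0][0].label == "blank"

    def test_repeat_flip_timeline(self):
        seq, _ = build_protocol_sequence("repeat_flip", grid=50)
        labels = [e[0].label for e in seq.epochs]
        assert labels == ["square_left_white", "square_right_black", "square_left_white"]
        assert seq.boundaries() == [0.0, 500.0, 1000.0, 1500.0]

    def test_posner_cue_positions(self):
        _, valid = build_protocol_sequence("posner", grid=100, condition="valid")
        _, invalid = build_protocol_sequence("posner", grid=100, condition="invalid")
        _, neutral = build_protocol_sequence("posner", grid=100, condition="neutral")
        bnd = crf_boundary(100)
        assert valid.center[1] == pytest.approx(bnd - 20)  # square center
        assert invalid.center[1] > bnd + 20  # fully outside, opposite side
        assert neutral.amplitude == 0.0

    def test_unknown_protocol(self):
        with pytest.raises(ValueError):
            build_protocol_sequence("strobe", grid=50)

    def test_frame_lookup(self):
        seq, _ = build_protocol_sequence("flip", grid=50)
        assert seq.frame_at(100.0).label.startswith("square_left")
        assert seq.frame_at(700.0).label.startswith("square_right")


class TestAttentionCue:
    def test_render_peak_and_zero(self):
        cue = AttentionCue((10.0, 20.0), 4.0, 0.7, "valid")
        m = cue.render(50)
        assert m[10, 20] == pytest.approx(0.7)
        assert m.max() == pytest.approx(0.7)
        assert AttentionCue(label="none").render(50).sum() == 0.0

    def test_mirrored(self):
        cue = AttentionCue((10.0, 14.0), 4.0, 0.7, "left")
        mir = cue.mirrored(50)
        assert mir.center == (10.0, 35.0) and mir.label == "right"


class TestRandomBlocks:
    def test_determinism(self):
        a = make_random_block(1, seed=0, grid=50)
        b = make_random_block(1, seed=0, grid=50)
        assert np.array_equal(a.luminance, b.luminance)

    def test_coherent_central_contour(self):
        fr = make_random_block(1, grid=50)
        assert np.all(fr.luminance[:, 24] == 0.75)
        assert np.all(fr.luminance[:, 25] == 0.25)

    def test_stimuli_differ_pairwise(self):
        frames = [make_random_block(i, grid=50) for i in (1, 2, 3)]
        for i in range(3):
            for j in range(i + 1, 3):
                frac = np.mean(frames[i].luminance != frames[j].luminance)
                assert frac > 0.10

    def test_invalid_stim_id(self):
        with pytest.raises(ValueError):
            make_random_block(9, grid=50)


def test_mirrored_protocol_frames_mirror_exactly():
    """A protocol with swapped sides is the pixel mirror of the original."""
    seq, _ = build_protocol_sequence("ambiguous", grid=50)
    mirrored = [mirror_frame(e[0]).luminance for e in seq.epochs]
    sq = make_square("right", "white", 20, 50).luminance
    amb = make_ambiguous_edge("right", "white", 50).luminance
    assert np.array_equal(mirrored[0], sq)
    assert np.array_equal(mirrored[1], amb)
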