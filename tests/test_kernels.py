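"""Surround-region generation, screening and convolution identities."""

import numpy as np
import pytest

from bodyn.kernels import (
    GaussianLobe,
    SurroundKernelSet,
    SurroundRegion,
    _render_lobes,
    default_kernel_set,
    generate_candidate,
    select_kernels,
    surround_signals,
)
from bodyn.stimuli import crf_nodes, make_ambiguous_edge, make_square
from bodyn.v1 import GaborBank, extract_contrast


class TestCandidates:
    def test_seeded_reproducibility(self):
        a = generate_candidate(np.random.default_rng(7))
        b = generate_candidate(np.random.default_rng(7))
        assert a == b

    def test_rendered_mass_balance(self):
        cand = generate_candidate(np.random.default_rng(3))
        kf = _render_lobes(cand.facilitatory, 60)
        ks = _render_lobes(cand.suppressive, 60)
        assert kf.sum() == pytest.approx(ks.sum(), abs=1e-9)
        assert kf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mirror_reflects_centers(self):
        cand = generate_candidate(np.random.default_rng(3))
        mir = cand.mirrored()
        assert mir.bo_side == "left"
        for lo, lm in zip(cand.facilitatory, mir.facilitatory):
            assert lm.dcol == -lo.dcol and lm.drow == lo.drow

    def test_serialization_roundtrip(self):
        cand = generate_candidate(np.random.default_rng(5))
        assert SurroundRegion.from_dict(cand.to_dict()) == cand


class TestSelection:
    def test_crf_centered_lobe_rejected(self):
        # a candidate whose lobes hug the midline has no side preference:
        # the guard band removes its mass, so it cannot pass screening
        flat = SurroundRegion(
            (GaussianLobe(0.0, 1.0, 3.0, 1.0),),
            (GaussianLobe(0.0, -1.0, 3.0, 1.0),),
            "right",
        )
        good = [generate_candidate(np.random.default_rng(s)) for s in range(60)]
        ks = select_kernels([flat] + good, n_types=2)
        assert flat not in ks.regions

    def test_pool_too_small(self):
        with pytest.raises(ValueError):
            select_kernels([generate_candidate(np.random.default_rng(0))])


class TestDefaultSet:
    def test_mirror_antisymmetry_of_rendered_kernels(self):
        ks = default_kernel_set(50)
        d = ks.diff_kernels
        assert np.allclose(d[: ks.n_types], d[ks.n_types :][:, :, ::-1], atol=1e-12)

    def test_all_types_agree_on_square(self):
        ks = default_kernel_set(100)
        pooled = extract_contrast(make_square("left", "white", 40, 100), GaborBank())
        o2 = surround_signals(pooled.values.sum(0), ks).o2
        nodes = crf_nodes(100)
        for i in range(ks.n_types):
            left_pref = np.mean([o2[i, r, c] for r, c in nodes])
            right_pref = np.mean([o2[ks.n_types + i, r, c] for r, c in nodes])
            assert left_pref > 0 > right_pref

    def test_ambiguous_edge_is_side_balanced(self):
        ks = default_kernel_set(100)
        pooled = extract_contrast(make_ambiguous_edge("left", "white", 100), GaborBank())
        o2 = surround_signals(pooled.values.sum(0), ks).o2
        nodes = crf_nodes(100)
        left = np.mean([o2[: ks.n_types, r, c].sum() for r, c in nodes])
        right = np.mean([o2[ks.n_types :, r, c].sum() for r, c in nodes])
        assert left == pytest.approx(right, abs=1e-9)
        assert abs(left) < 0.25  # an order of magnitude below the square signal


class TestSurroundSignals:
    def test_zero_field(self):
        ks = default_kernel_set(50)
        sig = surround_signals(np.zeros((50, 50)), ks)
        assert np.all(sig.cf == 0) and np.all(sig.o2 == 0)

    def test_sign_convention_for_figure_side(self, rng):
        ks = default_kernel_set(50)
        pooled = extract_contrast(make_square("right", "white", 20, 50), GaborBank())
        o2 = surround_signals(pooled.values.sum(0), ks).o2
        nodes = crf_nodes(50)
        right_pref = np.mean([o2[ks.n_types :, r, c].sum() for r, c in nodes])
        left_pref = np.mean([o2[: ks.n_types, r, c].sum() for r, c in nodes])
        assert right_pref > 0 > left_pref

    def test_convolution_matches_direct_summation(self, rng):
        """FFT correlation equals the brute-force double loop to 1e-10."""
        grid = 20
        region = SurroundRegion(
            (GaussianLobe(5.0, 20.0, 8.0, 1.0),),
            (GaussianLobe(-5.0, -20.0, 8.0, 1.0),),
            "right",
        )
        ks = SurroundKernelSet.from_regions_right([region], grid)
        field = rng.uniform(0.0, 1.0, (grid, grid))
        sig = surround_signals(field, ks)
        kernel = ks.cf[1]  # the right-type facilitatory map
        direct = np.zeros((grid, grid))
        r0 = kernel.shape[0] // 2
        for x in range(grid):
            for y in range(grid):
                acc = 0.0
                for u in range(grid):
                    for v in range(grid):
                        acc += field[u, v] * kernel[r0 + u - x, r0 + v - y]
                direct[x, y] = acc
        assert sig.cf[1] == pytest.approx(direct, abs=1e-10)

    def test_shape_mismatch(self):
        ks = default_kernel_set(50)
        with pytest.raises(ValueError):
            surround_signals(np.zeros((40, 40)), ks)
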