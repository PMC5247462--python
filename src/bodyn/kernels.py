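"""Surround facilitation/suppression kernels defining BO cell types.

Each border-ownership-selective cell type pairs a facilitatory and a
suppressive region made of a few Gaussian lobes placed on opposite sides of
the classical receptive field (CRF).  Contrast falling into the
facilitatory region excites the cell and contrast in the suppressive
region inhibits it, so a cell whose facilitatory side matches the figure
side responds more: that asymmetry is the border-ownership signal.  Ten
types are selected from a random pool by requiring a consistent side
preference over test squares of several sizes; the left-preferring set is
the exact mirror image of the right-preferring set.

Lobe geometry is stored at the 100-pixel reference scale and rendered at
any grid size by scaling centers and widths proportionally; every lobe is
normalized to unit integral so rendered kernels have scale-stable mass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .stimuli import REFERENCE_GRID, crf_nodes

__all__ = [
    "GaussianLobe",
    "SurroundRegion",
    "SurroundKernelSet",
    "SurroundSignals",
    "generate_candidate",
    "select_kernels",
    "build_kernel_set",
    "surround_signals",
    "default_kernel_set",
    "MASTER_SEED",
]

#: Seed from which the shipped default cell types were generated.
MASTER_SEED = 20160913


@dataclass(frozen=True)
class GaussianLobe:
    """One Gaussian region: offset from the CRF at reference scale."""

    drow: float
    dcol: float
    sigma: float
    weight: float


@dataclass(frozen=True)
class SurroundRegion:
    """Paired facilitatory/suppressive lobes for one BO cell type."""

    facilitatory: tuple[GaussianLobe, ...]
    suppressive: tuple[GaussianLobe, ...]
    bo_side: str  # side of the preferred figure: 'left' or 'right'

    def mirrored(self) -> "SurroundRegion":
        flip = lambda lobes: tuple(
            GaussianLobe(l.drow, -l.dcol, l.sigma, l.weight) for l in lobes
        )
        side = "left" if self.bo_side == "right" else "right"
        return SurroundRegion(flip(self.facilitatory), flip(self.suppressive), side)

    def to_dict(self) -> dict:
        pack = lambda lobes: [[l.drow, l.dcol, l.sigma, l.weight] for l in lobes]
        return {
            "bo_side": self.bo_side,
            "facilitatory": pack(self.facilitatory),
            "suppressive": pack(self.suppressive),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurroundRegion":
        unpack = lambda rows: tuple(GaussianLobe(*r) for r in rows)
        return cls(unpack(d["facilitatory"]), unpack(d["suppressive"]), d["bo_side"])


#: Half-width (reference pixels) of the band around the CRF column that is
#: excluded from every surround region: the surround mechanism pools
#: contrast *outside* the CRF, and without this exclusion the strong
#: response band of the central edge itself would dominate both regions.
CRF_GUARD = 4.0


def _render_lobes(lobes: Sequence[GaussianLobe], grid: int) -> np.ndarray:
    """Rasterize lobes on a (2*grid+1)^2 window centered on the CRF.

    The guard band around the CRF column is zeroed and the rendered map is
    renormalized to unit mass, so facilitatory and suppressive regions are
    mass-balanced exactly by construction.
    """
    f = grid / REFERENCE_GRID
    r = grid
    ys, xs = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    out = np.zeros_like(ys)
    for lobe in lobes:
        s = lobe.sigma * f
        g = np.exp(-((ys - lobe.drow * f) ** 2 + (xs - lobe.dcol * f) ** 2) / (2 * s**2))
        total = g.sum()
        if total > 0:
            out += lobe.weight * g / total
    out[:, np.abs(xs[0]) <= CRF_GUARD * f] = 0.0
    total = out.sum()
    if total > 0:
        out /= total
    return out


@dataclass
class SurroundKernelSet:
    """Rendered kernel stack for the 2 * n_types BO populations.

    Channel order is left-preferring types first, then the mirrored
    right-preferring types, matching the sign convention of the BO signal
    (left minus right).
    """

    regions: tuple[SurroundRegion, ...]  # left types then right types
    grid: int
    cf: np.ndarray = field(init=False)  # (2*n_types, 2*grid+1, 2*grid+1)
    cs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.regions)
        if n % 2:
            raise ValueError("kernel set must hold matched left/right types")
        self.cf = np.stack([_render_lobes(r.facilitatory, self.grid) for r in self.regions])
        self.cs = np.stack([_render_lobes(r.suppressive, self.grid) for r in self.regions])

    @property
    def n_types(self) -> int:
        return len(self.regions) // 2

    @property
    def diff_kernels(self) -> np.ndarray:
        """Facilitatory-minus-suppressive maps used for the O2 convolution."""
        return self.cf - self.cs

    def to_json(self) -> str:
        right = self.regions[self.n_types :]
        return json.dumps(
            {"master_seed": MASTER_SEED, "right_types": [r.to_dict() for r in right]},
            indent=1,
        )

    @classmethod
    def from_regions_right(
        cls, right: Sequence[SurroundRegion], grid: int
    ) -> "SurroundKernelSet":
        left = tuple(r.mirrored() for r in right)
        return cls(left + tuple(right), grid)


def generate_candidate(
    rng: np.random.Generator,
    offset_range: tuple[float, float] = (5.0, 45.0),
    sigma_range: tuple[float, float] = (3.0, 12.0),
    row_span: float = 30.0,
    max_lobes: int = 3,
) -> SurroundRegion:
    """Draw one random right-preferring candidate region.

    The facilitatory lobes sit to the right of the CRF and the suppressive
    lobes to the left; lobe weights are normalized so total facilitatory
    mass equals total suppressive mass (unit mass each side).
    """

    def lobes(side_sign: float) -> tuple[GaussianLobe, ...]:
        n = int(rng.integers(1, max_lobes + 1))
        raw = []
        weights = rng.uniform(0.5, 1.0, n)
        weights /= weights.sum()
        for w in weights:
            dcol = side_sign * rng.uniform(*offset_range)
            drow = rng.uniform(-row_span, row_span)
            sigma = rng.uniform(*sigma_range)
            raw.append(GaussianLobe(drow, dcol, sigma, float(w)))
        return tuple(raw)

    return SurroundRegion(lobes(+1.0), lobes(-1.0), "right")


@dataclass
class SurroundSignals:
    """CF, CS and their difference O2 per population channel."""

    cf: np.ndarray
    cs: np.ndarray

    @property
    def o2(self) -> np.ndarray:
        return self.cf - self.cs


def _correlate(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # kernel[u] weights the field at offset +u from the cell, i.e. a spatial
    # correlation; fftconvolve flips its kernel, so pre-flip to compensate.
    return fftconvolve(field, kernel[::-1, ::-1], mode="same")


def surround_signals(v1_sum: np.ndarray, kernel_set: SurroundKernelSet) -> SurroundSignals:
    """Pool the summed V1 map through every rendered surround region."""
    if v1_sum.shape != (kernel_set.grid, kernel_set.grid):
        raise ValueError("v1_sum shape does not match kernel grid")
    cf = np.stack([_correlate(v1_sum, k) for k in kernel_set.cf])
    cs = np.stack([_correlate(v1_sum, k) for k in kernel_set.cs])
    return SurroundSignals(cf, cs)


def _static_o2_at_crf(region: SurroundRegion, pooled_contrast: np.ndarray) -> float:
    grid = pooled_contrast.shape[0]
    kf = _render_lobes(region.facilitatory, grid)
    ks = _render_lobes(region.suppressive, grid)
    diff = _correlate(pooled_contrast, kf - ks)
    return float(np.mean([diff[r, c] for r, c in crf_nodes(grid)]))


def select_kernels(
    pool: Sequence[SurroundRegion],
    test_sizes: Sequence[int] = (24, 40, 48),
    n_types: int = 10,
    grid: int = REFERENCE_GRID,
    margin: float = 1e-3,
    ambiguity_tol: float = 0.02,
) -> SurroundKernelSet:
    """Keep candidates with a robust, size-consistent side preference.

    A right-preferring candidate passes if, for every test square size, the
    static surround signal at the CRF is positive for a square on the right
    of the CRF and negative for a square on the left, with at least
    ``margin`` separation.  In addition the candidate must be side-neutral
    for an isolated full-height edge (|O2| below ``ambiguity_tol``), the
    defining property of border-ownership cells facing an edge with no
    figural context.  Selection order follows the pool order, so a seeded
    pool yields a deterministic set.
    """
    from . import v1 as _v1
    from .stimuli import make_ambiguous_edge, make_square

    if len(pool) < 5 * n_types:
        raise ValueError("candidate pool too small for a robust selection")
    if len(test_sizes) < 2:
        raise ValueError("need at least two test square sizes")
    bank = _v1.GaborBank()
    scale = grid / REFERENCE_GRID
    contrasts = {}
    for size in test_sizes:
        px = int(round(size * scale / 2)) * 2
        for side in ("left", "right"):
            frame = make_square(side, "white", px, grid)
            contrasts[(size, side)] = _v1.extract_contrast(frame, bank).values.sum(axis=0)
    edge = make_ambiguous_edge("left", "white", grid)
    edge_contrast = _v1.extract_contrast(edge, bank).values.sum(axis=0)

    chosen: list[SurroundRegion] = []
    for cand in pool:
        ok = abs(_static_o2_at_crf(cand, edge_contrast)) < ambiguity_tol
        for size in test_sizes:
            if not ok:
                break
            pref = _static_o2_at_crf(cand, contrasts[(size, "right")])
            opp = _static_o2_at_crf(cand, contrasts[(size, "left")])
            if not (pref > margin and opp < -margin):
                ok = False
                break
        if ok:
            chosen.append(cand)
            if len(chosen) == n_types:
                break
    if len(chosen) < n_types:
        raise RuntimeError(
            f"only {len(chosen)} of {n_types} candidates passed selection; "
            "enlarge the candidate pool"
        )
    return SurroundKernelSet.from_regions_right(chosen, grid)


def build_kernel_set(
    master_seed: int = MASTER_SEED,
    pool_size: int = 120,
    grid: int = REFERENCE_GRID,
    n_types: int = 10,
) -> SurroundKernelSet:
    """Generate, screen and mirror a full kernel set from one seed."""
    rng = np.random.default_rng(master_seed)
    pool = [generate_candidate(rng) for _ in range(pool_size)]
    return select_kernels(pool, n_types=n_types, grid=grid)


_DEFAULT_CACHE: dict[int, SurroundKernelSet] = {}


def default_kernel_set(grid: int = REFERENCE_GRID) -> SurroundKernelSet:
    """The shipped cell types, rendered (and cached) at the given grid."""
    if grid not in _DEFAULT_CACHE:
        text = resources.files("bodyn").joinpath("data/kernels_default.json").read_text()
        right = [SurroundRegion.from_dict(d) for d in json.loads(text)["right_types"]]
        _DEFAULT_CACHE[grid] = SurroundKernelSet.from_regions_right(right, grid)
    return _DEFAULT_CACHE[grid]
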