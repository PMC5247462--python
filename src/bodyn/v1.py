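"""V1 stage: oriented contrast extraction and gain-modulated drive.

Local, oriented luminance contrast is measured with a quadrature-pair Gabor
energy model at four orientations, rescaled so a full-contrast edge maps to
the top of the [0, 2] contrast range.  The excitatory drive to the V1 field
divides that contrast by a Gaussian pool of neighbourhood contrast
(divisive normalization) and multiplies it by an exponential function of
the parietal feedback, so attention acts as a contrast-gain factor >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.ndimage import correlate, gaussian_filter
from scipy.signal import fftconvolve

from .core import NeuralField, TransferParams, rate_derivative, rk4_step
from .stimuli import Frame, GRAY

CONTRAST_CEILING = 2.0

__all__ = ["GaborBank", "ContrastMap", "extract_contrast", "v1_drive", "v1_step"]


@dataclass(frozen=True)
class GaborBank:
    """Quadrature Gabor filters at four edge orientations.

    ``orientations`` are preferred *edge* orientations in degrees (90 means
    a vertical edge); the carrier runs perpendicular to the edge.  A single
    spatial frequency suffices for the step-edge stimuli used here.
    """

    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    frequency: float = 0.25
    envelope_sigma: float = 2.0
    radius: int = 6

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return tuple(f"theta{int(o)}" for o in self.orientations)

    def kernels(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return _build_kernels(self)

    def edge_calibration(self) -> float:
        """Scale factor mapping a full white/black edge response to 2.0."""
        return _edge_calibration(self)


@lru_cache(maxsize=8)
def _build_kernels(bank: GaborBank) -> list[tuple[np.ndarray, np.ndarray]]:
    r = bank.radius
    ys, xs = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    envelope = np.exp(-(xs**2 + ys**2) / (2.0 * bank.envelope_sigma**2))
    pairs = []
    for theta in bank.orientations:
        phi = np.deg2rad(theta + 90.0)  # carrier direction: across the edge
        u = xs * np.cos(phi) + ys * np.sin(phi)
        even = envelope * np.cos(2.0 * np.pi * bank.frequency * u)
        odd = envelope * np.sin(2.0 * np.pi * bank.frequency * u)
        even -= even.mean()  # zero-mean: no response to uniform luminance
        odd -= odd.mean()
        norm = np.sqrt((even**2 + odd**2).sum() / 2.0)
        pairs.append((even / norm, odd / norm))
    return pairs


@lru_cache(maxsize=8)
def _edge_calibration(bank: GaborBank) -> float:
    size = 4 * bank.radius + 9
    lum = np.zeros((size, size))
    lum[:, : size // 2] = 1.0  # white | black step, contrast 1.0
    lum -= lum.mean()
    peak = 0.0
    for even, odd in _build_kernels(bank):
        e = fftconvolve(lum, even, mode="same")
        o = fftconvolve(lum, odd, mode="same")
        peak = max(peak, float(np.sqrt(e**2 + o**2).max()))
    return CONTRAST_CEILING / peak


@dataclass
class ContrastMap:
    """Normalized contrast energy per (orientation, row, col) in [0, 2]."""

    values: np.ndarray
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0 or self.values.max() > CONTRAST_CEILING + 1e-9:
            raise ValueError("contrast energy outside [0, 2]")


def extract_contrast(
    frame: Frame, bank: GaborBank = GaborBank(), floor: float = 5e-3
) -> ContrastMap:
    """Quadrature contrast energy of a frame for every orientation channel.

    The frame is measured relative to the mid-gray background and filtered
    with replicated borders (the frame is a window into a larger scene, so
    the image is continued outward rather than cut off, which would create
    spurious contrast along the window border).  Energies are globally
    rescaled by the bank's full-contrast-edge calibration and clipped to
    the [0, 2] range.  Energies below ``floor`` are zeroed; they are
    indistinguishable from quantization ripple and keeping them exactly
    zero lets downstream code treat unstimulated locations as silent.
    """
    signal = frame.luminance - GRAY
    scale = bank.edge_calibration()
    maps = []
    for even, odd in bank.kernels():
        e = correlate(signal, even[::-1, ::-1], mode="nearest")
        o = correlate(signal, odd[::-1, ::-1], mode="nearest")
        energy = scale * np.sqrt(e**2 + o**2)
        energy[energy < floor] = 0.0
        maps.append(np.minimum(energy, CONTRAST_CEILING))
    return ContrastMap(np.stack(maps), bank.channel_labels)


def contrast_pool(contrast: ContrastMap, pool_sigma: float = 4.0) -> np.ndarray:
    """Gaussian-weighted spatial pool of contrast summed over channels."""
    return gaussian_filter(contrast.values.sum(axis=0), pool_sigma, mode="constant")


def v1_drive(
    contrast: ContrastMap,
    pp_norm: np.ndarray | None = None,
    w_fb: float = 0.6,
    pool_sigma: float = 4.0,
    pool: np.ndarray | None = None,
) -> np.ndarray:
    """Excitatory V1 drive: attention-scaled contrast over a divisive pool.

    ``drive = contrast * exp(w_fb * pp_norm) / (1 + pool)`` per channel,
    re-clipped to the [0, 2] contrast range.  ``pp_norm`` is the parietal
    feedback field rescaled to [0, 1]; with no feedback the gain is exactly
    one and the drive is purely feedforward.
    """
    if pool is None:
        pool = contrast_pool(contrast, pool_sigma)
    gain = 1.0 if pp_norm is None else np.exp(w_fb * np.clip(pp_norm, 0.0, 1.0))
    drive = contrast.values * gain / (1.0 + pool)[None]
    return np.minimum(drive, CONTRAST_CEILING)


def v1_step(
    a_v1: NeuralField,
    drive: np.ndarray,
    noise: np.ndarray,
    dt: float = 0.1,
    mu: float = 0.95,
    params: TransferParams = TransferParams(),
) -> NeuralField:
    """One RK4 step of the V1 field with the noise sample held constant."""
    if drive.shape != a_v1.values.shape:
        raise ValueError("drive shape does not match V1 field")
    new = rk4_step(
        lambda y: rate_derivative(y, drive, mu, 0.0, params, noise), a_v1.values, dt
    )
    return NeuralField(new, a_v1.channels)
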