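"""End-to-end simulation of the coupled V1 / V2 / parietal network.

:class:`BONetwork` binds the stimulus pipeline (contrast extraction,
surround kernels, attention cues) to the RK4 engine and produces the
border-ownership signal ``nu(t)`` — the summed discharge rate of the
left-preferring minus the right-preferring BO populations at the recorded
edge location, in Hz — for one seeded trial at a time.

Numerical organisation: static per-epoch quantities (contrast maps, the
divisive-normalization pool) are computed when the stimulus frame changes;
slow inter-module signals (surround convolutions, the smoothed parietal
afferent) are refreshed every ``couple_every`` integration steps; noise is
redrawn per unit per step.  Within one step all inputs are frozen, which
makes the stepping exactly reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft2, next_fast_len, rfft2

from . import _engine
from .config import RunConfig
from .core import transfer, TransferParams
from .kernels import SurroundKernelSet, default_kernel_set
from .stimuli import AttentionCue, StimulusSequence, crf_nodes
from .v1 import GaborBank, contrast_pool, extract_contrast

__all__ = ["BOTrace", "BONetwork"]

#: Sub-rheobase activities above this level promote a unit into the
#: nonlinear active set at the next refresh (half the rheobase 0.1).
#: Strongly inhibited (negative) activities stay on the exact affine path.
ACTIVE_THRESHOLD = 0.05
#: Parietal drive below this leaves a unit on the affine path (its drive
#: still enters the affine update exactly).
PP_DRIVE_THRESHOLD = 0.02


@dataclass
class BOTrace:
    """BO signal time series for a single trial."""

    times: np.ndarray          #: ms, uniform grid including t=0
    nu: np.ndarray             #: Hz; positive = left side owns the border
    location: tuple[int, int]  #: nominal CRF node (row, col)
    trial_seed: int
    condition: str = ""

    def __post_init__(self) -> None:
        if len(self.times) != len(self.nu):
            raise ValueError("times and nu must align")
        d = np.diff(self.times)
        if len(d) and (np.any(d <= 0) or np.ptp(d) > 1e-9):
            raise ValueError("times must increase on a uniform grid")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def _gaussian_kernel(sigma: float) -> np.ndarray:
    r = max(1, int(np.ceil(4.0 * sigma)))
    ys, xs = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    g = np.exp(-(ys**2 + xs**2) / (2.0 * sigma**2))
    return g / g.sum()


def _trim_centered(kernel: np.ndarray, rel_tol: float = 1e-6) -> np.ndarray:
    """Symmetrically trim an odd-sized centered kernel to its support."""
    c = kernel.shape[0] // 2
    nz = np.argwhere(np.abs(kernel) > rel_tol * np.abs(kernel).max())
    if nz.size == 0:
        return kernel[c : c + 1, c : c + 1]
    r = int(np.abs(nz - c).max())
    return kernel[c - r : c + r + 1, c - r : c + r + 1]


class _CorrelationBank:
    """Batched FFT correlation of one field with a fixed kernel stack."""

    def __init__(self, kernels: list[np.ndarray], grid: int):
        trimmed = [_trim_centered(k) for k in kernels]
        self.radius = max(k.shape[0] // 2 for k in trimmed)
        size = 2 * self.radius + 1
        self.grid = grid
        self.pad = next_fast_len(grid + size - 1)
        stack = np.zeros((len(kernels), size, size))
        for i, k in enumerate(trimmed):
            r = k.shape[0] // 2
            c = self.radius
            stack[i, c - r : c + r + 1, c - r : c + r + 1] = k
        # correlation == convolution with the flipped kernel
        self.kfft = rfft2(stack[:, ::-1, ::-1], s=(self.pad, self.pad))

    def __call__(self, field: np.ndarray) -> np.ndarray:
        ffft = rfft2(field, s=(self.pad, self.pad))
        full = irfft2(ffft[None] * self.kfft, s=(self.pad, self.pad))
        r = self.radius
        return full[:, r : r + self.grid, r : r + self.grid]


class BONetwork:
    """The three-module border-ownership network for one configuration."""

    def __init__(self, config: RunConfig, kernel_set: SurroundKernelSet | None = None):
        self.config = config
        self.bank = GaborBank(
            frequency=config.gabor_freq, envelope_sigma=config.gabor_sigma
        )
        self.kernel_set = kernel_set or default_kernel_set(config.grid)
        if self.kernel_set.n_types != config.n_types:
            raise ValueError("kernel set size does not match configuration")
        g = config.grid
        self.hw = g * g
        self.n1 = len(self.bank.orientations) * self.hw
        self.n2 = 2 * config.n_types * self.hw
        diff = [config.surround_gain * k for k in self.kernel_set.diff_kernels]
        smooth = _gaussian_kernel(config.pp_smooth_sigma * config.scale)
        self._corr = _CorrelationBank(list(diff) + [smooth], g)
        self.crf_idx = np.array([r * g + c for r, c in crf_nodes(g)], dtype=np.int64)
        self._tp = TransferParams(config.tau, config.t_r)
        self._rho = _engine.rk4_linear_factor(config.dt, config.tau)
        # inhibitory pool normalization; the edge-dominated active
        # population grows linearly with the grid side, so the pool scale
        # is referenced to the 100-px grid
        ref = 100.0 / g
        self._kap2 = config.kappa * config.inh_scale_v2 * ref
        self._kapp = config.kappa * config.inh_scale_pp * ref
        self._contrast_cache: dict = {}

    # ------------------------------------------------------------------
    def _epoch_static(self, frame):
        key = hash(frame.luminance.tobytes())
        if key not in self._contrast_cache:
            cfg = self.config
            cmap = extract_contrast(frame, self.bank, cfg.contrast_floor)
            pool = contrast_pool(cmap, cfg.pool_sigma * cfg.scale)
            inv_flat = np.ascontiguousarray((1.0 / (1.0 + pool)).reshape(-1))
            contrast = np.ascontiguousarray(cmap.values.reshape(-1))
            c0 = contrast * np.tile(inv_flat, len(self.bank.orientations))
            # units whose drive cannot come near rheobase even at maximal
            # attention gain stay on the affine path for the whole epoch
            fireable = c0 * np.exp(cfg.w_fb) > 0.6 * (1.0 / cfg.tau)
            self._contrast_cache[key] = (contrast, inv_flat, c0, fireable)
        return self._contrast_cache[key]

    def _rates_map(self, a1: np.ndarray) -> np.ndarray:
        rates = transfer(a1.reshape(len(self.bank.orientations), -1), self._tp)
        return rates.sum(axis=0).reshape(self.config.grid, self.config.grid)

    # ------------------------------------------------------------------
    def run_trial(
        self,
        sequence: StimulusSequence,
        cue: AttentionCue | None = None,
        seed: int = 0,
        condition: str = "",
        snapshot_times: tuple[float, ...] = (),
    ) -> tuple[BOTrace, dict[float, dict[str, np.ndarray]]]:
        """Integrate one trial from a zeroed state.

        Returns the BO trace sampled at every step (plus t=0) and, if
        ``snapshot_times`` are given, per-module field snapshots taken at
        the nearest refresh boundary.
        """
        cfg = self.config
        if sequence.grid != cfg.grid:
            raise ValueError("stimulus grid does not match configuration")
        g = cfg.grid
        hw = self.hw
        rng = np.random.default_rng(np.random.SeedSequence([seed]))
        a1 = np.zeros(self.n1)
        a2 = np.zeros(self.n2)
        ap = np.zeros(hw)
        inh = np.zeros(2)
        cue_map = (cue or AttentionCue()).render(g).reshape(-1)

        n_total = int(round(sequence.total_duration / cfg.dt))
        nu = np.zeros(n_total + 1)
        snapshots: dict[float, dict[str, np.ndarray]] = {}
        want = sorted(snapshot_times)

        boundaries = [int(round(b / cfg.dt)) for b in sequence.boundaries()]
        step = 0
        nt = cfg.n_types
        n_noise = self.n1 + self.n2 + hw
        span = cfg.noise_high - cfg.noise_low
        for e, (frame, onset, offset) in enumerate(sequence.epochs):
            contrast, inv_pool, c0, fireable = self._epoch_static(frame)
            end = boundaries[e + 1]
            while step < end:
                n_chunk = min(cfg.couple_every, end - step)
                s_map = self._rates_map(a1)
                corr = self._corr(s_map)
                o2 = np.ascontiguousarray(corr[:-1].reshape(-1))
                aff_cue = cfg.pp_afferent_gain * corr[-1].reshape(-1) + cue_map

                act1 = np.flatnonzero(fireable | (a1 > ACTIVE_THRESHOLD))
                px1 = np.zeros(hw, dtype=bool)
                px1[act1 % hw] = True
                mask2 = np.zeros((2 * nt, hw), dtype=bool)
                mask2[:, px1] = True
                mask2 = mask2.reshape(-1) | (a2 > ACTIVE_THRESHOLD)
                act2 = np.flatnonzero(mask2)
                actp = np.flatnonzero(
                    (aff_cue > PP_DRIVE_THRESHOLD) | (ap > ACTIVE_THRESHOLD)
                )

                noise = rng.random((n_chunk, n_noise), dtype=np.float32)
                noise *= span
                noise += cfg.noise_low
                done = _engine.advance_chunk(
                    a1, a2, ap, inh,
                    act1, act2, actp,
                    act1 % hw, act2 % hw,
                    contrast, inv_pool, c0, o2, aff_cue,
                    noise, nu[step + 1 : step + 1 + n_chunk], self.crf_idx,
                    cfg.dt, cfg.tau, cfg.t_r, cfg.mu, cfg.gamma, cfg.lam,
                    self._kap2, self._kapp, cfg.w_fb, cfg.v1_to_v2_gain,
                    cfg.pp_norm_floor, self._rho, nt, hw,
                )
                if done < n_chunk:
                    raise FloatingPointError(
                        f"non-finite state at t={(step + done) * cfg.dt:.1f} ms "
                        f"(seed {seed}, condition {condition!r})"
                    )
                step += n_chunk
                t_now = step * cfg.dt
                while want and want[0] <= t_now + 1e-9:
                    want.pop(0)
                    snapshots[t_now] = {
                        "v1_sum": self._rates_map(a1),
                        "pp": transfer(ap, self._tp).reshape(g, g),
                        "v2_left": transfer(
                            a2.reshape(2 * nt, g, g)[:nt], self._tp
                        ).sum(axis=0),
                        "v2_right": transfer(
                            a2.reshape(2 * nt, g, g)[nt:], self._tp
                        ).sum(axis=0),
                    }

        times = np.arange(n_total + 1) * cfg.dt
        trace = BOTrace(times, nu, (g // 2, g // 2), seed, condition)
        return trace, snapshots
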