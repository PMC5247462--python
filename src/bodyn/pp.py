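"""Posterior-parietal stage: saliency field, inhibition, V1 feedback.

Standalone definitions of the parietal operations; the production
simulator fuses the same equations into its compiled loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import NoiseSpec, TransferParams, rk4_step, transfer
from .stimuli import AttentionCue

__all__ = ["PPParams", "PPState", "pp_afferent", "pp_step", "pp_feedback"]


@dataclass(frozen=True)
class PPParams:
    """Gains of the parietal field and its shared inhibitory unit."""

    mu: float = 0.95
    gamma: float = 0.8
    kappa: float = 0.05
    lam: float = 0.1
    afferent_gain: float = 0.3    #: V1 -> parietal drive scale
    smooth_sigma: float = 3.0     #: afferent smoothing width, px
    norm_floor: float = 1.0       #: floor of the feedback normalization
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    transfer: TransferParams = field(default_factory=TransferParams)


@dataclass
class PPState:
    """Parietal activities per grid node plus the inhibitory unit."""

    activities: np.ndarray
    inhibitory_activity: float = 0.0

    def __post_init__(self) -> None:
        self.activities = np.asarray(self.activities, dtype=float)
        if self.activities.ndim != 2:
            raise ValueError("expected a (rows, cols) parietal field")
        if not np.all(np.isfinite(self.activities)):
            raise ValueError("non-finite parietal activity")


def pp_afferent(v1_sum: np.ndarray, params: PPParams = PPParams()) -> np.ndarray:
    """Afferent drive: the pooled V1 rate map, smoothed and scaled.

    The Gaussian smoothing spreads each contour's contribution so the
    parietal field represents object *location* rather than fine contour
    structure; scaling is linear, so two stimuli of equal contrast
    contribute equal afferent mass.
    """
    return params.afferent_gain * gaussian_filter(
        np.asarray(v1_sum, dtype=float), params.smooth_sigma, mode="constant"
    )


def pp_step(
    state: PPState,
    afferent: np.ndarray,
    cue: AttentionCue | None = None,
    params: PPParams = PPParams(),
    noise: np.ndarray | float = 0.0,
    dt: float = 0.1,
) -> PPState:
    """One RK4 step of the parietal field and its inhibitory unit."""
    if np.shape(afferent) != state.activities.shape:
        raise ValueError("afferent shape does not match parietal state")
    tp = params.transfer
    grid = state.activities.shape[0]
    cue_map = (cue or AttentionCue()).render(grid)
    n = state.activities.size
    noise_flat = np.broadcast_to(np.asarray(noise, dtype=float), state.activities.shape)
    drive = (np.asarray(afferent, dtype=float) + cue_map + noise_flat).reshape(-1)
    y0 = np.concatenate([state.activities.reshape(-1), [state.inhibitory_activity]])

    def deriv(y):
        a, inh = y[:n], y[n]
        f = transfer(a, tp)
        f_inh = transfer(inh, tp)
        da = (-a + params.mu * f - params.gamma * f_inh + drive) / tp.tau
        di = (-inh + params.lam * f_inh + params.kappa * f.sum()) / tp.tau
        return np.concatenate([da, [di]])

    y1 = rk4_step(deriv, y0, dt)
    return PPState(y1[:n].reshape(state.activities.shape), float(y1[n]))


def pp_feedback(state: PPState, norm_floor: float = 1.0) -> np.ndarray:
    """Feedback field for the V1 contrast gain: activity rescaled to [0, 1].

    Rectified activities are divided by the field maximum, floored at
    ``norm_floor`` so a silent field feeds back zeros (unit V1 gain)
    rather than amplifying noise.
    """
    a = np.clip(state.activities, 0.0, None)
    return a / max(float(a.max()), norm_floor)
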