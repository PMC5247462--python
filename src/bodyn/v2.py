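"""Border-ownership cell stage: feedforward drive, dynamics, BO signal.

These operations define the V2 stage one step at a time on explicit state
objects.  The production simulator (:mod:`bodyn.model`) fuses the same
equations into a compiled loop; the definitions here are the reference
surface for analysis, experimentation and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import NoiseSpec, TransferParams, rk4_step, transfer
from .stimuli import crf_nodes

__all__ = ["V2Params", "V2State", "v2_feedforward", "v2_step", "bo_signal"]


@dataclass(frozen=True)
class V2Params:
    """Gains of the BO-cell field and its shared inhibitory unit."""

    mu: float = 0.95      #: excitatory recurrent gain
    gamma: float = 0.8    #: inhibitory-unit gain onto the BO cells
    kappa: float = 0.05   #: summed-rate input gain onto the inhibitory unit
    lam: float = 0.1      #: inhibitory-unit recurrent gain
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    transfer: TransferParams = field(default_factory=TransferParams)

    def __post_init__(self) -> None:
        if min(self.mu, self.gamma, self.kappa, self.lam) <= 0:
            raise ValueError("V2 gains must be positive")


@dataclass
class V2State:
    """Activities per (type x side, row, col) plus the inhibitory unit.

    The leading axis stacks the left-preferring types first, then the
    mirrored right-preferring types, matching the BO-signal convention.
    """

    activities: np.ndarray
    inhibitory_activity: float = 0.0

    def __post_init__(self) -> None:
        self.activities = np.asarray(self.activities, dtype=float)
        if self.activities.ndim != 3 or self.activities.shape[0] % 2:
            raise ValueError("expected (2*n_types, rows, cols) activities")
        if not np.all(np.isfinite(self.activities)):
            raise ValueError("non-finite V2 activity")

    @property
    def n_types(self) -> int:
        return self.activities.shape[0] // 2


def v2_feedforward(o1: np.ndarray, o2: np.ndarray) -> np.ndarray:
    """Surround-modulated feedforward drive ``O1 * (O1 + O2)``.

    ``o1`` is the (rows, cols) CRF response map from V1 and ``o2`` the
    per-channel surround signal.  The multiplicative ``O1`` acts as a
    switch: no drive, facilitatory or suppressive, arises where nothing
    falls on the CRF; net suppression (negative drive) is permitted.
    """
    o1 = np.asarray(o1, dtype=float)
    if np.any(o1 < 0):
        raise ValueError("the CRF response map must be nonnegative")
    return o1 * (o1 + np.asarray(o2, dtype=float))


def v2_step(
    state: V2State,
    drive: np.ndarray,
    params: V2Params = V2Params(),
    noise: np.ndarray | float = 0.0,
    dt: float = 0.1,
) -> V2State:
    """One RK4 step of the BO field and its inhibitory unit.

    The inhibitory unit receives ``kappa`` times the summed discharge of
    all excitatory units and inhibits them all; it carries no noise term
    of its own.  Noise and drive are frozen over the step.
    """
    if np.shape(drive) != state.activities.shape:
        raise ValueError("drive shape does not match V2 state")
    tp = params.transfer
    n = state.activities.size
    y0 = np.concatenate([state.activities.reshape(-1), [state.inhibitory_activity]])
    noise_flat = np.broadcast_to(np.asarray(noise, dtype=float), state.activities.shape)
    drive_eta = (np.asarray(drive, dtype=float) + noise_flat).reshape(-1)

    def deriv(y):
        a, inh = y[:n], y[n]
        f = transfer(a, tp)
        f_inh = transfer(inh, tp)
        da = (-a + params.mu * f - params.gamma * f_inh + drive_eta) / tp.tau
        di = (-inh + params.lam * f_inh + params.kappa * f.sum()) / tp.tau
        return np.concatenate([da, [di]])

    y1 = rk4_step(deriv, y0, dt)
    return V2State(y1[:n].reshape(state.activities.shape), float(y1[n]))


def bo_signal(
    state: V2State,
    location: tuple[int, int] | None = None,
    params: TransferParams = TransferParams(),
) -> float:
    """BO signal: left-preferring minus right-preferring rates, in Hz.

    Positive values indicate left border ownership.  With no explicit
    location the four nodes bracketing the recorded midline edge are
    averaged, as in the full simulator.
    """
    nt = state.n_types
    rates = transfer(state.activities, params)
    if location is None:
        grid = state.activities.shape[1]
        nodes = crf_nodes(grid)
    else:
        nodes = [location]
    vals = [rates[:nt, r, c].sum() - rates[nt:, r, c].sum() for r, c in nodes]
    return 1000.0 * float(np.mean(vals))
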