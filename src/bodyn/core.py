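"""Shared rate-unit dynamics: transfer function, noise, and RK4 stepping.

All module fields in the network obey the same first-order rate equation

    tau * dA/dt = -A + mu * F(A) - [inhibition] + I_drive + I_noise,

where ``A`` is a membrane-current-like activity in spikes/ms and ``F`` maps
that current onto an instantaneous discharge rate bounded by the absolute
refractory period.  This module owns the scalar primitives; the coupled
three-module network is integrated by :mod:`bodyn.engine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TransferParams",
    "IntegratorConfig",
    "NoiseSpec",
    "NeuralField",
    "transfer",
    "transfer_derivative",
    "rate_derivative",
    "rk4_step",
    "RHEOBASE_MARGIN",
]

#: Units with tau*A below 1 fire at exactly zero rate; activities driven by
#: noise alone stay far below this (stationary s.d. ~0.01 for +-0.25 noise).
RHEOBASE_MARGIN = 1e-12


@dataclass(frozen=True)
class TransferParams:
    """Membrane constants of the current-to-rate transfer function.

    Parameters
    ----------
    tau : float
        Membrane time constant in ms (default 10.0).
    t_r : float
        Absolute refractory time in ms (default 0.5).  Bounds the firing
        rate at ``1 / t_r`` spikes/ms.
    """

    tau: float = 10.0
    t_r: float = 0.5

    def __post_init__(self) -> None:
        if not (self.tau > 0 and self.t_r > 0):
            raise ValueError("tau and t_r must be positive")
        if not self.t_r < self.tau:
            raise ValueError("refractory time must be shorter than tau")


@dataclass(frozen=True)
class IntegratorConfig:
    """Fixed-step RK4 integration window."""

    dt: float = 0.1
    t_end: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        n = self.t_end / self.dt
        if self.t_end <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("t_end must be a positive multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


@dataclass(frozen=True)
class NoiseSpec:
    """Uniform per-unit, per-step current noise (activity units)."""

    low: float = -0.25
    high: float = 0.25

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("noise low bound exceeds high bound")

    def sample(self, rng: np.random.Generator, shape) -> np.ndarray:
        if self.low == self.high:
            return np.full(shape, self.low)
        return rng.uniform(self.low, self.high, shape)


@dataclass
class NeuralField:
    """A retinotopic grid of unit activities for one module.

    ``values`` has shape ``(n_channels, rows, cols)``; ``channels`` labels
    the leading axis (orientations for V1, cell-type x border-ownership
    side for V2, a single channel for the parietal map).
    """

    values: np.ndarray
    channels: Sequence[str] = field(default_factory=lambda: ("unit",))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[None]
        if self.values.ndim != 3:
            raise ValueError("NeuralField expects (channels, rows, cols)")
        if len(self.channels) != self.values.shape[0]:
            raise ValueError("channel labels do not match value shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite activity in NeuralField")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]


def transfer(x, params: TransferParams = TransferParams()) -> np.ndarray:
    """Current-to-discharge-rate transfer ``F``.

    ``F(x) = 1 / (t_r - tau * log(1 - 1/(tau*x)))`` for ``tau*x > 1`` and 0
    otherwise.  The sub-rheobase clamp keeps the log argument positive and
    makes quiescence (``F(0) = 0``) an exact fixed point; output lies in
    ``[0, 1/t_r]`` spikes/ms.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input to transfer function")
    tx = params.tau * x
    out = np.zeros_like(x)
    above = tx > 1.0 + RHEOBASE_MARGIN
    if np.any(above):
        t = tx[above]
        out[above] = 1.0 / (params.t_r - params.tau * np.log1p(-1.0 / t))
    return out if out.ndim else float(out)


def transfer_derivative(x, params: TransferParams = TransferParams()) -> np.ndarray:
    """dF/dx, used for linear-stability and operating-point analysis."""
    x = np.asarray(x, dtype=float)
    f = np.asarray(transfer(x, params))
    out = np.zeros_like(f)
    above = params.tau * x > 1.0 + RHEOBASE_MARGIN
    xa = x[above]
    out[above] = params.tau * f[above] ** 2 / (xa * (params.tau * xa - 1.0))
    return out if out.ndim else float(out)


def rate_derivative(
    a: np.ndarray,
    drive: np.ndarray | float,
    recurrent_gain: float,
    inhibition: float,
    params: TransferParams,
    noise: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Right-hand side of the rate equation for one field.

    ``inhibition`` is the already-scaled scalar subtraction (for modules
    with an inhibitory unit this is ``gamma * F(A_inh)``).  The noise sample
    is supplied by the caller and is held constant within one RK4 step.
    """
    a = np.asarray(a, dtype=float)
    drive_arr = np.asarray(drive, dtype=float)
    if drive_arr.ndim and drive_arr.shape != a.shape:
        raise ValueError("drive shape does not match activity shape")
    f = transfer(a, params)
    return (-a + recurrent_gain * f - inhibition + drive_arr + noise) / params.tau


def rk4_step(f: Callable[[np.ndarray], np.ndarray], y: np.ndarray, dt: float) -> np.ndarray:
    """One classical fourth-order Runge-Kutta step of ``dy/dt = f(y)``.

    The system must be autonomous over the step: time-dependent inputs
    (stimulus frames, noise) are frozen by the caller before stepping.
    Raises if the state goes non-finite.
    """
    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.5 * dt * k2)
    k4 = f(y + dt * k3)
    out = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite state after RK4 step")
    return out
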