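"""Run configuration: every model constant with its default value.

Printed constants of the network (membrane and refractory times, recurrent
and inhibitory gains, noise bounds, feedback weight, integration step,
grid and population sizes) carry their published defaults.  The remaining
connection gains (V1->V2 drive scale, surround scale, V1->parietal
afferent, inhibitory-pool scale, cue strength) are calibration constants
of this implementation: they were fixed once so that a 40-px square drives
a sustained border-ownership signal, an ambiguous edge leaves a balanced
one, and cueing modulates detection speed, and they are not tuned per
experiment.  See docs/methods.md for the calibration rationale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # -- geometry ---------------------------------------------------------
    grid: int = 100              #: retinotopic grid side (reference 100)
    square_size: int = 40        #: figure side at reference scale, px
    n_types: int = 10            #: BO cell types per side

    # -- dynamics ---------------------------------------------------------
    dt: float = 0.1              #: RK4 step, ms
    tau: float = 10.0            #: membrane time constant, ms
    t_r: float = 0.5             #: absolute refractory time, ms
    mu: float = 0.95             #: excitatory recurrent gain
    gamma: float = 0.8           #: inhibitory-unit gain onto excitatory cells
    kappa: float = 0.05          #: excitatory input gain onto inhibitory unit
    lam: float = 0.1             #: inhibitory-unit recurrent gain
    noise_low: float = -0.25     #: uniform current noise lower bound
    noise_high: float = 0.25     #: uniform current noise upper bound

    # -- V1 stage ---------------------------------------------------------
    gabor_sigma: float = 2.0     #: Gabor envelope width, px
    gabor_freq: float = 0.25     #: Gabor spatial frequency, cycles/px
    pool_sigma: float = 4.0      #: divisive-normalization pool width, px
    contrast_floor: float = 5e-3 #: contrast energies below this are zero
    w_fb: float = 0.6            #: parietal->V1 feedback weight

    # -- inter-module calibration gains ------------------------------------
    v1_to_v2_gain: float = 0.16  #: scale of the pooled V1 rate map into O1
    surround_gain: float = 1.6   #: scale of the surround convolution into O2
    inh_scale_v2: float = 0.006  #: normalization of the V2 inhibitory pool
    inh_scale_pp: float = 0.02   #: normalization of the parietal inhibitory pool
    pp_afferent_gain: float = 0.3   #: V1->parietal afferent scale
    pp_smooth_sigma: float = 3.0    #: afferent smoothing width, px
    pp_norm_floor: float = 1.0      #: floor of the feedback normalization max
    cue_amplitude: float = 1.0      #: attention bias peak, drive units
    cue_sigma: float = 20.0          #: attention Gaussian width, reference px

    # -- numerics / bookkeeping -------------------------------------------
    couple_every: int = 20       #: steps between surround/afferent refreshes
    n_trials: int = 20           #: trials per condition
    response_threshold_hz: float = 10.0
    smooth_ms: float = 5.0       #: moving-average window for index extraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid % 2:
            raise ValueError("grid must be even so the midline falls between columns")
        if self.dt <= 0 or self.couple_every < 1:
            raise ValueError("invalid integrator settings")
        if not (0 < self.t_r < self.tau):
            raise ValueError("need 0 < t_r < tau")
        if self.noise_low > self.noise_high:
            raise ValueError("noise bounds out of order")

    @property
    def scale(self) -> float:
        """Geometric scale factor relative to the 100-px reference grid."""
        return self.grid / 100.0

    @property
    def square_px(self) -> int:
        return max(2, int(round(self.square_size * self.scale / 2)) * 2)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML mapping merged over the defaults.

    Unknown keys are rejected with the offending key named, so typos in a
    configuration file cannot silently fall back to a default.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(raw)
    data.update(overrides)
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**data)
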