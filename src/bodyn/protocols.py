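"""The five simulated experiments, orchestrated end to end.

Each experiment builds its stimulus sequences and cues, runs a set of
seeded trials through :class:`~bodyn.model.BONetwork`, and reduces the
resulting BO traces to the timing indices of interest:

* flip vs. ambiguous replacement of a square at 500 ms (decay speed),
* figure-presentation duration sweep (decay-speed persistence),
* repeated figure presentations over 0-1500 ms (signal reset),
* spatial cueing of a square (response-time modulation),
* bi-stable random-block figures under left/right/no attention.

Trials are deterministic: trial k of a condition uses seed ``base + k``,
so an experiment is exactly reproducible from its specification.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .analysis import (
    ConditionSummary,
    compare_conditions,
    decay_time,
    response_time,
    smooth_trace,
    summarize,
)
from .config import RunConfig
from .model import BONetwork, BOTrace
from .stimuli import PROTOCOLS, build_protocol_sequence

__all__ = [
    "ExperimentSpec",
    "TrialResult",
    "run_experiment",
    "run_duration_sweep",
    "run_posner",
    "run_random_block_attention",
    "DURATIONS_MS",
    "POSNER_CONDITIONS",
]

log = logging.getLogger(__name__)

#: Figure presentation durations of the persistence experiment, ms.
DURATIONS_MS = (500.0, 250.0, 125.0, 63.0, 50.0)
POSNER_CONDITIONS = ("valid", "neutral", "invalid")


@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment: protocol, conditions, trial count and seeds."""

    protocol: str
    conditions: tuple[dict, ...]       # protocol kwargs per condition
    labels: tuple[str, ...]
    n_trials: int = 20
    t_end: float | None = None
    seed_base: int = 0                 # trial k uses seed_base + k + 1
    switch_time: float | None = 500.0  # for decay indices; None to skip

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.n_trials < 1 or len(self.conditions) != len(self.labels):
            raise ValueError("malformed experiment specification")

    def seeds(self) -> list[int]:
        return [self.seed_base + k + 1 for k in range(self.n_trials)]


@dataclass
class TrialResult:
    """A single trial's trace and its derived scalar indices."""

    trace: BOTrace
    condition: str
    decay_time: float | None = None
    response_time: float | None = None


def run_experiment(
    spec: ExperimentSpec, config: RunConfig | None = None, network: BONetwork | None = None
) -> dict[str, list[TrialResult]]:
    """Run every condition x trial of an experiment specification."""
    cfg = config or RunConfig()
    net = network or BONetwork(cfg)
    results: dict[str, list[TrialResult]] = {}
    for label, kw in zip(spec.labels, spec.conditions):
        seq, cue = build_protocol_sequence(
            spec.protocol,
            grid=cfg.grid,
            square_size=cfg.square_px,
            t_end=spec.t_end,
            cue_amplitude=cfg.cue_amplitude,
            cue_sigma=cfg.cue_sigma,
            **kw,
        )
        trials = []
        for seed in spec.seeds():
            trace, _ = net.run_trial(seq, cue, seed=seed, condition=label)
            tr = TrialResult(trace, label)
            if spec.switch_time is not None:
                tr.decay_time = decay_time(trace, spec.switch_time, cfg.smooth_ms)
            tr.response_time = response_time(
                trace, cfg.response_threshold_hz, cfg.smooth_ms
            )
            trials.append(tr)
        results[label] = trials
        log.info("%s/%s: %d trials done", spec.protocol, label, len(trials))
    return results


def run_duration_sweep(
    config: RunConfig | None = None,
    durations=DURATIONS_MS,
    n_trials: int | None = None,
    t_end: float = 1000.0,
    seed_base: int = 0,
    network: BONetwork | None = None,
) -> dict[float, ConditionSummary]:
    """Mean decay time of the BO signal for each figure duration.

    The figure onset moves to ``500 - duration`` ms and the ambiguous edge
    always starts at 500 ms, so the decay index is comparable across
    durations.
    """
    cfg = config or RunConfig()
    n = n_trials or cfg.n_trials
    spec = ExperimentSpec(
        "duration_sweep",
        conditions=tuple({"duration": d} for d in durations),
        labels=tuple(f"duration_{d:g}" for d in durations),
        n_trials=n,
        t_end=t_end,
        seed_base=seed_base,
    )
    results = run_experiment(spec, cfg, network)
    return {
        d: summarize(label, [t.decay_time for t in results[label]])
        for d, label in zip(durations, spec.labels)
    }


def run_posner(
    config: RunConfig | None = None,
    n_trials: int | None = None,
    t_end: float = 500.0,
    seed_base: int = 0,
    network: BONetwork | None = None,
) -> dict[str, ConditionSummary]:
    """Mean detection time under valid, neutral and invalid spatial cues.

    The response time is the first crossing of the 10 Hz level; trials
    that never cross are excluded with a warning.  Pairwise Welch tests
    between the conditions are attached to each summary.
    """
    cfg = config or RunConfig()
    n = n_trials or cfg.n_trials
    spec = ExperimentSpec(
        "posner",
        conditions=tuple({"condition": c} for c in POSNER_CONDITIONS),
        labels=POSNER_CONDITIONS,
        n_trials=n,
        t_end=t_end,
        seed_base=seed_base,
        switch_time=None,
    )
    results = run_experiment(spec, cfg, network)
    summaries = {
        c: summarize(c, [t.response_time for t in results[c]])
        for c in POSNER_CONDITIONS
    }
    for a, b in itertools.combinations(POSNER_CONDITIONS, 2):
        stat, p = compare_conditions(summaries[a].values, summaries[b].values)
        summaries[a].tests[b] = (stat, p)
        summaries[b].tests[a] = (-stat, p)
    return summaries


def run_random_block_attention(
    config: RunConfig | None = None,
    stim_ids=(1, 2, 3, 4, 5),
    cues=("none", "left", "right"),
    n_trials: int | None = None,
    t_end: float = 1000.0,
    seed_base: int = 0,
    network: BONetwork | None = None,
    steady_from: float = 600.0,
    onset_band_hz: float = 5.0,
) -> dict[tuple[int, str], dict]:
    """Attention-pulled border ownership for the bi-stable block figures.

    For every stimulus x cue the trial-mean smoothed trace is reduced to a
    steady-state mean (over ``steady_from``..``t_end``) and the onset time
    at which the mean |nu| leaves the ``onset_band_hz`` band around zero
    for good; None marks a trace that never leaves the band.
    """
    cfg = config or RunConfig()
    n = n_trials or cfg.n_trials
    net = network or BONetwork(cfg)
    out: dict[tuple[int, str], dict] = {}
    for stim_id in stim_ids:
        for cue_side in cues:
            seq, cue = build_protocol_sequence(
                "random_block",
                grid=cfg.grid,
                stim_id=stim_id,
                cue_side=cue_side,
                t_end=t_end,
                cue_amplitude=cfg.cue_amplitude,
                cue_sigma=cfg.cue_sigma,
            )
            traces = [
                net.run_trial(seq, cue, seed=seed_base + k + 1,
                              condition=f"rb{stim_id}_{cue_side}")[0]
                for k in range(n)
            ]
            mean = np.mean([smooth_trace(t, cfg.smooth_ms) for t in traces], axis=0)
            times = traces[0].times
            steady = float(mean[times >= steady_from].mean())
            outside = np.abs(mean) > onset_band_hz
            onset = None
            if outside.any():
                # last entry into the band-leaving state that persists
                idx = np.flatnonzero(outside)
                first = idx[0]
                onset = float(times[first])
            out[(stim_id, cue_side)] = {
                "mean_trace": mean,
                "times": times,
                "steady_nu": steady,
                "onset_ms": onset,
            }
    return out
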