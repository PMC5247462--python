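"""Result serialization: HDF5 containers for traces, CSV summaries.

Every results file embeds the full run configuration (as YAML text) and
the per-trial seeds, so any stored experiment can be re-run bit-for-bit
from the file alone.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .model import BOTrace
from .protocols import TrialResult

__all__ = ["write_results", "read_results", "summary_frame"]


def write_results(
    results: dict[str, list[TrialResult]], path: str | Path, config: RunConfig
) -> Path:
    """Store an experiment's traces and indices in one HDF5 container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["package_version"] = __version__
        f.attrs["config_yaml"] = yaml.safe_dump(config.to_dict())
        for condition, trials in results.items():
            grp = f.create_group(f"conditions/{condition}")
            grp.attrs["n_trials"] = len(trials)
            for k, tr in enumerate(trials):
                tg = grp.create_group(f"trial_{k:03d}")
                tg.create_dataset("nu_hz", data=tr.trace.nu, compression="gzip")
                tg.attrs["dt_ms"] = tr.trace.dt
                tg.attrs["seed"] = tr.trace.trial_seed
                tg.attrs["location"] = tr.trace.location
                if tr.decay_time is not None:
                    tg.attrs["decay_time_ms"] = tr.decay_time
                if tr.response_time is not None:
                    tg.attrs["response_time_ms"] = tr.response_time
    return path


def read_results(path: str | Path) -> tuple[dict[str, list[TrialResult]], RunConfig]:
    """Round-trip loader for :func:`write_results` containers."""
    out: dict[str, list[TrialResult]] = {}
    with h5py.File(path, "r") as f:
        config = RunConfig(**yaml.safe_load(f.attrs["config_yaml"]))
        for condition, grp in f["conditions"].items():
            trials = []
            for key in sorted(grp):
                tg = grp[key]
                nu = tg["nu_hz"][()]
                dt = float(tg.attrs["dt_ms"])
                trace = BOTrace(
                    np.arange(len(nu)) * dt,
                    nu,
                    tuple(int(v) for v in tg.attrs["location"]),
                    int(tg.attrs["seed"]),
                    condition,
                )
                trials.append(
                    TrialResult(
                        trace,
                        condition,
                        decay_time=tg.attrs.get("decay_time_ms"),
                        response_time=tg.attrs.get("response_time_ms"),
                    )
                )
            out[condition] = trials
    return out, config


def summary_frame(summaries: dict) -> pd.DataFrame:
    """Tabulate ConditionSummary objects (one row per condition)."""
    rows = []
    for key, s in summaries.items():
        rows.append(
            {
                "condition": str(key),
                "n": s.n,
                "n_missing": s.n_missing,
                "mean_ms": s.mean,
                "se_ms": s.se,
            }
        )
    return pd.DataFrame(rows)
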