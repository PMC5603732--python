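"""Trial-table, trace and configuration I/O.

Trial tables are comma-delimited UTF-8 text with a required header and
one row per trial:

    session_id, day, trial, c_left, c_right, choice, correct, rewarded,
    laser, repeat, rt

choice is L / R / NG; laser is none or a region tag (Lvis, Rvis, Lsom,
Rsom); contrasts are fractions in [0, 1] (a percent flag converts on
read/write); rt in seconds, empty for no-go trials.  Traces are
two-column (time, value) delimited text.  Schema violations are reported
with data row numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signals import Trace

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "read_trace",
    "write_trace",
    "load_run_config",
    "RunConfig",
]

TRIAL_COLUMNS = ["session_id", "day", "trial", "c_left", "c_right",
                 "choice", "correct", "rewarded", "laser", "repeat", "rt"]
VALID_CHOICES = {"L", "R", "NG"}
VALID_LASER = {"none", "Lvis", "Rvis", "Lsom", "Rsom"}


def _rows(mask: np.ndarray) -> str:
    """Format offending 1-based data row numbers (first few)."""
    idx = np.flatnonzero(mask) + 1
    shown = ", ".join(map(str, idx[:10]))
    more = "" if len(idx) <= 10 else f" (+{len(idx) - 10} more)"
    return shown + more


def validate_trials(trials: pd.DataFrame, variant: str | None = None
                    ) -> None:
    """Validate a trial table against the schema; raise with row numbers."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    errors = []
    for col in ("c_left", "c_right"):
        c = trials[col].to_numpy(float)
        bad = ~np.isfinite(c) | (c < 0) | (c > 1)
        if bad.any():
            errors.append(f"{col} outside [0, 1] at rows: {_rows(bad)}")
    bad = ~trials["choice"].isin(VALID_CHOICES).to_numpy()
    if bad.any():
        errors.append(f"invalid choice at rows: {_rows(bad)}")
    bad = ~trials["laser"].isin(VALID_LASER).to_numpy()
    if bad.any():
        errors.append(f"invalid laser tag at rows: {_rows(bad)}")
    for col in ("correct", "rewarded", "repeat"):
        bad = ~trials[col].isin((0, 1)).to_numpy()
        if bad.any():
            errors.append(f"{col} not in {{0,1}} at rows: {_rows(bad)}")
    if variant is not None and variant.startswith("afc2"):
        bad = (trials["choice"] == "NG").to_numpy()
        if bad.any():
            errors.append("no-go choices in 2AFC data at rows: "
                          f"{_rows(bad)}")
    if errors:
        raise ValueError("trial table schema violations:\n  "
                         + "\n  ".join(errors))


def read_trials(path, percent: bool = False,
                variant: str | None = None) -> pd.DataFrame:
    """Read and validate a trial table from delimited text."""
    trials = pd.read_csv(path, float_precision="round_trip",
                         dtype={"session_id": str, "day": str,
                                "choice": str, "laser": str})
    if percent:
        trials["c_left"] = trials["c_left"] / 100.0
        trials["c_right"] = trials["c_right"] / 100.0
    validate_trials(trials, variant=variant)
    return trials[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path,
                 percent: bool = False) -> None:
    """Write a trial table; round-trips losslessly through read_trials."""
    validate_trials(trials)
    out = trials[TRIAL_COLUMNS].copy()
    if percent:
        out["c_left"] = out["c_left"] * 100.0
        out["c_right"] = out["c_right"] * 100.0
    out.to_csv(path, index=False)


def read_trace(path, kind: str = "wheel_velocity") -> Trace:
    """Read a (time, value) two-column delimited trace.

    The sampling rate is inferred from the time column, which must be
    uniform.
    """
    tab = pd.read_csv(path, float_precision="round_trip")
    if tab.shape[1] < 2:
        raise ValueError("trace file needs (time, value) columns")
    t = tab.iloc[:, 0].to_numpy(float)
    v = tab.iloc[:, 1].to_numpy(float)
    if len(t) < 2:
        raise ValueError("trace needs at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace is not uniformly sampled")
    return Trace(v, 1.0 / dt[0], start_time=float(t[0]), kind=kind)


def write_trace(trace: Trace, path) -> None:
    pd.DataFrame({"time": trace.times,
                  "value": trace.samples}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Validated analysis/simulation configuration.

    Sections mirror the module boundaries: ``task`` feeds the simulator,
    ``fit`` the observer fitting (folds, constraint, seed), ``signals``
    the trace operators.
    """

    task: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    signals: dict = field(default_factory=dict)
    output_dir: str = "."

    _TASK_KEYS = {"variant", "contrast_set", "pedestal_set", "n_trials",
                  "laser_fraction", "laser_regions", "repeat_after_error",
                  "response_window", "reward_mode", "session_id", "day"}
    _FIT_KEYS = {"constraint", "k_folds", "seed", "variant"}
    _SIGNAL_KEYS = {"baseline_window", "baseline_smoothing", "filter_tau",
                    "high_mult", "low_mult"}

    def __post_init__(self) -> None:
        for name, keys, section in (("task", self._TASK_KEYS, self.task),
                                    ("fit", self._FIT_KEYS, self.fit),
                                    ("signals", self._SIGNAL_KEYS,
                                     self.signals)):
            unknown = set(section) - keys
            if unknown:
                raise ValueError(f"unknown {name} config keys: "
                                 f"{sorted(unknown)}")


def load_run_config(path) -> RunConfig:
    """Load a YAML run configuration with explicit validation errors."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(raw) - {"task", "fit", "signals", "output_dir"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return RunConfig(task=raw.get("task", {}), fit=raw.get("fit", {}),
                     signals=raw.get("signals", {}),
                     output_dir=raw.get("output_dir", "."))


def write_manifest(path, command: str, seed, params: dict) -> None:
    """Write a JSON run manifest for reproducibility."""
    from . import __version__
    manifest = {
        "command": command,
        "seed": seed,
        "package_version": __version__,
        "params": params,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
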