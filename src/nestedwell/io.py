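"""File formats: trace CSV + JSON manifest, per-step CSV, summary JSON.

All files use UTF-8, comma separation and '.' decimals; times in seconds,
concentrations in nM, temperature in kelvin.  No unit auto-detection.

Trace CSV (long format): columns exactly ``spot_id, probe_class, time_s,
sigma``.  A sidecar JSON manifest carries the injection schedule and the
condition metadata shared by every spot in the file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigError, ConsistencyError, FormatError
from .synthetic import BindingTrace, StepSchedule

__all__ = ["AnalysisConfig", "read_traces", "write_traces",
           "write_step_results", "read_step_results", "write_summary",
           "SCHEMA_VERSION"]

logger = logging.getLogger("nestedwell")

SCHEMA_VERSION = 1
TRACE_COLUMNS = ["spot_id", "probe_class", "time_s", "sigma"]


@dataclass
class AnalysisConfig:
    """Validated analysis settings; unknown keys are rejected by name."""

    traces: str = "traces.csv"
    manifest: str = "manifest.json"
    outdir: str = "."
    discard_s: float = 10.0
    kon_regressor: str = "c"          # c | delta_c | corrected
    bootstrap: bool = False
    n_boot: int = 500
    temperature_K: float | None = None   # override the manifest value
    gas_constant: float = 1.987e-3       # kcal/(mol K)
    seed: int = 0

    def __post_init__(self):
        if self.kon_regressor not in ("c", "delta_c", "corrected"):
            raise ConfigError(f"kon_regressor must be c|delta_c|corrected, "
                              f"got {self.kon_regressor!r}")
        if self.discard_s < 0:
            raise ConfigError("discard_s must be nonnegative")
        if self.n_boot < 1:
            raise ConfigError("n_boot must be positive")
        if self.gas_constant <= 0:
            raise ConfigError("gas_constant must be positive")
        self.seed = int(self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"configuration file {path} must contain a mapping")
        return cls.from_dict(d)

    def hash(self) -> str:
        """Stable short hash of the configuration, stamped into outputs."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def write_traces(traces: list[BindingTrace], csv_path: str | Path,
                 manifest_path: str | Path) -> None:
    """Write traces to the long CSV plus the shared-schedule manifest."""
    if not traces:
        raise ConsistencyError("no traces to write")
    sched = traces[0].schedule
    for tr in traces[1:]:
        if tr.schedule.step_times != sched.step_times or (
                tr.schedule.concentrations != sched.concentrations):
            raise ConsistencyError("all traces in one file must share the schedule")
    frames = [
        pd.DataFrame({
            "spot_id": tr.spot_id,
            "probe_class": tr.probe_class,
            "time_s": tr.times,
            "sigma": tr.sigma,
        })
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "temperature_K": sched.temperature,
        "ionic_strength_mM": sched.ionic_strength,
        "schedule": {
            "step_times_s": list(sched.step_times),
            "concentrations_nM": list(sched.concentrations),
            "end_time_s": sched.end_time,
        },
    }
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_traces(csv_path: str | Path, manifest_path: str | Path) -> list[BindingTrace]:
    """Read and validate a trace CSV with its manifest.

    Unsorted times are sorted with a logged warning; a missing column or a
    schedule/trace mismatch raises a named error.
    """
    df = pd.read_csv(csv_path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trace CSV {csv_path} is missing column(s): {', '.join(missing)}")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    try:
        sched_d = manifest["schedule"]
        step_times = sched_d["step_times_s"]
        conc = sched_d["concentrations_nM"]
    except KeyError as exc:
        raise FormatError(f"manifest {manifest_path} is missing key {exc}") from exc
    if len(step_times) != len(conc):
        raise ConsistencyError(
            f"manifest lists {len(conc)} concentrations for {len(step_times)} steps")
    schedule = StepSchedule(
        step_times=tuple(step_times),
        concentrations=tuple(conc),
        temperature=float(manifest.get("temperature_K", 303.15)),
        ionic_strength=float(manifest.get("ionic_strength_mM", 150.0)),
        end_time=sched_d.get("end_time_s"),
    )
    traces = []
    for spot_id, grp in df.groupby("spot_id", sort=True):
        pclass = grp["probe_class"].iloc[0]
        if not (grp["probe_class"] == pclass).all():
            raise ConsistencyError(f"spot {spot_id!r} has inconsistent probe_class values")
        if pclass not in ("specific", "nonspecific"):
            raise FormatError(f"spot {spot_id!r}: probe_class must be "
                              f"'specific' or 'nonspecific', got {pclass!r}")
        t = grp["time_s"].to_numpy(dtype=float)
        s = grp["sigma"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            logger.warning("spot %r: times not sorted; sorting", spot_id)
            order = np.argsort(t, kind="stable")
            t, s = t[order], s[order]
        if t.min() < schedule.step_times[0] or t.max() >= schedule.end_time:
            raise ConsistencyError(
                f"spot {spot_id!r}: sample times [{t.min()}, {t.max()}] fall outside "
                f"the scheduled span [{schedule.step_times[0]}, {schedule.end_time})")
        traces.append(BindingTrace(times=t, sigma=s, schedule=schedule,
                                   probe_class=str(pclass), spot_id=str(spot_id)))
    if not traces:
        raise ConsistencyError(f"trace CSV {csv_path} contains no spots")
    return traces


def write_step_results(rows: list[dict], path: str | Path) -> None:
    """Per-step results as CSV (one row per spot × injection step)."""
    pd.DataFrame(rows).to_csv(path, index=False)


def read_step_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"spot_id", "probe_class", "c_nM", "Sigma", "Gamma", "slope0",
                "sigma_prev", "c_prev", "usable"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"step-results CSV {path} is missing column(s): "
                          f"{', '.join(sorted(missing))}")
    return df


def write_summary(summary: dict, path: str | Path, config: AnalysisConfig | None = None) -> None:
    """Machine-readable condition summary; stamped with schema, seed, config hash."""
    out = {"schema_version": SCHEMA_VERSION}
    if config is not None:
        out["config_hash"] = config.hash()
        out["seed"] = config.seed
    out.update(summary)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
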