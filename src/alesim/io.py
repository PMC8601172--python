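"""File interfaces: config loading, trace/event/lineage files, run manifest.

Formats (all plain text, hours / ml / h^-1 units throughout):

* config — TOML (``tomllib``) or YAML by extension, validated against the
  :mod:`alesim.config` schema;
* trace — CSV with header ``time_h,od_measured,od_true,raw_reading,flags``
  (flags ``|``-joined, empty when none);
* events — JSON-lines, one object per event with keys
  ``time_h, kind, payload``;
* lineage — CSV ``genotype_id,parent_id,birth_time_h,growth_rate,
  final_count`` (empty parent for founders);
* manifest — JSON written atomically at run end with the config echo, seed,
  version, wall times and SHA-256 checksums of every emitted file.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import os
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import ConfigError, SimulationConfig, validate_config
from .controller import Event, EventKind, RunResult

TRACE_COLUMNS = ["time_h", "od_measured", "od_true", "raw_reading", "flags"]
LINEAGE_COLUMNS = ["genotype_id", "parent_id", "birth_time_h", "growth_rate",
                   "final_count"]


# ---------------------------------------------------------------------------
# config

def load_config(path) -> SimulationConfig:
    """Parse and validate a TOML/YAML config file into the default-filled
    tree; unknown keys and invariant violations raise :class:`ConfigError`
    naming the key path."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        if path.suffix.lower() == ".toml":
            data = tomllib.loads(path.read_text())
        elif path.suffix.lower() in (".yaml", ".yml", ".json"):
            data = yaml.safe_load(path.read_text()) or {}
        else:
            raise ConfigError(f"unsupported config format: {path.suffix}")
    except (tomllib.TOMLDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from None
    if not isinstance(data, dict):
        raise ConfigError(f"config root of {path} must be a mapping")
    return validate_config(data)


# ---------------------------------------------------------------------------
# trace CSV

def write_trace(path, trace: pd.DataFrame) -> None:
    missing = [c for c in TRACE_COLUMNS if c not in trace.columns]
    if missing:
        raise ValueError(f"trace is missing columns {missing}")
    trace.to_csv(path, index=False, columns=TRACE_COLUMNS)


def read_trace(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"flags": str}, keep_default_na=False,
                     na_values=[])
    if list(df.columns) != TRACE_COLUMNS:
        raise ValueError(f"bad trace header in {path}: expected "
                         f"{','.join(TRACE_COLUMNS)}, got "
                         f"{','.join(df.columns)}")
    for col in TRACE_COLUMNS[:-1]:
        df[col] = pd.to_numeric(df[col])
    t = df["time_h"].to_numpy()
    if t.size > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise ValueError(f"non-monotone time in {path} at data row "
                             f"{int(bad[0]) + 2} (time {float(t[bad[0] + 1])}"
                             f" after {float(t[bad[0]])})")
    return df


# ---------------------------------------------------------------------------
# events JSON-lines

def write_events(path, events: list[Event]) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(json.dumps({"time_h": e.time, "kind": e.kind.value,
                                 "payload": e.payload}) + "\n")


def read_events(path) -> list[Event]:
    events: list[Event] = []
    last_t = -np.inf
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: bad JSON: {exc}") from None
            try:
                kind = EventKind(obj["kind"])
                t = float(obj["time_h"])
                payload = obj.get("payload", {})
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad event: {exc}") from None
            if t < last_t:
                raise ValueError(f"{path}:{lineno}: event time {t} precedes "
                                 f"{last_t}")
            last_t = t
            events.append(Event(t, kind, payload))
    return events


# ---------------------------------------------------------------------------
# lineage CSV

def write_lineage(path, lineage: pd.DataFrame) -> None:
    df = lineage.copy()
    df["parent_id"] = df["parent_id"].map(
        lambda p: "" if int(p) < 0 else str(int(p)))
    df.to_csv(path, index=False, columns=LINEAGE_COLUMNS)


def read_lineage(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    if list(df.columns) != LINEAGE_COLUMNS:
        raise ValueError(f"bad lineage header in {path}")
    df["parent_id"] = df["parent_id"].map(
        lambda p: -1 if str(p) == "" else int(p))
    return df


# ---------------------------------------------------------------------------
# manifest

@dataclass(frozen=True)
class RunManifest:
    config: dict
    seed: int
    version: str
    started_utc: str
    finished_utc: str
    outputs: dict  # name -> {path, sha256, bytes}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_run_outputs(result: RunResult, out_dir,
                      started_utc: str | None = None) -> RunManifest:
    """Write trace/events/lineage and, last and atomically, the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = started_utc or _dt.datetime.now(_dt.timezone.utc).isoformat()
    files = {"trace": out / "trace.csv", "events": out / "events.jsonl",
             "lineage": out / "lineage.csv"}
    write_trace(files["trace"], result.trace)
    write_events(files["events"], result.events)
    write_lineage(files["lineage"],
                  result.final_state.population.lineage_table())
    if result.frequencies is not None:
        files["frequencies"] = out / "frequencies.csv"
        result.frequencies.to_csv(files["frequencies"], index=False)
    outputs = {name: {"path": p.name, "sha256": _sha256(p),
                      "bytes": p.stat().st_size}
               for name, p in files.items()}
    manifest = RunManifest(result.config, result.seed, __version__, started,
                           _dt.datetime.now(_dt.timezone.utc).isoformat(),
                           outputs)
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(vars(manifest), indent=2) + "\n")
    os.replace(tmp, out / "manifest.json")
    return manifest


def read_manifest(path) -> RunManifest:
    obj = json.loads(Path(path).read_text())
    return RunManifest(**obj)


def verify_manifest(manifest: RunManifest, out_dir) -> bool:
    """Check every recorded checksum against the files on disk."""
    out = Path(out_dir)
    return all(_sha256(out / meta["path"]) == meta["sha256"]
               for meta in manifest.outputs.values())
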