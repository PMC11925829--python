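"""Configuration loading, event-log serialisation, and run manifests.

Event logs are plain CSV with a ``#``-prefixed header block of
``key = json`` lines (configuration echo, seeds, instructed-side mapping)
followed by one row per event; timestamps carry 3 decimal places, which is
lossless at the engine's 10 ms resolution.  Manifests are JSON files listing
every produced artefact with its SHA-256, so a run can be verified later.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import ValidationError

from . import __version__
from .errors import ConfigError
from .events import Event, EventLog
from .session import SessionConfig


# ---------------------------------------------------------------------------
# Configuration files
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> SessionConfig:
    """Load and validate a YAML session configuration.

    Raises :class:`ConfigError` listing the offending keys when the file
    does not match the schema (see ``docs/config_schema.md``).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return SessionConfig.model_validate(raw)
    except ValidationError as exc:
        keys = [".".join(str(p) for p in err["loc"]) for err in exc.errors()]
        msgs = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"{path}: invalid configuration ({msgs})", keys=keys) from exc


def config_hash(config: SessionConfig) -> str:
    """SHA-256 of the canonical JSON form of a configuration."""
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# Event-log CSV round trip
# ---------------------------------------------------------------------------


def write_event_log(log: EventLog, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for key in sorted(log.meta):
            fh.write(f"# {key} = {json.dumps(log.meta[key], sort_keys=True)}\n")
        frame = log.to_frame()
        frame["t_s"] = frame["t_s"].map(lambda t: f"{t:.3f}")
        frame.to_csv(fh, index=False)
    return path


def read_event_log(path: str | Path) -> EventLog:
    path = Path(path)
    meta: dict = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = json.loads(val)
    frame = pd.read_csv(
        path, skiprows=header_lines, dtype={"payload": str},
        keep_default_na=False, na_values=[],
    )
    events = [
        Event(
            t_s=float(row.t_s),
            phase=row.phase,
            block=int(row.block),
            cycle=int(row.cycle),
            component_index=int(row.component_index),
            component_label=row.component_label,
            event=row.event,
            payload=json.loads(row.payload),
        )
        for row in frame.itertuples()
    ]
    return EventLog(meta=meta, events=events)


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    config: SessionConfig,
    phase_outcomes: dict,
    files: list[Path],
    extra: dict | None = None,
) -> Path:
    """Write ``manifest.json`` covering every produced file."""
    out_dir = Path(out_dir)
    manifest = {
        "engine_version": __version__,
        "config_hash": config_hash(config),
        "seeds": {"engine": config.seed, "agent": config.agent.seed},
        "phase_outcomes": phase_outcomes,
        "files": {
            str(p.relative_to(out_dir)): _sha256(p) for p in files
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def verify_manifest(manifest_path: str | Path) -> list[str]:
    """Return a list of problems (missing or altered files); empty if OK."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    problems = []
    for rel, digest in manifest.get("files", {}).items():
        p = base / rel
        if not p.exists():
            problems.append(f"missing: {rel}")
        elif _sha256(p) != digest:
            problems.append(f"hash mismatch: {rel}")
    return problems
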