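"""Trial-log CSV readers/writers, config files and run manifests.

The interchange format is a comma-separated, UTF-8, header-mandatory trial
log with one row per trial::

    subject,session,phase,trial,a1,s2,a2,outcome,transition,aborted,rt

``a1``/``a2`` in {L, R}; ``s2`` in {S1, S2}; ``outcome`` and ``aborted`` in
{0, 1}; ``transition`` in {common, rare}; ``rt`` empty or decimal seconds;
``a2`` empty exactly when ``aborted`` is 1.  Simulated files carry one extra
optional column, ``rewarding`` (the latent rewarding stage-2 state), which
the control analyses use and readers tolerate being absent.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .task import ACTIONS, PHASES, STATES, TRIAL_COLUMNS

REQUIRED_COLUMNS = TRIAL_COLUMNS
OPTIONAL_COLUMNS = ("rewarding",)


class ValidationError(ValueError):
    """A trial log failed schema validation; the message names the row."""


def _package_version() -> str:
    try:
        return version("twostage")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    Row numbers in error messages are 1-based file lines (the header is
    line 1).
    """
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, header row is mandatory")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValidationError(f"{path}: missing column(s) {missing}")
        unknown = [
            c for c in reader.fieldnames
            if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS
        ]
        if unknown:
            raise ValidationError(f"{path}: unknown column(s) {unknown}")
        has_rewarding = "rewarding" in reader.fieldnames
        for lineno, raw in enumerate(reader, start=2):
            rows.append(_parse_row(raw, lineno, has_rewarding, path))
    cols = list(REQUIRED_COLUMNS) + (["rewarding"] if rows and "rewarding" in rows[0] else [])
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        df = pd.DataFrame(columns=cols)
    return df


def _parse_row(raw: dict, lineno: int, has_rewarding: bool, path) -> dict:
    def err(msg: str):
        raise ValidationError(f"{path}:{lineno}: {msg}")

    try:
        session = int(raw["session"])
        trial = int(raw["trial"])
    except (TypeError, ValueError):
        err("session and trial must be integers")
    if raw["phase"] not in PHASES:
        err(f"unknown phase {raw['phase']!r}")
    if raw["a1"] not in ACTIONS:
        err(f"invalid stage-1 action {raw['a1']!r}")
    if raw["s2"] not in STATES:
        err(f"invalid stage-2 state {raw['s2']!r}")
    if raw["outcome"] not in ("0", "1"):
        err(f"outcome must be 0 or 1, got {raw['outcome']!r}")
    if raw["transition"] not in ("common", "rare"):
        err(f"invalid transition label {raw['transition']!r}")
    if raw["aborted"] not in ("0", "1"):
        err(f"aborted must be 0 or 1, got {raw['aborted']!r}")
    aborted = int(raw["aborted"])
    a2 = raw["a2"]
    if aborted:
        if a2 != "":
            err("a2 must be empty on aborted rows")
        a2 = None
        if raw["outcome"] == "1":
            err("aborted trials cannot be rewarded")
    elif a2 not in ACTIONS:
        err(f"invalid stage-2 action {a2!r}")
    rt_raw = raw.get("rt", "")
    if rt_raw in ("", None):
        rt = np.nan
    else:
        try:
            rt = float(rt_raw)
        except ValueError:
            err(f"rt must be empty or decimal seconds, got {rt_raw!r}")
        if rt < 0:
            err("rt must be non-negative")
    row = {
        "subject": raw["subject"],
        "session": session,
        "phase": raw["phase"],
        "trial": trial,
        "a1": raw["a1"],
        "s2": raw["s2"],
        "a2": a2,
        "outcome": int(raw["outcome"]),
        "transition": raw["transition"],
        "aborted": aborted,
        "rt": rt,
    }
    if has_rewarding:
        rew = raw.get("rewarding", "")
        if rew not in ("",) + STATES:
            err(f"invalid rewarding state {rew!r}")
        row["rewarding"] = rew if rew else None
    return row


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        if np.isnan(v):
            return ""
        return format(v, "g")
    return str(v)


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial log in canonical formatting (roundtrip-stable)."""
    cols = list(REQUIRED_COLUMNS)
    if "rewarding" in df.columns and df["rewarding"].notna().any():
        cols.append("rewarding")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(cols)
        for row in df[cols].itertuples(index=False):
            writer.writerow([_fmt(v) for v in row])


# ---------------------------------------------------------------------------
# Config files and manifests
# ---------------------------------------------------------------------------

def write_config(obj, path) -> None:
    """Serialize a (dataclass) config as key-value YAML."""
    if hasattr(obj, "__dataclass_fields__"):
        data = {name: getattr(obj, name) for name in obj.__dataclass_fields__}
    else:
        data = dict(obj)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_plain(data), fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def read_task_config(path) -> "TaskConfig":
    """Load a key-value config file mirroring the TaskConfig fields."""
    from .task import TaskConfig

    return TaskConfig(**read_config(path))


def _plain(x):
    if isinstance(x, dict):
        return {k: _plain(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_plain(v) for v in x]
    if hasattr(x, "items"):  # MappingProxyType
        return {k: _plain(v) for k, v in x.items()}
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x


@dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    command: str
    seed: Optional[int]
    config_hash: str
    artifacts: list[str] = field(default_factory=list)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    version: str = field(default_factory=_package_version)

    @classmethod
    def create(cls, command: str, seed: Optional[int], config_payload,
               artifacts: list[str]) -> "RunManifest":
        blob = json.dumps(_plain(config_payload), sort_keys=True, default=str)
        digest = hashlib.sha256(blob.encode()).hexdigest()[:16]
        return cls(command=command, seed=seed, config_hash=digest,
                   artifacts=list(map(str, artifacts)))

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)
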