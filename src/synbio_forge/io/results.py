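"""Result writing: CSV tables, JSON summaries, run records and manifests.

All numeric CSV output uses one fixed decimal format (``%.12g``) so that
fixed-seed reruns produce byte-identical tables and stable content hashes
across platforms.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .. import __version__

__all__ = ["RunRecord", "write_results", "FLOAT_FORMAT", "file_sha256"]

FLOAT_FORMAT = "%.12g"


@dataclass
class RunRecord:
    """Provenance of one run: config echo, code version, seed, stage log."""

    config: Mapping[str, Any]
    root_seed: int
    version: str = __version__
    started: float = field(default_factory=time.time)
    finished: float | None = None
    stages: list[str] = field(default_factory=list)

    def log(self, stage: str) -> None:
        self.stages.append(stage)

    def close(self) -> None:
        self.finished = time.time()

    def to_dict(self) -> dict:
        return {
            "config": dict(self.config), "root_seed": self.root_seed,
            "version": self.version, "started": self.started,
            "finished": self.finished, "stages": list(self.stages),
        }


def file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_results(
    record: RunRecord,
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    summary: Mapping[str, Any] | None = None,
    *,
    force: bool = False,
) -> dict:
    """Write tables + summary + run record, and a manifest of content hashes.

    Refuses to write into an existing non-empty directory unless ``force``.
    The manifest excludes the run record (which carries wall-clock
    timestamps); everything in the manifest is a pure function of config and
    seed, so rerunning reproduces the hashes exactly.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} is not empty (pass force=True / --force to overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    record.close()
    entries = {}
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
        entries[path.name] = file_sha256(path)
    if summary is not None:
        path = out / "summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n")
        entries[path.name] = file_sha256(path)
    (out / "run_record.json").write_text(
        json.dumps(record.to_dict(), indent=2, default=_json_default) + "\n")
    manifest = {"root_seed": record.root_seed, "version": record.version, "files": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
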