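"""CSV schemas, run manifests and shared file plumbing.

All interchange formats are plain CSV with documented headers:

* colony tables: ``condition, timepoint_weeks, colony_size_cells``
* limiting-dilution plates: ``dose_cells_per_well, wells_total, wells_negative``
* luminescence plates: ``concentration, replicate, signal, well_type``
* barcode tables: barcode rows x sample columns with a ``#role`` row

Every CLI invocation writes one JSON manifest next to its outputs
recording the command, parameters, seeds, input digests, package
version and timestamp, so any run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ColonyParseError",
    "read_colony_csv",
    "write_colony_csv",
    "RunManifest",
    "write_manifest",
]

COLONY_COLUMNS = ("condition", "timepoint_weeks", "colony_size_cells")


class ColonyParseError(ValueError):
    """A colony CSV violated the schema; the message names the row."""


def read_colony_csv(path) -> dict:
    """Read a colony table into ``{(condition, weeks): size array}``.

    Unknown columns are preserved in the file but ignored here.  Raises
    :class:`ColonyParseError` naming the offending data row (1-based,
    excluding the header) for missing columns, non-numeric sizes, or
    sizes below 1.
    """
    df = pd.read_csv(path)
    missing = set(COLONY_COLUMNS) - set(df.columns)
    if missing:
        raise ColonyParseError(f"{path}: missing columns {sorted(missing)}")
    sizes = pd.to_numeric(df["colony_size_cells"], errors="coerce")
    bad = np.flatnonzero(sizes.isna().to_numpy())
    if len(bad):
        raise ColonyParseError(
            f"{path}: non-numeric colony_size_cells on row {bad[0] + 1}"
        )
    small = np.flatnonzero((sizes < 1).to_numpy())
    if len(small):
        raise ColonyParseError(
            f"{path}: colony_size_cells < 1 on row {small[0] + 1}"
        )
    weeks = pd.to_numeric(df["timepoint_weeks"], errors="coerce")
    badw = np.flatnonzero(weeks.isna().to_numpy())
    if len(badw):
        raise ColonyParseError(
            f"{path}: non-numeric timepoint_weeks on row {badw[0] + 1}"
        )
    out: dict = {}
    for (cond, wk), grp in df.assign(
        colony_size_cells=sizes, timepoint_weeks=weeks
    ).groupby(["condition", "timepoint_weeks"], sort=True):
        out[(cond, int(wk))] = grp["colony_size_cells"].to_numpy(dtype=np.int64)
    return out


def write_colony_csv(path, samples: dict) -> None:
    """Write ``{(condition, weeks): sizes}`` to the colony CSV schema."""
    rows = []
    for (cond, wk), sizes in samples.items():
        for s in np.asarray(sizes):
            rows.append((cond, int(wk), int(s)))
    pd.DataFrame(rows, columns=list(COLONY_COLUMNS)).to_csv(path, index=False)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    command: str
    parameters: dict
    seed: int | None
    inputs: dict = field(default_factory=dict)  # path -> sha256 prefix
    version: str = ""
    timestamp: str = ""


def write_manifest(out_dir, command: str, parameters: dict, seed, inputs=()) -> Path:
    """Write ``<out_dir>/<command>.manifest.json`` and return its path."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    man = RunManifest(
        command=command,
        parameters={k: _jsonable(v) for k, v in parameters.items()},
        seed=seed,
        inputs={str(p): _digest(p) for p in inputs if p is not None},
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    path = out_dir / f"{command}.manifest.json"
    path.write_text(json.dumps(asdict(man), indent=2) + "\n")
    return path


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, Path):
        return str(v)
    return v
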