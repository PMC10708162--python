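"""CSV/JSON interchange with provenance headers and schema validation.

All tables are UTF-8 CSV with a mandatory header row and dot decimals.
Outputs written by the pipeline carry ``#``-prefixed comment lines recording
the tool version, the run seed and SHA-256 digests of the inputs; readers
skip any such lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__

LEAF_COLUMNS = ["species_id", "individual_id", "plot_id", "leaf_id", "la_mm2", "lfm_mg", "ldm_mg"]
INVENTORY_COLUMNS = [
    "plot_id", "elevation_m", "trail_position", "tree_id", "stem_id",
    "species_id", "dbh_cm", "height_m",
]
ORIGIN_COLUMNS = ["species_id", "origin"]
PROFILE_COLUMNS = [
    "species_id", "origin", "la_mm2", "ldmc_pct", "sla_mm2_mg", "n_individuals", "n_leaves",
]
SCORE_COLUMNS = ["species_id", "c", "s", "r", "strategy_class"]


class SchemaError(ValueError):
    """A CSV violated its expected schema (missing column, bad value)."""


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def provenance_lines(seed: int | None = None, inputs: Iterable[str | Path] = ()) -> list[str]:
    lines = [f"# csrpipe={__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    for p in inputs:
        lines.append(f"# input {Path(p).name} sha256:{file_digest(p)}")
    return lines


def write_csv(df: pd.DataFrame, path: str | Path, *, seed: int | None = None,
              inputs: Iterable[str | Path] = ()) -> Path:
    """Write a table with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in provenance_lines(seed, inputs):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)
    return path


def read_csv(path: str | Path, required: Iterable[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if required is not None:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def validate_rows(df: pd.DataFrame, path: str | Path, checks: Mapping[str, callable]) -> None:
    """Raise SchemaError naming file, row and field on the first failing cell.

    ``checks`` maps column name -> predicate on a scalar value.
    """
    for col, ok in checks.items():
        vals = df[col]
        bad = [i for i, v in zip(df.index, vals) if not ok(v)]
        if bad:
            raise SchemaError(f"{path}: row {bad[0]}, field '{col}' failed validation "
                              f"(value={df.loc[bad[0], col]!r})")


def write_json(obj: dict, path: str | Path, *, seed: int | None = None,
               inputs: Iterable[str | Path] = ()) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    payload["_provenance"] = {
        "tool": f"csrpipe {__version__}",
        "seed": seed,
        "inputs": {Path(p).name: file_digest(p) for p in inputs},
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n", encoding="utf-8")
    return path


def read_json(path: str | Path) -> dict:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    obj.pop("_provenance", None)
    return obj
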