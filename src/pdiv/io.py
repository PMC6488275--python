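"""CSV / JSON / YAML interchange, schema validation, and seed management.

Schemas (exact headers, UTF-8, '.' decimal separator):

* cells.csv     -- cell_id,size,septated,fluor,condition (septated in {0,1})
* records.csv   -- birth_time,division_time,birth_size,division_size,extension,duration
* snapshot.csv  -- time,size,phase,cyclin_amount (phase in {growing,septated})

Floats are written with 12 significant digits so a write/read round trip is
lossless at that precision.  Schema violations raise :class:`SchemaError`
naming the offending column and line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .simulator import (AdderParams, Cdc13Params, DivisionRecord, HillCurve,
                        PopulationSnapshot, SimulationConfig, SizerParams,
                        TimerParams, records_to_dataframe)

__all__ = [
    "SchemaError",
    "RunManifest",
    "CELLS_COLUMNS",
    "RECORDS_COLUMNS",
    "SNAPSHOT_COLUMNS",
    "read_cells",
    "write_cells",
    "read_records",
    "write_records",
    "write_snapshot",
    "read_simulation_config",
    "simulation_config_to_dict",
    "config_digest",
    "derive_seed",
    "stage_rng",
    "write_manifest",
]

CELLS_COLUMNS = ["cell_id", "size", "septated", "fluor", "condition"]
RECORDS_COLUMNS = ["birth_time", "division_time", "birth_size",
                   "division_size", "extension", "duration"]
SNAPSHOT_COLUMNS = ["time", "size", "phase", "cyclin_amount"]

FLOAT_FORMAT = "%.12g"


class SchemaError(ValueError):
    """A table violated its declared schema."""


def _check_header(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    cols = list(df.columns)
    missing = [c for c in expected if c not in cols]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    extra = [c for c in cols if c not in expected]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra}")
    if cols != list(expected):
        raise SchemaError(f"{path}: columns must appear in order {list(expected)}")


def _numeric(df: pd.DataFrame, column: str, path) -> np.ndarray:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = converted.isna() & df[column].notna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        raise SchemaError(
            f"{path}: non-numeric value {df[column][bad].iloc[0]!r} in "
            f"column '{column}' on line {line}")
    if converted.isna().any():
        line = int(df.index[converted.isna()][0]) + 2
        raise SchemaError(f"{path}: empty value in column '{column}' on line {line}")
    return converted.to_numpy(dtype=float)


def read_cells(path) -> pd.DataFrame:
    """Read and validate a cytometry cells table (septated becomes bool)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False,
                     na_values=[""], skip_blank_lines=True)
    _check_header(df, CELLS_COLUMNS, path)
    if len(df) == 0:
        return pd.DataFrame({"cell_id": pd.Series(dtype=str),
                             "size": pd.Series(dtype=float),
                             "septated": pd.Series(dtype=bool),
                             "fluor": pd.Series(dtype=float),
                             "condition": pd.Series(dtype=str)})
    size = _numeric(df, "size", path)
    sept_raw = _numeric(df, "septated", path)
    bad = ~np.isin(sept_raw, (0.0, 1.0))
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise SchemaError(f"{path}: septated must be 0 or 1, got "
                          f"{sept_raw[bad][0]!r} on line {line}")
    fluor = _numeric(df, "fluor", path)
    if np.any(size <= 0.0):
        line = int(np.flatnonzero(size <= 0.0)[0]) + 2
        raise SchemaError(f"{path}: size must be > 0 on line {line}")
    if np.any(fluor < 0.0):
        line = int(np.flatnonzero(fluor < 0.0)[0]) + 2
        raise SchemaError(f"{path}: fluor must be >= 0 on line {line}")
    return pd.DataFrame({"cell_id": df["cell_id"].astype(str),
                         "size": size,
                         "septated": sept_raw.astype(bool),
                         "fluor": fluor,
                         "condition": df["condition"].astype(str)})


def write_cells(table: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "cell_id": table["cell_id"].astype(str),
        "size": np.asarray(table["size"], dtype=float),
        "septated": np.asarray(table["septated"]).astype(bool).astype(int),
        "fluor": np.asarray(table["fluor"], dtype=float),
        "condition": table["condition"].astype(str),
    })
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_records(path) -> List[DivisionRecord]:
    """Read a division-records CSV back into :class:`DivisionRecord` objects."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False,
                     na_values=[""], skip_blank_lines=True)
    _check_header(df, RECORDS_COLUMNS, path)
    if len(df) == 0:
        return []
    cols = {c: _numeric(df, c, path) for c in RECORDS_COLUMNS}
    records = []
    for i in range(len(df)):
        rec = DivisionRecord(birth_time=cols["birth_time"][i],
                             division_time=cols["division_time"][i],
                             birth_size=cols["birth_size"][i],
                             division_size=cols["division_size"][i])
        for derived in ("extension", "duration"):
            if not np.isclose(cols[derived][i], getattr(rec, derived),
                              rtol=1e-9, atol=1e-9):
                raise SchemaError(
                    f"{path}: inconsistent '{derived}' on line {i + 2}")
        records.append(rec)
    return records


def write_records(records: Union[Sequence[DivisionRecord], pd.DataFrame],
                  path) -> None:
    df = (records if isinstance(records, pd.DataFrame)
          else records_to_dataframe(records))
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT,
              columns=RECORDS_COLUMNS)


def write_snapshot(snapshots: Union[PopulationSnapshot,
                                    Sequence[PopulationSnapshot]],
                   path) -> None:
    if isinstance(snapshots, PopulationSnapshot):
        snapshots = [snapshots]
    df = pd.concat([s.to_dataframe() for s in snapshots], ignore_index=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT,
              columns=SNAPSHOT_COLUMNS)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_RULE_PARAM_TYPES = {
    "adder": AdderParams, "sizer": SizerParams, "timer": TimerParams,
    "pdiv": HillCurve, "cdc13": Cdc13Params,
}


def _build_params(rule: str, payload: dict):
    cls = _RULE_PARAM_TYPES[rule]
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise SchemaError(f"unknown rule_params key(s) for rule {rule!r}: "
                          f"{sorted(unknown)}")
    return cls(**payload)


def read_simulation_config(path) -> SimulationConfig:
    """Load a simulation config from JSON (or YAML, accepted as a
    convenience superset); unknown keys are rejected."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith((".yaml", ".yml")):
        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(payload) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
    rule = payload.get("rule", "pdiv")
    if rule not in _RULE_PARAM_TYPES:
        raise SchemaError(f"{path}: unknown rule {rule!r}")
    params = payload.pop("rule_params", None)
    if params is not None:
        if not isinstance(params, dict):
            raise SchemaError(f"{path}: rule_params must be a mapping")
        payload["rule_params"] = _build_params(rule, params)
    try:
        return SimulationConfig(**payload)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def simulation_config_to_dict(config: SimulationConfig) -> dict:
    out = dataclasses.asdict(config)
    return out


def config_digest(config) -> str:
    """Stable SHA-256 digest of a config mapping (key order independent)."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


# ---------------------------------------------------------------------------
# seeds and manifests
# ---------------------------------------------------------------------------


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed: the top-level seed combined with a stable hash of the
    stage name, so stages are independent but reproducible."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0] >> 1)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, stage))


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    subcommand: str
    config_digest: str
    seed: Optional[int]
    inputs: List[str]
    outputs: List[str]
    package_version: str
    timestamp: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_manifest(out_dir, subcommand: str, config, seed: Optional[int],
                   inputs: Sequence, outputs: Sequence) -> Path:
    from . import __version__
    manifest = RunManifest(
        subcommand=subcommand,
        config_digest=config_digest(config),
        seed=seed,
        inputs=[str(p) for p in inputs],
        outputs=[str(p) for p in outputs],
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest.to_dict(), indent=2) + "\n",
                    encoding="utf-8")
    return path
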