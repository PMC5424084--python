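"""CSV readers/writers for gas-exchange logs, trait tables and sensor series.

The reader is dialect-driven: a column-name map lets the same code ingest
instrument exports and the synthetic generator's output.  Rows violating
domain invariants are rejected (and counted), never silently coerced.

Ci unit convention: instrument logs report intercellular CO2 as a mole
fraction (umol mol-1); internally Ci is a partial pressure in Pa, obtained
as ``ci_Pa = ci_umol_per_mol * pressure_kPa / 1000``.  When the log has no
pressure column, standard pressure (101.325 kPa) is assumed and the
assumption is recorded in the run-metadata sidecar.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .records import (
    STANDARD_PRESSURE_KPA,
    CurveDataset,
    GasExchangeRecord,
    LeafTraitRecord,
    RecordInvariantError,
)

log = logging.getLogger("herbphys")


class ConfigurationError(ValueError):
    """A required column or config entry is missing."""


DEFAULT_DIALECT = {
    # herbphys column name -> CSV column name
    "columns": {
        "plant_id": "plant_id",
        "species": "species",
        "life_stage": "life_stage",
        "treatment": "treatment",
        "timestamp": "timestamp",
        "ppfd": "ppfd",
        "a_net": "a_net",
        "ci": "ci",
        "leaf_temp": "leaf_temp",
        "co2_ref": "co2_ref",
        "pressure": "pressure",
    },
    # units of the ci column in the file: "umol_mol" (instrument) or "Pa"
    "ci_units": "umol_mol",
    "timestamp_format": None,  # None -> ISO 8601 / pandas-parseable
}

REQUIRED_FIELDS = ("plant_id", "species", "treatment", "timestamp", "ppfd", "a_net")
OPTIONAL_FIELDS = ("life_stage", "ci", "leaf_temp", "co2_ref", "pressure")


def load_dialect(path: str | Path | None) -> dict:
    """Load a YAML dialect file, merged over the default dialect."""
    dialect = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_DIALECT.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if "columns" in user:
            dialect["columns"].update(user["columns"])
        for key in ("ci_units", "timestamp_format"):
            if key in user:
                dialect[key] = user[key]
    return dialect


@dataclass
class ReadResult:
    """Accepted records plus an accounting of what was rejected."""

    records: list = field(default_factory=list)
    n_rejected: int = 0
    rejection_reasons: list = field(default_factory=list)
    assumed_pressure: bool = False

    @property
    def n_accepted(self) -> int:
        return len(self.records)


def _parse_timestamp(raw: str, fmt: Optional[str]) -> datetime:
    if fmt:
        return datetime.strptime(raw, fmt)
    ts = pd.Timestamp(raw)
    if pd.isna(ts):
        raise ValueError(f"unparseable timestamp {raw!r}")
    return ts.to_pydatetime()


def _opt_float(row: dict, col: Optional[str]) -> Optional[float]:
    if col is None or col not in row:
        return None
    raw = row[col]
    if raw is None or raw == "" or raw.upper() in ("NA", "NAN"):
        return None
    return float(raw)


def read_gas_exchange_log(path: str | Path, dialect: dict | None = None) -> ReadResult:
    """Read an instrument-style gas-exchange CSV into validated records.

    Returns a :class:`ReadResult`; ``n_accepted + n_rejected`` always equals
    the number of data rows in the file.
    """
    dialect = dialect or DEFAULT_DIALECT
    cols = dialect["columns"]
    ci_units = dialect.get("ci_units", "umol_mol")
    fmt = dialect.get("timestamp_format")

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for fld in REQUIRED_FIELDS:
            if cols.get(fld) not in header:
                raise ConfigurationError(
                    f"required column {cols.get(fld)!r} (for field {fld!r}) "
                    f"not found in {path}"
                )
        have = {fld: (cols.get(fld) if cols.get(fld) in header else None)
                for fld in REQUIRED_FIELDS + OPTIONAL_FIELDS}

        result = ReadResult()
        for lineno, row in enumerate(reader, start=2):
            try:
                pressure = _opt_float(row, have["pressure"])
                ci = _opt_float(row, have["ci"])
                if ci is not None and ci_units == "umol_mol":
                    if pressure is None:
                        p_kpa = STANDARD_PRESSURE_KPA
                        result.assumed_pressure = True
                    else:
                        p_kpa = pressure
                    ci = ci * p_kpa / 1000.0  # mole fraction x pressure -> Pa
                rec = GasExchangeRecord(
                    plant_id=str(row[have["plant_id"]]),
                    species=row[have["species"]],
                    treatment=row[have["treatment"]],
                    timestamp=_parse_timestamp(row[have["timestamp"]], fmt),
                    ppfd=float(row[have["ppfd"]]),
                    a_net=float(row[have["a_net"]]),
                    ci=ci,
                    leaf_temp=_opt_float(row, have["leaf_temp"]),
                    co2_ref=_opt_float(row, have["co2_ref"]),
                    pressure=pressure,
                    life_stage=(row.get(have["life_stage"]) or "NA")
                    if have["life_stage"] else "NA",
                )
                rec.validate()
            except (RecordInvariantError, ValueError, KeyError) as exc:
                result.n_rejected += 1
                result.rejection_reasons.append(f"line {lineno}: {exc}")
                log.debug("rejected row at line %d: %s", lineno, exc)
                continue
            result.records.append(rec)
    return result


def write_gas_exchange_log(records: Iterable[GasExchangeRecord], path: str | Path) -> None:
    """Write records to CSV (ppfd/a_net to 4 decimals; Ci stored in Pa)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([
            "plant_id", "species", "life_stage", "treatment", "timestamp",
            "ppfd", "a_net", "ci", "leaf_temp", "co2_ref", "pressure",
        ])
        for r in records:
            writer.writerow([
                r.plant_id, r.species, r.life_stage, r.treatment,
                r.timestamp.isoformat(),
                f"{r.ppfd:.4f}", f"{r.a_net:.4f}",
                "" if r.ci is None else f"{r.ci:.6f}",
                "" if r.leaf_temp is None else f"{r.leaf_temp:.4f}",
                "" if r.co2_ref is None else f"{r.co2_ref:.4f}",
                "" if r.pressure is None else f"{r.pressure:.4f}",
            ])


PA_DIALECT = {
    "columns": dict(DEFAULT_DIALECT["columns"]),
    "ci_units": "Pa",
    "timestamp_format": None,
}


def read_trait_table(path: str | Path) -> list[LeafTraitRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rec = LeafTraitRecord(
                plant_id=str(row["plant_id"]),
                species=row["species"],
                treatment=row["treatment"],
                sample_date=pd.Timestamp(row["sample_date"]).to_pydatetime(),
                leaf_area=float(row["leaf_area"]),
                dry_mass=float(row["dry_mass"]),
                life_stage=row.get("life_stage", "NA") or "NA",
            )
            rec.validate()
            out.append(rec)
    return out


def write_trait_table(records: Iterable[LeafTraitRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plant_id", "species", "life_stage", "treatment",
                         "sample_date", "leaf_area", "dry_mass", "sla"])
        for r in records:
            writer.writerow([r.plant_id, r.species, r.life_stage, r.treatment,
                             r.sample_date.date().isoformat(),
                             f"{r.leaf_area:.4f}", f"{r.dry_mass:.6f}", f"{r.sla:.4f}"])


def group_into_curves(
    records: Iterable[GasExchangeRecord],
    curve_kind: str,
    session_gap: timedelta = timedelta(minutes=30),
) -> list[CurveDataset]:
    """Partition records into per-plant measurement-session curves.

    A new session starts when consecutive records of the same plant are more
    than ``session_gap`` apart.  Curves below the minimum-size invariant are
    flagged ``below_minimum`` (by CurveDataset itself), never dropped.
    """
    by_plant: dict[str, list[GasExchangeRecord]] = {}
    for r in sorted(records, key=lambda r: (r.plant_id, r.timestamp)):
        by_plant.setdefault(r.plant_id, []).append(r)

    curves = []
    for plant_id, recs in by_plant.items():
        session: list[GasExchangeRecord] = []
        n_session = 0
        for r in recs:
            if session and (r.timestamp - session[-1].timestamp) > session_gap:
                curves.append(CurveDataset(
                    curve_id=f"{plant_id}-{n_session}", plant_id=plant_id,
                    curve_kind=curve_kind, records=session))
                session, n_session = [], n_session + 1
            session.append(r)
        if session:
            curves.append(CurveDataset(
                curve_id=f"{plant_id}-{n_session}", plant_id=plant_id,
                curve_kind=curve_kind, records=session))
    return curves


def run_metadata(seed: Optional[int] = None, config: dict | None = None,
                 **extra) -> dict:
    """Assemble the JSON run-metadata sidecar (seed, config hash, counts)."""
    config = config or {}
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    meta = {
        "seed": seed,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "config": config,
    }
    meta.update(extra)
    return meta


def write_run_metadata(meta: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
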