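"""Domain types shared across the package.

A :class:`GasExchangeRecord` is one logged observation from a portable
photosynthesis system (LI-6400 style): incident light (PPFD), net CO2
assimilation, intercellular CO2, and plant metadata.  All downstream fitting
and inference consumes these records (or the curve/trait containers built
from them) -- no stage re-reads raw files.

Units follow gas-exchange convention: PPFD in umol photons m-2 s-1, net
assimilation in umol CO2 m-2 s-1, and intercellular CO2 (Ci) internally in
Pa (instrument logs report a mole fraction in umol mol-1; conversion happens
at read time, see :mod:`herbphys.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional

import pandas as pd

SPECIES = ("Alliaria", "Maianthemum", "Trillium", "other")
LIFE_STAGES = ("rosette", "adult", "NA")
TREATMENTS = ("fenced", "unfenced")
CURVE_KINDS = ("light_response", "aci", "spot")

#: minimum distinct light levels for a usable light-response curve
MIN_LIGHT_LEVELS = 6
#: minimum distinct Ci values for a usable A/Ci curve
MIN_ACI_LEVELS = 8

STANDARD_PRESSURE_KPA = 101.325


class RecordInvariantError(ValueError):
    """A record violates a domain invariant (negative PPFD, bad treatment...)."""


@dataclass
class GasExchangeRecord:
    """One logged gas-exchange observation.

    ``ci`` is intercellular CO2 partial pressure in Pa (may be None for
    spot/light-curve records where it was not logged).  ``a_net`` may be
    negative (respiration exceeds gross assimilation in the dark).
    """

    plant_id: str
    species: str
    treatment: str
    timestamp: datetime
    ppfd: float
    a_net: float
    ci: Optional[float] = None
    leaf_temp: Optional[float] = None
    co2_ref: Optional[float] = None
    pressure: Optional[float] = None
    life_stage: str = "NA"

    @property
    def day_of_year(self) -> int:
        return self.timestamp.timetuple().tm_yday

    def validate(self) -> None:
        if self.species not in SPECIES:
            raise RecordInvariantError(f"unknown species {self.species!r}")
        if self.treatment not in TREATMENTS:
            raise RecordInvariantError(f"unknown treatment {self.treatment!r}")
        if self.life_stage not in LIFE_STAGES:
            raise RecordInvariantError(f"unknown life_stage {self.life_stage!r}")
        if not isinstance(self.timestamp, datetime):
            raise RecordInvariantError("timestamp must be a datetime")
        if not math.isfinite(self.ppfd) or self.ppfd < 0:
            raise RecordInvariantError(f"ppfd must be >= 0, got {self.ppfd}")
        if not math.isfinite(self.a_net):
            raise RecordInvariantError("a_net must be finite")
        if self.ci is not None and not (math.isfinite(self.ci) and self.ci > 0):
            raise RecordInvariantError(f"ci must be > 0 when present, got {self.ci}")


@dataclass
class LeafTraitRecord:
    """One sampled leaf: area, dry mass and the derived specific leaf area."""

    plant_id: str
    species: str
    treatment: str
    sample_date: datetime
    leaf_area: float  # cm2
    dry_mass: float  # g
    life_stage: str = "NA"

    @property
    def sla(self) -> float:
        """Specific leaf area, cm2 g-1."""
        return self.leaf_area / self.dry_mass

    def validate(self) -> None:
        if self.species not in SPECIES:
            raise RecordInvariantError(f"unknown species {self.species!r}")
        if self.treatment not in TREATMENTS:
            raise RecordInvariantError(f"unknown treatment {self.treatment!r}")
        if not (math.isfinite(self.leaf_area) and self.leaf_area > 0):
            raise RecordInvariantError(f"leaf_area must be > 0, got {self.leaf_area}")
        if not (math.isfinite(self.dry_mass) and self.dry_mass > 0):
            raise RecordInvariantError(f"dry_mass must be > 0, got {self.dry_mass}")


@dataclass
class CurveDataset:
    """An ordered set of records forming one response curve for one plant."""

    curve_id: str
    plant_id: str
    curve_kind: str
    records: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.curve_kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve_kind {self.curve_kind!r}")
        if any(r.plant_id != self.plant_id for r in self.records):
            raise RecordInvariantError("all records in a curve must share plant_id")
        if self.curve_kind == "light_response":
            if self.n_distinct_ppfd < MIN_LIGHT_LEVELS and "below_minimum" not in self.flags:
                self.flags.append("below_minimum")
        elif self.curve_kind == "aci":
            if self.n_distinct_ci < MIN_ACI_LEVELS and "below_minimum" not in self.flags:
                self.flags.append("below_minimum")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_distinct_ppfd(self) -> int:
        return len({round(r.ppfd, 6) for r in self.records})

    @property
    def n_distinct_ci(self) -> int:
        return len({round(r.ci, 6) for r in self.records if r.ci is not None})

    @property
    def treatment(self) -> str:
        return self.records[0].treatment if self.records else "NA"

    @property
    def species(self) -> str:
        return self.records[0].species if self.records else "other"

    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


RECORD_COLUMNS = [
    "plant_id", "species", "life_stage", "treatment", "timestamp",
    "ppfd", "a_net", "ci", "leaf_temp", "co2_ref", "pressure",
]


def records_to_frame(records: Iterable[GasExchangeRecord]) -> pd.DataFrame:
    rows = [
        {
            "plant_id": r.plant_id,
            "species": r.species,
            "life_stage": r.life_stage,
            "treatment": r.treatment,
            "timestamp": r.timestamp,
            "ppfd": r.ppfd,
            "a_net": r.a_net,
            "ci": r.ci,
            "leaf_temp": r.leaf_temp,
            "co2_ref": r.co2_ref,
            "pressure": r.pressure,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[GasExchangeRecord]:
    out = []
    for row in frame.itertuples(index=False):
        ts = row.timestamp
        if not isinstance(ts, datetime):
            ts = pd.Timestamp(ts).to_pydatetime()
        rec = GasExchangeRecord(
            plant_id=str(row.plant_id),
            species=row.species,
            treatment=row.treatment,
            timestamp=ts,
            ppfd=float(row.ppfd),
            a_net=float(row.a_net),
            ci=None if pd.isna(row.ci) else float(row.ci),
            leaf_temp=None if pd.isna(row.leaf_temp) else float(row.leaf_temp),
            co2_ref=None if pd.isna(row.co2_ref) else float(row.co2_ref),
            pressure=None if pd.isna(row.pressure) else float(row.pressure),
            life_stage=row.life_stage if isinstance(row.life_stage, str) else "NA",
        )
        rec.validate()
        out.append(rec)
    return out
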