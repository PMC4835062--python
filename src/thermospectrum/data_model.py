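"""Core data structures for collations of temperature-dependent growth rates.

A *collation* is a table of growth observations gathered from many sources:
one row per (strain, temperature, specific growth rate).  Strains carry
metadata on respiration and trophic status, and three cardinal temperatures
are derived from their observed curves:

* ``t_min`` / ``t_max`` — lowest / highest temperature with observed growth,
* ``t_opt`` — the temperature at which the strain grows most rapidly.

All rates are held internally as specific growth rates per minute; all
temperatures are degrees Celsius.  Conversion to Kelvin happens only inside
the thermodynamic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RESPIRATION_STATUSES",
    "TROPHIC_STATUSES",
    "GrowthRecord",
    "StrainCurve",
    "Collation",
    "TemperatureBin",
    "LoadReport",
    "SchemaError",
    "UnitConversionError",
    "generation_time_to_rate",
    "load_collation",
    "write_collation",
    "derive_topt",
    "filter_for_thermo",
    "make_bins",
    "split_by_topt",
]

RESPIRATION_STATUSES = frozenset(
    {"aerobe", "anaerobe", "facultative_anaerobe", "microaerobe", "unknown"}
)
TROPHIC_STATUSES = frozenset({"autotroph", "heterotroph", "mixotroph", "unknown"})

#: time-unit declarations accepted by :func:`load_collation`
RATE_UNITS = {"per_minute": 1.0, "per_hour": 1.0 / 60.0, "per_day": 1.0 / 1440.0}
GENTIME_UNITS = {"minutes": 1.0, "hours": 60.0, "days": 1440.0}


class SchemaError(ValueError):
    """Raised when an input table lacks mandatory columns or is empty."""


class UnitConversionError(ValueError):
    """Raised for invalid unit declarations or non-positive time values."""


def generation_time_to_rate(g: float) -> float:
    """Convert a generation (doubling) time in minutes to a specific rate.

    Uses r = ln(2)/g, the standard relation between doubling time and
    exponential-phase specific growth rate.
    """
    if not math.isfinite(g) or g <= 0:
        raise UnitConversionError(f"generation time must be finite and > 0, got {g!r}")
    return math.log(2.0) / g


@dataclass(frozen=True)
class GrowthRecord:
    """One growth observation: a strain's specific rate at one temperature."""

    strain_id: str
    temperature: float  # degrees Celsius
    rate: float  # specific growth rate per minute
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.strain_id:
            raise ValueError("strain_id must be non-empty")
        if not math.isfinite(self.temperature):
            raise ValueError(f"temperature must be finite, got {self.temperature!r}")
        if not (math.isfinite(self.rate) and self.rate > 0):
            raise ValueError(f"rate must be finite and > 0, got {self.rate!r}")


def derive_topt(records: "Sequence[GrowthRecord] | StrainCurve") -> float:
    """Temperature of the maximum observed rate of one strain's curve.

    Ties are broken toward the lowest tied temperature so the result is
    deterministic regardless of record order.
    """
    if isinstance(records, StrainCurve):
        records = records.records
    if not records:
        raise ValueError("cannot derive T_opt from an empty curve")
    best = records[0]
    for rec in records[1:]:
        if rec.rate > best.rate or (rec.rate == best.rate and rec.temperature < best.temperature):
            best = rec
    return best.temperature


@dataclass
class StrainCurve:
    """A strain's observed growth curve plus metadata and cardinal temperatures.

    Records are kept sorted by temperature.  ``t_opt`` is derived (argmax of
    rate, lowest temperature on ties); ``t_min``/``t_max`` are the observed
    extremes.
    """

    strain_id: str
    records: list[GrowthRecord]
    respiration: str = "unknown"
    trophic: str = "unknown"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"strain {self.strain_id!r} has no records")
        if self.respiration not in RESPIRATION_STATUSES:
            raise ValueError(f"unknown respiration status {self.respiration!r}")
        if self.trophic not in TROPHIC_STATUSES:
            raise ValueError(f"unknown trophic status {self.trophic!r}")
        self.records = sorted(self.records, key=lambda r: r.temperature)

    @property
    def t_min(self) -> float:
        return self.records[0].temperature

    @property
    def t_max(self) -> float:
        return self.records[-1].temperature

    @property
    def t_opt(self) -> float:
        return derive_topt(self.records)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([r.temperature for r in self.records], dtype=float)

    @property
    def rates(self) -> np.ndarray:
        return np.array([r.rate for r in self.records], dtype=float)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def has_interior_peak(self) -> bool:
        """True when T_opt lies strictly between the observed extremes."""
        return self.t_min < self.t_opt < self.t_max


@dataclass
class LoadReport:
    """Validation summary produced by :func:`load_collation`."""

    n_rows_in: int = 0
    n_records: int = 0
    n_strains: int = 0
    dropped: list[tuple[int, str]] = field(default_factory=list)  # (row index, reason)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def to_text(self) -> str:
        lines = [
            f"rows read:      {self.n_rows_in}",
            f"records kept:   {self.n_records}",
            f"strains:        {self.n_strains}",
            f"rows dropped:   {self.n_dropped}",
        ]
        for idx, reason in self.dropped:
            lines.append(f"  row {idx}: {reason}")
        return "\n".join(lines) + "\n"


@dataclass
class Collation:
    """The full set of strain curves under analysis."""

    strains: list[StrainCurve]

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_records(self) -> int:
        return sum(s.n_records for s in self.strains)

    @property
    def temperature_range(self) -> tuple[float, float]:
        temps = [r.temperature for s in self.strains for r in s.records]
        return (min(temps), max(temps))

    def __iter__(self):
        return iter(self.strains)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "strain_id": s.strain_id,
                "temperature_C": r.temperature,
                "rate_per_min": r.rate,
                "respiration": s.respiration,
                "trophic": s.trophic,
                "source": r.source or "",
            }
            for s in self.strains
            for r in s.records
        ]
        return pd.DataFrame(rows)


_MANDATORY = ("strain_id", "temperature_C")


def load_collation(
    source: "str | Path | pd.DataFrame",
    unit: str = "per_minute",
    delimiter: str = ",",
) -> tuple[Collation, LoadReport]:
    """Read and validate a delimiter-separated collation table.

    The table must have columns ``strain_id`` and ``temperature_C`` plus
    either ``rate`` (in the declared rate unit) or ``generation_time`` (in the
    declared time unit); the canonical column name ``rate_per_min`` is
    accepted as ``rate`` with unit ``per_minute``.  Optional columns:
    ``respiration``, ``trophic``, ``source``.

    ``unit`` is one of ``per_minute | per_hour | per_day`` for rates, or
    ``minutes | hours | days`` for generation times.  Rows failing the
    invariants (non-positive or non-finite rate, non-finite temperature,
    empty strain id) are dropped and listed in the returned
    :class:`LoadReport`.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=delimiter)
    if len(df) == 0:
        raise SchemaError("input table is empty")
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    if "rate_per_min" in df.columns:
        values = df["rate_per_min"].to_numpy(dtype=float)
        factor, is_gentime = 1.0, False
    elif "rate" in df.columns:
        if unit not in RATE_UNITS:
            raise UnitConversionError(f"unit {unit!r} is not a rate unit {sorted(RATE_UNITS)}")
        values = df["rate"].to_numpy(dtype=float)
        factor, is_gentime = RATE_UNITS[unit], False
    elif "generation_time" in df.columns:
        if unit not in GENTIME_UNITS:
            raise UnitConversionError(
                f"unit {unit!r} is not a generation-time unit {sorted(GENTIME_UNITS)}"
            )
        values = df["generation_time"].to_numpy(dtype=float)
        factor, is_gentime = GENTIME_UNITS[unit], True
    else:
        raise SchemaError("need a 'rate', 'rate_per_min' or 'generation_time' column")

    report = LoadReport(n_rows_in=len(df))
    per_strain: dict[str, list[GrowthRecord]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        sid = str(getattr(row, "strain_id", "") or "")
        temp = float(getattr(row, "temperature_C"))
        v = values[i]
        if not sid:
            report.dropped.append((i, "empty strain_id"))
            continue
        if not math.isfinite(temp):
            report.dropped.append((i, "non-finite temperature"))
            continue
        if not (math.isfinite(v) and v > 0):
            what = "generation time" if is_gentime else "rate"
            report.dropped.append((i, f"non-positive or non-finite {what}: {v!r}"))
            continue
        rate = generation_time_to_rate(v * factor) if is_gentime else v * factor
        src = str(getattr(row, "source", "") or "") or None
        per_strain.setdefault(sid, []).append(GrowthRecord(sid, temp, rate, src))
        if sid not in meta:
            resp = str(getattr(row, "respiration", "unknown") or "unknown")
            trop = str(getattr(row, "trophic", "unknown") or "unknown")
            meta[sid] = (
                resp if resp in RESPIRATION_STATUSES else "unknown",
                trop if trop in TROPHIC_STATUSES else "unknown",
            )

    if not per_strain:
        raise SchemaError("no valid rows after validation")
    strains = [
        StrainCurve(sid, recs, respiration=meta[sid][0], trophic=meta[sid][1])
        for sid, recs in per_strain.items()
    ]
    coll = Collation(strains)
    report.n_records = coll.n_records
    report.n_strains = coll.n_strains
    return coll, report


def write_collation(collation: Collation, path: "str | Path", delimiter: str = ",") -> None:
    """Write a collation in the canonical column layout."""
    collation.to_frame().to_csv(path, sep=delimiter, index=False)


def filter_for_thermo(collation: Collation, min_points: int = 5) -> list[StrainCurve]:
    """Strains eligible for the thermodynamic fit.

    Keeps strains with at least ``min_points`` records and a distinct peak,
    i.e. an interior maximum: T_opt strictly between the strain's lowest and
    highest observed temperatures.
    """
    return [
        s for s in collation.strains if s.n_records >= min_points and s.has_interior_peak()
    ]


@dataclass(frozen=True)
class TemperatureBin:
    """Half-open temperature interval (lower, upper] for grouping by T_opt."""

    lower: float  # open bound; -inf for the first bin
    upper: float  # closed bound; +inf for the last bin
    label: str

    def contains(self, t_opt: float) -> bool:
        return self.lower < t_opt <= self.upper

    @property
    def midpoint(self) -> float:
        """Finite representative temperature, used for trend plotting."""
        if math.isinf(self.lower):
            return self.upper - 15.0
        if math.isinf(self.upper):
            return self.lower + 15.0
        return 0.5 * (self.lower + self.upper)


def make_bins(width: float = 30.0) -> list[TemperatureBin]:
    """The standard ladder of overlapping T_opt bins.

    First bin (−∞, 30], then (k, k+30] for k = 1…45, then (75, +∞):
    47 bins, each interior bin 30 °C wide and displaced 1 °C from its
    neighbour.  Membership is by a strain's T_opt with the convention
    lower < T_opt ≤ upper.
    """
    bins = [TemperatureBin(-math.inf, width, f"<= {width:g}")]
    for k in range(1, 46):
        bins.append(TemperatureBin(float(k), k + width, f"({k:g}, {k + width:g}]"))
    bins.append(TemperatureBin(75.0, math.inf, "> 75"))
    return bins


def split_by_topt(
    collation: Collation, threshold: float = 50.0
) -> tuple[Collation, Collation]:
    """Partition strains into T_opt ≤ threshold and T_opt > threshold groups.

    The split is exhaustive and disjoint; every record travels with its
    strain.  Either group may be empty.
    """
    low = [s for s in collation.strains if s.t_opt <= threshold]
    high = [s for s in collation.strains if s.t_opt > threshold]
    return Collation(low), Collation(high)
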