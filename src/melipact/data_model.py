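"""Record model, CSV round-tripping, and regulatory threshold policy.

One honey sample is identified by an opaque id and carries three identity
labels (botanical type as declared by the beekeeper, Serbian region, harvest
year) plus nine measured physicochemical parameters:

======  ==============================  =========
field   parameter                       unit
======  ==============================  =========
glu     glucose                         g/100 g
fru     fructose                        g/100 g
suc     sucrose                         g/100 g
hmf     5-hydroxymethylfurfural (5-HMF) mg/kg
mc      moisture content                %
acid    free acidity                    meq/kg
dia     diastase activity               Schade/DN
ins     insoluble matter                %
econd   electrical conductivity         mS/cm
======  ==============================  =========

Sucrose and 5-HMF determinations below the limit of quantification are
reported as "<0.50"; such values are stored at the LOQ (0.50) with a
censoring flag so the CSV round-trip is lossless.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

__all__ = [
    "LOQ",
    "PARAMETERS",
    "HoneyType",
    "Region",
    "HoneySample",
    "SampleTable",
    "ThresholdPolicy",
    "SchemaError",
    "ParseError",
    "IntegrityError",
    "PolicyError",
    "read_samples",
    "write_samples",
    "load_policy",
]

#: Limit of quantification for sucrose and 5-HMF (value stored for "<0.50" cells).
LOQ = 0.50

#: Measurement columns in canonical CSV order.
PARAMETERS = ("glu", "fru", "suc", "hmf", "mc", "acid", "dia", "ins", "econd")

CSV_COLUMNS = ("sample_id", "declared_type", "region", "year") + PARAMETERS

YEAR_MIN, YEAR_MAX = 2018, 2023


class SchemaError(ValueError):
    """A required CSV column is missing."""


class ParseError(ValueError):
    """A cell could not be parsed as a measurement."""


class IntegrityError(ValueError):
    """A table-level constraint (e.g. unique sample_id) is violated."""


class PolicyError(ValueError):
    """A threshold-policy document is invalid."""


class HoneyType(str, Enum):
    ACACIA = "acacia"
    HONEYDEW = "honeydew"
    LINDEN = "linden"
    MONOFLORAL = "monofloral"
    POLYFLORAL = "polyfloral"
    SUNFLOWER = "sunflower"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Region(str, Enum):
    WESTERN = "Western"
    BELGRADE = "Belgrade"
    NORTHERN = "Northern"
    CENTRAL = "Central"
    EASTERN = "Eastern"
    SOUTHERN = "Southern"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class HoneySample:
    """One honey record: identity labels plus the nine measurements.

    ``final_type`` is ``None`` until conductivity-based reclassification has
    run; afterwards it holds the (possibly unchanged) botanical class used by
    every downstream rule.
    """

    sample_id: str
    declared_type: HoneyType
    region: Region
    year: int
    glu: float
    fru: float
    suc: float
    hmf: float
    mc: float
    acid: float
    dia: float
    ins: float
    econd: float
    suc_censored: bool = False
    hmf_censored: bool = False
    final_type: HoneyType | None = None

    def __post_init__(self) -> None:
        for name in PARAMETERS:
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ValueError(f"{self.sample_id}: {name} must be >= 0, got {v!r}")
        if not YEAR_MIN <= self.year <= YEAR_MAX:
            raise ValueError(
                f"{self.sample_id}: year {self.year} outside {YEAR_MIN}-{YEAR_MAX}"
            )
        if self.suc_censored and self.suc != LOQ:
            raise ValueError(f"{self.sample_id}: censored sucrose must be stored at {LOQ}")
        if self.hmf_censored and self.hmf != LOQ:
            raise ValueError(f"{self.sample_id}: censored 5-HMF must be stored at {LOQ}")

    @property
    def sugar_sum(self) -> float:
        """Glucose + fructose in g/100 g (the monosaccharide sum)."""
        return self.glu + self.fru

    @property
    def effective_type(self) -> HoneyType:
        """Final type when set, else the declared type."""
        return self.final_type if self.final_type is not None else self.declared_type

    def with_final_type(self, final: HoneyType) -> "HoneySample":
        return replace(self, final_type=final)


class SampleTable:
    """Ordered, id-unique collection of :class:`HoneySample` records."""

    def __init__(self, samples: Iterable[HoneySample], provenance: str = "") -> None:
        self._samples = list(samples)
        self.provenance = provenance
        seen: set[str] = set()
        for s in self._samples:
            if s.sample_id in seen:
                raise IntegrityError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)

    def __iter__(self) -> Iterator[HoneySample]:
        return iter(self._samples)

    def __len__(self) -> int:
        return len(self._samples)

    def __getitem__(self, i: int) -> HoneySample:
        return self._samples[i]

    def values(self, parameter: str) -> list[float]:
        """All values of one measurement column, in table order."""
        if parameter not in PARAMETERS:
            raise KeyError(parameter)
        return [getattr(s, parameter) for s in self._samples]

    def to_dataframe(self):
        """Pandas view (labels as strings); measurement columns float."""
        import pandas as pd

        rows = []
        for s in self._samples:
            row = {
                "sample_id": s.sample_id,
                "declared_type": s.declared_type.value,
                "final_type": s.final_type.value if s.final_type else None,
                "region": s.region.value,
                "year": s.year,
            }
            row.update({p: getattr(s, p) for p in PARAMETERS})
            rows.append(row)
        return pd.DataFrame(rows)


def _format_cell(value: float, censored: bool) -> str:
    if censored:
        return "<0.50"
    return repr(float(value))


def _parse_measurement(cell: str, column: str, row_index: int) -> tuple[float, bool]:
    cell = cell.strip()
    if cell == "<0.50":
        if column not in ("suc", "hmf"):
            raise ParseError(
                f"row {row_index}: censored marker only allowed for suc/hmf, got {column}"
            )
        return LOQ, True
    try:
        return float(cell), False
    except ValueError:
        raise ParseError(
            f"row {row_index}: non-numeric value {cell!r} in column {column}"
        ) from None


def read_samples(path: str | Path) -> SampleTable:
    """Read a sample table from CSV.

    The header must name every canonical column; ``suc``/``hmf`` cells may be
    the censored marker ``"<0.50"``.  Raises :class:`SchemaError`,
    :class:`ParseError` or :class:`IntegrityError` on malformed input.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        samples: list[HoneySample] = []
        for i, row in enumerate(reader, start=1):
            kwargs: dict = {}
            for p in PARAMETERS:
                value, censored = _parse_measurement(row[p], p, i)
                kwargs[p] = value
                if p == "suc":
                    kwargs["suc_censored"] = censored
                elif p == "hmf":
                    kwargs["hmf_censored"] = censored
            try:
                declared = HoneyType(row["declared_type"].strip())
                region = Region(row["region"].strip())
            except ValueError as exc:
                raise ParseError(f"row {i}: {exc}") from None
            try:
                year = int(row["year"])
            except ValueError:
                raise ParseError(f"row {i}: non-integer year {row['year']!r}") from None
            samples.append(
                HoneySample(
                    sample_id=row["sample_id"].strip(),
                    declared_type=declared,
                    region=region,
                    year=year,
                    **kwargs,
                )
            )
    return SampleTable(samples, provenance=str(path))


def write_samples(table: SampleTable, path: str | Path) -> None:
    """Write a sample table to CSV (lossless: read→write→read is identity).

    Floats are written with ``repr`` (shortest round-trip form) and censored
    sucrose/5-HMF cells as ``"<0.50"``, so re-reading reproduces the table
    bit-identically.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for s in table:
            row = [s.sample_id, s.declared_type.value, s.region.value, str(s.year)]
            for p in PARAMETERS:
                censored = (p == "suc" and s.suc_censored) or (
                    p == "hmf" and s.hmf_censored
                )
                row.append(_format_cell(getattr(s, p), censored))
            writer.writerow(row)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Regulatory limits driving all compliance rules.

    Defaults are the international (IHC / EU honey directive) limits: nectar
    honey needs glucose+fructose >= 60 g/100 g (honeydew and its blends
    >= 45), sucrose <= 5 g/100 g (10 for acacia and a few other listed
    types), 5-HMF <= 40 mg/kg, free acidity <= 50 meq/kg, diastase >= 8 DN,
    moisture <= 20 %, insoluble matter <= 0.1 % (0.5 % for pressed honey).
    Conductivity above 0.8 mS/cm marks honeydew; below 0.1 mS/cm is flagged
    as suspiciously low.  ``blend_econd_min`` is the lower edge of the
    conductivity band in which a low-sum flower honey is annotated as a
    possible nectar/honeydew blend.
    """

    econd_flower_max: float = 0.8
    econd_low_flag: float = 0.1
    sugar_sum_min_blossom: float = 60.0
    sugar_sum_min_honeydew: float = 45.0
    sucrose_max_default: float = 5.0
    sucrose_max_exception: float = 10.0
    sucrose_exception_types: frozenset[HoneyType] = frozenset({HoneyType.ACACIA})
    hmf_max: float = 40.0
    acidity_max: float = 50.0
    diastase_min: float = 8.0
    moisture_max: float = 20.0
    insoluble_max: float = 0.1
    insoluble_max_pressed: float = 0.5
    blend_econd_min: float = 0.70

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "sucrose_exception_types":
                continue
            v = getattr(self, f.name)
            if not (v > 0):
                raise PolicyError(f"{f.name} must be strictly positive, got {v!r}")
        if not self.sugar_sum_min_honeydew < self.sugar_sum_min_blossom:
            raise PolicyError("honeydew sugar floor must lie below the blossom floor")
        if not self.sucrose_max_exception > self.sucrose_max_default:
            raise PolicyError("exception sucrose ceiling must exceed the default")
        if self.blend_econd_min > self.econd_flower_max:
            raise PolicyError("blend conductivity band must sit below the honeydew cut")

    def sucrose_max(self, honey_type: HoneyType) -> float:
        if honey_type in self.sucrose_exception_types:
            return self.sucrose_max_exception
        return self.sucrose_max_default

    def sugar_sum_min(self, honey_type: HoneyType) -> float:
        if honey_type is HoneyType.HONEYDEW:
            return self.sugar_sum_min_honeydew
        return self.sugar_sum_min_blossom


_POLICY_FIELDS = {f.name for f in fields(ThresholdPolicy)}


def load_policy(config: str | Path | Mapping | None = None) -> ThresholdPolicy:
    """Build a :class:`ThresholdPolicy` from a YAML file path, a mapping, or
    nothing (all defaults).

    Unknown keys and non-positive limits raise :class:`PolicyError`.
    """
    if config is None:
        return ThresholdPolicy()
    if isinstance(config, (str, Path)):
        with Path(config).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise PolicyError("policy file must be a flat key-value document")
    else:
        data = dict(config)
    unknown = set(data) - _POLICY_FIELDS
    if unknown:
        raise PolicyError(f"unknown policy key(s): {', '.join(sorted(unknown))}")
    kwargs = dict(data)
    if "sucrose_exception_types" in kwargs:
        kwargs["sucrose_exception_types"] = frozenset(
            HoneyType(t) for t in kwargs["sucrose_exception_types"]
        )
    return ThresholdPolicy(**kwargs)
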