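"""Strain-pair genome-relatedness tables.

Each record holds, for one pair of *Streptomyces* type strains, the three
relatedness metrics this package calibrates against each other:

* ``anim`` — average nucleotide identity from MUMmer alignments, in percent;
* ``mlsa`` — evolutionary distance (substitutions/site, Kimura two-parameter)
  over the concatenated *atpD–gyrB–recA–rpoB–trpB* housekeeping genes;
* ``ddh`` — digital DNA–DNA hybridization (GGDC formula 2), in percent.

A curated 80-pair table for the genus *Streptomyces* ships with the package
(:func:`load_packaged_table`); every pair in it was pre-selected to have
ANIm >= 90%, the range where MUMmer-based ANI is reliable.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

__all__ = [
    "StrainPairRecord",
    "MetricTable",
    "Interval",
    "SchemaError",
    "TableValidationError",
    "load_packaged_table",
    "read_table",
    "write_table",
    "count_where",
    "filter_where",
]

_COLUMNS = ("species_a", "species_b", "anim", "mlsa", "ddh")

_PACKAGED_RESOURCE = "streptomyces_pairs.tsv"


class SchemaError(ValueError):
    """The input file does not have the expected five-column header."""


class TableValidationError(ValueError):
    """A record violates a metric-domain invariant; carries the row index."""

    def __init__(self, message: str, row: Optional[int] = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class StrainPairRecord:
    """One strain pair with its three relatedness metrics.

    Labels are opaque strings exactly as curated (type-strain superscript T
    rendered as a plain trailing ``T``); no nomenclature normalization is
    attempted.
    """

    species_a: str
    species_b: str
    anim: float
    mlsa: float
    ddh: float

    def __post_init__(self) -> None:
        if not self.species_a or not self.species_b:
            raise TableValidationError("empty species label")
        if self.species_a == self.species_b:
            raise TableValidationError(
                f"self-pair: {self.species_a!r} compared with itself"
            )
        for name, value, lo, hi in (
            ("anim", self.anim, 0.0, 100.0),
            ("ddh", self.ddh, 0.0, 100.0),
        ):
            if not math.isfinite(value) or not (lo <= value <= hi):
                raise TableValidationError(
                    f"{name}={value!r} outside [{lo}, {hi}]"
                )
        if not math.isfinite(self.mlsa) or self.mlsa < 0:
            raise TableValidationError(f"mlsa={self.mlsa!r} must be >= 0")

    @property
    def pair_key(self) -> frozenset:
        """Unordered pair identity: (A, B) and (B, A) are the same pair."""
        return frozenset((self.species_a, self.species_b))


@dataclass
class MetricTable:
    """Ordered collection of :class:`StrainPairRecord` with provenance."""

    records: list[StrainPairRecord] = field(default_factory=list)
    source: str = "unspecified"

    def __post_init__(self) -> None:
        seen: dict[frozenset, int] = {}
        for i, rec in enumerate(self.records, start=1):
            key = rec.pair_key
            if key in seen:
                raise TableValidationError(
                    f"duplicate pair {sorted(key)} (also row {seen[key]})",
                    row=i,
                )
            seen[key] = i

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StrainPairRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetricTable):
            return NotImplemented
        return self.records == other.records

    def column(self, name: str) -> list[float]:
        """Numeric column (``anim``, ``mlsa`` or ``ddh``) as a list."""
        if name not in ("anim", "mlsa", "ddh"):
            raise KeyError(name)
        return [getattr(r, name) for r in self.records]

    def find_pair(self, token_a: str, token_b: str) -> StrainPairRecord:
        """Locate the unique record whose two labels contain the two tokens.

        Matching is order-insensitive substring search, convenient for
        pulling out named pairs (e.g. ``find_pair("antimycoticus",
        "melanosporofaciens")``).
        """
        hits = [
            r
            for r in self.records
            if (token_a in r.species_a and token_b in r.species_b)
            or (token_a in r.species_b and token_b in r.species_a)
        ]
        if len(hits) != 1:
            raise KeyError(
                f"tokens ({token_a!r}, {token_b!r}) matched {len(hits)} records"
            )
        return hits[0]


@dataclass(frozen=True)
class Interval:
    """Numeric interval with explicit per-bound openness.

    ``None`` bounds are unbounded.  The default is closed on both present
    bounds, so ``Interval(0.008, 0.014, hi_closed=False)`` expresses the
    half-open band [0.008, 0.014).
    """

    lo: Optional[float] = None
    hi: Optional[float] = None
    lo_closed: bool = True
    hi_closed: bool = True

    def __post_init__(self) -> None:
        if self.lo is not None and self.hi is not None and self.lo > self.hi:
            raise ValueError(f"inverted interval: lo={self.lo} > hi={self.hi}")

    def contains(self, x: float) -> bool:
        if self.lo is not None:
            if x < self.lo or (x == self.lo and not self.lo_closed):
                return False
        if self.hi is not None:
            if x > self.hi or (x == self.hi and not self.hi_closed):
                return False
        return True

    @classmethod
    def at_least(cls, lo: float) -> "Interval":
        return cls(lo=lo)

    @classmethod
    def greater_than(cls, lo: float) -> "Interval":
        return cls(lo=lo, lo_closed=False)

    @classmethod
    def less_than(cls, hi: float) -> "Interval":
        return cls(hi=hi, hi_closed=False)

    @classmethod
    def at_most(cls, hi: float) -> "Interval":
        return cls(hi=hi)


IntervalLike = Union[Interval, tuple, None]


def _as_interval(spec: IntervalLike) -> Optional[Interval]:
    if spec is None or isinstance(spec, Interval):
        return spec
    if isinstance(spec, tuple) and len(spec) == 2:
        return Interval(lo=spec[0], hi=spec[1])
    raise TypeError(f"cannot interpret {spec!r} as an interval")


def filter_where(
    table: MetricTable,
    mlsa_range: IntervalLike = None,
    ddh_range: IntervalLike = None,
    anim_range: IntervalLike = None,
) -> list[StrainPairRecord]:
    """Records satisfying ALL provided metric constraints."""
    constraints = [
        ("mlsa", _as_interval(mlsa_range)),
        ("ddh", _as_interval(ddh_range)),
        ("anim", _as_interval(anim_range)),
    ]
    out = []
    for rec in table:
        if all(
            iv is None or iv.contains(getattr(rec, name))
            for name, iv in constraints
        ):
            out.append(rec)
    return out


def count_where(
    table: MetricTable,
    mlsa_range: IntervalLike = None,
    ddh_range: IntervalLike = None,
    anim_range: IntervalLike = None,
) -> int:
    """Number of records satisfying all provided constraints."""
    return len(filter_where(table, mlsa_range, ddh_range, anim_range))


def _sniff_delimiter(sample: str, dialect: Optional[str]) -> str:
    if dialect is not None:
        return {"tsv": "\t", "csv": ",", "\t": "\t", ",": ","}[dialect]
    first = sample.splitlines()[0] if sample else ""
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_table(
    path: Union[str, Path], dialect: Optional[str] = None
) -> MetricTable:
    """Read a metric table from TSV/CSV (delimiter auto-detected).

    The header must name the five columns ``species_a species_b anim mlsa
    ddh`` (any order).  Rows failing a domain invariant raise
    :class:`TableValidationError` naming the offending 1-based data row.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    delim = _sniff_delimiter(text, dialect)
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    header = reader.fieldnames or []
    missing = [c for c in _COLUMNS if c not in header]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing}; found header {header}"
        )
    records = []
    for i, row in enumerate(reader, start=1):
        try:
            values = {k: float(row[k]) for k in ("anim", "mlsa", "ddh")}
        except (TypeError, ValueError) as exc:
            raise TableValidationError(
                f"non-numeric metric in {dict(row)!r}: {exc}", row=i
            ) from exc
        try:
            records.append(
                StrainPairRecord(
                    species_a=row["species_a"],
                    species_b=row["species_b"],
                    **values,
                )
            )
        except TableValidationError as exc:
            raise TableValidationError(str(exc), row=i) from exc
    return MetricTable(records=records, source=str(path))


def write_table(table: MetricTable, path: Union[str, Path]) -> Path:
    """Write a table as TSV, preserving curated precision.

    Column order is fixed; anim prints to 2 dp, mlsa to 3 dp, ddh to 1 dp,
    so a round trip through :func:`read_table` reproduces the table exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in table:
            fh.write(
                f"{r.species_a}\t{r.species_b}\t"
                f"{r.anim:.2f}\t{r.mlsa:.3f}\t{r.ddh:.1f}\n"
            )
    return path


def load_packaged_table() -> MetricTable:
    """The packaged 80-pair *Streptomyces* table, in curated order.

    Raises a fatal configuration error (RuntimeError) if the packaged data
    file is missing or fails validation — that indicates a broken install.
    """
    try:
        ref = resources.files("strepdelim.data").joinpath(_PACKAGED_RESOURCE)
        text = ref.read_text(encoding="utf-8")
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise RuntimeError(
            f"packaged table {_PACKAGED_RESOURCE!r} is missing: {exc}"
        ) from exc
    delim = "\t"
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    try:
        records = [
            StrainPairRecord(
                species_a=row["species_a"],
                species_b=row["species_b"],
                anim=float(row["anim"]),
                mlsa=float(row["mlsa"]),
                ddh=float(row["ddh"]),
            )
            for row in reader
        ]
        table = MetricTable(records=records, source="packaged:streptomyces_pairs")
    except (KeyError, ValueError) as exc:
        raise RuntimeError(f"packaged table is corrupted: {exc}") from exc
    if any(r.anim < 90 for r in table):
        raise RuntimeError(
            "packaged table is corrupted: contains a pair with ANIm < 90%"
        )
    return table
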