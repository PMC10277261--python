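"""Pairwise divergence-time tables and matrices.

Divergence times between species pairs are kept in two interchangeable
shapes: a long-format "vectorized" three-column table (taxon A, taxon B,
time in millions of years), which is the natural export format for batch
retrieval, and a square symmetric matrix keyed by a species list, which is
the shape downstream matrix statistics (e.g. Mantel tests) consume.

Times are medians (or adjusted medians) over published studies, in MYA.
A time may be unknown ("missing"), represented as ``None`` throughout; a
missing time is a first-class value so that batch runs never abort on a
single unresolved pair.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "TableMode",
    "DivergencePair",
    "PairwiseTable",
    "DivergenceMatrix",
    "DivergenceDataError",
    "normalize_name",
    "read_species_list",
    "table_to_matrix",
    "matrix_to_table",
    "find_missing",
    "write_table_csv",
    "read_table_csv",
]

#: Sentinel for an unknown divergence time (serialized as an empty CSV field).
MISSING = None

#: Default tolerance (MY) for reconciling the two orderings of a pair in a
#: full table; the upstream resource prints times to one decimal place.
DEFAULT_CONFLICT_TOL = 0.05


class DivergenceDataError(ValueError):
    """Malformed or inconsistent divergence-time data."""


class TableMode(str, enum.Enum):
    """Pair coverage of a :class:`PairwiseTable`.

    FULL lists all n**2 ordered pairs including self-pairs (the layout the
    batch retrieval prints); UNORDERED lists each distinct unordered pair
    once, n(n-1)/2 rows.
    """

    FULL = "full"
    UNORDERED = "unordered"


def normalize_name(raw: str) -> str:
    """Normalize a species name: underscores to spaces, whitespace collapsed.

    Case is preserved. Raises :class:`DivergenceDataError` on an empty or
    whitespace-only input.
    """
    if raw is None:
        raise DivergenceDataError("species name is missing")
    name = " ".join(str(raw).replace("_", " ").split())
    if not name:
        raise DivergenceDataError(f"unusable species entry: {raw!r}")
    return name


@dataclass(frozen=True)
class DivergencePair:
    """One pairwise divergence record (one row of the vectorized table).

    ``time_mya`` is the median divergence time in MYA, or ``None`` when
    unknown. The confidence interval, when present, is the range over the
    contributing studies; the median is *not* required to fall inside it
    (the resource reports medians and adjusted medians separately).
    """

    taxon_a: str
    taxon_b: str
    time_mya: Optional[float] = MISSING
    ci_low_mya: Optional[float] = None
    ci_high_mya: Optional[float] = None
    n_studies: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxon_a", normalize_name(self.taxon_a))
        object.__setattr__(self, "taxon_b", normalize_name(self.taxon_b))
        if self.time_mya is not None:
            t = float(self.time_mya)
            if math.isnan(t):
                t = None  # NaN (e.g. from pandas) means missing
            elif t < 0:
                raise DivergenceDataError(
                    f"negative divergence time {t} for "
                    f"({self.taxon_a}, {self.taxon_b})"
                )
            object.__setattr__(self, "time_mya", t)
        if self.is_self_pair and self.time_mya not in (None, 0.0):
            raise DivergenceDataError(
                f"self-pair ({self.taxon_a}) must have time 0, got {self.time_mya}"
            )
        lo, hi = self.ci_low_mya, self.ci_high_mya
        if lo is not None and hi is not None and float(lo) > float(hi):
            raise DivergenceDataError(
                f"CI bounds reversed for ({self.taxon_a}, {self.taxon_b}): "
                f"{lo} > {hi}"
            )
        if self.n_studies is not None and int(self.n_studies) < 1:
            raise DivergenceDataError("study count must be a positive integer")

    @property
    def is_self_pair(self) -> bool:
        return self.taxon_a == self.taxon_b

    @property
    def is_missing(self) -> bool:
        return self.time_mya is None

    def key(self) -> tuple[str, str]:
        return (self.taxon_a, self.taxon_b)

    def unordered_key(self) -> frozenset:
        return frozenset((self.taxon_a, self.taxon_b))


@dataclass
class PairwiseTable:
    """An ordered collection of :class:`DivergencePair` over a species list."""

    species: list[str]
    rows: list[DivergencePair]
    mode: TableMode = TableMode.FULL

    def __post_init__(self) -> None:
        self.species = [normalize_name(s) for s in self.species]
        if len(set(self.species)) != len(self.species):
            raise DivergenceDataError("duplicate species in table species list")
        self.mode = TableMode(self.mode)
        seen: set[tuple[str, str]] = set()
        for row in self.rows:
            if row.key() in seen:
                raise DivergenceDataError(
                    f"duplicate (taxon_a, taxon_b) key {row.key()} in table"
                )
            seen.add(row.key())

    def __len__(self) -> int:
        return len(self.rows)

    def lookup(self, a: str, b: str) -> Optional[DivergencePair]:
        """Return the row for (a, b) in either ordering, or None."""
        a, b = normalize_name(a), normalize_name(b)
        for row in self.rows:
            if row.key() in ((a, b), (b, a)):
                return row
        return None

    def replace_time(self, a: str, b: str, pair: DivergencePair) -> None:
        """Replace the stored record(s) for an unordered pair in place."""
        a, b = normalize_name(a), normalize_name(b)
        for i, row in enumerate(self.rows):
            if row.key() == (a, b):
                self.rows[i] = pair
            elif row.key() == (b, a):
                self.rows[i] = replace(pair, taxon_a=b, taxon_b=a)


@dataclass
class DivergenceMatrix:
    """Square symmetric matrix of divergence times (MY), zero diagonal."""

    labels: list[str]
    values: np.ndarray
    _sym_tol: float = field(default=1e-8, repr=False)

    def __post_init__(self) -> None:
        self.labels = [normalize_name(s) for s in self.labels]
        if len(set(self.labels)) != len(self.labels):
            raise DivergenceDataError("matrix labels must be unique")
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise DivergenceDataError(
                f"matrix shape {v.shape} does not match {n} labels"
            )
        if np.any(v < 0):
            raise DivergenceDataError("divergence times must be nonnegative")
        if not np.allclose(v, v.T, atol=self._sym_tol, rtol=0):
            raise DivergenceDataError("matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise DivergenceDataError("matrix diagonal must be exactly zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = (normalize_name(x) for x in pair)
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def read_species_list(path) -> list[str]:
    """Read a plain-text species list, one binomial per line.

    Blank lines are skipped; duplicates are dropped with a warning, keeping
    the first occurrence. Raises on an unreadable file or an empty list.
    """
    text = Path(path).read_text(encoding="utf-8")
    names: list[str] = []
    seen: set[str] = set()
    for line in text.splitlines():
        if not line.strip():
            continue
        name = normalize_name(line)
        if name in seen:
            warnings.warn(
                f"duplicate species {name!r} in {path}; keeping first occurrence",
                stacklevel=2,
            )
            continue
        seen.add(name)
        names.append(name)
    if not names:
        raise DivergenceDataError(f"no usable species names in {path}")
    return names


def _unordered_pairs(species: Sequence[str]) -> list[tuple[str, str]]:
    return [
        (species[i], species[j])
        for i in range(len(species))
        for j in range(i + 1, len(species))
    ]


def table_to_matrix(
    table: PairwiseTable, tol: float = DEFAULT_CONFLICT_TOL
) -> DivergenceMatrix:
    """Convert a vectorized pairwise table to a square symmetric matrix.

    Every unordered pair of the table's species must carry a non-missing
    time. When a FULL table supplies both orderings of a pair they must
    agree within ``tol`` MY; the value from the ordering whose first taxon
    appears earlier in the species list is stored.
    """
    species = table.species
    index = {s: i for i, s in enumerate(species)}
    by_key: dict[tuple[str, str], DivergencePair] = {}
    for row in table.rows:
        if row.taxon_a in index and row.taxon_b in index:
            by_key[row.key()] = row

    missing = find_missing(table)
    if missing:
        raise DivergenceDataError(
            "cannot build matrix; missing pairs: "
            + ", ".join(f"({a}, {b})" for a, b in missing)
        )

    n = len(species)
    values = np.zeros((n, n), dtype=float)
    for a, b in _unordered_pairs(species):
        fwd = by_key.get((a, b))
        rev = by_key.get((b, a))
        if fwd is not None and rev is not None:
            if abs(fwd.time_mya - rev.time_mya) > tol:
                raise DivergenceDataError(
                    f"conflicting times for pair ({a}, {b}): "
                    f"{fwd.time_mya} vs {rev.time_mya} (tol {tol})"
                )
        t = (fwd or rev).time_mya
        values[index[a], index[b]] = values[index[b], index[a]] = t
    return DivergenceMatrix(labels=list(species), values=values)


def matrix_to_table(matrix: DivergenceMatrix, mode: TableMode) -> PairwiseTable:
    """Flatten a square matrix back to the vectorized three-column form.

    FULL emits all n**2 ordered pairs in row-major label order, self-pairs
    at time 0; UNORDERED emits the n(n-1)/2 distinct pairs with ``taxon_a``
    preceding ``taxon_b`` in label order.
    """
    mode = TableMode(mode)
    labels = matrix.labels
    rows: list[DivergencePair] = []
    if mode is TableMode.FULL:
        for a in labels:
            for b in labels:
                rows.append(DivergencePair(a, b, matrix[a, b]))
    else:
        for a, b in _unordered_pairs(labels):
            rows.append(DivergencePair(a, b, matrix[a, b]))
    return PairwiseTable(species=list(labels), rows=rows, mode=mode)


def find_missing(table: PairwiseTable) -> list[tuple[str, str]]:
    """List unordered pairs with unknown divergence times.

    A pair is missing when a row carries a missing time, or when the pair
    is absent from the table altogether (in either ordering). An empty
    result means the table can be converted to a complete matrix.
    """
    present: set[frozenset] = set()
    blanked: set[frozenset] = set()
    in_list = set(table.species)
    for row in table.rows:
        if row.is_self_pair or not (row.taxon_a in in_list and row.taxon_b in in_list):
            continue
        key = row.unordered_key()
        if row.is_missing:
            blanked.add(key)
        else:
            present.add(key)
    out: list[tuple[str, str]] = []
    for a, b in _unordered_pairs(table.species):
        key = frozenset((a, b))
        if key in blanked or key not in (present | blanked):
            out.append((a, b))
    return out


_MANDATORY_COLUMNS = ("Taxa 1", "Taxa 2", "Divergence time")
_OPTIONAL_COLUMNS = ("CI_low", "CI_high", "Studies")

# Strings accepted as "no value" on read; the table diagonal prints "n. a".
_NA_STRINGS = {"", "na", "n.a", "n. a", "n.a.", "nan"}


def _is_na(cell) -> bool:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return True
    return str(cell).strip().lower() in _NA_STRINGS


def write_table_csv(table: PairwiseTable, path) -> Path:
    """Write a table as CSV; missing values become empty fields.

    Optional columns are emitted only when some row carries them.
    """
    has_ci = any(r.ci_low_mya is not None or r.ci_high_mya is not None for r in table.rows)
    has_studies = any(r.n_studies is not None for r in table.rows)
    records = []
    for r in table.rows:
        rec = {
            "Taxa 1": r.taxon_a,
            "Taxa 2": r.taxon_b,
            "Divergence time": "" if r.time_mya is None else r.time_mya,
        }
        if has_ci:
            rec["CI_low"] = "" if r.ci_low_mya is None else r.ci_low_mya
            rec["CI_high"] = "" if r.ci_high_mya is None else r.ci_high_mya
        if has_studies:
            rec["Studies"] = "" if r.n_studies is None else r.n_studies
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)
    return Path(path)


def read_table_csv(path) -> PairwiseTable:
    """Read a vectorized pairwise table from CSV.

    Requires the header columns "Taxa 1", "Taxa 2", "Divergence time";
    "CI_low", "CI_high" and "Studies" are optional. Empty fields and the
    strings "NA" / "n. a" are missing values — except a self-pair's time,
    which maps to 0.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _MANDATORY_COLUMNS:
        if col not in df.columns:
            raise DivergenceDataError(f"CSV {path} lacks mandatory column {col!r}")
    rows: list[DivergencePair] = []
    species: list[str] = []
    seen: set[str] = set()
    for i, rec in enumerate(df.to_dict("records")):
        a = normalize_name(rec["Taxa 1"])
        b = normalize_name(rec["Taxa 2"])
        for s in (a, b):
            if s not in seen:
                seen.add(s)
                species.append(s)

        def parse_number(col: str, cast=float):
            if col not in rec or _is_na(rec[col]):
                return None
            try:
                return cast(str(rec[col]).replace("MYA", "").strip())
            except ValueError as exc:
                raise DivergenceDataError(
                    f"row {i + 2} of {path}: cannot parse {col!r} value "
                    f"{rec[col]!r}"
                ) from exc

        time = parse_number("Divergence time")
        if time is None and a == b:
            time = 0.0
        rows.append(
            DivergencePair(
                a,
                b,
                time,
                ci_low_mya=parse_number("CI_low"),
                ci_high_mya=parse_number("CI_high"),
                n_studies=parse_number("Studies", cast=lambda x: int(float(x))),
            )
        )
    n = len(species)
    mode = TableMode.FULL if len(rows) == n * n else TableMode.UNORDERED
    return PairwiseTable(species=species, rows=rows, mode=mode)
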