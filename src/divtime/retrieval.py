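"""Backend contract for divergence-time, timeline and time-tree retrieval.

The durable part of a retrieval layer is its contract, not its transport.
:class:`Backend` defines the four operations every data source must
provide — availability checks, pairwise divergence lookup, timeline
images and Newick time trees. :class:`FixtureBackend` implements the
contract over the packaged example records and synthetic genus trees, so
the whole toolkit is exercisable offline; a live web client would be a
second implementation of the same contract (see ``LiveBackend`` below for
the documented stub).

Unresolved queries are value-level outcomes: a pair involving an unknown
species comes back with a missing time plus a :class:`SubstitutionRecord`,
never an exception, so batch runs always complete and can be validated
and repaired afterwards.
"""

from __future__ import annotations

import abc
import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from . import fixture_factory as ff
from .divergence_data import (
    DivergencePair,
    PairwiseTable,
    TableMode,
    find_missing,
    normalize_name,
    table_to_matrix,
)
from .timetrees import TimeTree, divergence_from_tree, tree_from_matrix, write_newick

__all__ = [
    "AvailabilityRecord",
    "SubstitutionRecord",
    "RetrievalError",
    "Backend",
    "FixtureBackend",
    "check_availability_list",
    "batch_divergence",
    "repair_missing",
]

AVAILABLE = "Available"
NOT_AVAILABLE = "Not Available"


class RetrievalError(RuntimeError):
    """Transport or query failure, distinct from a 'Not Available' answer."""


@dataclass(frozen=True)
class AvailabilityRecord:
    species: str
    available: bool

    @property
    def label(self) -> str:
        return AVAILABLE if self.available else NOT_AVAILABLE


@dataclass(frozen=True)
class SubstitutionRecord:
    """A species that could not be resolved, or was silently renamed."""

    requested: str
    resolved: Optional[str]
    note: str = ""

    def __post_init__(self) -> None:
        if self.resolved is not None and self.resolved == self.requested:
            raise ValueError("a substitution must change the name")


class Backend(abc.ABC):
    """Contract all retrieval backends implement.

    Invariants: divergence lookup is symmetric in its arguments, and a
    self-query on a known species has time 0.
    """

    #: identifier string, e.g. "fixture" or "live"
    name: str = "abstract"

    @abc.abstractmethod
    def check_availability(self, species: str) -> AvailabilityRecord:
        """True iff the backend holds any record mentioning the species."""

    @abc.abstractmethod
    def get_divergence(
        self, a: str, b: str
    ) -> tuple[DivergencePair, list[SubstitutionRecord]]:
        """Divergence record for a pair; unresolved pairs carry a missing
        time and one SubstitutionRecord per unknown species."""

    @abc.abstractmethod
    def get_timetree(
        self, query: Union[str, Sequence[str]]
    ) -> tuple[str, list[SubstitutionRecord]]:
        """Newick text (branch lengths in MY) for a taxon or species list."""

    @abc.abstractmethod
    def get_timeline(self, species: str, out) -> Path:
        """Write a JPEG evolutionary-timeline image; return its path."""


class FixtureBackend(Backend):
    """Offline backend over the packaged records and synthetic genus trees.

    Holds the four-species example table (keyed by both scientific and
    common names), the 35-MYA thrush × fairywren pair, and one synthetic
    ultrametric tree per packaged genus; within-genus divergences are read
    off the tree, so tree and pairwise answers agree by construction.
    """

    name = "fixture"

    def __init__(self) -> None:
        self._aliases = {
            normalize_name(k): normalize_name(v)
            for k, v in ff.COMMON_NAMES.items()
        }
        self._pairs: dict[frozenset, DivergencePair] = {}
        for row in ff.table1_fixture().rows:
            if not row.is_self_pair:
                self._pairs[row.unordered_key()] = row
        usage = ff.usage_pair_fixture()
        self._pairs[usage.unordered_key()] = usage

        self._trees = {
            "Catharus": ff.packaged_tree("Catharus"),
            "Malurus": ff.packaged_tree("Malurus"),
        }
        self._tree_matrices = {
            genus: divergence_from_tree(tree)
            for genus, tree in self._trees.items()
        }
        self._species: set[str] = set()
        for key in self._pairs:
            self._species |= set(key)
        for tree in self._trees.values():
            self._species |= set(tree.tip_labels)

    # -- resolution ------------------------------------------------------
    def _resolve(self, species: str) -> Optional[str]:
        name = normalize_name(species)
        name = self._aliases.get(name, name)
        return name if name in self._species else None

    def check_availability(self, species: str) -> AvailabilityRecord:
        return AvailabilityRecord(
            species=normalize_name(species),
            available=self._resolve(species) is not None,
        )

    # -- divergence ------------------------------------------------------
    def get_divergence(
        self, a: str, b: str
    ) -> tuple[DivergencePair, list[SubstitutionRecord]]:
        a_raw, b_raw = normalize_name(a), normalize_name(b)
        ra, rb = self._resolve(a_raw), self._resolve(b_raw)
        subs = [
            SubstitutionRecord(requested=req, resolved=None, note="not in database")
            for req, res in ((a_raw, ra), (b_raw, rb))
            if res is None
        ]
        if subs:
            return DivergencePair(a_raw, b_raw, None), subs
        if ra == rb:
            return DivergencePair(a_raw, b_raw, 0.0), []
        rec = self._pairs.get(frozenset((ra, rb)))
        if rec is None:
            for genus, matrix in self._tree_matrices.items():
                if ra in matrix.labels and rb in matrix.labels:
                    return DivergencePair(a_raw, b_raw, matrix[ra, rb]), []
            return (
                DivergencePair(a_raw, b_raw, None),
                [
                    SubstitutionRecord(
                        requested=f"{a_raw} x {b_raw}",
                        resolved=None,
                        note="no shared record for this pair",
                    )
                ],
            )
        # reorient the stored record to the requested argument order
        pair = DivergencePair(
            a_raw, b_raw, rec.time_mya, rec.ci_low_mya, rec.ci_high_mya,
            rec.n_studies,
        )
        return pair, []

    # -- trees -----------------------------------------------------------
    def get_timetree(
        self, query: Union[str, Sequence[str]]
    ) -> tuple[str, list[SubstitutionRecord]]:
        if isinstance(query, str):
            genus = normalize_name(query)
            if genus in self._trees:
                return write_newick(self._trees[genus]), []
            raise RetrievalError(f"no time tree available for taxon {genus!r}")
        species = [normalize_name(s) for s in query]
        subs: list[SubstitutionRecord] = []
        resolved: list[str] = []
        for s in species:
            r = self._resolve(s)
            if r is None:
                subs.append(
                    SubstitutionRecord(requested=s, resolved=None, note="dropped")
                )
            else:
                resolved.append(s)
        if len(resolved) < 2:
            raise RetrievalError(
                "need at least 2 resolvable species for a time tree"
            )
        table, pair_subs = batch_divergence(
            self, resolved, mode=TableMode.UNORDERED
        )
        while find_missing(table):
            # drop the species involved in the most unresolved pairs
            missing = find_missing(table)
            counts: dict[str, int] = {}
            for x, y in missing:
                counts[x] = counts.get(x, 0) + 1
                counts[y] = counts.get(y, 0) + 1
            worst = max(sorted(counts), key=counts.get)
            resolved = [s for s in resolved if s != worst]
            subs.append(
                SubstitutionRecord(
                    requested=worst, resolved=None,
                    note="dropped: unresolved pairwise times",
                )
            )
            if len(resolved) < 2:
                raise RetrievalError(
                    "fewer than 2 species with complete pairwise times"
                )
            table, _ = batch_divergence(self, resolved, mode=TableMode.UNORDERED)
        tree = tree_from_matrix(table_to_matrix(table))
        return write_newick(tree), subs + pair_subs

    # -- timelines -------------------------------------------------------
    def get_timeline(self, species: str, out) -> Path:
        record = self.check_availability(species)
        if not record.available:
            raise RetrievalError(f"species {record.species!r} is not available")
        return _placeholder_timeline_jpeg(record.species, out)


def _placeholder_timeline_jpeg(species: str, out) -> Path:
    """Generate a schematic timeline JPEG embedding the species name.

    The fixture stand-in for a retrieved timeline figure: era bands on the
    left, the species name on top. Purely synthetic artwork.
    """
    from PIL import Image, ImageDraw

    img = Image.new("RGB", (480, 320), "white")
    draw = ImageDraw.Draw(img)
    eras = [("Paleozoic", 100), ("Mesozoic", 200), ("Cenozoic", 300)]
    palette = ["#c8d8e8", "#d8e8c8", "#e8d8c8"]
    top = 40
    for (era, y), color in zip(eras, palette):
        draw.rectangle([20, top, 120, y + 20], fill=color, outline="black")
        draw.text((28, (top + y + 20) // 2 - 6), era, fill="black")
        top = y + 20
    draw.text((20, 10), f"Evolutionary timeline: {species}", fill="black")
    draw.line([160, 40, 160, 300], fill="black", width=2)
    out = Path(out)
    img.save(out, format="JPEG")
    return out


class LiveBackend(Backend):
    """Documented contract for a live web-resource client (not implemented).

    A production client would drive the public divergence-time website or
    its HTTP API behind this same contract, with polite defaults: at least
    1 s between requests, 3 retries with exponential backoff, and a
    descriptive User-Agent. It is transport-fragile by nature and is
    deliberately not exercised by the test suite; every operation raises
    until a transport is plugged in.
    """

    name = "live"

    #: polite-client defaults a transport implementation must honour
    MIN_REQUEST_INTERVAL_S = 1.0
    MAX_RETRIES = 3

    def _unavailable(self):
        raise RetrievalError(
            "the live backend has no transport in this build; "
            "use the fixture backend"
        )

    def check_availability(self, species):
        self._unavailable()

    def get_divergence(self, a, b):
        self._unavailable()

    def get_timetree(self, query):
        self._unavailable()

    def get_timeline(self, species, out):
        self._unavailable()


# ---------------------------------------------------------------------------
# Batch helpers (backend-agnostic)
# ---------------------------------------------------------------------------

def check_availability_list(
    backend: Backend, species: Sequence[str], out=None
) -> list[AvailabilityRecord]:
    """Check a species list; optionally write a Species/Availability CSV."""
    if not species:
        raise RetrievalError("empty species list")
    records = [backend.check_availability(s) for s in species]
    if out is not None:
        with open(out, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["Species", "Availability"])
            for rec in records:
                writer.writerow([rec.species, rec.label])
    return records


def batch_divergence(
    backend: Backend,
    species: Sequence[str],
    mode: TableMode = TableMode.FULL,
) -> tuple[PairwiseTable, list[SubstitutionRecord]]:
    """Query every pair of a species list in deterministic order.

    FULL mode queries all ordered pairs including self-pairs (taxon_a is
    the outer loop); UNORDERED queries each distinct pair once. Unresolved
    pairs appear with a missing time; substitution records are collected,
    deduplicated, in first-encounter order.
    """
    names = [normalize_name(s) for s in species]
    if len(names) < 2:
        raise RetrievalError("batch retrieval needs at least 2 species")
    if all(not backend.check_availability(s).available for s in names):
        raise RetrievalError("none of the requested species is available")
    mode = TableMode(mode)
    rows: list[DivergencePair] = []
    subs: list[SubstitutionRecord] = []
    seen_subs: set[tuple] = set()

    def query(a: str, b: str) -> None:
        pair, pair_subs = backend.get_divergence(a, b)
        rows.append(pair)
        for s in pair_subs:
            key = (s.requested, s.resolved)
            if key not in seen_subs:
                seen_subs.add(key)
                subs.append(s)

    if mode is TableMode.FULL:
        for a in names:
            for b in names:
                query(a, b)
    else:
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                query(a, b)
    return PairwiseTable(species=names, rows=rows, mode=mode), subs


def repair_missing(
    backend: Backend, table: PairwiseTable
) -> tuple[PairwiseTable, list[tuple[str, str]]]:
    """Re-query every missing pair of a table and fill what resolves.

    Returns the repaired table and the list of pairs still missing (e.g.
    pairs involving species the backend does not know). The input table is
    not modified; no non-missing value is ever overwritten.
    """
    missing = find_missing(table)
    repaired = PairwiseTable(
        species=list(table.species), rows=list(table.rows), mode=table.mode
    )
    if not missing:
        return repaired, []
    still_missing: list[tuple[str, str]] = []
    for a, b in missing:
        pair, subs = backend.get_divergence(a, b)
        if pair.is_missing:
            still_missing.append((a, b))
            continue
        if repaired.lookup(a, b) is None:
            repaired.rows.append(pair)
        else:
            repaired.replace_time(a, b, pair)
    return repaired, still_missing
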