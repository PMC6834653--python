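"""shRNA screen library: the barcode ↔ hairpin ↔ gene mapping.

Every stage of a pooled-screen analysis is keyed on the library: each short
hairpin RNA (shRNA) clone carries a fixed-length clonal DNA barcode that is
read out by sequencing, and each shRNA targets one gene.  This module holds
the in-memory model (:class:`ScreenLibrary`), the TSV reader/writer, and a
generator of random synthetic libraries with a guaranteed minimum pairwise
Hamming distance between barcodes (which makes single-mismatch rescue during
counting provably unambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LibraryError",
    "ShrnaRecord",
    "ScreenLibrary",
    "hamming",
    "read_library",
    "write_library",
    "make_random_library",
]

LIBRARY_COLUMNS = ("shrna_id", "gene", "barcode")
_BASES = "ACGT"
_BASE_SET = frozenset(_BASES)


class LibraryError(ValueError):
    """A library (or library file) violates a structural invariant."""


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming distance needs equal lengths ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class ShrnaRecord:
    """One hairpin: an opaque unique id, its target gene, and its barcode."""

    shrna_id: str
    gene: str
    barcode: str


@dataclass
class ScreenLibrary:
    """An ordered collection of :class:`ShrnaRecord` with unique barcodes.

    Parameters
    ----------
    records
        Ordered hairpin records; order is preserved through file round trips
        and defines the row order of every count matrix downstream.
    barcode_length
        Declared barcode length; every record's barcode must match it.
    min_pairwise_hamming
        Design property of the barcode set.  It is *recorded*, not verified,
        at construction (verifying is quadratic); call
        :meth:`min_pairwise_distance` to check it explicitly.  Libraries read
        from vendor TSVs typically carry 0 here.
    """

    records: list[ShrnaRecord]
    barcode_length: int
    min_pairwise_hamming: int = 0
    _barcode_to_id: dict[str, str] = field(init=False, repr=False, default_factory=dict)
    _gene_of: dict[str, str] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.records = list(self.records)
        if self.records and self.barcode_length < 8:
            raise LibraryError(f"barcode_length must be >= 8, got {self.barcode_length}")
        if self.min_pairwise_hamming < 0:
            raise LibraryError("min_pairwise_hamming must be >= 0")
        seen_ids: dict[str, int] = {}
        for i, rec in enumerate(self.records):
            if rec.shrna_id in seen_ids:
                raise LibraryError(
                    f"duplicate shrna_id {rec.shrna_id!r} (records {seen_ids[rec.shrna_id]} and {i})"
                )
            seen_ids[rec.shrna_id] = i
            if len(rec.barcode) != self.barcode_length:
                raise LibraryError(
                    f"record {i} ({rec.shrna_id}): barcode length {len(rec.barcode)} != {self.barcode_length}"
                )
            if not _BASE_SET.issuperset(rec.barcode):
                raise LibraryError(
                    f"record {i} ({rec.shrna_id}): barcode contains non-ACGT characters"
                )
            if rec.barcode in self._barcode_to_id:
                raise LibraryError(
                    f"duplicate barcode {rec.barcode!r} shared by "
                    f"{self._barcode_to_id[rec.barcode]} and {rec.shrna_id}"
                )
            self._barcode_to_id[rec.barcode] = rec.shrna_id
            self._gene_of[rec.shrna_id] = rec.gene

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScreenLibrary):
            return NotImplemented
        return (
            self.records == other.records
            and self.barcode_length == other.barcode_length
        )

    @property
    def shrna_ids(self) -> list[str]:
        return [r.shrna_id for r in self.records]

    @property
    def genes(self) -> list[str]:
        """Unique gene symbols in first-appearance order."""
        return list(dict.fromkeys(r.gene for r in self.records))

    @property
    def barcode_to_id(self) -> dict[str, str]:
        return self._barcode_to_id

    @property
    def gene_of(self) -> dict[str, str]:
        return self._gene_of

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "shrna_id": [r.shrna_id for r in self.records],
                "gene": [r.gene for r in self.records],
                "barcode": [r.barcode for r in self.records],
            }
        )

    def min_pairwise_distance(self) -> int:
        """Exact minimum pairwise Hamming distance (brute force, O(n^2 L)).

        Feasible up to a few thousand barcodes; use for validation of the
        declared ``min_pairwise_hamming``, not in hot paths.
        """
        if len(self.records) < 2:
            return self.barcode_length
        arr = _encode([r.barcode for r in self.records])
        best = self.barcode_length
        for i in range(len(arr) - 1):
            d = int((arr[i + 1 :] != arr[i]).sum(axis=1).min())
            if d < best:
                best = d
                if best == 0:
                    break
        return best


def _encode(barcodes: Sequence[str]) -> np.ndarray:
    """Barcodes as a (n, L) uint8 matrix of ASCII codes."""
    joined = "".join(barcodes).encode("ascii")
    return np.frombuffer(joined, dtype=np.uint8).reshape(len(barcodes), -1)


def read_library(path: str | Path) -> ScreenLibrary:
    """Read a library TSV (columns ``shrna_id``, ``gene``, ``barcode``).

    Errors name the offending data rows (1-based, excluding the header) so a
    malformed vendor file can be fixed by hand.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise LibraryError(f"{path}: missing required column(s) {sorted(missing)}")
    if len(df) == 0:
        return ScreenLibrary(records=[], barcode_length=0)

    for col in ("shrna_id", "barcode"):
        dup = df[col].duplicated(keep=False)
        if dup.any():
            val = df.loc[dup, col].iloc[0]
            rows = [int(i) + 1 for i in df.index[df[col] == val]]
            raise LibraryError(f"{path}: duplicate {col} {val!r} in rows {rows}")
    bad = ~df["barcode"].map(lambda b: bool(b) and _BASE_SET.issuperset(b))
    if bad.any():
        row = int(df.index[bad][0]) + 1
        raise LibraryError(f"{path}: non-ACGT barcode in row {row}")
    lengths = df["barcode"].str.len()
    if lengths.nunique() > 1:
        row = int(df.index[lengths != lengths.iloc[0]][0]) + 1
        raise LibraryError(
            f"{path}: ragged barcode lengths (row {row} differs from row 1)"
        )
    records = [
        ShrnaRecord(r.shrna_id, r.gene, r.barcode)
        for r in df.itertuples(index=False)
    ]
    return ScreenLibrary(records=records, barcode_length=int(lengths.iloc[0]))


def write_library(lib: ScreenLibrary, path: str | Path) -> None:
    """Write a library TSV (UTF-8, LF endings); inverse of :func:`read_library`."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(LIBRARY_COLUMNS) + "\n")
        for rec in lib.records:
            fh.write(f"{rec.shrna_id}\t{rec.gene}\t{rec.barcode}\n")


def _segment_bounds(length: int, n_segments: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, length, n_segments + 1).astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_segments)]


def make_random_library(
    n_genes: int,
    shrnas_per_gene: tuple[int, int] = (5, 6),
    barcode_length: int = 18,
    min_hamming: int = 3,
    seed: int = 0,
    max_attempts: int = 1000,
) -> ScreenLibrary:
    """Generate a random synthetic library.

    Per-gene hairpin counts are drawn uniformly from the inclusive
    ``shrnas_per_gene`` range (5-6 hairpins per gene is typical of pooled
    Cellecta-style libraries).  Barcodes are uniform random ACGT strings
    accepted by rejection so that every pair differs at >= ``min_hamming``
    positions.  The rejection test uses a pigeonhole index: two barcodes at
    distance < m must agree exactly on at least one of m contiguous
    segments, so only barcodes sharing a segment are ever compared —
    this keeps generation of ~30k-barcode libraries fast.

    Deterministic for a fixed seed (byte-identical TSV output).
    """
    lo, hi = shrnas_per_gene
    if not (1 <= lo <= hi):
        raise LibraryError(f"invalid shrnas_per_gene range {shrnas_per_gene}")
    if n_genes < 1:
        raise LibraryError("n_genes must be >= 1")
    if min_hamming < 0:
        raise LibraryError("min_hamming must be >= 0")
    if min_hamming > barcode_length:
        raise LibraryError("min_hamming cannot exceed barcode_length")
    rng = np.random.default_rng(seed)
    per_gene = rng.integers(lo, hi + 1, size=n_genes)
    total = int(per_gene.sum())
    if 4**barcode_length < 10 * total:
        raise LibraryError(
            f"barcode space 4^{barcode_length} too small for {total} barcodes"
        )

    m = max(min_hamming, 1)  # m=1 degenerates to a plain uniqueness check
    bounds = _segment_bounds(barcode_length, m)
    segment_index: list[dict[str, list[int]]] = [dict() for _ in range(m)]
    barcodes: list[str] = []

    for _ in range(total):
        for _attempt in range(max_attempts):
            cand = "".join(_BASES[i] for i in rng.integers(0, 4, size=barcode_length))
            candidates: set[int] = set()
            for seg, (a, b) in zip(segment_index, bounds):
                candidates.update(seg.get(cand[a:b], ()))
            if all(hamming(cand, barcodes[j]) >= m for j in candidates):
                idx = len(barcodes)
                barcodes.append(cand)
                for seg, (a, b) in zip(segment_index, bounds):
                    seg.setdefault(cand[a:b], []).append(idx)
                break
        else:
            raise LibraryError(
                f"could not place barcode {len(barcodes) + 1}/{total} at Hamming "
                f">= {min_hamming} after {max_attempts} attempts"
            )

    records: list[ShrnaRecord] = []
    k = 0
    for g in range(n_genes):
        gene = f"G{g + 1:06d}"
        for j in range(int(per_gene[g])):
            records.append(ShrnaRecord(f"{gene}_sh{j + 1}", gene, barcodes[k]))
            k += 1
    return ScreenLibrary(
        records=records,
        barcode_length=barcode_length,
        min_pairwise_hamming=min_hamming,
    )
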