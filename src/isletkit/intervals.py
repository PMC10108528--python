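"""Genomic interval data model, BED/narrowPeak I/O, and set algebra.

All coordinates are BED-convention: 0-based, half-open ``[start, end)``.
Every operation consumes and returns canonical :class:`RegionSet` objects
(sorted by ``(chrom, start, end)``, exact coordinate duplicates collapsed),
so overlap and membership questions have set semantics throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "RegionParseError",
    "read_regions",
    "write_regions",
    "intersect_any",
    "merge_regions",
    "intersection_regions",
    "subtract_regions",
    "coverage_bp",
]


class RegionParseError(ValueError):
    """Raised for malformed BED/narrowPeak records; names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)


class RegionSet:
    """Canonical, ordered collection of :class:`GenomicInterval` with metadata.

    ``meta`` carries sample-level labels used by the pipeline: ``cell_type``,
    ``replicate``, ``track_kind`` (one of ``atac``, ``chip_tf``, ``histone``,
    ``enhancer_catalog``, ``fragments``, ``other``) and a free-form ``label``.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        meta: Mapping[str, object] | None = None,
    ) -> None:
        self.meta: dict[str, object] = dict(meta or {})
        self.intervals: list[GenomicInterval] = self._canonicalize(intervals)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] | None = None

    @staticmethod
    def _canonicalize(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
        # Sort by (chrom, start, end) with full-record tie-breaks, then collapse
        # exact duplicates (identical records; set semantics).
        ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.name, iv.strand, iv.score))
        out: list[GenomicInterval] = []
        for iv in ordered:
            if not out or iv != out[-1]:
                out.append(iv)
        return out

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        label = self.meta.get("label", "")
        return f"RegionSet(n={len(self)}{', ' + str(label) if label else ''})"

    # -- indexed access ------------------------------------------------------
    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, list[int]]]:
        """chrom -> (starts, ends, original indices), arrays sorted by start."""
        if self._by_chrom is None:
            table: dict[str, tuple[list, list, list]] = {}
            for i, iv in enumerate(self.intervals):
                table.setdefault(iv.chrom, ([], [], []))
                s, e, idx = table[iv.chrom]
                s.append(iv.start)
                e.append(iv.end)
                idx.append(i)
            self._by_chrom = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64), idx)
                for c, (s, e, idx) in table.items()
            }
        return self._by_chrom

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )

    def with_meta(self, **meta) -> "RegionSet":
        out = RegionSet.__new__(RegionSet)
        out.intervals = self.intervals
        out.meta = {**self.meta, **meta}
        out._by_chrom = self._by_chrom
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def _infer_format(path: Path) -> str:
    return "narrowpeak" if path.suffix.lower() == ".narrowpeak" else "bed6"


def read_regions(path: str | Path, format: str = "auto", meta: Mapping[str, object] | None = None) -> RegionSet:
    """Read a BED6 or narrowPeak file into a canonical :class:`RegionSet`.

    narrowPeak column 7 (signalValue) is mapped to ``score``. Coordinates are
    taken verbatim (already 0-based half-open in both formats). Malformed
    lines raise :class:`RegionParseError` naming the 1-based line number.
    """
    path = Path(path)
    if format == "auto":
        format = _infer_format(path)
    if format not in ("bed6", "narrowpeak"):
        raise ValueError(f"unknown region format: {format!r}")
    min_cols = 10 if format == "narrowpeak" else 3

    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise RegionParseError(
                    f"{path}, line {lineno}: expected >= {min_cols} tab-separated columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise RegionParseError(f"{path}, line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise RegionParseError(f"{path}, line {lineno}: invalid interval [{start}, {end})")
            name = cols[3] if len(cols) > 3 and cols[3] != "." else ""
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            if format == "narrowpeak":
                try:
                    score = float(cols[6])
                except ValueError as exc:
                    raise RegionParseError(f"{path}, line {lineno}: bad signalValue") from exc
            else:
                try:
                    score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
                except ValueError as exc:
                    raise RegionParseError(f"{path}, line {lineno}: bad score") from exc
            intervals.append(GenomicInterval(cols[0], start, end, name, score, strand))
    return RegionSet(intervals, meta=meta)


def write_regions(rs: RegionSet, path: str | Path, format: str = "bed6") -> Path:
    """Write a canonical RegionSet as BED6 or narrowPeak (tab-separated, no header).

    Scores are written with 6 significant digits; read(write(rs)) is the
    identity for sets whose scores carry at most that precision.
    """
    if format not in ("bed6", "narrowpeak"):
        raise ValueError(f"unknown region format: {format!r}")
    path = Path(path)
    with open(path, "w") as fh:
        for iv in rs:
            name = iv.name or "."
            if format == "bed6":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{iv.score:.6g}\t{iv.strand}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}"
                    f"\t{iv.score:.6g}\t-1\t-1\t-1\n"
                )
    return path


# ---------------------------------------------------------------------------
# Set algebra
# ---------------------------------------------------------------------------

def overlap_mask(a: RegionSet, b: RegionSet, min_overlap_bp: int = 1) -> np.ndarray:
    """Boolean mask over a's intervals: has >= min_overlap_bp overlap with b."""
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    mask = np.zeros(len(a), dtype=bool)
    b_index = b.by_chrom()
    for chrom, (sa, ea, idx) in a.by_chrom().items():
        if chrom not in b_index:
            continue
        sb, eb, _ = b_index[chrom]
        # chunked all-pairs overlap; fine at pipeline scales (<= tens of thousands)
        for lo in range(0, len(sa), 512):
            hi = min(lo + 512, len(sa))
            ov = np.minimum(ea[lo:hi, None], eb[None, :]) - np.maximum(sa[lo:hi, None], sb[None, :])
            hit = (ov >= min_overlap_bp).any(axis=1)
            for j, h in enumerate(hit):
                if h:
                    mask[idx[lo + j]] = True
    return mask


def intersect_any(a: RegionSet, b: RegionSet, min_overlap_bp: int = 1) -> RegionSet:
    """Subset of a's intervals overlapping >= 1 interval of b by >= min_overlap_bp.

    Intervals of ``a`` are returned whole (membership, not clipped geometry):
    downstream consumers (enhancer filtering, consensus membership) need
    whole-region answers.
    """
    mask = overlap_mask(a, b, min_overlap_bp)
    return RegionSet([iv for iv, keep in zip(a.intervals, mask) if keep], meta=a.meta)


def merge_regions(rs: RegionSet, max_gap: int = 0) -> RegionSet:
    """Merge intervals whose gap is <= max_gap into minimal covering intervals.

    Idempotent; preserves base-level coverage exactly for max_gap=0.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged: list[GenomicInterval] = []
    cur = None
    for iv in rs:
        if cur is not None and iv.chrom == cur.chrom and iv.start - cur.end <= max_gap:
            if iv.end > cur.end:
                cur = replace(cur, end=iv.end)
        else:
            if cur is not None:
                merged.append(cur)
            cur = GenomicInterval(iv.chrom, iv.start, iv.end)
        # canonical order guarantees starts are non-decreasing per chrom
    if cur is not None:
        merged.append(cur)
    return RegionSet(merged, meta=rs.meta)


def _disjoint_arrays(rs: RegionSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    m = merge_regions(rs)
    return {c: (s, e) for c, (s, e, _) in m.by_chrom().items()}


def intersection_regions(a: RegionSet, b: RegionSet) -> RegionSet:
    """Base-level intersection geometry of the merged inputs (clipped pieces)."""
    out: list[GenomicInterval] = []
    da, db = _disjoint_arrays(a), _disjoint_arrays(b)
    for chrom in da:
        if chrom not in db:
            continue
        sa, ea = da[chrom]
        sb, eb = db[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            s = max(sa[i], sb[j])
            e = min(ea[i], eb[j])
            if s < e:
                out.append(GenomicInterval(chrom, int(s), int(e)))
            if ea[i] <= eb[j]:
                i += 1
            else:
                j += 1
    return RegionSet(out)


def subtract_regions(a: RegionSet, b: RegionSet) -> RegionSet:
    """Base-level difference: bases of (merged) a not covered by b."""
    out: list[GenomicInterval] = []
    da, db = _disjoint_arrays(a), _disjoint_arrays(b)
    for chrom, (sa, ea) in da.items():
        if chrom not in db:
            out.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(sa, ea))
            continue
        sb, eb = db[chrom]
        for s, e in zip(sa, ea):
            cursor = s
            j = int(np.searchsorted(eb, cursor, side="right"))
            while j < len(sb) and sb[j] < e:
                if sb[j] > cursor:
                    out.append(GenomicInterval(chrom, int(cursor), int(sb[j])))
                cursor = max(cursor, eb[j])
                j += 1
            if cursor < e:
                out.append(GenomicInterval(chrom, int(cursor), int(e)))
    return RegionSet(out)


def coverage_bp(rs: RegionSet) -> int:
    """Total bases covered (after merging)."""
    return sum(iv.length for iv in merge_regions(rs))


def read_fragment_table(path: str | Path) -> pd.DataFrame:
    """Fast loader for per-sample fragment BEDs (columns chrom/start/end only).

    Fragments are counted with multiplicity, so they bypass the RegionSet
    canonicalization; midpoints are precomputed for counting operations.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64}, comment="#",
    )
    df["mid"] = (df["start"] + df["end"]) // 2
    return df


def as_point_arrays(obj) -> tuple[np.ndarray, np.ndarray]:
    """(chroms, midpoints) from a RegionSet or a fragment DataFrame."""
    if isinstance(obj, pd.DataFrame):
        mids = obj["mid"].to_numpy() if "mid" in obj else ((obj["start"] + obj["end"]) // 2).to_numpy()
        return obj["chrom"].to_numpy(), mids.astype(np.int64)
    chroms = np.asarray([iv.chrom for iv in obj])
    mids = np.asarray([iv.midpoint for iv in obj], dtype=np.int64)
    return chroms, mids


def points_in_regions(chroms: np.ndarray, positions: np.ndarray, rs: RegionSet) -> np.ndarray:
    """Boolean mask: is position i (on chroms[i]) inside any (merged) region of rs.

    Membership is half-open: a point p is inside [start, end) iff start <= p < end.
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    mask = np.zeros(len(positions), dtype=bool)
    disjoint = _disjoint_arrays(rs)
    for chrom, (s, e) in disjoint.items():
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        pos = positions[sel]
        k = np.searchsorted(s, pos, side="right") - 1
        ok = k >= 0
        ok[ok] &= pos[ok] < e[k[ok]]
        mask[sel] = ok
    return mask
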