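"""Genomic interval data model, BED/narrowPeak I/O, and overlap set algebra.

All coordinates are 0-based half-open (BED convention). narrowPeak summit
offsets are converted to absolute genomic positions on ingestion; a summit
offset of ``-1`` means "no summit".

Chromosome names are compared by exact string equality; callers that need
``chr1``/``1`` reconciliation can pass an alias map to :func:`read_peaks`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

CLONES = ("control", "WT", "Y537S", "K303R")
ASSAYS = ("ATAC", "ChIP")
FLAGS = ("plus", "minus")

#: the four (dox, e2) treatment conditions, in canonical order
CONDITIONS = (
    ("minus", "minus"),
    ("minus", "plus"),
    ("plus", "minus"),
    ("plus", "plus"),
)


class PeakFileError(ValueError):
    """Raised when a peak file cannot be parsed."""


class IntervalError(ValueError):
    """Raised when interval invariants are violated."""


def _flag_symbol(flag: str) -> str:
    return "+" if flag == "plus" else "-"


@dataclass(frozen=True, order=True)
class SampleKey:
    """Coordinate of one peak set: (clone, dox, e2, assay)."""

    clone: str
    dox: str
    e2: str
    assay: str

    def __post_init__(self) -> None:
        if self.clone not in CLONES:
            raise ValueError(f"unknown clone {self.clone!r}; expected one of {CLONES}")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        for field_name in ("dox", "e2"):
            value = getattr(self, field_name)
            if value not in FLAGS:
                raise ValueError(f"{field_name} must be 'plus' or 'minus', got {value!r}")

    @property
    def condition(self) -> tuple[str, str]:
        return (self.dox, self.e2)

    def label(self) -> str:
        return (
            f"{self.clone}_{self.assay}"
            f"_Dox{_flag_symbol(self.dox)}_E2{_flag_symbol(self.e2)}"
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label()


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional score and summit."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float | None = None
    summit: int | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise IntervalError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise IntervalError(
                f"summit {self.summit} outside [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class PeakSet:
    """An ordered, validated collection of :class:`GenomicInterval`.

    Intervals are sorted by (chrom, start, end) on construction. Intervals
    with identical coordinates are deduplicated with a warning; duplicate
    names on distinct coordinates are an error.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        sample: SampleKey | None = None,
    ) -> None:
        ivs = sorted(intervals, key=GenomicInterval.sort_key)
        deduped: list[GenomicInterval] = []
        seen_coords: set[tuple[str, int, int]] = set()
        n_dup = 0
        for iv in ivs:
            key = iv.sort_key()
            if key in seen_coords:
                n_dup += 1
                continue
            seen_coords.add(key)
            deduped.append(iv)
        if n_dup:
            warnings.warn(
                f"dropped {n_dup} interval(s) with duplicate coordinates",
                stacklevel=2,
            )
        names = [iv.name for iv in deduped if iv.name]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise IntervalError(f"duplicate interval names: {dupes[:5]}")
        self.intervals: tuple[GenomicInterval, ...] = tuple(deduped)
        self.sample = sample
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def chroms(self) -> list[str]:
        out: list[str] = []
        for iv in self.intervals:
            if not out or out[-1] != iv.chrom:
                out.append(iv.chrom)
        return out

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, each sorted by start."""
        if self._by_chrom is None:
            index: dict[str, tuple[list[int], list[int]]] = {}
            for iv in self.intervals:
                starts, ends = index.setdefault(iv.chrom, ([], []))
                starts.append(iv.start)
                ends.append(iv.end)
            self._by_chrom = {
                chrom: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                for chrom, (s, e) in index.items()
            }
        return self._by_chrom


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_peaks(
    path: str | Path,
    sample: SampleKey | None = None,
    format: str = "narrowPeak",
    chrom_aliases: Mapping[str, str] | None = None,
) -> PeakSet:
    """Read a BED6 or ENCODE narrowPeak file into a :class:`PeakSet`.

    Parameters
    ----------
    path
        Peak file path. Empty files yield an empty PeakSet.
    sample
        Optional :class:`SampleKey` to attach.
    format
        ``"bed6"`` (>= 3 columns) or ``"narrowPeak"`` (exactly 10 columns).
    chrom_aliases
        Optional chromosome-name rewrite map applied on ingestion.
    """
    if format not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                iv = _parse_row(fields, format, lineno)
            except IntervalError as exc:
                raise PeakFileError(f"{path}:{lineno}: {exc}") from exc
            if chrom_aliases and iv.chrom in chrom_aliases:
                iv = replace(iv, chrom=chrom_aliases[iv.chrom])
            if not iv.name:
                iv = replace(iv, name=f"peak_{lineno}")
            intervals.append(iv)
    return PeakSet(intervals, sample=sample)


def _parse_row(fields: Sequence[str], format: str, lineno: int) -> GenomicInterval:
    if format == "narrowPeak" and len(fields) != 10:
        raise PeakFileError(
            f"line {lineno}: narrowPeak requires 10 columns, got {len(fields)}"
        )
    if format == "bed6" and len(fields) < 3:
        raise PeakFileError(f"line {lineno}: BED requires >= 3 columns, got {len(fields)}")
    try:
        chrom = fields[0]
        start = int(fields[1])
        end = int(fields[2])
    except ValueError as exc:
        raise PeakFileError(f"line {lineno}: non-integer coordinates") from exc
    name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
    score: float | None = None
    if len(fields) > 4 and fields[4] != ".":
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise PeakFileError(f"line {lineno}: bad score {fields[4]!r}") from exc
    summit: int | None = None
    if format == "narrowPeak":
        try:
            offset = int(fields[9])
        except ValueError as exc:
            raise PeakFileError(f"line {lineno}: bad summit offset {fields[9]!r}") from exc
        if offset >= 0:
            summit = start + offset
    return GenomicInterval(chrom, start, end, name=name, score=score, summit=summit)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED6 (tab-separated, strand always ``.``)."""
    with open(path, "w") as handle:
        for iv in peaks:
            score = "0" if iv.score is None else str(float(iv.score))
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t.\n")


def write_narrowpeak(peaks: PeakSet, path: str | Path, signal: float = 5.0) -> None:
    """Write a PeakSet as 10-column ENCODE narrowPeak."""
    with open(path, "w") as handle:
        for iv in peaks:
            score = 0 if iv.score is None else int(round(iv.score))
            offset = -1 if iv.summit is None else iv.summit - iv.start
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t."
                f"\t{signal}\t-1\t-1\t{offset}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` TSV."""
    sizes: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise PeakFileError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as handle:
        for chrom, length in sizes.items():
            handle.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# Set algebra
# ---------------------------------------------------------------------------

def overlaps_any(
    query: PeakSet | Sequence[GenomicInterval],
    reference: PeakSet,
    min_bp: int = 1,
    min_frac: float | None = None,
) -> np.ndarray:
    """Flag, per query interval, whether any reference interval overlaps it.

    An overlap counts when the shared span is at least ``min_bp`` bases
    (half-open coordinates: book-ended intervals never overlap). When
    ``min_frac`` is given, the shared span must additionally cover at least
    that fraction of the *shorter* of the two intervals.

    Query order is preserved; an empty reference yields all-False.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    query_ivs = list(query)
    flags = np.zeros(len(query_ivs), dtype=bool)

    ref_index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray | None]] = {}
    for chrom, (starts, ends) in reference.by_chrom().items():
        if min_frac is None:
            keep = (ends - starts) >= min_bp
            s, e = starts[keep], ends[keep]
            prefix_max_end = np.maximum.accumulate(e) if len(e) else e
            ref_index[chrom] = (s, e, prefix_max_end)
        else:
            ref_index[chrom] = (starts, ends, None)

    for i, iv in enumerate(query_ivs):
        entry = ref_index.get(iv.chrom)
        if entry is None:
            continue
        starts, ends, prefix_max_end = entry
        if prefix_max_end is not None:
            # overlap >= min_bp  <=>  both widths >= min_bp, ref.start <= q.end - min_bp
            # and ref.end >= q.start + min_bp (prefix max over the start-sorted refs).
            if iv.width < min_bp or not len(starts):
                continue
            count = int(np.searchsorted(starts, iv.end - min_bp, side="right"))
            if count and prefix_max_end[count - 1] >= iv.start + min_bp:
                flags[i] = True
        else:
            shared = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
            shorter = np.minimum(ends - starts, iv.width)
            hit = (shared >= min_bp) & (shared >= min_frac * shorter)
            flags[i] = bool(np.any(hit))
    return flags


def merge_union(
    sets: Sequence[PeakSet],
    gap: int = 0,
    name_prefix: str = "region",
) -> PeakSet:
    """Merge one or more peak sets into the minimal set of maximal intervals.

    Intervals that overlap, or whose gap is at most ``gap`` bases
    (book-ended intervals merge at the default ``gap=0``), are fused.
    """
    if not sets:
        raise ValueError("merge_union requires at least one PeakSet")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    all_ivs = sorted(
        (iv for ps in sets for iv in ps), key=GenomicInterval.sort_key
    )
    merged: list[tuple[str, int, int]] = []
    for iv in all_ivs:
        if merged and merged[-1][0] == iv.chrom and iv.start <= merged[-1][2] + gap:
            chrom, start, end = merged[-1]
            merged[-1] = (chrom, start, max(end, iv.end))
        else:
            merged.append((iv.chrom, iv.start, iv.end))
    width = max(6, len(str(len(merged))))
    return PeakSet(
        GenomicInterval(c, s, e, name=f"{name_prefix}_{i:0{width}d}")
        for i, (c, s, e) in enumerate(merged, start=1)
    )


def summit_windows(
    peaks: PeakSet,
    flank: int,
    chrom_sizes: Mapping[str, int],
    midpoint_fallback: bool = True,
) -> PeakSet:
    """Replace each peak by a ``[summit - flank, summit + flank)`` window.

    Windows are clipped to ``[0, chrom length)``. Peaks without a summit use
    their midpoint when ``midpoint_fallback`` is enabled, otherwise error.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    out: list[GenomicInterval] = []
    for iv in peaks:
        if iv.chrom not in chrom_sizes:
            raise KeyError(f"chromosome {iv.chrom!r} missing from chrom_sizes")
        if iv.summit is not None:
            anchor = iv.summit
        elif midpoint_fallback:
            anchor = iv.midpoint
        else:
            raise IntervalError(f"interval {iv.name!r} has no summit")
        start = max(0, anchor - flank)
        end = min(chrom_sizes[iv.chrom], anchor + flank)
        if start >= end:
            continue
        summit = anchor if start <= anchor < end else None
        out.append(
            GenomicInterval(iv.chrom, start, end, name=iv.name, score=iv.score, summit=summit)
        )
    return PeakSet(out, sample=peaks.sample)
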