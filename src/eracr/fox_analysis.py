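"""Fox-motif co-occurrence statistics on ER-alpha ChIP peaks.

Covers four measurements: the fraction of ChIP peaks carrying a Fox motif,
the fraction of those without any ERE, the per-direction sharing between two
clones' Fox-positive peak sets, and chromatin-opening rates (ATAC overlap)
stratified by clone partition and ERE label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .intervals import GenomicInterval, PeakSet, overlaps_any


@dataclass
class StratumRate:
    """An opening rate with its numerator/denominator; rate None if empty."""

    n_open: int
    n_total: int

    @property
    def rate(self) -> float | None:
        return None if self.n_total == 0 else self.n_open / self.n_total


@dataclass
class FoxPeakReport:
    clone: str
    n_chip: int
    n_fox: int
    fox_fraction: float
    ere_free_fraction: float | None = None
    shared_fraction: float | None = None
    opening: dict[str, StratumRate] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "clone": self.clone,
            "n_chip": self.n_chip,
            "n_fox": self.n_fox,
            "fox_fraction": self.fox_fraction,
            "ere_free_fraction": self.ere_free_fraction,
            "shared_fraction": self.shared_fraction,
            "opening": {
                stratum: {"n_open": s.n_open, "n_total": s.n_total, "rate": s.rate}
                for stratum, s in self.opening.items()
            },
        }


def fox_chip_fraction(chip: PeakSet, fox_hits: Sequence[bool]) -> float:
    """Fraction of ChIP peaks carrying the Fox motif."""
    if len(chip) == 0:
        raise ValueError("fox fraction undefined on an empty ChIP peak set")
    if len(fox_hits) != len(chip):
        raise ValueError(
            f"flag vector length {len(fox_hits)} != peak count {len(chip)}"
        )
    return sum(bool(f) for f in fox_hits) / len(chip)


def ere_free_fraction(ere_labels: Sequence[str]) -> float:
    """Fraction of (Fox-positive) peaks whose ERE label is ``none``."""
    labels = list(ere_labels)
    if not labels:
        raise ValueError("ERE-free fraction undefined on an empty peak set")
    bad = sorted({l for l in labels if l not in ("none", "half", "full")})
    if bad:
        raise ValueError(f"unknown ERE labels: {bad}")
    return sum(l == "none" for l in labels) / len(labels)


def shared_fraction(
    fox_a: PeakSet,
    fox_b: PeakSet,
    min_bp: int = 1,
) -> tuple[float, float]:
    """Per-direction sharing between two Fox-positive peak sets.

    Returns (fraction of A peaks overlapping any B peak, fraction of B peaks
    overlapping any A peak). Empty inputs yield 0.0 on that side.
    """
    frac_a = (
        float(overlaps_any(fox_a, fox_b, min_bp=min_bp).mean()) if len(fox_a) else 0.0
    )
    frac_b = (
        float(overlaps_any(fox_b, fox_a, min_bp=min_bp).mean()) if len(fox_b) else 0.0
    )
    return frac_a, frac_b


def opening_rate(
    fox_peaks: Sequence[GenomicInterval],
    strata: Sequence[str],
    atac: PeakSet,
    min_bp: int = 1,
) -> dict[str, StratumRate]:
    """Per-stratum fraction of Fox-positive peaks overlapping an ATAC peak.

    ``strata`` assigns each peak a label (e.g. "common/full",
    "WT_specific/none"). Empty strata never appear; a stratum's rate is
    ``None`` only if constructed externally with zero peaks.
    """
    peaks = list(fox_peaks)
    if len(strata) != len(peaks):
        raise ValueError("strata labels must align with peaks")
    open_flags = overlaps_any(peaks, atac, min_bp=min_bp)  # preserves query order
    rates: dict[str, StratumRate] = {}
    for flag, stratum in zip(open_flags, strata):
        entry = rates.setdefault(stratum, StratumRate(0, 0))
        entry.n_total += 1
        entry.n_open += int(flag)
    return rates


def build_fox_report(
    clone: str,
    chip: PeakSet,
    fox_flags: Sequence[bool],
    ere_labels_fox: Sequence[str] | None = None,
    shared: float | None = None,
    opening: Mapping[str, StratumRate] | None = None,
) -> FoxPeakReport:
    n_fox = sum(bool(f) for f in fox_flags)
    report = FoxPeakReport(
        clone=clone,
        n_chip=len(chip),
        n_fox=n_fox,
        fox_fraction=fox_chip_fraction(chip, fox_flags),
    )
    if ere_labels_fox is not None:
        report.ere_free_fraction = ere_free_fraction(ere_labels_fox)
    report.shared_fraction = shared
    if opening is not None:
        report.opening = dict(opening)
    return report


def write_fox_reports(reports: Sequence[FoxPeakReport], path: str | Path) -> None:
    payload = {r.clone: r.to_dict() for r in reports}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
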