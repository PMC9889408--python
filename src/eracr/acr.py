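"""ER-alpha-bound active chromatin regions (ChIP peaks gated by ATAC overlap).

An ACR region keeps the ChIP peak's coordinates: ChIP defines "bound", the
ATAC overlap only gates "active". Cross-clone identity is overlap-based
because clones have independent peak calls; synthetic fixtures use identical
coordinates, for which overlap identity is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet, overlaps_any

ERA_CLONES = ("WT", "Y537S", "K303R")

CLONE_PARTITIONS = (
    "common",
    "WT_specific",
    "Y537S_specific",
    "K303R_specific",
    "shared_subset",
)


class EmptyRegionSetError(ValueError):
    """A rate was requested over an empty region set."""


@dataclass
class ACRRegion:
    """One ER-alpha ACR: a ChIP peak overlapping >= 1 ATAC peak."""

    interval: GenomicInterval
    clone: str
    condition: tuple[str, str] | None = None
    condition_group: str | None = None
    clone_partition: str | None = None


def define_acr(
    chip: PeakSet,
    atac: PeakSet,
    min_bp: int = 1,
) -> list[ACRRegion]:
    """Select the ChIP peaks with >= ``min_bp`` bases of ATAC overlap.

    Both peak sets must come from the same clone and condition when their
    SampleKeys are attached; swapped assays are rejected.
    """
    for peak_set, expected in ((chip, "ChIP"), (atac, "ATAC")):
        if peak_set.sample is not None and peak_set.sample.assay != expected:
            raise ValueError(
                f"expected a {expected} peak set, got assay "
                f"{peak_set.sample.assay!r} ({peak_set.sample.label()})"
            )
    if (
        chip.sample is not None
        and atac.sample is not None
        and (chip.sample.clone, chip.sample.condition)
        != (atac.sample.clone, atac.sample.condition)
    ):
        raise ValueError(
            f"clone/condition mismatch: {chip.sample.label()} vs {atac.sample.label()}"
        )
    clone = chip.sample.clone if chip.sample is not None else ""
    condition = chip.sample.condition if chip.sample is not None else None
    flags = overlaps_any(chip, atac, min_bp=min_bp)
    return [
        ACRRegion(interval=iv, clone=clone, condition=condition)
        for iv, flag in zip(chip, flags)
        if flag
    ]


def _acr_peakset(regions: Sequence[ACRRegion]) -> PeakSet:
    # names may collide across clones; identity here is coordinate-based
    return PeakSet(
        GenomicInterval(r.interval.chrom, r.interval.start, r.interval.end,
                        name=f"acr_{i}")
        for i, r in enumerate(regions)
    )


def partition_clone_specificity(
    acr_by_clone: Mapping[str, Sequence[ACRRegion]],
    min_bp: int = 1,
) -> dict[str, list[str]]:
    """Label every ACR region of every clone by cross-clone sharing.

    ``common``: overlaps ACR of both other clones; ``<clone>_specific``:
    overlaps neither; ``shared_subset``: overlaps exactly one other clone
    (reported explicitly so totals stay auditable). All three ER-alpha
    clones must be present. Labels are also written onto the regions.
    """
    missing = [c for c in ERA_CLONES if c not in acr_by_clone]
    if missing:
        raise ValueError(f"missing clone(s) for partition: {missing}")
    peaksets = {clone: _acr_peakset(acr_by_clone[clone]) for clone in ERA_CLONES}
    labels: dict[str, list[str]] = {}
    for clone in ERA_CLONES:
        regions = acr_by_clone[clone]
        others = [c for c in ERA_CLONES if c != clone]
        query = [r.interval for r in regions]  # preserves caller's order
        hit_counts = np.zeros(len(regions), dtype=int)
        for other in others:
            hit_counts += overlaps_any(
                query, peaksets[other], min_bp=min_bp
            ).astype(int)
        clone_labels = []
        for region, n_hits in zip(regions, hit_counts):
            if n_hits == 2:
                label = "common"
            elif n_hits == 0:
                label = f"{clone}_specific"
            else:
                label = "shared_subset"
            region.clone_partition = label
            clone_labels.append(label)
        labels[clone] = clone_labels
    return labels


def motif_rate(motif_flags: Sequence[bool]) -> float:
    """Fraction of regions with >= 1 hit of the motif."""
    flags = list(motif_flags)
    if not flags:
        raise EmptyRegionSetError("motif rate undefined on an empty region set")
    return sum(bool(f) for f in flags) / len(flags)


def select_variable_motifs(
    rates: pd.DataFrame,
    ratio_min: float = 3.0,
    rate_min: float = 0.15,
    largest_group_size: int | None = None,
) -> list[str]:
    """Motifs whose rates vary strongly across clones/conditions.

    ``rates`` is a motif x cell table of fractions (rows: motif ids). A motif
    is selected when max(rate) >= ``rate_min`` and
    max(rate) / max(min(rate), eps) >= ``ratio_min``, with
    eps = 1 / largest_group_size guarding zero minima.
    """
    if rates.isna().any().any():
        raise ValueError("rate table must be complete (no NaN cells)")
    if largest_group_size is None:
        largest_group_size = 10_000
    eps = 1.0 / largest_group_size
    selected = []
    for motif_id, row in rates.iterrows():
        max_rate = float(row.max())
        min_rate = float(row.min())
        if max_rate >= rate_min and max_rate / max(min_rate, eps) >= ratio_min:
            selected.append(str(motif_id))
    return selected


def select_high_enrichment_motifs(results, p_max: float = 1e-20) -> list[str]:
    """Motifs with p <= ``p_max`` in any clone x condition cell.

    The printed filter "-log(p) <= 1e-20" reads literally as p near 1; it is
    interpreted here as p <= p_max (equivalently -log10 p >= 20). Pass
    ``p_max`` > 0.5 style values to apply the literal reading instead.
    """
    selected = sorted({r.motif_id for r in results if r.p_value <= p_max})
    return selected


def acr_table(acr_by_clone: Mapping[str, Sequence[ACRRegion]]) -> pd.DataFrame:
    rows = []
    for clone, regions in acr_by_clone.items():
        for r in regions:
            rows.append(
                {
                    "clone": clone,
                    "chrom": r.interval.chrom,
                    "start": r.interval.start,
                    "end": r.interval.end,
                    "name": r.interval.name,
                    "dox": r.condition[0] if r.condition else "",
                    "e2": r.condition[1] if r.condition else "",
                    "condition_group": r.condition_group or "",
                    "clone_partition": r.clone_partition or "",
                }
            )
    return pd.DataFrame(rows)
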