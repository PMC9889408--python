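"""Classification of consensus regions by their Dox x E2 presence pattern.

Within one clone and one assay, a consensus region is scored for presence in
each of the four treatment conditions. Two classifications are derived:

* condition-specific: present in exactly one condition;
* ER-alpha-dependent groups: present only under Dox(+), split into
  E2-minus-only, E2-plus-only, and E2-independent (both Dox(+) conditions).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .intervals import CONDITIONS, GenomicInterval, PeakSet, overlaps_any

Condition = tuple[str, str]  # (dox, e2), each "plus" / "minus"

CONDITION_SPECIFIC_LABELS = {
    ("minus", "minus"): "nontreated_specific",
    ("minus", "plus"): "E2_specific",
    ("plus", "minus"): "Dox_specific",
    ("plus", "plus"): "DoxE2_specific",
}

ERA_GROUP_LABELS = ("E2minus_ERa", "E2plus_ERa", "E2ind_ERa")
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class PresencePattern:
    """Presence of one consensus region across the four conditions."""

    region: GenomicInterval
    present: Mapping[Condition, bool]

    def __post_init__(self) -> None:
        if set(self.present) != set(CONDITIONS):
            missing = sorted(set(CONDITIONS) - set(self.present))
            raise ValueError(f"pattern must cover all 4 conditions; missing {missing}")


class MissingConditionError(ValueError):
    """A required (dox, e2) condition peak set was not supplied."""


def build_presence(
    consensus: PeakSet,
    per_condition: Mapping[Condition, PeakSet],
    min_bp: int = 1,
) -> list[PresencePattern]:
    """Score each consensus region for overlap-based presence per condition."""
    missing = [c for c in CONDITIONS if c not in per_condition]
    if missing:
        raise MissingConditionError(
            "missing condition peak set(s): "
            + ", ".join(f"Dox({d}) E2({e})" for d, e in missing)
        )
    flags = {
        cond: overlaps_any(consensus, per_condition[cond], min_bp=min_bp)
        for cond in CONDITIONS
    }
    return [
        PresencePattern(
            region=iv, present={cond: bool(flags[cond][i]) for cond in CONDITIONS}
        )
        for i, iv in enumerate(consensus)
    ]


def classify_condition_specific(pattern: PresencePattern) -> str:
    """Label a region present in exactly one condition; else ``unclassified``."""
    present = [cond for cond in CONDITIONS if pattern.present[cond]]
    if len(present) == 1:
        return CONDITION_SPECIFIC_LABELS[present[0]]
    return UNCLASSIFIED


def classify_era_groups(pattern: PresencePattern) -> str:
    """Label ER-alpha-dependent regions (Dox(+)-only presence patterns).

    ``E2minus_ERa``: present only under Dox(+)/E2(-);
    ``E2plus_ERa``: present only under Dox(+)/E2(+);
    ``E2ind_ERa``: present under both Dox(+) conditions and neither Dox(-)
    condition. Anything present under Dox(-) is ``unclassified``.
    """
    if pattern.present[("minus", "minus")] or pattern.present[("minus", "plus")]:
        return UNCLASSIFIED
    dox_e2minus = pattern.present[("plus", "minus")]
    dox_e2plus = pattern.present[("plus", "plus")]
    if dox_e2minus and dox_e2plus:
        return "E2ind_ERa"
    if dox_e2minus:
        return "E2minus_ERa"
    if dox_e2plus:
        return "E2plus_ERa"
    return UNCLASSIFIED


def write_group_table(
    patterns: Sequence[PresencePattern],
    path: str | Path,
    extra: Mapping[str, str] | None = None,
) -> None:
    """TSV report: region coordinates, 4 presence flags, both labels."""
    extra = extra or {}
    header = ["chrom", "start", "end", "name"]
    header += [f"dox_{d}_e2_{e}" for d, e in CONDITIONS]
    header += ["condition_specific", "era_group"]
    header += list(extra)
    with open(path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for pat in patterns:
            iv = pat.region
            row = [iv.chrom, str(iv.start), str(iv.end), iv.name]
            row += [str(int(pat.present[c])) for c in CONDITIONS]
            row += [classify_condition_specific(pat), classify_era_groups(pat)]
            row += [extra[k] for k in extra]
            handle.write("\t".join(row) + "\n")
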