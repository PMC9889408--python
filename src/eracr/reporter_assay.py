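"""Dual-luciferase fold-change normalization.

Each well's firefly signal is normalized by its own Renilla signal; condition
means of the per-well ratios are then expressed relative to the reference
condition's mean ratio.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

Condition = tuple[str, str]  # (ERalpha construct, E2 status)


@dataclass(frozen=True)
class LuciferaseWell:
    firefly: float
    renilla: float
    condition: Condition
    replicate: int

    def __post_init__(self) -> None:
        if self.firefly < 0:
            raise ValueError("firefly signal must be >= 0")
        if self.renilla <= 0:
            raise ValueError("renilla signal must be > 0")

    @property
    def ratio(self) -> float:
        return self.firefly / self.renilla


def read_wells(path: str | Path) -> list[LuciferaseWell]:
    """CSV columns: construct, e2, replicate, firefly, renilla."""
    wells = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle):
            wells.append(
                LuciferaseWell(
                    firefly=float(row["firefly"]),
                    renilla=float(row["renilla"]),
                    condition=(row["construct"], row["e2"]),
                    replicate=int(row["replicate"]),
                )
            )
    return wells


def fold_change(
    wells: Sequence[LuciferaseWell],
    reference_condition: Condition,
) -> dict[Condition, dict]:
    """Per-condition fold increase relative to the reference condition.

    Returns, per condition, the mean fold, plus per-replicate folds (each
    well's ratio over the reference mean ratio).
    """
    by_condition: dict[Condition, list[LuciferaseWell]] = {}
    for well in wells:
        by_condition.setdefault(well.condition, []).append(well)
    if reference_condition not in by_condition:
        raise ValueError(f"reference condition {reference_condition} has no wells")
    reference_mean = sum(w.ratio for w in by_condition[reference_condition]) / len(
        by_condition[reference_condition]
    )
    if reference_mean == 0:
        raise ValueError("reference condition has zero mean ratio")
    out: dict[Condition, dict] = {}
    for condition, group in by_condition.items():
        ratios = [w.ratio for w in group]
        out[condition] = {
            "fold": (sum(ratios) / len(ratios)) / reference_mean,
            "replicate_folds": {
                w.replicate: w.ratio / reference_mean for w in group
            },
            "n": len(group),
        }
    return out


def write_fold_table(folds: dict[Condition, dict], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("construct\te2\tn\tfold\n")
        for (construct, e2), entry in sorted(folds.items()):
            handle.write(f"{construct}\t{e2}\t{entry['n']}\t{entry['fold']:.6g}\n")
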