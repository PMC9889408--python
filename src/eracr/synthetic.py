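"""Seeded synthetic genomes, motif-planted peak landscapes, and ground truth.

The default ``fig4c`` scenario plants, as Bernoulli ground truth, the rate
structure that the analysis modules are meant to recover: per-clone Fox-motif
fractions on ChIP peaks, ERE-free fractions among Fox-positive peaks,
WT/K303R sharing, per-stratum chromatin-opening rates, and per-condition ERE
half/full-site rates in the tri-clone common ACR pool.

Every planted region sits in its own non-overlapping locus, and locus
backgrounds are rejection-sampled to contain no spurious hit of any bundled
motif at the configured scan threshold, so motif presence recovered by
scanning equals the planted flags exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .intervals import (
    CONDITIONS,
    GenomicInterval,
    PeakSet,
    SampleKey,
    write_chrom_sizes,
    write_narrowpeak,
)
from .motif import PWM, _window_scores, bundled_motifs, classify_ere_many, encode, reverse_complement

ERA_CLONES = ("WT", "Y537S", "K303R")
_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

DOX_PLUS_CONDITIONS = (("plus", "minus"), ("plus", "plus"))


class CapacityError(ValueError):
    """The genome is too small for the requested regions."""


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic landscape; defaults give ``fig4c``."""

    seed: int = 11
    n_chroms: int = 5
    chrom_length: int = 1_200_000
    gc_fraction: float = 0.41
    region_width: int = 200
    region_gap: int = 100
    n_chip: int = 4000
    n_common_acr: int = 1500  # per E2 condition
    n_background: int = 800
    fox_fraction: dict[str, float] = field(
        default_factory=lambda: {"WT": 0.165, "Y537S": 0.165, "K303R": 0.185}
    )
    ere_free_fraction: dict[str, float] = field(
        default_factory=lambda: {"WT": 0.636, "Y537S": 0.65, "K303R": 0.681}
    )
    fox_full_ere_fraction: float = 0.4  # among ERE-carrying Fox peaks
    shared_fraction: float = 0.80  # WT vs K303R Fox-positive peaks
    opening: dict[str, float] = field(
        default_factory=lambda: {
            "WT_specific": 0.085,
            "K303R_specific": 0.452,
            "Y537S_specific": 0.20,
            "common_WT": 0.20,
            "common_K303R": 0.40,
        }
    )
    nonfox_opening: float = 0.30
    ere_half_rate: dict[str, float] = field(
        default_factory=lambda: {"minus": 0.11, "plus": 0.25}
    )
    ere_full_rate: dict[str, float] = field(
        default_factory=lambda: {"minus": 0.05, "plus": 0.15}
    )
    threshold_fraction: float = 0.8
    spacer: int = 3
    fox_motif: str = "FOX_LIKE"
    ere_half_motif: str = "ERE_HALF"

    def __post_init__(self) -> None:
        for name, rate in self.iter_rates():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rate {name} out of [0, 1]: {rate}")

    def iter_rates(self):
        yield "gc_fraction", self.gc_fraction
        for clone, r in self.fox_fraction.items():
            yield f"fox_fraction[{clone}]", r
        for clone, r in self.ere_free_fraction.items():
            yield f"ere_free_fraction[{clone}]", r
        yield "fox_full_ere_fraction", self.fox_full_ere_fraction
        yield "shared_fraction", self.shared_fraction
        for stratum, r in self.opening.items():
            yield f"opening[{stratum}]", r
        yield "nonfox_opening", self.nonfox_opening
        for e2, r in self.ere_half_rate.items():
            yield f"ere_half_rate[{e2}]", r
        for e2, r in self.ere_full_rate.items():
            yield f"ere_full_rate[{e2}]", r

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class LocusSpec:
    """Internal bookkeeping for one planted locus."""

    name: str
    role: str  # fox | nonfox | common_acr | background
    fox_clones: tuple[str, ...] = ()
    chip_clones: tuple[str, ...] = ()
    partition: str = ""
    ere: str = "none"
    e2: str = ""  # for common_acr pool
    open_in: dict[str, bool] = field(default_factory=dict)
    chrom: str = ""
    start: int = 0
    end: int = 0
    motifs: list[dict] = field(default_factory=list)
    sequence: np.ndarray | None = None

    def chip_conditions(self, clone: str) -> tuple[tuple[str, str], ...]:
        if clone not in self.chip_clones:
            return ()
        if self.role == "common_acr":
            return (("plus", self.e2),)
        return DOX_PLUS_CONDITIONS

    def atac_conditions(self, clone: str) -> tuple[tuple[str, str], ...]:
        if self.role == "background":
            return CONDITIONS
        if self.role == "common_acr":
            return (("plus", self.e2),)
        if self.open_in.get(clone, False):
            return DOX_PLUS_CONDITIONS
        return ()


@dataclass
class TruthManifest:
    config: dict
    regions: list[dict]
    expected: dict
    genome_fasta: str = ""
    chrom_sizes: str = ""
    peak_files: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Sequence machinery
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_bases(rng: np.random.Generator, shape, gc: float) -> np.ndarray:
    return rng.choice(4, size=shape, p=_base_probs(gc)).astype(np.uint8)


def decode(encoded: np.ndarray) -> str:
    return _BASES[encoded].tobytes().decode("ascii")


def _any_hit(encoded: np.ndarray, pwms: Sequence[PWM], threshold_fraction: float) -> np.ndarray:
    """Per-row flag: any window on either strand hits any of the motifs."""
    hit = np.zeros(encoded.shape[0], dtype=bool)
    for pwm in pwms:
        thr = threshold_fraction * pwm.max_score - 1e-9
        for spwm in (pwm, pwm.reverse_complement()):
            scores = _window_scores(encoded, spwm)
            if scores.shape[1]:
                hit |= (scores >= thr).any(axis=1)
    return hit


def clean_backgrounds(
    rng: np.random.Generator,
    n: int,
    length: int,
    gc: float,
    pwms: Sequence[PWM],
    threshold_fraction: float,
    max_rounds: int = 200,
) -> np.ndarray:
    """n motif-free background sequences, rejection-sampled in batches."""
    out = np.empty((n, length), dtype=np.uint8)
    remaining = np.arange(n)
    for _ in range(max_rounds):
        if not len(remaining):
            return out
        batch = _random_bases(rng, (len(remaining), length), gc)
        bad = _any_hit(batch, pwms, threshold_fraction)
        out[remaining[~bad]] = batch[~bad]
        remaining = remaining[bad]
    raise RuntimeError("could not draw motif-free backgrounds; motif set too dense")


def _full_site_insert(rng: np.random.Generator, half_consensus: str, spacer: int, gc: float) -> str:
    spacer_bases = decode(_random_bases(rng, spacer, gc)) if spacer else ""
    return half_consensus + spacer_bases + reverse_complement(half_consensus)


def _plan_inserts(
    rng: np.random.Generator,
    spec: LocusSpec,
    pwms: Mapping[str, PWM],
    config: ScenarioConfig,
) -> list[tuple[str, str, str]]:
    """(motif_id, strand, insert sequence) for each motif to plant."""
    inserts: list[tuple[str, str, str]] = []
    if spec.role == "fox":
        strand = "+" if rng.random() < 0.5 else "-"
        consensus = pwms[config.fox_motif].consensus
        seq = consensus if strand == "+" else reverse_complement(consensus)
        inserts.append((config.fox_motif, strand, seq))
    if spec.ere == "half":
        strand = "+" if rng.random() < 0.5 else "-"
        consensus = pwms[config.ere_half_motif].consensus
        seq = consensus if strand == "+" else reverse_complement(consensus)
        inserts.append((config.ere_half_motif, strand, seq))
    elif spec.ere == "full":
        consensus = pwms[config.ere_half_motif].consensus
        seq = _full_site_insert(rng, consensus, config.spacer, config.gc_fraction)
        inserts.append(("ERE_FULL", "+", seq))
    return inserts


def _plant(
    rng: np.random.Generator,
    background: np.ndarray,
    inserts: Sequence[tuple[str, str, str]],
    margin: int = 5,
) -> list[dict]:
    """Write inserts into one encoded sequence at non-overlapping offsets."""
    length = len(background)
    records: list[dict] = []
    if len(inserts) == 1:
        ranges = [(margin, length - margin)]
    else:
        mid = length // 2
        ranges = [(margin, mid - 2), (mid + 2, length - margin)]
        if rng.random() < 0.5:
            ranges.reverse()
    for (motif_id, strand, seq), (lo, hi) in zip(inserts, ranges):
        offset = int(rng.integers(lo, hi - len(seq) + 1))
        background[offset : offset + len(seq)] = encode(seq)
        records.append({"motif_id": motif_id, "offset": offset, "strand": strand, "sequence": seq})
    return records


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------

def _exact_flags(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Boolean vector with exactly round(p * n) True entries, order randomized.

    Exact-count assignment keeps the planted rates identifiable at small
    stratum sizes; the randomness is in *which* loci carry the property.
    """
    flags = np.zeros(n, dtype=bool)
    flags[: int(round(p * n))] = True
    rng.shuffle(flags)
    return flags


def _exact_ere_labels(
    rng: np.random.Generator, n: int, p_none: float, p_full_given_ere: float
) -> list[str]:
    n_ere = n - int(round(p_none * n))
    n_full = int(round(p_full_given_ere * n_ere))
    labels = ["full"] * n_full + ["half"] * (n_ere - n_full) + ["none"] * (n - n_ere)
    rng.shuffle(labels)
    return labels


def _exact_categories(
    rng: np.random.Generator, n: int, p_full: float, p_half: float
) -> list[str]:
    n_full = int(round(p_full * n))
    n_half = int(round(p_half * n))
    labels = ["full"] * n_full + ["half"] * n_half + ["none"] * (n - n_full - n_half)
    rng.shuffle(labels)
    return labels


def _build_locus_specs(config: ScenarioConfig, rng: np.random.Generator) -> list[LocusSpec]:
    specs: list[LocusSpec] = []
    counter = [0]

    def new(role: str, **kwargs) -> LocusSpec:
        counter[0] += 1
        spec = LocusSpec(name=f"locus_{counter[0]:06d}", role=role, **kwargs)
        specs.append(spec)
        return spec

    n_fox = {
        clone: int(round(config.fox_fraction[clone] * config.n_chip))
        for clone in ERA_CLONES
    }
    n_shared = int(round(config.shared_fraction * min(n_fox["WT"], n_fox["K303R"])))

    # shared (WT+K303R) Fox loci: one sequence and one ERE status per locus
    # (drawn at the WT rate), independent opening assignment per clone
    shared_ere = _exact_ere_labels(
        rng, n_shared, config.ere_free_fraction["WT"], config.fox_full_ere_fraction
    )
    shared_open = {
        clone: _exact_flags(rng, n_shared, config.opening[f"common_{clone}"])
        for clone in ("WT", "K303R")
    }
    for i in range(n_shared):
        new(
            "fox",
            fox_clones=("WT", "K303R"),
            chip_clones=("WT", "K303R"),
            partition="common",
            ere=shared_ere[i],
            open_in={
                "WT": bool(shared_open["WT"][i]),
                "K303R": bool(shared_open["K303R"][i]),
            },
        )
    free_shared = sum(label == "none" for label in shared_ere)

    # K303R-specific ERE-free count is adjusted so the clone-level total
    # still matches the configured rate despite the shared loci having been
    # assigned at the WT rate.
    n_k_specific = n_fox["K303R"] - n_shared
    target_free_k = int(round(config.ere_free_fraction["K303R"] * n_fox["K303R"]))
    free_k_specific = min(max(target_free_k - free_shared, 0), n_k_specific)
    q_k = free_k_specific / n_k_specific if n_k_specific else 0.0

    specific_plan = {
        "WT": (n_fox["WT"] - n_shared, config.ere_free_fraction["WT"]),
        "K303R": (n_k_specific, q_k),
        "Y537S": (n_fox["Y537S"], config.ere_free_fraction["Y537S"]),
    }
    for clone, (count, p_free) in specific_plan.items():
        ere_labels = _exact_ere_labels(rng, count, p_free, config.fox_full_ere_fraction)
        open_flags = _exact_flags(rng, count, config.opening[f"{clone}_specific"])
        for i in range(count):
            new(
                "fox",
                fox_clones=(clone,),
                chip_clones=(clone,),
                partition=f"{clone}_specific",
                ere=ere_labels[i],
                open_in={clone: bool(open_flags[i])},
            )

    # each Dox(+) condition's ChIP set totals n_chip per clone:
    # fox + nonfox (both conditions) + that condition's common-ACR pool
    for clone in ERA_CLONES:
        n_nonfox = config.n_chip - n_fox[clone] - config.n_common_acr
        if n_nonfox < 0:
            raise ValueError(
                "n_chip too small for the configured fox fraction and common pool"
            )
        open_flags = _exact_flags(rng, n_nonfox, config.nonfox_opening)
        for i in range(n_nonfox):
            new(
                "nonfox",
                chip_clones=(clone,),
                partition=f"{clone}_specific",
                open_in={clone: bool(open_flags[i])},
            )

    for e2 in ("minus", "plus"):
        labels = _exact_categories(
            rng, config.n_common_acr, config.ere_full_rate[e2], config.ere_half_rate[e2]
        )
        for i in range(config.n_common_acr):
            new(
                "common_acr",
                chip_clones=ERA_CLONES,
                partition="common",
                ere=labels[i],
                e2=e2,
                open_in={clone: True for clone in ERA_CLONES},
            )

    for _ in range(config.n_background):
        new("background")
    return specs


def _assign_positions(config: ScenarioConfig, rng: np.random.Generator, specs: list[LocusSpec]) -> None:
    slot_width = config.region_width + config.region_gap
    slots_per_chrom = config.chrom_length // slot_width
    total_slots = slots_per_chrom * config.n_chroms
    if len(specs) > total_slots:
        raise CapacityError(
            f"{len(specs)} regions requested but genome holds only {total_slots} "
            f"non-overlapping slots"
        )
    chosen = rng.choice(total_slots, size=len(specs), replace=False)
    for spec, slot in zip(specs, chosen):
        chrom_index, slot_index = divmod(int(slot), slots_per_chrom)
        spec.chrom = f"chr{chrom_index + 1}"
        spec.start = slot_index * slot_width + config.region_gap // 2
        spec.end = spec.start + config.region_width


def _materialize_sequences(
    config: ScenarioConfig,
    rng: np.random.Generator,
    specs: list[LocusSpec],
    pwms: Mapping[str, PWM],
    max_rounds: int = 50,
) -> None:
    """Clean backgrounds for every locus, then plant and re-verify motifs."""
    pwm_list = list(pwms.values())
    backgrounds = clean_backgrounds(
        rng, len(specs), config.region_width, config.gc_fraction,
        pwm_list, config.threshold_fraction,
    )
    for spec, row in zip(specs, backgrounds):
        spec.sequence = row.copy()

    planted = [s for s in specs if s.role == "fox" or s.ere != "none"]
    pending = planted
    for _ in range(max_rounds):
        if not pending:
            break
        for spec in pending:
            inserts = _plan_inserts(rng, spec, pwms, config)
            spec.motifs = _plant(rng, spec.sequence, inserts)
        pending = _verification_failures(config, pending, pwms)
        for spec in pending:  # replant on a fresh clean background
            spec.sequence = clean_backgrounds(
                rng, 1, config.region_width, config.gc_fraction,
                pwm_list, config.threshold_fraction,
            )[0]
            spec.motifs = []
    if pending:
        raise RuntimeError(f"could not realize {len(pending)} planted loci")


def _verification_failures(
    config: ScenarioConfig,
    specs: Sequence[LocusSpec],
    pwms: Mapping[str, PWM],
) -> list[LocusSpec]:
    """Loci whose realized sequence disagrees with the planting plan."""
    if not specs:
        return []
    encoded = np.stack([s.sequence for s in specs])
    sequences = [decode(s.sequence) for s in specs]
    presence: dict[str, np.ndarray] = {}
    for motif_id, pwm in pwms.items():
        thr = config.threshold_fraction * pwm.max_score - 1e-9
        hit = np.zeros(len(specs), dtype=bool)
        for spwm in (pwm, pwm.reverse_complement()):
            scores = _window_scores(encoded, spwm)
            if scores.shape[1]:
                hit |= (scores >= thr).any(axis=1)
        presence[motif_id] = hit
    ere_labels = classify_ere_many(
        sequences, pwms[config.ere_half_motif], config.spacer, config.threshold_fraction
    )
    failures = []
    for i, spec in enumerate(specs):
        want_fox = spec.role == "fox"
        ok = presence[config.fox_motif][i] == want_fox
        ok &= ere_labels[i] == spec.ere
        for motif_id in pwms:
            if motif_id in (config.fox_motif, config.ere_half_motif):
                continue
            ok &= not presence[motif_id][i]
        if not ok:
            failures.append(spec)
    return failures


def _write_genome(
    config: ScenarioConfig,
    rng: np.random.Generator,
    specs: Sequence[LocusSpec],
    path: Path,
) -> dict[str, int]:
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    chrom_arrays = {
        chrom: _random_bases(rng, config.chrom_length, config.gc_fraction)
        for chrom in sizes
    }
    for spec in specs:
        chrom_arrays[spec.chrom][spec.start : spec.end] = spec.sequence
    with open(path, "w") as handle:
        for chrom, arr in chrom_arrays.items():
            handle.write(f">{chrom}\n")
            text = decode(arr)
            for i in range(0, len(text), 80):
                handle.write(text[i : i + 80] + "\n")
    return sizes


def simulate_genome(config: ScenarioConfig, path: str | Path) -> dict[str, int]:
    """Background-only genome FASTA at the configured GC fraction (seeded)."""
    if config.chrom_length < 10 * config.region_width:
        raise CapacityError("chrom_length must be >= 10x region width")
    rng = np.random.default_rng(config.seed)
    return _write_genome(config, rng, [], Path(path))


def _sample_keys() -> list[SampleKey]:
    return [
        SampleKey(clone=c, dox=d, e2=e, assay=a)
        for c in ERA_CLONES
        for a in ("ChIP", "ATAC")
        for (d, e) in CONDITIONS
    ]


def _emit_peaks(
    config: ScenarioConfig,
    specs: Sequence[LocusSpec],
    out_dir: Path,
) -> dict[str, str]:
    files: dict[str, str] = {}
    for key in _sample_keys():
        members = []
        for spec in specs:
            conditions = (
                spec.chip_conditions(key.clone)
                if key.assay == "ChIP"
                else spec.atac_conditions(key.clone)
            )
            if key.condition in conditions:
                members.append(spec)
        members.sort(key=lambda s: (s.chrom, s.start))
        intervals = [
            GenomicInterval(
                s.chrom, s.start, s.end,
                name=f"{key.label()}_{i:06d}",
                score=100.0,
                summit=s.start + config.region_width // 2,
            )
            for i, s in enumerate(members, start=1)
        ]
        path = out_dir / f"{key.label()}.narrowPeak"
        write_narrowpeak(PeakSet(intervals, sample=key), path)
        files[key.label()] = str(path)
    return files


def _expected_stats(config: ScenarioConfig, specs: Sequence[LocusSpec]) -> dict:
    """Realized (planted) rates, the ground truth every recovery test targets."""
    fox = {c: [s for s in specs if s.role == "fox" and c in s.fox_clones] for c in ERA_CLONES}
    # ChIP peaks per clone in one Dox(+) condition: fox + nonfox + one common pool
    n_common = sum(1 for s in specs if s.role == "common_acr" and s.e2 == "plus")
    n_chip = {
        c: sum(1 for s in specs if c in s.chip_clones and s.role in ("fox", "nonfox"))
        + n_common
        for c in ERA_CLONES
    }
    shared = [s for s in fox["WT"] if "K303R" in s.fox_clones]
    stats: dict = {
        "n_chip": n_chip,
        "n_fox": {c: len(fox[c]) for c in ERA_CLONES},
        "fox_fraction": {c: len(fox[c]) / n_chip[c] for c in ERA_CLONES},
        "ere_free_fraction": {
            c: sum(s.ere == "none" for s in fox[c]) / len(fox[c]) if fox[c] else None
            for c in ERA_CLONES
        },
        "shared_fraction": {
            "WT": len(shared) / len(fox["WT"]) if fox["WT"] else 0.0,
            "K303R": len(shared) / len(fox["K303R"]) if fox["K303R"] else 0.0,
        },
    }
    opening: dict[str, dict] = {}
    for clone in ("WT", "K303R"):
        for stratum, pool in (
            (f"{clone}_specific", [s for s in fox[clone] if s.partition == f"{clone}_specific"]),
            (f"common_{clone}", [s for s in shared]),
        ):
            opening[stratum] = {
                "n": len(pool),
                "rate": (
                    sum(s.open_in.get(clone, False) for s in pool) / len(pool)
                    if pool
                    else None
                ),
            }
    stats["opening"] = opening
    common = {e2: [s for s in specs if s.role == "common_acr" and s.e2 == e2]
              for e2 in ("minus", "plus")}
    stats["common_acr"] = {
        e2: {
            "n": len(pool),
            "half_rate": sum(s.ere == "half" for s in pool) / len(pool) if pool else None,
            "full_rate": sum(s.ere == "full" for s in pool) / len(pool) if pool else None,
        }
        for e2, pool in common.items()
    }
    return stats


def plant_scenario(config: ScenarioConfig, out_dir: str | Path) -> TruthManifest:
    """Generate the full scenario: FASTA, per-sample narrowPeak files, manifest.

    Deterministic: identical config (including seed) gives byte-identical
    outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    pwms = {p.motif_id: p for p in bundled_motifs()}
    for needed in (config.fox_motif, config.ere_half_motif):
        if needed not in pwms:
            raise ValueError(f"motif {needed!r} not in the bundled library")

    specs = _build_locus_specs(config, rng)
    _assign_positions(config, rng, specs)
    _materialize_sequences(config, rng, specs, pwms)

    fasta_path = out_dir / "genome.fa"
    sizes = _write_genome(config, rng, specs, fasta_path)
    sizes_path = out_dir / "genome.chrom.sizes"
    write_chrom_sizes(sizes, sizes_path)
    peak_files = _emit_peaks(config, specs, out_dir)

    regions = []
    for spec in specs:
        regions.append(
            {
                "name": spec.name,
                "chrom": spec.chrom,
                "start": spec.start,
                "end": spec.end,
                "role": spec.role,
                "fox_clones": list(spec.fox_clones),
                "chip_clones": list(spec.chip_clones),
                "partition": spec.partition,
                "ere": spec.ere,
                "e2": spec.e2,
                "open_in": spec.open_in,
                "motifs": spec.motifs,
            }
        )
    manifest = TruthManifest(
        config=asdict(config),
        regions=regions,
        expected=_expected_stats(config, specs),
        genome_fasta=str(fasta_path),
        chrom_sizes=str(sizes_path),
        peak_files=peak_files,
    )
    manifest.to_json(out_dir / "manifest.json")
    config.to_json(out_dir / "scenario_config.json")
    return manifest


def write_sample_sheet(manifest: TruthManifest, path: str | Path) -> None:
    """Pipeline sample sheet (TSV) pointing at the scenario's peak files."""
    rows = ["clone\tdox\te2\tassay\tpath\tformat"]
    for clone in ERA_CLONES:
        for assay in ("ChIP", "ATAC"):
            for dox, e2 in CONDITIONS:
                key = SampleKey(clone, dox, e2, assay)
                rows.append(
                    f"{clone}\t{dox}\t{e2}\t{assay}\t"
                    f"{manifest.peak_files[key.label()]}\tnarrowPeak"
                )
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Manifest verification
# ---------------------------------------------------------------------------

@dataclass
class VerificationReport:
    checks: list[dict]

    @property
    def ok(self) -> bool:
        return all(c["passed"] for c in self.checks)

    def failures(self) -> list[dict]:
        return [c for c in self.checks if not c["passed"]]


def _rate_check(name: str, observed: float | None, expected: float, n: int) -> dict:
    if observed is None or n == 0:
        return {"check": name, "passed": False, "detail": "empty stratum"}
    se = float(np.sqrt(max(expected * (1 - expected), 1e-12) / n))
    tolerance = 4 * se
    passed = abs(observed - expected) <= tolerance
    return {
        "check": name,
        "passed": bool(passed),
        "detail": f"observed={observed:.4f} expected={expected:.4f} tol={tolerance:.4f} n={n}",
    }


def verify_manifest(
    manifest: TruthManifest | str | Path,
    fasta_path: str | Path | None = None,
    check_rates: bool = True,
) -> VerificationReport:
    """Check manifest/FASTA consistency and planted-rate recovery bounds.

    Sequence checks assert that every recorded motif instance is literally
    present at its coordinates. Rate checks assert empirical Bernoulli rates
    lie within 4 standard errors of the configured rates.
    """
    from pyfaidx import Fasta

    if not isinstance(manifest, TruthManifest):
        manifest = TruthManifest.from_json(manifest)
    config = ScenarioConfig(**manifest.config)
    checks: list[dict] = []

    fasta_path = fasta_path or manifest.genome_fasta
    genome = Fasta(str(fasta_path))
    n_motifs = 0
    mismatches = []
    for region in manifest.regions:
        for record in region["motifs"]:
            n_motifs += 1
            start = region["start"] + record["offset"]
            observed = str(genome[region["chrom"]][start : start + len(record["sequence"])]).upper()
            if observed != record["sequence"]:
                mismatches.append(f"{region['name']}:{record['motif_id']}")
    for name in mismatches:
        checks.append({"check": f"motif_sequence:{name}", "passed": False,
                       "detail": "sequence mismatch"})
    checks.append(
        {
            "check": "motif_sequences",
            "passed": not mismatches,
            "detail": f"{n_motifs - len(mismatches)}/{n_motifs} motif records match",
        }
    )

    if check_rates:
        exp = manifest.expected
        for clone in ERA_CLONES:
            checks.append(
                _rate_check(
                    f"fox_fraction[{clone}]",
                    exp["fox_fraction"][clone],
                    config.fox_fraction[clone],
                    exp["n_chip"][clone],
                )
            )
            checks.append(
                _rate_check(
                    f"ere_free_fraction[{clone}]",
                    exp["ere_free_fraction"][clone],
                    config.ere_free_fraction[clone],
                    exp["n_fox"][clone],
                )
            )
        for stratum in ("WT_specific", "K303R_specific"):
            entry = exp["opening"][stratum]
            checks.append(
                _rate_check(
                    f"opening[{stratum}]", entry["rate"], config.opening[stratum], entry["n"]
                )
            )
        for e2 in ("minus", "plus"):
            entry = exp["common_acr"][e2]
            checks.append(
                _rate_check(
                    f"ere_half_rate[{e2}]", entry["half_rate"],
                    config.ere_half_rate[e2], entry["n"],
                )
            )
            checks.append(
                _rate_check(
                    f"ere_full_rate[{e2}]", entry["full_rate"],
                    config.ere_full_rate[e2], entry["n"],
                )
            )
    return VerificationReport(checks)


# ---------------------------------------------------------------------------
# Auxiliary simulators for recovery tests
# ---------------------------------------------------------------------------

def simulate_enrichment_flags(
    n_group: int = 500,
    n_background: int = 5000,
    rate_group: float = 0.30,
    rate_background: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, bool], dict[str, bool], dict[str, bool]]:
    """Motif-presence flags for a planted enrichment instance.

    Returns (mutant group flags, mutant background flags, wildtype group
    flags); the wildtype group carries the motif only at the background rate.
    The group regions are a subset of the background regions.
    """
    rng = np.random.default_rng(seed)
    names = [f"r{i:05d}" for i in range(n_background)]
    group_names = names[:n_group]
    group_flags = {name: bool(rng.random() < rate_group) for name in group_names}
    background = dict(group_flags)
    for name in names[n_group:]:
        background[name] = bool(rng.random() < rate_background)
    wt_group = {name: bool(rng.random() < rate_background) for name in group_names}
    return group_flags, background, wt_group


def simulate_clustered_samples(
    n_clusters: int = 3,
    samples_per_cluster: int = 4,
    loci_per_cluster: int = 80,
    p_in: float = 0.9,
    p_out: float = 0.05,
    region_width: int = 200,
    seed: int = 0,
) -> tuple[list[PeakSet], list[int]]:
    """Peak sets drawn around cluster-specific locus archetypes.

    Each cluster owns a disjoint block of loci; a sample carries a locus with
    probability ``p_in`` for its own cluster's loci and ``p_out`` otherwise.
    Returns the samples and their true cluster labels.
    """
    rng = np.random.default_rng(seed)
    loci = [
        ("chrS", i * (region_width + 100), i * (region_width + 100) + region_width)
        for i in range(n_clusters * loci_per_cluster)
    ]
    cluster_of_locus = np.repeat(np.arange(n_clusters), loci_per_cluster)
    samples: list[PeakSet] = []
    labels: list[int] = []
    for cluster in range(n_clusters):
        for s in range(samples_per_cluster):
            intervals = []
            for (chrom, start, end), owner in zip(loci, cluster_of_locus):
                p = p_in if owner == cluster else p_out
                if rng.random() < p:
                    intervals.append(
                        GenomicInterval(chrom, start, end, name=f"c{cluster}s{s}_{start}")
                    )
            samples.append(PeakSet(intervals))
            labels.append(cluster)
    return samples, labels
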