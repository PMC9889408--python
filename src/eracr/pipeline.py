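"""End-to-end orchestration: sample sheet -> groups -> ACR -> reports.

All analysis stages are deterministic; randomness lives exclusively in the
synthetic generator. Every reported fraction is emitted with its numerator
and denominator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .acr import (
    ERA_CLONES,
    acr_table,
    define_acr,
    motif_rate,
    partition_clone_specificity,
    select_high_enrichment_motifs,
    select_variable_motifs,
)
from .condition_groups import (
    CONDITIONS,
    build_presence,
    classify_era_groups,
    write_group_table,
)
from .fox_analysis import (
    build_fox_report,
    opening_rate,
    shared_fraction,
    write_fox_reports,
)
from .intervals import GenomicInterval, PeakSet, SampleKey, merge_union, overlaps_any, read_peaks
from .motif import (
    PWM,
    bundled_motifs,
    classify_ere_many,
    enrichment_test,
    load_motifs,
    scan_presence,
    differential_enrichment,
)
from .sample_similarity import build_matrix, pca_project, write_coordinates_tsv, write_matrix_tsv

ALL_STAGES = ("groups", "acr", "enrich", "fox", "pca")


class MissingSampleError(ValueError):
    """A stage required a SampleKey absent from the sample sheet."""


@dataclass
class RunConfig:
    sample_sheet: str
    genome: str
    out_dir: str
    motifs: str | None = None  # None -> bundled toy library
    min_bp: int = 1
    threshold_fraction: float = 0.8
    delta_min: float = 10.0
    ratio_min: float = 3.0
    rate_min: float = 0.15
    p_max: float = 1e-20
    flank: int = 3000
    spacer: int = 3
    fox_motif: str = "FOX_LIKE"
    ere_half_motif: str = "ERE_HALF"
    fox_condition: tuple[str, str] = ("plus", "plus")
    n_components: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.fox_condition = tuple(self.fox_condition)  # JSON round-trip
        for name in ("min_bp", "threshold_fraction", "delta_min", "ratio_min",
                     "rate_min", "p_max", "flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def load_sample_sheet(path: str | Path) -> dict[SampleKey, PeakSet]:
    """TSV columns: clone, dox, e2, assay, path, format."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"clone", "dox", "e2", "assay", "path", "format"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    base = Path(path).parent
    samples: dict[SampleKey, PeakSet] = {}
    for row in sheet.itertuples(index=False):
        key = SampleKey(clone=row.clone, dox=row.dox, e2=row.e2, assay=row.assay)
        if key in samples:
            raise ValueError(f"duplicate sample sheet entry: {key.label()}")
        peak_path = Path(row.path)
        if not peak_path.is_absolute():
            peak_path = base / peak_path
        samples[key] = read_peaks(peak_path, sample=key, format=row.format)
    return samples


def _require(samples: Mapping[SampleKey, PeakSet], key: SampleKey) -> PeakSet:
    if key not in samples:
        raise MissingSampleError(f"required sample missing from sheet: {key.label()}")
    return samples[key]


class _Genome:
    """Thin pyfaidx wrapper extracting uppercase region sequences."""

    def __init__(self, path: str | Path) -> None:
        from pyfaidx import Fasta

        self.fasta = Fasta(str(path))

    def sequences(self, intervals: Sequence[GenomicInterval]) -> list[str]:
        out = []
        for iv in intervals:
            record = self.fasta[iv.chrom]
            start = max(0, iv.start)
            end = min(len(record), iv.end)
            out.append(str(record[start:end]).upper())
        return out


def _motif_flags(
    pwms: Sequence[PWM],
    sequences: Sequence[str],
    threshold_fraction: float,
) -> dict[str, "pd.Series"]:
    return {
        pwm.motif_id: scan_presence(pwm, sequences, threshold_fraction)
        for pwm in pwms
    }


def run_pipeline(
    config: RunConfig,
    stages: Sequence[str] = ALL_STAGES,
) -> dict[str, str]:
    """Run the requested stages; returns a map of output name -> path."""
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = load_sample_sheet(config.sample_sheet)
    genome = _Genome(config.genome)
    pwms = (
        bundled_motifs()
        if config.motifs is None
        else load_motifs(config.motifs)
    )
    pwm_by_id = {p.motif_id: p for p in pwms}
    outputs: dict[str, str] = {}
    patterns_by_clone_assay: dict[tuple[str, str], list] = {}

    clones = sorted({k.clone for k in samples}, key=ERA_CLONES.index if all(
        k.clone in ERA_CLONES for k in samples) else str)

    if "groups" in stages or "enrich" in stages:
        for clone in clones:
            for assay in ("ATAC", "ChIP"):
                keys = [SampleKey(clone, d, e, assay) for d, e in CONDITIONS]
                present = [k for k in keys if k in samples]
                if not present:
                    continue
                if len(present) < len(keys):
                    missing = [k.label() for k in keys if k not in samples]
                    raise MissingSampleError(
                        f"incomplete condition grid for {clone}/{assay}; "
                        f"missing: {', '.join(missing)}"
                    )
                per_condition = {k.condition: samples[k] for k in keys}
                consensus = merge_union(
                    list(per_condition.values()), name_prefix=f"{clone}_{assay}"
                )
                patterns = build_presence(consensus, per_condition, min_bp=config.min_bp)
                patterns_by_clone_assay[(clone, assay)] = patterns
                if "groups" in stages:
                    path = out_dir / f"condition_groups_{clone}_{assay}.tsv"
                    write_group_table(patterns, path)
                    outputs[f"groups_{clone}_{assay}"] = str(path)

    if "acr" in stages:
        outputs.update(_run_acr_stage(config, samples, genome, pwms, out_dir))

    if "enrich" in stages:
        outputs.update(
            _run_enrich_stage(config, genome, pwms, patterns_by_clone_assay, out_dir)
        )

    if "fox" in stages:
        outputs.update(_run_fox_stage(config, samples, genome, pwm_by_id, out_dir))

    if "pca" in stages:
        atac_samples = [ps for key, ps in sorted(samples.items()) if key.assay == "ATAC"]
        if len(atac_samples) < 2:
            raise MissingSampleError("pca stage needs >= 2 ATAC samples")
        matrix = build_matrix(atac_samples, mode="binary", min_bp=config.min_bp)
        result = pca_project(
            matrix, n_components=min(config.n_components, len(atac_samples))
        )
        matrix_path = out_dir / "presence_matrix.tsv"
        coords_path = out_dir / "pca_coordinates.tsv"
        write_matrix_tsv(matrix, matrix_path)
        write_coordinates_tsv(result, coords_path)
        outputs["presence_matrix"] = str(matrix_path)
        outputs["pca_coordinates"] = str(coords_path)

    provenance = {
        "config": asdict(config),
        "config_sha256": config.config_hash(),
        "eracr_version": __version__,
        "stages": list(stages),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    outputs["provenance"] = str(prov_path)
    return outputs


def _run_acr_stage(config, samples, genome, pwms, out_dir) -> dict[str, str]:
    outputs: dict[str, str] = {}
    acr_frames = []
    rate_rows = []
    common_ere = {}
    enrichment_results = []
    for dox, e2 in (("plus", "minus"), ("plus", "plus")):
        acr_by_clone = {}
        for clone in ERA_CLONES:
            chip = _require(samples, SampleKey(clone, dox, e2, "ChIP"))
            atac = _require(samples, SampleKey(clone, dox, e2, "ATAC"))
            acr_by_clone[clone] = define_acr(chip, atac, min_bp=config.min_bp)
        partition_clone_specificity(acr_by_clone, min_bp=config.min_bp)
        acr_frames.append(acr_table(acr_by_clone))

        common_regions = [
            r.interval
            for r in acr_by_clone["WT"]
            if r.clone_partition == "common"
        ]
        if common_regions:
            seqs = genome.sequences(common_regions)
            labels = classify_ere_many(
                seqs,
                {p.motif_id: p for p in pwms}[config.ere_half_motif],
                config.spacer,
                config.threshold_fraction,
            )
            common_ere[f"dox_{dox}_e2_{e2}"] = {
                "n": len(labels),
                "half_rate": motif_rate([l == "half" for l in labels]),
                "full_rate": motif_rate([l == "full" for l in labels]),
            }

        for clone in ERA_CLONES:
            regions = acr_by_clone[clone]
            if not regions:
                continue
            chip = samples[SampleKey(clone, dox, e2, "ChIP")]
            chip_seqs = genome.sequences(list(chip))
            # ACR regions are ChIP peaks, so one scan of the ChIP set covers both
            acr_names = {r.interval.name for r in regions}
            acr_mask = [iv.name in acr_names for iv in chip]
            for pwm in pwms:
                chip_flags = scan_presence(pwm, chip_seqs, config.threshold_fraction)
                acr_flags = [bool(f) for f, m in zip(chip_flags, acr_mask) if m]
                rate_rows.append(
                    {
                        "motif_id": pwm.motif_id,
                        "clone": clone,
                        "dox": dox,
                        "e2": e2,
                        "scope": "raw_acr",
                        "k": int(sum(acr_flags)),
                        "n": len(regions),
                        "rate": motif_rate(acr_flags),
                    }
                )
                specific = [
                    bool(f)
                    for f, r in zip(acr_flags, regions)
                    if r.clone_partition == f"{clone}_specific"
                ]
                if specific:
                    rate_rows.append(
                        {
                            "motif_id": pwm.motif_id,
                            "clone": clone,
                            "dox": dox,
                            "e2": e2,
                            "scope": "clone_specific",
                            "k": sum(specific),
                            "n": len(specific),
                            "rate": motif_rate(specific),
                        }
                    )
                # enrichment of the motif in ACR against the clone's ChIP peaks
                background = {iv.name: bool(f) for iv, f in zip(chip, chip_flags)}
                group = {name: background[name] for name in acr_names}
                enrichment_results.append(
                    enrichment_test(
                        group,
                        background,
                        motif_id=pwm.motif_id,
                        group_id=f"{clone}_dox_{dox}_e2_{e2}_acr",
                    )
                )

    acr_path = out_dir / "acr.tsv"
    pd.concat(acr_frames, ignore_index=True).to_csv(acr_path, sep="\t", index=False)
    outputs["acr"] = str(acr_path)

    rates = pd.DataFrame(rate_rows)
    rates_path = out_dir / "acr_motif_rates.tsv"
    rates.to_csv(rates_path, sep="\t", index=False)
    outputs["acr_motif_rates"] = str(rates_path)

    specific = rates[rates["scope"] == "clone_specific"]
    selected_variable: list[str] = []
    if not specific.empty:
        table = specific.pivot_table(
            index="motif_id", columns=["clone", "dox", "e2"], values="rate"
        ).dropna(axis=1, how="all").fillna(0.0)
        largest = int(specific["n"].max())
        selected_variable = select_variable_motifs(
            table, ratio_min=config.ratio_min, rate_min=config.rate_min,
            largest_group_size=largest,
        )
    selected_high = select_high_enrichment_motifs(enrichment_results, p_max=config.p_max)
    summary = {
        "common_acr_ere_rates": common_ere,
        "variable_motifs": selected_variable,
        "highly_enriched_motifs": selected_high,
    }
    summary_path = out_dir / "acr_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    outputs["acr_summary"] = str(summary_path)
    return outputs


def _run_enrich_stage(config, genome, pwms, patterns_by_clone_assay, out_dir) -> dict[str, str]:
    rows = []
    results_by = {}
    for (clone, assay), patterns in sorted(patterns_by_clone_assay.items()):
        if not patterns:
            continue
        regions = [p.region for p in patterns]
        seqs = genome.sequences(regions)
        flags_by_motif = _motif_flags(pwms, seqs, config.threshold_fraction)
        era_labels = [classify_era_groups(p) for p in patterns]
        names = [r.name for r in regions]
        for group_label in ("E2minus_ERa", "E2plus_ERa", "E2ind_ERa"):
            members = [i for i, l in enumerate(era_labels) if l == group_label]
            if not members:
                continue
            for pwm in pwms:
                flags = flags_by_motif[pwm.motif_id]
                group = {names[i]: bool(flags[i]) for i in members}
                background = {names[i]: bool(flags[i]) for i in range(len(names))}
                result = enrichment_test(
                    group, background, motif_id=pwm.motif_id,
                    group_id=f"{clone}_{assay}_{group_label}",
                )
                results_by.setdefault((clone, assay, group_label), []).append(result)
                rows.append(
                    {
                        "clone": clone, "assay": assay, "group": group_label,
                        "motif_id": pwm.motif_id, "k": result.k, "n": result.n,
                        "K": result.K, "N": result.N,
                        "p_value": result.p_value, "score": result.score,
                    }
                )
    enrich_path = out_dir / "enrichment.tsv"
    pd.DataFrame(rows).to_csv(enrich_path, sep="\t", index=False)

    diff_rows = []
    for (clone, assay, group_label), results in sorted(results_by.items()):
        if clone == "WT":
            continue
        wt = results_by.get(("WT", assay, group_label))
        if not wt:
            continue
        for record in differential_enrichment(results, wt, delta_min=config.delta_min):
            diff_rows.append(
                {
                    "clone": clone, "assay": assay, "group": group_label,
                    "motif_id": record.motif_id, "delta": record.delta,
                    "mutant_score": record.mutant_score,
                    "wildtype_score": record.wildtype_score,
                    "flagged": record.flagged,
                }
            )
    diff_path = out_dir / "differential_motifs.tsv"
    pd.DataFrame(diff_rows).to_csv(diff_path, sep="\t", index=False)
    return {"enrichment": str(enrich_path), "differential_motifs": str(diff_path)}


def _run_fox_stage(config, samples, genome, pwm_by_id, out_dir) -> dict[str, str]:
    dox, e2 = config.fox_condition
    fox_pwm = pwm_by_id[config.fox_motif]
    half_pwm = pwm_by_id[config.ere_half_motif]
    data = {}
    for clone in ("WT", "K303R"):
        chip = _require(samples, SampleKey(clone, dox, e2, "ChIP"))
        atac = _require(samples, SampleKey(clone, dox, e2, "ATAC"))
        seqs = genome.sequences(list(chip))
        fox_flags = scan_presence(fox_pwm, seqs, config.threshold_fraction)
        fox_peaks = [iv for iv, f in zip(chip, fox_flags) if f]
        fox_seqs = [s for s, f in zip(seqs, fox_flags) if f]
        ere_labels = classify_ere_many(
            fox_seqs, half_pwm, config.spacer, config.threshold_fraction
        )
        data[clone] = {
            "chip": chip, "atac": atac, "fox_flags": fox_flags,
            "fox_peaks": fox_peaks, "ere_labels": ere_labels,
        }
    fox_wt = PeakSet(data["WT"]["fox_peaks"])
    fox_k = PeakSet(data["K303R"]["fox_peaks"])
    frac_wt, frac_k = shared_fraction(fox_wt, fox_k, min_bp=config.min_bp)
    shared_by_clone = {"WT": frac_wt, "K303R": frac_k}

    reports = []
    for clone, other_set in (("WT", fox_k), ("K303R", fox_wt)):
        entry = data[clone]
        shared_flags = overlaps_any(entry["fox_peaks"], other_set, min_bp=config.min_bp)
        strata = [
            ("common" if shared else f"{clone}_specific") + "/" + ere
            for shared, ere in zip(shared_flags, entry["ere_labels"])
        ]
        opening = opening_rate(
            entry["fox_peaks"], strata, entry["atac"], min_bp=config.min_bp
        )
        partition_only = opening_rate(
            entry["fox_peaks"],
            ["common" if s else f"{clone}_specific" for s in shared_flags],
            entry["atac"],
            min_bp=config.min_bp,
        )
        opening.update(partition_only)
        reports.append(
            build_fox_report(
                clone=clone,
                chip=entry["chip"],
                fox_flags=entry["fox_flags"],
                ere_labels_fox=entry["ere_labels"],
                shared=shared_by_clone[clone],
                opening=opening,
            )
        )
    path = out_dir / "fox_report.json"
    write_fox_reports(reports, path)
    return {"fox_report": str(path)}
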