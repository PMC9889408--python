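"""DBA-lite sample comparison: consensus presence matrix and PCA.

True differential-binding-affinity analysis re-counts reads per consensus
region; without raw reads this module substitutes binary occupancy (or the
maximum overlapping peak score) over a global merged consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .intervals import PeakSet, merge_union, overlaps_any


@dataclass
class PresenceMatrix:
    """regions x samples matrix over a global consensus."""

    regions: PeakSet
    sample_labels: list[str]
    values: np.ndarray  # (n_regions, n_samples)
    mode: str

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.regions), len(self.sample_labels)):
            raise ValueError("matrix dimensions inconsistent with labels")
        if self.mode == "binary" and not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary matrix must contain only 0/1")


@dataclass
class PCAResult:
    coordinates: np.ndarray  # (n_samples, n_components)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    sample_labels: list[str]


def build_matrix(
    samples: Sequence[PeakSet],
    mode: str = "binary",
    min_bp: int = 1,
) -> PresenceMatrix:
    """Global consensus (merge across all samples) scored per sample.

    ``binary`` mode stores presence; ``score`` mode stores the maximum score
    of overlapping peaks (0 when absent or unscored).
    """
    if len(samples) < 2:
        raise ValueError("build_matrix requires >= 2 samples")
    if mode not in ("binary", "score"):
        raise ValueError(f"unknown matrix mode {mode!r}")
    consensus = merge_union(list(samples))
    labels = [
        ps.sample.label() if ps.sample is not None else f"sample_{i}"
        for i, ps in enumerate(samples)
    ]
    values = np.zeros((len(consensus), len(samples)))
    for j, ps in enumerate(samples):
        if mode == "binary":
            values[:, j] = overlaps_any(consensus, ps, min_bp=min_bp).astype(float)
        else:
            values[:, j] = _max_overlap_scores(consensus, ps, min_bp)
    return PresenceMatrix(consensus, labels, values, mode)


def _max_overlap_scores(consensus: PeakSet, ps: PeakSet, min_bp: int) -> np.ndarray:
    by_chrom: dict[str, list] = {}
    for iv in ps:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = np.zeros(len(consensus))
    for i, region in enumerate(consensus):
        best = 0.0
        found = False
        for iv in by_chrom.get(region.chrom, ()):
            shared = min(iv.end, region.end) - max(iv.start, region.start)
            if shared >= min_bp:
                found = True
                best = max(best, iv.score or 0.0)
        out[i] = best if found else 0.0
    return out


def pca_project(matrix: PresenceMatrix, n_components: int = 2) -> PCAResult:
    """Column-centered PCA of the sample x region matrix.

    Deterministic for fixed input up to per-component sign. A degenerate
    all-equal matrix yields zero explained variance without error.
    """
    n_samples = len(matrix.sample_labels)
    if n_components > n_samples:
        raise ValueError(
            f"n_components={n_components} exceeds sample count {n_samples}"
        )
    X = matrix.values.T.astype(float)  # samples x regions
    pca = PCA(n_components=n_components, svd_solver="full")
    with np.errstate(invalid="ignore"):  # zero-variance input is allowed
        coords = pca.fit_transform(X)
    total_var = X.var(axis=0, ddof=1).sum() if n_samples > 1 else 0.0
    if total_var == 0.0:
        coords = np.zeros_like(coords)
        ev = np.zeros(n_components)
        evr = np.zeros(n_components)
    else:
        ev = pca.explained_variance_
        evr = pca.explained_variance_ratio_
    return PCAResult(coords, ev, evr, list(matrix.sample_labels))


def write_matrix_tsv(matrix: PresenceMatrix, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("region\t" + "\t".join(matrix.sample_labels) + "\n")
        for i, region in enumerate(matrix.regions):
            row = "\t".join(f"{v:g}" for v in matrix.values[i])
            handle.write(f"{region.chrom}:{region.start}-{region.end}\t{row}\n")


def write_coordinates_tsv(result: PCAResult, path: str | Path) -> None:
    n_components = result.coordinates.shape[1]
    with open(path, "w") as handle:
        header = ["sample"] + [f"PC{i+1}" for i in range(n_components)]
        handle.write("\t".join(header) + "\n")
        for label, row in zip(result.sample_labels, result.coordinates):
            handle.write(label + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
        handle.write(
            "#explained_variance_ratio\t"
            + "\t".join(f"{v:.6g}" for v in result.explained_variance_ratio)
            + "\n"
        )
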