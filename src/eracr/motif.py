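"""PWM motif scanning, ERE half/full-site calls, and enrichment statistics.

Scanning uses log2-odds scores against a background base composition; a
window is a hit when its score reaches ``threshold_fraction`` of the PWM's
maximum attainable score. Windows containing ``N`` never hit. Both strands
are always scanned.

Enrichment is a one-sided (upper-tail) hypergeometric test on per-region
motif presence within a group against a stated background region set; a
binomial alternative is available. The reported enrichment score is
``-log10(p)``; Benjamini-Hochberg adjusted p-values are carried alongside
but never drive the selection filters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

ALPHABET = "ACGT"
_BASE_TO_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N
_P_FLOOR = 1e-300  # keeps -log10(p) finite for astronomically small p

_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _i in _BASE_TO_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


class MotifFormatError(ValueError):
    """Raised for unparsable or inconsistent motif libraries."""


def encode(sequence: str) -> np.ndarray:
    """Encode a DNA string as uint8 (A=0, C=1, G=2, T=3, anything else=4)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def reverse_complement(sequence: str) -> str:
    table = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return sequence.translate(table)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with a background model.

    ``matrix`` has shape (length, 4) over A,C,G,T and each row sums to 1;
    ``background`` is a length-4 probability vector.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        background = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "background", background)
        if matrix.ndim != 2 or matrix.shape[1] != 4:
            raise MotifFormatError(f"{self.motif_id}: matrix must be (length, 4)")
        if len(matrix) < 4:
            raise MotifFormatError(f"{self.motif_id}: motif length must be >= 4")
        if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
            raise MotifFormatError(f"{self.motif_id}: matrix rows must sum to 1")
        if not math.isclose(background.sum(), 1.0, abs_tol=1e-9):
            raise MotifFormatError(f"{self.motif_id}: background must sum to 1")

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.25,
    ) -> "PWM":
        """Build a PWM from a (length, 4) count matrix with pseudocounts."""
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise MotifFormatError(f"{motif_id}: counts must be (length, 4)")
        if counts.shape[0] == 0:
            raise MotifFormatError(f"{motif_id}: zero-length motif")
        if np.any(counts < 0):
            raise MotifFormatError(f"{motif_id}: negative counts")
        padded = counts + pseudocount
        matrix = padded / padded.sum(axis=1, keepdims=True)
        if background is None:
            background = np.full(4, 0.25)
        return cls(motif_id, matrix, background, pseudocount)

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def log_odds(self) -> np.ndarray:
        """(length, 4) log2-odds score matrix."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / self.background)

    @property
    def score_lut(self) -> np.ndarray:
        """(length, 5) lookup table; the 5th column (N) scores -inf."""
        lut = np.full((len(self), 5), -np.inf)
        lut[:, :4] = self.log_odds
        return lut

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id,
            self.matrix[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.pseudocount,
        )


@dataclass(frozen=True)
class MotifHit:
    region_name: str
    motif_id: str
    offset: int
    strand: str
    score: float


# ---------------------------------------------------------------------------
# Motif library I/O
# ---------------------------------------------------------------------------

def load_motifs(
    path: str | Path,
    format: str | None = None,
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
) -> list[PWM]:
    """Load a motif library in JASPAR (counts) or MEME minimal text format.

    The format is inferred from the file extension when not given
    (``.jaspar``/``.pfm`` vs ``.meme``/``.txt``).
    """
    from Bio import motifs as bio_motifs

    path = Path(path)
    if format is None:
        format = "jaspar" if path.suffix.lower() in (".jaspar", ".pfm") else "meme"
    if format not in ("jaspar", "meme"):
        raise ValueError(f"unknown motif format {format!r}")
    parser = "jaspar" if format == "jaspar" else "minimal"
    with open(path) as handle:
        records = list(bio_motifs.parse(handle, parser))
    pwms: list[PWM] = []
    seen: set[str] = set()
    for record in records:
        motif_id = getattr(record, "matrix_id", None) or record.name
        if not motif_id:
            raise MotifFormatError(f"{path}: motif without an id")
        if motif_id in seen:
            raise MotifFormatError(f"{path}: duplicate motif id {motif_id!r}")
        seen.add(motif_id)
        source = record.counts if record.counts is not None else record.pwm
        counts = np.array([source[b] for b in ALPHABET], dtype=float).T
        if counts.shape[0] == 0:
            raise MotifFormatError(f"{path}: motif {motif_id!r} has zero columns")
        pwms.append(
            PWM.from_counts(motif_id, counts, background=background, pseudocount=pseudocount)
        )
    return pwms


def bundled_motifs(pseudocount: float = 0.25) -> list[PWM]:
    """The packaged toy motif library (Fox, ERE half, AP-1, NHR, GATA)."""
    source = resources.files("eracr.data").joinpath("toy_motifs.jaspar")
    with resources.as_file(source) as path:
        return load_motifs(path, format="jaspar", pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _window_scores(encoded: np.ndarray, pwm: PWM) -> np.ndarray:
    """Score every window of a (batch, L) encoded array; returns (batch, W)."""
    m = len(pwm)
    length = encoded.shape[-1]
    n_windows = length - m + 1
    batch = encoded.shape[0]
    if n_windows <= 0:
        return np.zeros((batch, 0))
    lut = pwm.score_lut
    scores = np.zeros((batch, n_windows))
    for j in range(m):
        scores += lut[j, encoded[:, j : j + n_windows]]
    return scores


def _threshold(pwm: PWM, threshold_fraction: float) -> float:
    if not (0.0 < threshold_fraction <= 1.0):
        raise ValueError("threshold_fraction must be in (0, 1]")
    return threshold_fraction * pwm.max_score - 1e-9


def scan(
    pwm: PWM,
    sequence: str,
    threshold_fraction: float = 0.8,
    region_name: str = "",
) -> list[MotifHit]:
    """Scan one sequence on both strands; return hits sorted by offset.

    A minus-strand hit at offset ``o`` means the reverse complement of
    ``sequence[o:o+len(pwm)]`` matches the motif. Sequences shorter than the
    motif yield no hits.
    """
    thr = _threshold(pwm, threshold_fraction)
    encoded = encode(sequence)[None, :]
    hits: list[MotifHit] = []
    for strand, spwm in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = _window_scores(encoded, spwm)[0]
        for offset in np.flatnonzero(scores >= thr):
            hits.append(
                MotifHit(region_name, pwm.motif_id, int(offset), strand, float(scores[offset]))
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def _grouped_by_length(sequences: Sequence[str]) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for i, seq in enumerate(sequences):
        groups.setdefault(len(seq), []).append(i)
    return groups


def scan_presence(
    pwm: PWM,
    sequences: Sequence[str],
    threshold_fraction: float = 0.8,
) -> np.ndarray:
    """Per-sequence boolean: does any window on either strand hit the motif?

    Vectorized across sequences (grouped by length) for large batches.
    """
    thr = _threshold(pwm, threshold_fraction)
    out = np.zeros(len(sequences), dtype=bool)
    rc = pwm.reverse_complement()
    for length, idx in _grouped_by_length(sequences).items():
        if length < len(pwm):
            continue
        encoded = np.stack([encode(sequences[i]) for i in idx])
        hit = np.zeros(len(idx), dtype=bool)
        for spwm in (pwm, rc):
            scores = _window_scores(encoded, spwm)
            hit |= (scores >= thr).any(axis=1)
        out[np.asarray(idx)] = hit
    return out


# ---------------------------------------------------------------------------
# ERE half/full-site classification
# ---------------------------------------------------------------------------

def classify_ere_many(
    sequences: Sequence[str],
    half_site_pwm: PWM,
    spacer: int = 3,
    threshold_fraction: float = 0.8,
) -> list[str]:
    """Label each sequence ``none``/``half``/``full`` for ERE content.

    ``full``: a plus-strand half-site hit followed, after exactly ``spacer``
    intervening bases, by a minus-strand half-site hit (the palindromic
    arrangement). ``half``: at least one half-site hit on either strand but
    no full site.
    """
    if spacer < 0:
        raise ValueError("spacer must be >= 0")
    thr = _threshold(half_site_pwm, threshold_fraction)
    m = len(half_site_pwm)
    gap = m + spacer
    rc = half_site_pwm.reverse_complement()
    labels = ["none"] * len(sequences)
    for length, idx in _grouped_by_length(sequences).items():
        if length < m:
            continue
        encoded = np.stack([encode(sequences[i]) for i in idx])
        plus = _window_scores(encoded, half_site_pwm) >= thr
        minus = _window_scores(encoded, rc) >= thr
        n_windows = plus.shape[1]
        if n_windows > gap:
            full = (plus[:, : n_windows - gap] & minus[:, gap:]).any(axis=1)
        else:
            full = np.zeros(len(idx), dtype=bool)
        any_hit = plus.any(axis=1) | minus.any(axis=1)
        for row, i in enumerate(idx):
            labels[i] = "full" if full[row] else ("half" if any_hit[row] else "none")
    return labels


def classify_ere(
    sequence: str,
    half_site_pwm: PWM,
    spacer: int = 3,
    threshold_fraction: float = 0.8,
) -> str:
    return classify_ere_many([sequence], half_site_pwm, spacer, threshold_fraction)[0]


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    group_id: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    score: float
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"inconsistent counts k={self.k}, n={self.n}, K={self.K}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of range: {self.p_value}")


def enrichment_from_counts(
    k: int,
    n: int,
    K: int,
    N: int,
    motif_id: str = "",
    group_id: str = "",
    method: str = "hypergeom",
) -> EnrichmentResult:
    """Upper-tail enrichment p-value P(X >= k) for k motif-positive regions
    out of n, drawn from a background of N regions of which K are positive."""
    if not (0 <= n <= N and 0 <= K <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"invalid counts k={k}, n={n}, K={K}, N={N}")
    if method not in ("hypergeom", "binom"):
        raise ValueError(f"unknown enrichment method {method!r}")
    if k == 0:
        p = 1.0  # P(X >= 0) = 1, also covers degenerate N = 0
    elif method == "hypergeom":
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    else:
        p = float(stats.binom.sf(k - 1, n, K / N))
    p = min(max(p, _P_FLOOR), 1.0)
    return EnrichmentResult(
        motif_id=motif_id, group_id=group_id, k=k, n=n, K=K, N=N,
        p_value=p, score=float(-np.log10(p)),
    )


def enrichment_test(
    group: Mapping[str, bool],
    background: Mapping[str, bool],
    motif_id: str = "",
    group_id: str = "",
    method: str = "hypergeom",
) -> EnrichmentResult:
    """Enrichment of a motif within a region group against a background.

    Both arguments map region name -> motif presence; the group's regions
    must be a subset of the background's.
    """
    if not set(group).issubset(background):
        extra = sorted(set(group) - set(background))
        raise ValueError(f"group regions not in background: {extra[:5]}")
    k = sum(bool(v) for v in group.values())
    n = len(group)
    K = sum(bool(v) for v in background.values())
    N = len(background)
    return enrichment_from_counts(k, n, K, N, motif_id, group_id, method)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass(frozen=True)
class DifferentialMotif:
    motif_id: str
    delta: float
    mutant_score: float
    wildtype_score: float
    flagged: bool


def differential_enrichment(
    mutant: Iterable[EnrichmentResult],
    wildtype: Iterable[EnrichmentResult],
    delta_min: float = 10.0,
) -> list[DifferentialMotif]:
    """Per-motif enrichment-score difference (mutant minus wildtype).

    Motifs present on only one side contribute score 0 on the missing side
    (with a warning). Output is sorted by delta descending, ties broken by
    motif id.
    """
    mutant_scores = {r.motif_id: r.score for r in mutant}
    wt_scores = {r.motif_id: r.score for r in wildtype}
    only_one_side = set(mutant_scores) ^ set(wt_scores)
    if only_one_side:
        warnings.warn(
            f"motifs present on one side only (scored 0 on the other): "
            f"{sorted(only_one_side)[:5]}",
            stacklevel=2,
        )
    rows = []
    for motif_id in set(mutant_scores) | set(wt_scores):
        ms = mutant_scores.get(motif_id, 0.0)
        ws = wt_scores.get(motif_id, 0.0)
        delta = ms - ws
        rows.append(DifferentialMotif(motif_id, delta, ms, ws, delta >= delta_min))
    rows.sort(key=lambda r: (-r.delta, r.motif_id))
    return rows


def top_enriched(results: Iterable[EnrichmentResult], k: int) -> list[EnrichmentResult]:
    """The k highest-scoring motifs; ties broken by motif id ascending."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(results, key=lambda r: (-r.score, r.motif_id))
    return ordered[:k]
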