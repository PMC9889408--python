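import math

import numpy as np
import pytest

from eracr.motif import (
    ALPHABET,
    EnrichmentResult,
    MotifFormatError,
    PWM,
    bh_adjust,
    classify_ere,
    classify_ere_many,
    differential_enrichment,
    enrichment_from_counts,
    enrichment_test,
    load_motifs,
    reverse_complement,
    scan,
    scan_presence,
    top_enriched,
)


# ---------------------------------------------------------------------------
# Naive oracles
# ---------------------------------------------------------------------------

def naive_window_score(pwm, window):
    score = 0.0
    for j, base in enumerate(window):
        if base not in ALPHABET:
            return -math.inf
        score += math.log2(pwm.matrix[j, ALPHABET.index(base)] / pwm.background[ALPHABET.index(base)])
    return score


def naive_scan(pwm, sequence, threshold_fraction):
    thr = threshold_fraction * pwm.max_score - 1e-9
    m = len(pwm)
    hits = []
    for offset in range(len(sequence) - m + 1):
        window = sequence[offset : offset + m]
        plus = naive_window_score(pwm, window)
        if plus >= thr:
            hits.append((offset, "+"))
        minus = naive_window_score(pwm, reverse_complement(window))
        if minus >= thr:
            hits.append((offset, "-"))
    return sorted(hits)


def naive_classify_ere(sequence, half_pwm, spacer, threshold_fraction):
    hits = naive_scan(half_pwm, sequence, threshold_fraction)
    plus = [o for o, s in hits if s == "+"]
    minus = [o for o, s in hits if s == "-"]
    m = len(half_pwm)
    for p in plus:
        for q in minus:
            if q - (p + m) == spacer:
                return "full"
    return "half" if hits else "none"


def naive_hypergeom_upper(k, N, K, n):
    total = 0.0
    for x in range(k, min(n, K) + 1):
        total += (
            math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        )
    return min(total, 1.0)


def random_seq(rng, length, with_n=False):
    bases = "ACGTN" if with_n else "ACGT"
    p = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(bases), size=length, p=p))


# ---------------------------------------------------------------------------
# PWM model and motif I/O
# ---------------------------------------------------------------------------

class TestPWM:
    def test_from_counts_normalizes(self):
        counts = np.array([[97, 1, 1, 1]] * 5)
        pwm = PWM.from_counts("m", counts)
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0)
        assert pwm.consensus == "AAAAA"

    def test_min_length(self):
        with pytest.raises(MotifFormatError):
            PWM("m", np.full((3, 4), 0.25))

    def test_rows_must_sum_to_one(self):
        bad = np.full((5, 4), 0.3)
        with pytest.raises(MotifFormatError):
            PWM("m", bad)

    def test_reverse_complement_consensus(self):
        counts = np.eye(4)[[0, 2, 2, 3, 1, 0]] * 100  # AGGTCA
        pwm = PWM.from_counts("m", counts)
        assert pwm.reverse_complement().consensus == "TGACCT"

    def test_jaspar_load(self, tmp_path, pwms):
        assert set(pwms) == {"FOX_LIKE", "ERE_HALF", "AP1_LIKE", "NHR_LIKE", "GATA_LIKE"}
        assert pwms["FOX_LIKE"].consensus == "TGTTTAC"
        assert len(pwms["FOX_LIKE"]) == 7
        assert np.allclose(pwms["ERE_HALF"].matrix.sum(axis=1), 1.0)

    def test_jaspar_duplicate_id_rejected(self, tmp_path):
        block = ">M1 M1\nA [ 9 1 1 1 ]\nC [ 1 9 1 1 ]\nG [ 1 1 9 1 ]\nT [ 1 1 1 9 ]\n"
        path = tmp_path / "dup.jaspar"
        path.write_text(block + block)
        with pytest.raises(MotifFormatError, match="duplicate"):
            load_motifs(path, format="jaspar")

    def test_meme_minimal_load(self, tmp_path):
        path = tmp_path / "toy.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF TOY1\nletter-probability matrix: alength= 4 w= 4 nsites= 20 E= 0\n"
            " 0.85 0.05 0.05 0.05\n 0.05 0.85 0.05 0.05\n"
            " 0.05 0.05 0.85 0.05\n 0.05 0.05 0.05 0.85\n"
        )
        pwms = load_motifs(path, format="meme")
        assert len(pwms) == 1
        assert pwms[0].consensus == "ACGT"


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

class TestScan:
    def test_background_pwm_scores_zero(self):
        pwm = PWM("flat", np.full((5, 4), 0.25))
        hits = scan(pwm, "ACGTACGTACGT", threshold_fraction=1.0)
        assert pwm.max_score == 0.0
        # every window on both strands scores exactly 0 = threshold
        assert len(hits) == 2 * (12 - 5 + 1)
        assert all(h.score == 0.0 for h in hits)

    def test_perfect_consensus_at_threshold_one(self, fox_pwm):
        seq = "A" * 10 + "TGTTTAC" + "A" * 10
        hits = scan(fox_pwm, seq, threshold_fraction=1.0)
        assert [(h.offset, h.strand) for h in hits] == [(10, "+")]

    def test_minus_strand_hit(self, fox_pwm):
        seq = "A" * 10 + reverse_complement("TGTTTAC") + "A" * 10
        hits = scan(fox_pwm, seq, threshold_fraction=1.0)
        assert [(h.offset, h.strand) for h in hits] == [(10, "-")]

    def test_sequence_shorter_than_motif(self, fox_pwm):
        assert scan(fox_pwm, "ACG", 0.8) == []

    def test_window_with_n_never_hits(self, fox_pwm):
        assert scan(fox_pwm, "TGTNTAC", threshold_fraction=0.5) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_naive_oracle(self, seed, pwms):
        rng = np.random.default_rng(seed)
        for pwm in pwms.values():
            for with_n in (False, True):
                seq = random_seq(rng, 200, with_n=with_n)
                got = sorted((h.offset, h.strand) for h in scan(pwm, seq, 0.7))
                assert got == naive_scan(pwm, seq, 0.7)

    def test_strand_swap_symmetry(self, pwms):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 150) + "TGTTTAC" + random_seq(rng, 40)
        for pwm in pwms.values():
            m = len(pwm)
            forward = {(h.offset, h.strand) for h in scan(pwm, seq, 0.75)}
            mirrored = {
                (len(seq) - m - o, "-" if s == "+" else "+")
                for o, s in (
                    (h.offset, h.strand)
                    for h in scan(pwm, reverse_complement(seq), 0.75)
                )
            }
            assert forward == mirrored

    def test_scan_presence_matches_scan(self, pwms):
        rng = np.random.default_rng(6)
        seqs = [random_seq(rng, int(rng.integers(10, 120))) for _ in range(30)]
        seqs[3] = seqs[3][:20] + "TGTTTAC" + seqs[3][27:]
        for pwm in pwms.values():
            expected = [bool(scan(pwm, s, 0.8)) for s in seqs]
            assert list(scan_presence(pwm, seqs, 0.8)) == expected

    def test_threshold_fraction_validation(self, fox_pwm):
        with pytest.raises(ValueError):
            scan(fox_pwm, "ACGTACGT", threshold_fraction=0.0)


# ---------------------------------------------------------------------------
# ERE classification
# ---------------------------------------------------------------------------

class TestClassifyEre:
    def test_full_site(self, half_pwm):
        assert classify_ere("CCCC" + "AGGTCA" + "TTT" + "TGACCT" + "CCCC", half_pwm) == "full"

    def test_half_site(self, half_pwm):
        assert classify_ere("CCCCAGGTCACCCC", half_pwm) == "half"

    def test_minus_only_half(self, half_pwm):
        assert classify_ere("CCCCTGACCTCCCC", half_pwm) == "half"

    def test_none(self, half_pwm):
        assert classify_ere("CCCCCCCCCCCCCC", half_pwm) == "none"

    def test_wrong_spacer_is_half(self, half_pwm):
        assert classify_ere("CCCC" + "AGGTCA" + "TT" + "TGACCT" + "CCCC", half_pwm, spacer=3) == "half"
        assert classify_ere("CCCC" + "AGGTCA" + "TT" + "TGACCT" + "CCCC", half_pwm, spacer=2) == "full"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pair_enumeration_oracle(self, seed, half_pwm):
        rng = np.random.default_rng(seed)
        seqs = []
        for _ in range(40):
            seq = list(random_seq(rng, 120))
            # plant a random number of half sites to exercise all labels
            for _ in range(int(rng.integers(0, 3))):
                site = "AGGTCA" if rng.random() < 0.5 else "TGACCT"
                off = int(rng.integers(0, 114))
                seq[off : off + 6] = site
            seqs.append("".join(seq))
        got = classify_ere_many(seqs, half_pwm, spacer=3, threshold_fraction=0.9)
        expected = [naive_classify_ere(s, half_pwm, 3, 0.9) for s in seqs]
        assert got == expected


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

class TestEnrichment:
    def test_motif_absent_everywhere(self):
        r = enrichment_from_counts(0, 10, 0, 30)
        assert r.p_value == 1.0
        assert r.score == 0.0

    def test_group_equals_background(self):
        r = enrichment_from_counts(10, 30, 10, 30)
        assert r.p_value == pytest.approx(1.0)

    def test_exact_pmf_sum_example(self):
        r = enrichment_from_counts(8, 10, 10, 30)
        assert r.p_value == pytest.approx(naive_hypergeom_upper(8, 30, 10, 10), rel=1e-12)
        assert r.score == pytest.approx(-math.log10(r.p_value))

    def test_monotone_in_k(self):
        scores = [enrichment_from_counts(k, 10, 12, 40).score for k in range(11)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError, match="not in background"):
            enrichment_test({"a": True}, {"b": True})

    def test_counts_from_flags(self):
        group = {"a": True, "b": False, "c": True}
        background = {**group, "d": False, "e": True}
        r = enrichment_test(group, background, motif_id="m", group_id="g")
        assert (r.k, r.n, r.K, r.N) == (2, 3, 3, 5)

    def test_binomial_alternative(self):
        r = enrichment_from_counts(5, 10, 50, 100, method="binom")
        from scipy import stats

        assert r.p_value == pytest.approx(float(stats.binom.sf(4, 10, 0.5)))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            enrichment_from_counts(5, 4, 10, 30)

    def test_result_invariants(self):
        with pytest.raises(ValueError):
            EnrichmentResult("m", "g", k=5, n=4, K=10, N=30, p_value=0.5, score=0.3)


def make_result(motif_id, score):
    p = 10.0 ** (-score)
    return EnrichmentResult(motif_id, "g", 0, 1, 0, 1, p_value=min(p, 1.0), score=score)


class TestDifferential:
    def test_identical_scores_nothing_flagged(self):
        results = [make_result("a", 5.0), make_result("b", 7.0)]
        out = differential_enrichment(results, results, delta_min=0.1)
        assert all(not r.flagged for r in out)
        assert all(r.delta == 0.0 for r in out)

    def test_flagging_and_delta(self):
        out = differential_enrichment(
            [make_result("a", 30.0)], [make_result("a", 5.0)], delta_min=10.0
        )
        assert out[0].flagged and out[0].delta == pytest.approx(25.0)

    def test_missing_side_warns_and_scores_zero(self):
        with pytest.warns(UserWarning, match="one side only"):
            out = differential_enrichment([make_result("a", 12.0)], [], delta_min=10.0)
        assert out[0].delta == pytest.approx(12.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_recompute_oracle(self, seed):
        rng = np.random.default_rng(seed)
        motifs = [f"m{i}" for i in range(20)]
        mutant = [make_result(m, float(rng.uniform(0, 40))) for m in motifs]
        wildtype = [make_result(m, float(rng.uniform(0, 40))) for m in motifs]
        out = differential_enrichment(mutant, wildtype, delta_min=8.0)
        mut = {r.motif_id: r.score for r in mutant}
        wt = {r.motif_id: r.score for r in wildtype}
        expected_flags = {m: mut[m] - wt[m] >= 8.0 for m in motifs}
        assert {r.motif_id: r.flagged for r in out} == expected_flags
        deltas = [r.delta for r in out]
        assert deltas == sorted(deltas, reverse=True)


class TestTopEnriched:
    def test_k_exceeds_available(self):
        results = [make_result("a", 1.0), make_result("b", 2.0), make_result("c", 3.0)]
        assert len(top_enriched(results, 5)) == 3

    def test_tie_break_lexicographic(self):
        results = [make_result("b", 2.0), make_result("a", 2.0), make_result("c", 9.0)]
        assert [r.motif_id for r in top_enriched(results, 2)] == ["c", "a"]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        results = [make_result(f"m{i}", float(rng.integers(0, 5))) for i in range(30)]
        got = [r.motif_id for r in top_enriched(results, 5)]
        expected = [
            r.motif_id for r in sorted(results, key=lambda r: (-r.score, r.motif_id))[:5]
        ]
        assert got == expected


def test_bh_adjust_known_values():
    p = [0.01, 0.02, 0.03, 0.04]
    adjusted = bh_adjust(p)
    assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])
    assert list(bh_adjust([])) == []
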