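"""Ortholog pairing: FASTA loading, the seed-and-extend aligner and clipping."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from glandscope.pairing import (
    ClippedRegion,
    OrthologPair,
    Transcript,
    banded_local_align,
    clip_overlap,
    find_ortholog_pairs,
    load_transcripts,
)
from glandscope.pairing import _align_candidate, _kmers

from conftest import random_dna


def full_smith_waterman(a, b, match=1, mis=-2, gap=-3):
    """Quadratic Smith-Waterman with linear gaps: the alignment oracle.

    Same scoring and tie-breaks as the production aligner: best cell is the
    first maximum in (i asc, j asc), traceback prefers diag, up, left.
    """
    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    P = [[0] * (n + 1) for _ in range(m + 1)]
    best = (0, 0, 0)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mis
            sc, p = H[i - 1][j - 1] + s, 1
            if H[i - 1][j] + gap > sc:
                sc, p = H[i - 1][j] + gap, 2
            if H[i][j - 1] + gap > sc:
                sc, p = H[i][j - 1] + gap, 3
            if sc <= 0:
                sc, p = 0, 0
            H[i][j], P[i][j] = sc, p
            if sc > best[0]:
                best = (sc, i, j)
    sc, i, j = best
    if sc <= 0:
        return None
    cols = matches = 0
    ei, ej = i, j
    while i >= 1 and j >= 1 and P[i][j] != 0:
        p = P[i][j]
        if p == 1:
            cols += 1
            matches += a[i - 1] == b[j - 1] and a[i - 1] != "N"
            i -= 1
            j -= 1
        elif p == 2:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return sc, matches, cols, (i + 1, ei), (j + 1, ej)


def production_alignment(a, b, k=12):
    idx = {}
    for kmer, pos in _kmers(b, k):
        idx.setdefault(kmer, []).append(pos)
    diags = sorted(
        {pos - wp for kmer, pos in _kmers(a, k) for wp in idx.get(kmer, ())}
    )
    if not diags:
        return None
    return _align_candidate(a, b, diags)


class TestLoadTranscripts:
    def test_parses_and_uppercases(self, tmp_path):
        fa = tmp_path / "in.fasta"
        fa.write_text(">a\nacgTACGT\nACGT\n>b\nTTTT\n")
        ts = load_transcripts(fa)
        assert [t.id for t in ts] == ["a", "b"]
        assert ts[0].seq == "ACGTACGTACGT"
        assert ts[0].length == 12 and ts[1].length == 4

    def test_duplicate_id_is_an_error(self, tmp_path):
        fa = tmp_path / "dup.fasta"
        fa.write_text(">x\nACGT\n>x\nTTTT\n")
        with pytest.raises(ValueError, match="x"):
            load_transcripts(fa)

    def test_empty_sequence_is_an_error(self, tmp_path):
        fa = tmp_path / "empty.fasta"
        fa.write_text(">x\n\n>y\nACGT\n")
        with pytest.raises(ValueError, match="x"):
            load_transcripts(fa)


class TestFindOrthologPairs:
    def test_identical_sequence_self_match(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 200)
        pairs = find_ortholog_pairs(
            [Transcript("s1", seq)], [Transcript("w1", seq)]
        )
        assert len(pairs) == 1
        p = pairs[0]
        assert p.identity == 1.0 and p.overlap_len == 200
        assert p.sg_span == (1, 200) and p.wb_span == (1, 200)

    def test_short_shared_block_rejected(self):
        rng = np.random.default_rng(1)
        shared = random_dna(rng, 100)
        sg = Transcript("s", random_dna(rng, 120) + shared)
        wb = Transcript("w", shared + random_dna(rng, 120))
        assert find_ortholog_pairs([sg], [wb]) == []

    @pytest.mark.parametrize("n_mismatches,accepted", [(2, True), (3, False)])
    def test_identity_strictly_above_99_percent(self, n_mismatches, accepted):
        """300 columns with 2 mismatches is 298/300 > 0.99; with 3 interior
        mismatches identity is exactly 0.99, which the strict rule rejects."""
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 300)
        mut = list(seq)
        # interior positions, >2 bp from the ends so no end-trimming applies
        for pos in (60, 150, 240)[:n_mismatches]:
            mut[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[pos]]
        pairs = find_ortholog_pairs(
            [Transcript("s", "".join(mut))], [Transcript("w", seq)]
        )
        oracle = full_smith_waterman("".join(mut), seq)
        assert oracle[2] == 300 and oracle[1] == 300 - n_mismatches
        if accepted:
            assert len(pairs) == 1
            assert pairs[0].identity == pytest.approx((300 - n_mismatches) / 300)
        else:
            assert pairs == []

    def test_one_pair_per_gene_best_identity_wins(self):
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 300)
        near = list(seq)
        near[150] = {"A": "C", "C": "G", "G": "T", "T": "A"}[near[150]]
        sg = [Transcript("s", seq)]
        wb = [Transcript("w_exact", seq), Transcript("w_near", "".join(near))]
        pairs = find_ortholog_pairs(sg, wb)
        assert len(pairs) == 1 and pairs[0].wb_id == "w_exact"

    def test_symmetry_under_role_swap(self):
        rng = np.random.default_rng(4)
        sg, wb = [], []
        for i in range(12):
            seq = random_dna(rng, int(rng.integers(200, 400)))
            mut, _ = list(seq), None
            for pos in rng.integers(10, len(seq) - 10, size=rng.integers(0, 3)):
                mut[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[pos]]
            sg.append(Transcript(f"s{i}", "".join(mut)))
            wb.append(Transcript(f"w{i}", seq))
        fwd = find_ortholog_pairs(sg, wb)
        rev = find_ortholog_pairs(wb, sg)
        assert {(p.sg_id, p.wb_id) for p in fwd} == {
            (q.wb_id, q.sg_id) for q in rev
        }
        rev_by = {(q.wb_id, q.sg_id): q for q in rev}
        for p in fwd:
            q = rev_by[(p.sg_id, p.wb_id)]
            assert p.identity == q.identity and p.overlap_len == q.overlap_len
            assert p.sg_span == q.wb_span and p.wb_span == q.sg_span

    def test_reverse_complement_only_found_with_flag(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 250)
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        sg, wb = [Transcript("s", rc)], [Transcript("w", seq)]
        assert find_ortholog_pairs(sg, wb) == []
        pairs = find_ortholog_pairs(sg, wb, search_reverse=True)
        assert len(pairs) == 1 and pairs[0].overlap_len == 250


class TestAlignerOracle:
    def test_matches_full_dp_on_random_instances(self):
        """Seeded random pairs up to 500 bp with substitutions and small
        indels: banded seed-and-extend equals quadratic Smith-Waterman."""
        n_checked = 0
        for trial in range(60):
            rng = np.random.default_rng(1000 + trial)
            length = int(rng.integers(60, 500))
            a = random_dna(rng, length)
            b = list(a)
            for pos in rng.integers(0, len(b), size=rng.integers(0, 6)):
                b[pos] = "ACGT"[rng.integers(0, 4)]
            b = "".join(b)
            if rng.random() < 0.5 and len(b) > 40:
                cut = int(rng.integers(15, len(b) - 15))
                b = b[:cut] + b[cut + int(rng.integers(1, 3)):]
            mine = production_alignment(a, b)
            if mine is None:
                continue
            assert mine == full_smith_waterman(a, b)
            n_checked += 1
        assert n_checked >= 50

    def test_n_bases_never_match(self):
        # one interior N: spanning it (11 matches - 2) beats either flank,
        # but the N column itself counts as a mismatch
        seq = "ACGTANGTACGT"
        score, matches, columns, *_ = banded_local_align(seq, seq, -3, 3)
        assert columns == 12 and matches == 11
        assert score == 11 - 2


class TestRecoveryStatistics:
    def test_pair_recovery_matches_binomial_prediction(self):
        """Orthologs of length 300 mutated at per-base rate 0.005 keep
        identity > 99% iff they carry <= 2 mismatches, so the recovered
        fraction must sit in the 99% binomial band of P(Bin(300, 0.005) <= 2)."""
        n_pairs, length, rate = 400, 300, 0.005
        rng = np.random.default_rng(42)
        recovered = 0
        for _ in range(n_pairs):
            seq = random_dna(rng, length)
            mut = list(seq)
            for pos in np.flatnonzero(rng.random(length) < rate):
                mut[pos] = "ACGT"[(("ACGT".index(mut[pos])) + 1 + rng.integers(0, 3)) % 4]
            pairs = find_ortholog_pairs(
                [Transcript("s", "".join(mut))], [Transcript("w", seq)]
            )
            recovered += bool(pairs)
        p0 = stats.binom.cdf(2, length, rate)
        lo = stats.binom.ppf(0.005, n_pairs, p0) / n_pairs
        hi = stats.binom.ppf(0.995, n_pairs, p0) / n_pairs
        assert lo <= recovered / n_pairs <= hi


class TestClipOverlap:
    def _pair(self, sg_span, wb_span, overlap):
        return OrthologPair("s", "w", 1.0, overlap, sg_span, wb_span)

    def test_full_length_identity_pair(self):
        rng = np.random.default_rng(6)
        seq = random_dna(rng, 180)
        region = clip_overlap(
            self._pair((1, 180), (1, 180), 180),
            Transcript("s", seq), Transcript("w", seq),
        )
        assert region.sg_region_seq == seq and region.wb_region_seq == seq

    def test_offset_spans_extract_the_aligned_substrings(self):
        rng = np.random.default_rng(7)
        shared = random_dna(rng, 200)
        sg = Transcript("s", random_dna(rng, 50) + shared)
        wb = Transcript("w", shared)
        region = clip_overlap(self._pair((51, 250), (1, 200), 200), sg, wb)
        assert region.len_sg == region.len_wb == 200
        assert region.sg_region_seq == shared == region.wb_region_seq

    def test_span_outside_transcript_is_an_error(self):
        t = Transcript("s", "ACGTACGT")
        w = Transcript("w", "ACGTACGT")
        with pytest.raises(ValueError, match="span"):
            clip_overlap(self._pair((1, 9), (1, 8), 8), t, w)

    def test_mismatched_ids_are_an_error(self):
        t = Transcript("other", "ACGT")
        with pytest.raises(ValueError, match="does not match"):
            clip_overlap(self._pair((1, 4), (1, 4), 4), t, Transcript("w", "ACGT"))
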