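"""CDS extraction, topology parsing, the secretion retention rule and
homolog filtering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from glandscope.pairing import Transcript
from glandscope.secretome import (
    INCOMPLETE,
    MEMBRANE,
    NO_SIGNAL,
    SECRETED,
    BLAST_COLUMNS,
    CodingSequence,
    TopologyCall,
    classify_secretion,
    extract_cds,
    filter_homologs,
    load_topology,
    read_blast_tabular,
    toy_topology,
    triage_batch,
)
from glandscope.simulate import (
    SyntheticTruth,
    simulate_secretome_proteins,
    simulate_transcriptomes,
    simulate_annotations_and_topology,
)


def dna_for(protein: str, stop: bool = True) -> str:
    table = {
        "M": "ATG", "K": "AAA", "L": "CTG", "S": "TCT", "G": "GGT",
        "V": "GTT", "A": "GCT", "I": "ATT", "F": "TTT", "D": "GAT",
        "E": "GAA", "N": "AAT", "T": "ACT", "R": "CGT", "H": "CAT",
        "Q": "CAA", "P": "CCT", "W": "TGG", "Y": "TAT", "C": "TGT",
    }
    return "".join(table[aa] for aa in protein) + ("TAA" if stop else "")


class TestExtractCds:
    def test_single_orf_spanning_whole_sequence(self):
        protein = "M" + "KLSGVAIFDENTRHQ" * 3
        t = Transcript("g1", dna_for(protein))
        cds = extract_cds(t)
        assert cds is not None
        assert cds.frame == 1 and cds.complete_5p
        assert cds.protein == protein
        assert cds.cds_span == (1, 3 * len(protein))
        # invariant: translating the span in the stated frame == protein
        assert str(Seq(t.seq[cds.cds_span[0] - 1 : cds.cds_span[1]]).translate()) == protein

    def test_reverse_frame_hit_reports_forward_coordinates(self):
        """A 60 bp toy whose coding strand is the reverse complement: the
        protein must equal the manual reverse-complement translation and the
        span must be on the forward transcript."""
        protein = "MKLSGVAIFDENTRHQWYCP"
        fwd_cds = dna_for(protein, stop=False)  # 60 bp
        t = Transcript("g2", str(Seq(fwd_cds).reverse_complement()))
        hit = pd.DataFrame(
            [["g2", "sbj", 100.0, 20, 0, 0, 60, 1, 1, 20, 1e-30, 120.0]],
            columns=BLAST_COLUMNS,
        )
        cds = extract_cds(t, hit)
        assert cds is not None and cds.frame < 0
        manual = str(Seq(t.seq).reverse_complement().translate())
        assert cds.protein in manual
        assert cds.protein == protein
        lo, hi = cds.cds_span
        assert str(Seq(t.seq[lo - 1 : hi]).reverse_complement().translate()) == protein

    def test_five_prime_truncated_cds_flagged_incomplete(self):
        # open reading through the 5' end with no ATG anywhere upstream
        protein = "KLSGVAIFDENTRHQWYCPKLSGVAIFDENT"
        t = Transcript("g3", dna_for(protein))
        cds = extract_cds(t)
        assert cds is not None and not cds.complete_5p
        assert cds.protein.startswith("KLSG")

    def test_no_orf_returns_none(self):
        t = Transcript("g4", "TAATAGTGATAATAGTGA" * 3)
        assert extract_cds(t) is None

    def test_blast_anchor_overrides_longer_orf_elsewhere(self):
        anchored = "MKLSGVAIFDENTRHQWYCPKLSG"
        decoy = "M" + "KLSGVAIFDENTRHQWYCP" * 3
        seq = dna_for(anchored) + dna_for(decoy)
        t = Transcript("g5", seq)
        qstart = 1 + 3  # inside the anchored ORF, frame +1
        hit = pd.DataFrame(
            [["g5", "sbj", 95.0, 20, 1, 0, qstart, qstart + 59, 1, 20, 1e-20, 90.0]],
            columns=BLAST_COLUMNS,
        )
        cds = extract_cds(t, hit)
        assert cds.protein == anchored


class TestTopologyParsing:
    def test_tmhmm_short_format(self, tmp_path):
        f = tmp_path / "tm.txt"
        f.write_text(
            "g1\tlen=227\tExpAA=44.8\tFirst60=0.0\tPredHel=2\tTopology=o5-27i33-55o\n"
            "g2\tlen=120\tExpAA=0.1\tFirst60=0.0\tPredHel=0\tTopology=o\n"
        )
        calls = load_topology(tm_path=f)
        assert calls["g1"].tm_segments == [(5, 27), (33, 55)]
        assert calls["g2"].tm_segments == []

    def test_tmhmm_predhel_mismatch_is_an_error(self, tmp_path):
        f = tmp_path / "tm.txt"
        f.write_text("g1\tlen=100\tExpAA=20\tFirst60=0\tPredHel=2\tTopology=o5-27i\n")
        with pytest.raises(ValueError, match="line 1"):
            load_topology(tm_path=f)

    def test_signalp3_short_format(self, tmp_path):
        f = tmp_path / "sp.txt"
        f.write_text(
            "# SignalP-3.0 euk predictions\n"
            "g1  0.936  22 Y  0.902  22 Y  0.957  14 Y  0.845 Y  0.873 Y\n"
            "g2  0.193  36 N  0.097  36 N  0.119   1 N  0.087 N  0.092 N\n"
        )
        calls = load_topology(sp_path=f)
        assert calls["g1"].sp_present and calls["g1"].cleavage_pos == 22
        assert not calls["g2"].sp_present

    def test_canonical_tsvs_combined(self, tmp_path):
        sp = tmp_path / "sp.tsv"
        sp.write_text("gene_id\tsp_present\tcleavage_pos\ng1\tY\t23\ng2\tN\t0\n")
        tm = tmp_path / "tm.tsv"
        tm.write_text("gene_id\ttm_start\ttm_end\ng1\t30\t52\ng1\t7\t24\n")
        calls = load_topology(sp, tm)
        assert calls["g1"].sp_present and calls["g1"].cleavage_pos == 23
        assert calls["g1"].tm_segments == [(7, 24), (30, 52)]
        assert not calls["g2"].sp_present and calls["g2"].tm_segments == []


def _cds(gene_id="g", complete=True):
    return CodingSequence(gene_id, 1, (1, 30), "M" + "A" * 9, complete)


class TestClassifySecretion:
    def test_no_signal_peptide(self):
        v = classify_secretion(_cds(), TopologyCall("g", sp_present=False))
        assert v.verdict == NO_SIGNAL

    def test_sp_and_no_tm_is_secreted(self):
        v = classify_secretion(
            _cds(), TopologyCall("g", sp_present=True, cleavage_pos=20)
        )
        assert v.verdict == SECRETED

    def test_single_tm_inside_sp_is_secreted_outside_is_membrane(self):
        # cleavage at 23: signal peptide = residues 1..22
        inside = TopologyCall("g", True, 23, [(7, 24)])
        outside = TopologyCall("g", True, 23, [(30, 52)])
        assert classify_secretion(_cds(), inside).verdict == SECRETED
        assert classify_secretion(_cds(), outside).verdict == MEMBRANE

    def test_two_tms_always_membrane(self):
        topo = TopologyCall("g", True, 23, [(5, 20), (40, 60)])
        assert classify_secretion(_cds(), topo).verdict == MEMBRANE

    def test_incomplete_5p_overrides_everything(self):
        topo = TopologyCall("g", True, 20, [])
        v = classify_secretion(_cds(complete=False), topo)
        assert v.verdict == INCOMPLETE

    def test_batch_accounting_identity(self):
        """356 SP-positive complete candidates, 61 with an extra TM: the
        retention rule keeps 356 - 61 = 295."""
        cdss, topology = [], {}
        for i in range(356):
            gid = f"c{i:03d}"
            cdss.append(_cds(gid))
            tm = [(60, 80)] if i < 61 else []
            topology[gid] = TopologyCall(gid, True, 22, tm)
        verdicts, summary = triage_batch(cdss, topology)
        assert summary["sp_positive_complete"] == 356
        assert summary["removed_by_tm"] == 61
        assert summary["secreted"] == 295
        # order independence
        _, reversed_summary = triage_batch(list(reversed(cdss)), topology)
        assert reversed_summary == summary


class TestFilterHomologs:
    def _hits(self):
        rows = [
            ["q1", "s1", 90.0, 100, 5, 0, 1, 100, 1, 100, 1e-4, 50.0],
            ["q2", "s1", 95.0, 100, 3, 0, 1, 100, 1, 100, 1e-6, 80.0],
            ["q3", "s1", 97.0, 100, 2, 0, 1, 100, 1, 100, 1e-6, 70.0],
            ["q3", "s2", 99.0, 100, 1, 0, 1, 100, 1, 100, 1e-9, 95.0],
        ]
        return pd.DataFrame(rows, columns=BLAST_COLUMNS)

    def test_threshold_and_best_hit_dedup(self):
        best = filter_homologs(self._hits(), 1e-5)
        assert set(best["query"]) == {"q2", "q3"}  # q1 at 1e-4 excluded
        q3 = best[best["query"] == "q3"].iloc[0]
        assert q3["subject"] == "s2" and q3["evalue"] == 1e-9

    def test_non_numeric_evalue_is_an_error(self, tmp_path):
        f = tmp_path / "hits.tsv"
        f.write_text("q1\ts1\t90\t100\t5\t0\t1\t100\t1\t100\tnot_a_number\t50\n")
        with pytest.raises(ValueError):
            read_blast_tabular(f)


class TestToyPredictorRecovery:
    def test_planted_labels_recovered_without_crossover(self):
        """Synthetic proteins with hydrophobic N-terminal cores (planted
        secreted), interior TM stretches (planted membrane) or neither:
        triage with the toy hydropathy predictor reproduces every label."""
        _, _, truth = simulate_transcriptomes(80, 0, seed=5)
        truth.genes["planted_log2"] = 0.0
        simulate_annotations_and_topology(truth, seed=6)
        proteins = simulate_secretome_proteins(truth, seed=7)
        genes = truth.genes.set_index("sg_id")
        for gid, protein, _dna in proteins:
            topo = toy_topology(gid, protein)
            cds = CodingSequence(gid, 1, (1, 3 * len(protein)), protein, True)
            verdict = classify_secretion(cds, topo).verdict
            if genes.loc[gid, "secreted"]:
                assert verdict == SECRETED, gid
            elif genes.loc[gid, "extra_tm"]:
                assert verdict == MEMBRANE, gid
            else:
                assert verdict == NO_SIGNAL, gid
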