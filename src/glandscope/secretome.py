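"""Secretome triage: CDS extraction, topology parsing and the retention rule.

A candidate is a potential secreted protein when its predicted protein has a
signal peptide and either no transmembrane (TM) segment or exactly one that
coincides with the signal peptide itself.  A predicted protein whose CDS is
5'-incomplete (no in-frame start codon at the CDS start) cannot have its
signal peptide assessed and is set aside as ``incomplete_5p``.

CDS extraction is homology-guided where BLASTx hits are available (the best
hit fixes frame and region) and falls back to the longest open reading frame
otherwise.  Signal-peptide and TM predictions are consumed as files —
SignalP 3.0 short output, TMHMM short output, or canonical TSVs; a toy
hydropathy predictor is bundled so the triage can be exercised with no
external tools.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .pairing import Transcript

__all__ = [
    "CodingSequence",
    "TopologyCall",
    "SecretionVerdict",
    "BLAST_COLUMNS",
    "read_blast_tabular",
    "extract_cds",
    "load_topology",
    "classify_secretion",
    "triage_batch",
    "filter_homologs",
    "toy_topology",
]

BLAST_COLUMNS = [
    "query", "subject", "pident", "aln_len", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

STOP = "*"
MIN_ORF_CODONS = 30

SECRETED = "secreted"
MEMBRANE = "membrane_anchored"
NO_SIGNAL = "no_signal"
INCOMPLETE = "incomplete_5p"


@dataclass
class CodingSequence:
    gene_id: str
    frame: int  # +1..+3 forward, -1..-3 reverse
    cds_span: tuple[int, int]  # 1-based inclusive on the forward transcript
    protein: str
    complete_5p: bool


@dataclass
class TopologyCall:
    gene_id: str
    sp_present: bool
    cleavage_pos: int | None = None  # signal peptide = residues 1..pos-1
    tm_segments: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SecretionVerdict:
    gene_id: str
    verdict: str
    reason: str


# ---------------------------------------------------------------------------
# CDS extraction


def read_blast_tabular(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 12:
        raise ValueError(
            f"expected 12-column BLAST tabular, got {df.shape[1]} columns"
        )
    df.columns = BLAST_COLUMNS
    if not pd.api.types.is_numeric_dtype(df["evalue"]):
        raise ValueError("non-numeric E-value field in BLAST tabular input")
    return df


def _frame_offset(frame: int) -> int:
    return abs(frame) - 1


def _oriented(seq: str, frame: int) -> str:
    return str(Seq(seq).reverse_complement()) if frame < 0 else seq


def _codon_stretches(oriented: str, offset: int) -> list[tuple[int, int]]:
    """Maximal stop-free codon runs as (start_codon_idx, end_codon_idx)."""
    n_codons = (len(oriented) - offset) // 3
    stretches = []
    start = 0
    for ci in range(n_codons):
        codon = oriented[offset + 3 * ci : offset + 3 * ci + 3]
        if Seq(codon).translate() == STOP:
            if ci > start:
                stretches.append((start, ci - 1))
            start = ci + 1
    if n_codons > start:
        stretches.append((start, n_codons - 1))
    return stretches


def _codon(oriented: str, offset: int, ci: int) -> str:
    return oriented[offset + 3 * ci : offset + 3 * ci + 3]


def _cds_from_stretch(
    t: Transcript, frame: int, oriented: str, offset: int,
    stretch: tuple[int, int], anchor_ci: int | None,
) -> CodingSequence | None:
    """Build a CDS from a stop-free codon stretch.

    The CDS starts at the first in-frame ATG in the stretch (complete 5'),
    searching no further than *anchor_ci* when a homology anchor is given;
    with no ATG available the stretch itself is taken and the CDS is marked
    5'-incomplete.
    """
    s_ci, e_ci = stretch
    limit = e_ci if anchor_ci is None else min(anchor_ci, e_ci)
    atg_ci = None
    for ci in range(s_ci, limit + 1):
        if _codon(oriented, offset, ci) == "ATG":
            atg_ci = ci
            break
    if atg_ci is not None:
        start_ci, complete = atg_ci, True
    else:
        start_ci, complete = s_ci, False
    n_codons = e_ci - start_ci + 1
    if n_codons < 1:
        return None
    lo = offset + 3 * start_ci  # 0-based on oriented strand
    hi = offset + 3 * (e_ci + 1)  # exclusive
    protein = str(Seq(oriented[lo:hi]).translate())
    if not protein:
        return None
    if frame > 0:
        span = (lo + 1, hi)
    else:
        L = t.length
        span = (L - hi + 1, L - lo)
    return CodingSequence(
        gene_id=t.id, frame=frame, cds_span=span,
        protein=protein, complete_5p=complete,
    )


def extract_cds(
    t: Transcript, hits: pd.DataFrame | None = None
) -> CodingSequence | None:
    """Predict the coding sequence of a transcript.

    With BLASTx *hits* (12-column tabular rows for this query), the lowest-E
    hit (ties: highest bit score) fixes the frame and anchors the coding
    region; the CDS is the surrounding in-frame stop-free stretch, started
    at the first upstream in-frame ATG when one exists.  Without hits the
    longest ORF over all six frames is taken (minimum 30 codons).  Returns
    None when no acceptable CDS exists.
    """
    if hits is not None and len(hits):
        rows = hits[hits["query"] == t.id] if "query" in hits else hits
        if len(rows):
            best = rows.sort_values(
                ["evalue", "bitscore"], ascending=[True, False]
            ).iloc[0]
            qstart, qend = int(best["qstart"]), int(best["qend"])
            if qstart <= qend:
                frame = (qstart - 1) % 3 + 1
                anchor_fwd = qstart
            else:
                rc_start = t.length - qstart + 1
                frame = -((rc_start - 1) % 3 + 1)
                anchor_fwd = rc_start
            oriented = _oriented(t.seq, frame)
            offset = _frame_offset(frame)
            anchor_ci = (anchor_fwd - 1 - offset) // 3
            for stretch in _codon_stretches(oriented, offset):
                if stretch[0] <= anchor_ci <= stretch[1]:
                    return _cds_from_stretch(
                        t, frame, oriented, offset, stretch, anchor_ci
                    )
            return None

    best_cds: CodingSequence | None = None
    for frame in (1, 2, 3, -1, -2, -3):
        oriented = _oriented(t.seq, frame)
        offset = _frame_offset(frame)
        for stretch in _codon_stretches(oriented, offset):
            cds = _cds_from_stretch(t, frame, oriented, offset, stretch, None)
            if cds is None or len(cds.protein) < MIN_ORF_CODONS:
                continue
            if (
                best_cds is None
                or len(cds.protein) > len(best_cds.protein)
                or (
                    len(cds.protein) == len(best_cds.protein)
                    and cds.complete_5p and not best_cds.complete_5p
                )
            ):
                best_cds = cds
    return best_cds


# ---------------------------------------------------------------------------
# topology parsing


def _parse_signalp_short(path) -> dict[str, TopologyCall]:
    """SignalP 3.0 short (one line per protein; D-score decision is used,
    the Ymax position is taken as the cleavage site)."""
    calls: dict[str, TopologyCall] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 14:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=14 whitespace fields "
                    "of SignalP 3.0 short output"
                )
            try:
                ymax_pos = int(f[5])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: bad Ymax position {f[5]!r}"
                ) from exc
            d_flag = f[13]
            if d_flag not in ("Y", "N"):
                raise ValueError(
                    f"{path}: line {lineno}: bad D decision {d_flag!r}"
                )
            calls[f[0]] = TopologyCall(
                gene_id=f[0], sp_present=d_flag == "Y",
                cleavage_pos=ymax_pos if d_flag == "Y" else None,
            )
    return calls


_TM_INTERVAL = re.compile(r"(\d+)-(\d+)")


def _parse_tmhmm_short(path) -> dict[str, TopologyCall]:
    """TMHMM short format: `name len= ExpAA= First60= PredHel= Topology=`."""
    calls: dict[str, TopologyCall] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            kv = dict(
                part.split("=", 1) for part in f[1:] if "=" in part
            )
            if "PredHel" not in kv or "Topology" not in kv:
                raise ValueError(
                    f"{path}: line {lineno}: missing PredHel=/Topology= fields"
                )
            pred_hel = int(kv["PredHel"])
            segs = [
                (int(a), int(b)) for a, b in _TM_INTERVAL.findall(kv["Topology"])
            ]
            if len(segs) != pred_hel:
                raise ValueError(
                    f"{path}: line {lineno}: PredHel={pred_hel} but "
                    f"{len(segs)} intervals parsed from Topology"
                )
            calls[f[0]] = TopologyCall(
                gene_id=f[0], sp_present=False, tm_segments=sorted(segs)
            )
    return calls


def _parse_sp_tsv(path) -> dict[str, TopologyCall]:
    """Canonical TSV: `gene_id sp_present(Y/N) cleavage_pos`."""
    calls: dict[str, TopologyCall] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id"):
                continue
            f = line.split("\t")
            if len(f) < 3 or f[1] not in ("Y", "N"):
                raise ValueError(
                    f"{path}: line {lineno}: expected `gene_id Y/N cleavage_pos`"
                )
            present = f[1] == "Y"
            calls[f[0]] = TopologyCall(
                gene_id=f[0], sp_present=present,
                cleavage_pos=int(f[2]) if present else None,
            )
    return calls


def _parse_tm_tsv(path) -> dict[str, TopologyCall]:
    """Canonical TSV: `gene_id tm_start tm_end`, one segment per row."""
    calls: dict[str, TopologyCall] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected `gene_id tm_start tm_end`"
                )
            call = calls.setdefault(
                f[0], TopologyCall(gene_id=f[0], sp_present=False)
            )
            call.tm_segments.append((int(f[1]), int(f[2])))
    for call in calls.values():
        call.tm_segments.sort()
    return calls


def _sniff(path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.startswith("gene_id"):
                continue
            if "Topology=" in line:
                return "tmhmm"
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3 and f[1] in ("Y", "N"):
                return "sp_tsv"
            if len(f) == 3 and f[1].isdigit() and f[2].isdigit():
                return "tm_tsv"
            return "signalp"
    return "empty"


def load_topology(sp_path=None, tm_path=None) -> dict[str, TopologyCall]:
    """Combine a signal-peptide file and a TM file into per-gene calls.

    Each file may be SignalP 3.0 short output, TMHMM short output, or the
    canonical TSVs; the format is sniffed from the first data line.
    """
    parsers = {
        "signalp": _parse_signalp_short,
        "tmhmm": _parse_tmhmm_short,
        "sp_tsv": _parse_sp_tsv,
        "tm_tsv": _parse_tm_tsv,
        "empty": lambda p: {},
    }
    merged: dict[str, TopologyCall] = {}
    for path in (sp_path, tm_path):
        if path is None:
            continue
        for gid, call in parsers[_sniff(path)](path).items():
            tgt = merged.setdefault(
                gid, TopologyCall(gene_id=gid, sp_present=False)
            )
            if call.sp_present:
                tgt.sp_present = True
                tgt.cleavage_pos = call.cleavage_pos
            if call.tm_segments:
                tgt.tm_segments = sorted(
                    set(tgt.tm_segments) | set(call.tm_segments)
                )
    return merged


# ---------------------------------------------------------------------------
# classification


def _overlaps(seg: tuple[int, int], lo: int, hi: int) -> bool:
    return seg[0] <= hi and seg[1] >= lo and lo <= hi


def classify_secretion(cds: CodingSequence, topo: TopologyCall) -> SecretionVerdict:
    """Apply the retention rule to one candidate.

    Secreted: signal peptide present and no TM segment, or exactly one TM
    segment that overlaps the signal peptide (residues 1..cleavage_pos-1).
    A 5'-incomplete CDS is never called either way.
    """
    gid = cds.gene_id
    if not cds.complete_5p:
        return SecretionVerdict(gid, INCOMPLETE, "CDS lacks an in-frame start codon")
    if not topo.sp_present:
        return SecretionVerdict(gid, NO_SIGNAL, "no signal peptide predicted")
    n_tm = len(topo.tm_segments)
    if n_tm == 0:
        return SecretionVerdict(gid, SECRETED, "signal peptide, no TM segment")
    if n_tm == 1:
        cleave = topo.cleavage_pos or 1
        if _overlaps(topo.tm_segments[0], 1, cleave - 1):
            return SecretionVerdict(
                gid, SECRETED, "single TM segment coincides with the signal peptide"
            )
    return SecretionVerdict(
        gid, MEMBRANE, f"{n_tm} TM segment(s) outside the signal peptide"
    )


def triage_batch(
    cdss: Iterable[CodingSequence],
    topology: dict[str, TopologyCall],
) -> tuple[list[SecretionVerdict], dict[str, int]]:
    """Classify a batch and return verdicts plus the accounting summary.

    The summary satisfies secreted = sp_positive_complete - removed_by_tm.
    """
    verdicts = []
    for cds in cdss:
        topo = topology.get(
            cds.gene_id, TopologyCall(gene_id=cds.gene_id, sp_present=False)
        )
        verdicts.append(classify_secretion(cds, topo))
    counts = {v: 0 for v in (SECRETED, MEMBRANE, NO_SIGNAL, INCOMPLETE)}
    for v in verdicts:
        counts[v.verdict] += 1
    summary = {
        "sp_positive_complete": counts[SECRETED] + counts[MEMBRANE],
        "removed_by_tm": counts[MEMBRANE],
        "secreted": counts[SECRETED],
        "no_signal": counts[NO_SIGNAL],
        "incomplete_5p": counts[INCOMPLETE],
    }
    return verdicts, summary


def filter_homologs(hits: pd.DataFrame, e_cut: float = 1.0e-5) -> pd.DataFrame:
    """Best hit per query at E <= e_cut (ties broken by higher bit score)."""
    if not pd.api.types.is_numeric_dtype(hits["evalue"]):
        raise ValueError("non-numeric E-value field")
    passing = hits[hits["evalue"] <= e_cut]
    if passing.empty:
        return passing
    ranked = passing.sort_values(
        ["query", "evalue", "bitscore"], ascending=[True, True, False]
    )
    return ranked.groupby("query", sort=True).head(1).reset_index(drop=True)


# ---------------------------------------------------------------------------
# toy hydropathy predictor (test scaffolding only)

_KD = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


def _hydropathy(protein: str) -> list[float]:
    return [_KD.get(aa, 0.0) for aa in protein]


def toy_topology(
    gene_id: str,
    protein: str,
    sp_window: int = 8,
    sp_threshold: float = 2.5,
    tm_window: int = 19,
    tm_threshold: float = 1.8,
) -> TopologyCall:
    """A deliberately simple hydropathy-scan stand-in for external topology
    predictors, so the triage can run self-contained in tests.

    A signal peptide is called when some Kyte-Doolittle window of length
    *sp_window* inside the first 20 residues averages >= *sp_threshold*; the
    cleavage site is placed 4 residues past the end of the maximal
    hydrophobic run.  TM segments are merged windows of length *tm_window*
    averaging >= *tm_threshold* outside the signal-peptide region.
    """
    kd = _hydropathy(protein)
    n = len(kd)
    sp_present = False
    cleavage = None
    best_end = 0
    for start in range(0, min(20, n - sp_window + 1)):
        window = kd[start : start + sp_window]
        if sum(window) / sp_window >= sp_threshold:
            sp_present = True
            end = start + sp_window
            while end < min(n, 35) and kd[end] >= 1.5:
                end += 1
            best_end = max(best_end, end)
    if sp_present:
        cleavage = min(n, best_end + 4)
    tm_hits = []
    scan_from = (cleavage - 1) if cleavage else 0
    for start in range(scan_from, n - tm_window + 1):
        window = kd[start : start + tm_window]
        if sum(window) / tm_window >= tm_threshold:
            tm_hits.append((start + 1, start + tm_window))
    segments: list[tuple[int, int]] = []
    for lo, hi in tm_hits:
        if segments and lo <= segments[-1][1] + 1:
            segments[-1] = (segments[-1][0], hi)
        else:
            segments.append((lo, hi))
    return TopologyCall(
        gene_id=gene_id, sp_present=sp_present,
        cleavage_pos=cleavage, tm_segments=segments,
    )
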