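"""Ortholog-pair discovery between two de novo transcriptome assemblies.

Two assemblies of the same species (a tissue assembly, ``SG``, and a
whole-body assembly, ``WB``) contain near-identical copies of most shared
genes.  Pairs aligned at >99% identity over >=150 bp are treated as the same
gene in both assemblies ("ortholog pairs"), and the overlapping aligned
segment is clipped out as the common interval for downstream read counting.

The pairing aligner is a seed-and-extend local aligner: exact k-mer seeds
(k=20 by default) nominate candidate partners and diagonals, and a banded
Smith-Waterman extension with linear gap costs produces the final alignment.
Identity is defined as matching columns over total alignment columns; gap
columns and columns containing ``N`` count as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Transcript",
    "OrthologPair",
    "ClippedRegion",
    "load_transcripts",
    "find_ortholog_pairs",
    "clip_overlap",
    "write_pairs_tsv",
    "read_pairs_tsv",
    "write_regions_fasta",
]

# Local-alignment scoring.  Matches are rewarded modestly and both mismatches
# and gaps are penalised hard, which keeps optimal local alignments of
# near-identical orthologs contiguous and identity-dominated.
MATCH = 1
MISMATCH = -2
GAP = -3

PAIRS_HEADER = [
    "pair_id", "sg_id", "wb_id", "identity", "overlap_len",
    "sg_start", "sg_end", "wb_start", "wb_end",
]


@dataclass(frozen=True)
class Transcript:
    """A unigene: one unique assembled transcript sequence."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class OrthologPair:
    """A matched SG/WB gene pair with aligned spans (1-based inclusive)."""

    sg_id: str
    wb_id: str
    identity: float
    overlap_len: int  # alignment columns
    sg_span: tuple[int, int]
    wb_span: tuple[int, int]

    @property
    def pair_id(self) -> str:
        return f"{self.sg_id}|{self.wb_id}"


@dataclass(frozen=True)
class ClippedRegion:
    """The overlapping aligned segment of a pair, cut from both transcripts."""

    pair_id: str
    sg_region_seq: str
    wb_region_seq: str

    @property
    def len_sg(self) -> int:
        return len(self.sg_region_seq)

    @property
    def len_wb(self) -> int:
        return len(self.wb_region_seq)


def load_transcripts(path) -> list[Transcript]:
    """Read a (multi-record, wrapped or unwrapped) FASTA into Transcripts.

    Sequences are upper-cased; record order is preserved.  Duplicate ids and
    empty sequences are rejected.
    """
    out: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA id: {rec.id!r}")
        out.append(Transcript(id=rec.id, seq=seq))
    return out


# ---------------------------------------------------------------------------
# alignment engine


def _score(a: str, b: str) -> int:
    # N never counts as a match
    if a == b and a != "N":
        return MATCH
    return MISMATCH


def _traceback_stats(path_ops: list[tuple[str, str, str]]) -> tuple[int, int]:
    matches = 0
    for op, a, b in path_ops:
        if op == "D" and a == b and a != "N":
            matches += 1
    return matches, len(path_ops)


def banded_local_align(
    a: str, b: str, d_lo: int, d_hi: int
) -> tuple[int, int, int, tuple[int, int], tuple[int, int]] | None:
    """Banded Smith-Waterman (linear gaps) restricted to diagonals d=i-j in
    [d_lo, d_hi] (1-based i over ``a``, j over ``b``).

    Returns (score, matches, columns, a_span, b_span) with 1-based inclusive
    spans, or None if no positive-scoring cell exists.  Tie-breaks are fixed:
    the best cell is the first maximum in (i asc, j asc) scan order, and
    traceback prefers diagonal, then up (gap in b), then left (gap in a).
    """
    m, n = len(a), len(b)
    width = d_hi - d_lo + 1
    NEG = -(10 ** 9)
    prev = [0] * width  # H[i-1][d]
    ptr_rows: list[list[int]] = []  # 0 stop, 1 diag, 2 up, 3 left
    best = (0, 0, 0)  # score, i, d-index
    for i in range(1, m + 1):
        cur = [0] * width
        ptrs = [0] * width
        ai = a[i - 1]
        # iterate d from high to low => j ascending; 'left' dep is cur[k+1]
        for k in range(width - 1, -1, -1):
            d = d_lo + k
            j = i - d
            if j < 1 or j > n:
                cur[k] = NEG
                continue
            diag = prev[k] if prev[k] > 0 else 0
            sc = diag + _score(ai, b[j - 1])
            p = 1
            up = (prev[k - 1] if k >= 1 else NEG) + GAP
            if up > sc:
                sc, p = up, 2
            left = (cur[k + 1] if k + 1 < width else NEG) + GAP
            if left > sc:
                sc, p = left, 3
            if sc <= 0:
                sc, p = 0, 0
            cur[k] = sc
            ptrs[k] = p
        # best-cell scan: i ascending, j ascending (k descending)
        for k in range(width - 1, -1, -1):
            if cur[k] > best[0]:
                best = (cur[k], i, k)
        prev = cur
        ptr_rows.append(ptrs)
    score, bi, bk = best
    if score <= 0:
        return None
    # traceback
    i, k = bi, bk
    matches = columns = 0
    end_i, end_j = bi, bi - (d_lo + bk)
    while i >= 1:
        p = ptr_rows[i - 1][k]
        if p == 0:
            break
        j = i - (d_lo + k)
        if p == 1:
            columns += 1
            if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                matches += 1
            i -= 1
        elif p == 2:
            columns += 1
            i -= 1
            k -= 1
        else:
            columns += 1
            k += 1
    start_i, start_j = i + 1, (i - (d_lo + k)) + 1
    return score, matches, columns, (start_i, end_i), (start_j, end_j)


def _kmers(seq: str, k: int) -> Iterable[tuple[str, int]]:
    for pos in range(len(seq) - k + 1):
        kmer = seq[pos : pos + k]
        if "N" not in kmer:
            yield kmer, pos


def _align_candidate(
    sg_seq: str, wb_seq: str, diags: Sequence[int], pad: int = 4
):
    d_lo, d_hi = min(diags) - pad, max(diags) + pad
    # clamp band to diagonals that actually intersect the matrix
    d_lo = max(d_lo, 1 - len(wb_seq))
    d_hi = min(d_hi, len(sg_seq) - 1)
    return banded_local_align(sg_seq, wb_seq, d_lo, d_hi)


def find_ortholog_pairs(
    sg: Sequence[Transcript],
    wb: Sequence[Transcript],
    min_identity: float = 0.99,
    min_overlap: int = 150,
    k: int = 20,
    search_reverse: bool = False,
) -> list[OrthologPair]:
    """Discover one-to-one ortholog pairs between two transcript sets.

    A pair is accepted when identity is strictly greater than *min_identity*
    and the alignment spans at least *min_overlap* columns.  When one gene
    matches several partners, the pair with highest identity wins; ties are
    broken by longer overlap, then lexicographic ids.  Only forward-strand
    matches are considered unless *search_reverse* is set (assemblies are
    assumed to be consistently oriented).
    """
    if not sg or not wb:
        raise ValueError("both transcript sets must be nonempty")

    index: dict[str, list[tuple[int, int]]] = {}
    for wi, wt in enumerate(wb):
        for kmer, pos in _kmers(wt.seq, k):
            index.setdefault(kmer, []).append((wi, pos))

    candidates: list[tuple[float, int, str, str, OrthologPair]] = []
    for st in sg:
        variants = [(st.seq, False)]
        if search_reverse:
            variants.append((str(Seq(st.seq).reverse_complement()), True))
        per_wb: dict[int, dict[bool, set[int]]] = {}
        for seq, is_rc in variants:
            for kmer, pos in _kmers(seq, k):
                for wi, wpos in index.get(kmer, ()):
                    per_wb.setdefault(wi, {}).setdefault(is_rc, set()).add(
                        (pos + 1) - (wpos + 1)
                    )
        for wi, by_strand in per_wb.items():
            wt = wb[wi]
            best_aln = None
            best_rc = False
            for is_rc, diags in by_strand.items():
                seq = variants[1][0] if is_rc else st.seq
                aln = _align_candidate(seq, wt.seq, sorted(diags))
                if aln and (best_aln is None or aln[0] > best_aln[0]):
                    best_aln, best_rc = aln, is_rc
            if best_aln is None:
                continue
            _, matches, columns, sg_span, wb_span = best_aln
            if columns < min_overlap:
                continue
            identity = matches / columns
            if not identity > min_identity:
                continue
            if best_rc:  # report sg span on the forward transcript
                L = st.length
                sg_span = (L - sg_span[1] + 1, L - sg_span[0] + 1)
            pair = OrthologPair(
                sg_id=st.id, wb_id=wt.id, identity=identity,
                overlap_len=columns, sg_span=sg_span, wb_span=wb_span,
            )
            candidates.append(
                (-identity, -columns, st.id, wt.id, pair)
            )

    candidates.sort(key=lambda t: t[:4])
    used_sg: set[str] = set()
    used_wb: set[str] = set()
    accepted: list[OrthologPair] = []
    for *_key, pair in candidates:
        if pair.sg_id in used_sg or pair.wb_id in used_wb:
            continue
        used_sg.add(pair.sg_id)
        used_wb.add(pair.wb_id)
        accepted.append(pair)
    accepted.sort(key=lambda p: (p.sg_id, p.wb_id))
    return accepted


def clip_overlap(pair: OrthologPair, sg: Transcript, wb: Transcript) -> ClippedRegion:
    """Cut the overlapping aligned segment out of both transcripts."""
    if pair.sg_id != sg.id or pair.wb_id != wb.id:
        raise ValueError(
            f"pair ({pair.sg_id}, {pair.wb_id}) does not match transcripts "
            f"({sg.id}, {wb.id})"
        )
    for (start, end), t in ((pair.sg_span, sg), (pair.wb_span, wb)):
        if not (1 <= start <= end <= t.length):
            raise ValueError(
                f"span [{start},{end}] outside transcript {t.id!r} "
                f"(length {t.length})"
            )
    return ClippedRegion(
        pair_id=pair.pair_id,
        sg_region_seq=sg.seq[pair.sg_span[0] - 1 : pair.sg_span[1]],
        wb_region_seq=wb.seq[pair.wb_span[0] - 1 : pair.wb_span[1]],
    )


# ---------------------------------------------------------------------------
# serialization (coordinates 1-based inclusive throughout)


def write_pairs_tsv(pairs: Sequence[OrthologPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PAIRS_HEADER) + "\n")
        for p in pairs:
            fh.write(
                f"{p.pair_id}\t{p.sg_id}\t{p.wb_id}\t{p.identity:.6f}\t"
                f"{p.overlap_len}\t{p.sg_span[0]}\t{p.sg_span[1]}\t"
                f"{p.wb_span[0]}\t{p.wb_span[1]}\n"
            )


def read_pairs_tsv(path) -> list[OrthologPair]:
    pairs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PAIRS_HEADER:
            raise ValueError(f"unexpected pairs TSV header: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            pairs.append(
                OrthologPair(
                    sg_id=f[1], wb_id=f[2], identity=float(f[3]),
                    overlap_len=int(f[4]),
                    sg_span=(int(f[5]), int(f[6])),
                    wb_span=(int(f[7]), int(f[8])),
                )
            )
    return pairs


def write_regions_fasta(regions: Sequence[ClippedRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f">{r.pair_id}|sg\n{r.sg_region_seq}\n")
            fh.write(f">{r.pair_id}|wb\n{r.wb_region_seq}\n")


def read_regions_fasta(path) -> list[ClippedRegion]:
    by_pair: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        pair_id, _, side = rec.id.rpartition("|")
        if side not in ("sg", "wb"):
            raise ValueError(f"region header {rec.id!r} lacks |sg / |wb suffix")
        if pair_id not in by_pair:
            order.append(pair_id)
        by_pair.setdefault(pair_id, {})[side] = str(rec.seq).upper()
    out = []
    for pid in order:
        sides = by_pair[pid]
        if set(sides) != {"sg", "wb"}:
            raise ValueError(f"pair {pid!r} missing one region side")
        out.append(ClippedRegion(pid, sides["sg"], sides["wb"]))
    return out
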