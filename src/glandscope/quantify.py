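"""Read counting on clipped ortholog regions and RPKM normalization.

Each library's reads are mapped to its own side of the clipped regions (SG
reads to the SG-side region sequences, WB reads to the WB side).  Mapping is
exact substring matching by default, on either strand of the read; a read
whose sequence occurs in two or more distinct regions is discarded as
ambiguous so that near-identical orthologs are never double counted.  The
per-library ``total_mapped`` — the RPKM denominator and the library size of
the count statistic downstream — is the number of reads assigned uniquely to
some region.

RPKM (reads per kilobase of region per million mapped reads) is
``1e9 * C / (N * L)`` for raw count C, library total N and region length L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import reverse_complement
from Bio import SeqIO

from .pairing import ClippedRegion

__all__ = [
    "ReadLibrary",
    "RegionCounts",
    "MappingSummary",
    "load_reads",
    "map_reads_to_regions",
    "rpkm",
    "quantify_pairs",
    "write_counts_tsv",
    "read_counts_tsv",
]

COUNTS_HEADER = [
    "pair_id", "count_sg", "count_wb", "len_sg", "len_wb", "rpkm_sg", "rpkm_wb",
]


@dataclass
class ReadLibrary:
    """A sequencing library: labelled reads plus its mapped-read total."""

    label: str  # "SG" or "WB"
    reads: list[tuple[str, str]]
    total_mapped: int | None = None


@dataclass
class MappingSummary:
    total_reads: int
    mapped: int
    ambiguous: int
    unmapped: int


@dataclass
class RegionCounts:
    pair_id: str
    count_sg: int
    count_wb: int
    len_sg: int
    len_wb: int
    rpkm_sg: float = 0.0
    rpkm_wb: float = 0.0


def load_reads(path, label: str) -> ReadLibrary:
    """Load reads from FASTQ (qualities ignored) or FASTA, by extension."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    reads = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(p, fmt)]
    return ReadLibrary(label=label, reads=reads)


def _hamming_le(a: str, b: str, limit: int) -> bool:
    bad = 0
    for x, y in zip(a, b):
        if x != y:
            bad += 1
            if bad > limit:
                return False
    return True


class _ExactIndex:
    """Substring index: every length-L window of every region, per L."""

    AMBIG = -1

    def __init__(self, seqs: Sequence[str]):
        self.seqs = seqs
        self._by_len: dict[int, dict[str, int]] = {}

    def _index_for(self, L: int) -> dict[str, int]:
        idx = self._by_len.get(L)
        if idx is None:
            idx = {}
            for ri, seq in enumerate(self.seqs):
                for pos in range(len(seq) - L + 1):
                    window = seq[pos : pos + L]
                    prior = idx.get(window)
                    if prior is None:
                        idx[window] = ri
                    elif prior != ri:
                        idx[window] = self.AMBIG
            self._by_len[L] = idx
        return idx

    def lookup(self, read: str) -> int | None:
        """Region index, AMBIG, or None (unmapped); either read strand."""
        idx = self._index_for(len(read))
        hit = idx.get(read)
        rc_hit = idx.get(reverse_complement(read))
        hits = {h for h in (hit, rc_hit) if h is not None}
        if not hits:
            return None
        if self.AMBIG in hits or len(hits) > 1:
            return self.AMBIG
        return hits.pop()


def _mismatch_scan(read: str, seqs: Sequence[str], max_mm: int) -> int | None:
    hits: set[int] = set()
    for strand_read in (read, reverse_complement(read)):
        L = len(strand_read)
        for ri, seq in enumerate(seqs):
            if ri in hits:
                continue
            for pos in range(len(seq) - L + 1):
                if _hamming_le(strand_read, seq[pos : pos + L], max_mm):
                    hits.add(ri)
                    break
    if not hits:
        return None
    if len(hits) > 1:
        return _ExactIndex.AMBIG
    return hits.pop()


def map_reads_to_regions(
    lib: ReadLibrary,
    regions: Sequence[ClippedRegion],
    side: str,
    max_mismatches: int = 0,
) -> tuple[list[int], MappingSummary]:
    """Count uniquely-mapping reads per region for one library.

    Returns per-region counts (aligned with *regions*) and a summary.  Sets
    ``lib.total_mapped`` to the number of uniquely assigned reads.
    """
    if not regions:
        raise ValueError("regions must be nonempty")
    if side not in ("SG", "WB"):
        raise ValueError(f"side must be 'SG' or 'WB', got {side!r}")
    seqs = [
        r.sg_region_seq if side == "SG" else r.wb_region_seq for r in regions
    ]
    counts = [0] * len(regions)
    ambiguous = unmapped = 0
    if max_mismatches == 0:
        index = _ExactIndex(seqs)
        assign = index.lookup
    else:
        def assign(read: str) -> int | None:
            return _mismatch_scan(read, seqs, max_mismatches)
    for _rid, read in lib.reads:
        ri = assign(read)
        if ri is None:
            unmapped += 1
        elif ri == _ExactIndex.AMBIG:
            ambiguous += 1
        else:
            counts[ri] += 1
    mapped = sum(counts)
    lib.total_mapped = mapped
    return counts, MappingSummary(
        total_reads=len(lib.reads), mapped=mapped,
        ambiguous=ambiguous, unmapped=unmapped,
    )


def rpkm(count: int, total_mapped: int, length: int) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if length <= 0:
        raise ValueError("length must be positive")
    if count < 0:
        raise ValueError("count must be nonnegative")
    return 1e9 * count / (total_mapped * length)


def quantify_pairs(
    regions: Sequence[ClippedRegion],
    sg_lib: ReadLibrary,
    wb_lib: ReadLibrary,
    max_mismatches: int = 0,
) -> tuple[list[RegionCounts], MappingSummary, MappingSummary]:
    """Map both libraries to their region sides and compute RPKMs."""
    sg_counts, sg_summary = map_reads_to_regions(
        sg_lib, regions, "SG", max_mismatches
    )
    wb_counts, wb_summary = map_reads_to_regions(
        wb_lib, regions, "WB", max_mismatches
    )
    out = []
    for region, c_sg, c_wb in zip(regions, sg_counts, wb_counts):
        rc = RegionCounts(
            pair_id=region.pair_id,
            count_sg=c_sg, count_wb=c_wb,
            len_sg=region.len_sg, len_wb=region.len_wb,
        )
        if sg_lib.total_mapped:
            rc.rpkm_sg = rpkm(c_sg, sg_lib.total_mapped, rc.len_sg)
        if wb_lib.total_mapped:
            rc.rpkm_wb = rpkm(c_wb, wb_lib.total_mapped, rc.len_wb)
        out.append(rc)
    return out, sg_summary, wb_summary


def write_counts_tsv(counts: Sequence[RegionCounts], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(COUNTS_HEADER) + "\n")
        for c in counts:
            fh.write(
                f"{c.pair_id}\t{c.count_sg}\t{c.count_wb}\t{c.len_sg}\t"
                f"{c.len_wb}\t{c.rpkm_sg:.6f}\t{c.rpkm_wb:.6f}\n"
            )


def read_counts_tsv(path) -> list[RegionCounts]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != COUNTS_HEADER:
            raise ValueError(f"unexpected counts TSV header: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                RegionCounts(
                    pair_id=f[0], count_sg=int(f[1]), count_wb=int(f[2]),
                    len_sg=int(f[3]), len_wb=int(f[4]),
                    rpkm_sg=float(f[5]), rpkm_wb=float(f[6]),
                )
            )
    return out
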