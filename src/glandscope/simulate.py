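"""Ground-truthed synthetic inputs with the statistical structure the
analysis assumes.

The generator emulates the shape of the study's data: two de novo
assemblies sharing near-identical orthologs (i.i.d. per-base substitutions
at a small rate, default 0.003), mean transcript length ~300 bp (shifted
log-normal, echoing the study's mean unigene length of 297 bp, minimum
150 bp), 90 bp error-free reads drawn proportional to expression x length
with uniform start positions, planted fold changes, planted enriched terms,
planted secreted proteins, and Ct values derived from expression plus
Gaussian noise.  Everything is reproducible bitwise from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pairing import Transcript

__all__ = [
    "SyntheticTruth",
    "simulate_transcriptomes",
    "simulate_reads",
    "write_fastq",
    "simulate_annotations_and_topology",
    "simulate_secretome_proteins",
    "simulate_qpcr",
    "simulate_scenario",
]

BASES = np.array(list("ACGT"))

# one deterministic codon per amino acid, for reverse-translating planted
# proteins into coding sequences
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTG", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}

HYDROPHOBIC = list("LIVFA")
POLAR = list("GSTNQDEKRH")


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for truth-aware evaluation."""

    genes: pd.DataFrame  # one row per shared gene
    sg_unique: list[str] = field(default_factory=list)
    wb_unique: list[str] = field(default_factory=list)
    planted_terms: list[str] = field(default_factory=list)
    reference_gene: str = "tbp_ref"
    qpcr_intercept: float = 35.0
    qpcr_sigma: float = 0.2


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    n_mut = int(hit.sum())
    if n_mut:
        for i in np.flatnonzero(hit):
            alternatives = [b for b in "ACGT" if b != arr[i]]
            arr[i] = alternatives[rng.integers(0, 3)]
    return "".join(arr), n_mut


def _lengths(rng: np.random.Generator, n: int, mean: float) -> np.ndarray:
    # shifted log-normal: 150 bp floor, overall mean ~= `mean`
    sigma = 0.5
    mu = math.log(max(mean - 150, 1)) - sigma ** 2 / 2
    return (150 + np.round(rng.lognormal(mu, sigma, size=n))).astype(int)


def simulate_transcriptomes(
    n_shared: int,
    n_unique_each: int,
    length_mean: float = 300.0,
    mutation_rate: float = 0.003,
    seed: int = 0,
) -> tuple[list[Transcript], list[Transcript], SyntheticTruth]:
    """Two assemblies sharing `n_shared` near-identical ortholog pairs.

    Shared genes differ by i.i.d. per-base substitutions at *mutation_rate*;
    each assembly additionally carries `n_unique_each` independent random
    transcripts.  Expression values are not assigned here (see
    :func:`simulate_scenario`).
    """
    rng = np.random.default_rng(seed)
    lengths = _lengths(rng, n_shared, length_mean)
    rows = []
    sg, wb = [], []
    for i in range(n_shared):
        wb_seq = _random_seq(rng, int(lengths[i]))
        sg_seq, n_mut = _mutate(rng, wb_seq, mutation_rate)
        sg_id, wb_id = f"SG{i:05d}", f"WB{i:05d}"
        sg.append(Transcript(sg_id, sg_seq))
        wb.append(Transcript(wb_id, wb_seq))
        rows.append(
            {
                "sg_id": sg_id, "wb_id": wb_id, "length": int(lengths[i]),
                "n_mut": n_mut,
            }
        )
    sg_unique, wb_unique = [], []
    u_lengths = _lengths(rng, 2 * n_unique_each, length_mean)
    for i in range(n_unique_each):
        tid = f"SGU{i:05d}"
        sg.append(Transcript(tid, _random_seq(rng, int(u_lengths[i]))))
        sg_unique.append(tid)
    for i in range(n_unique_each):
        tid = f"WBU{i:05d}"
        wb.append(
            Transcript(tid, _random_seq(rng, int(u_lengths[n_unique_each + i])))
        )
        wb_unique.append(tid)
    truth = SyntheticTruth(
        genes=pd.DataFrame(rows), sg_unique=sg_unique, wb_unique=wb_unique
    )
    return sg, wb, truth


def simulate_reads(
    transcripts: list[Transcript],
    expression: np.ndarray,
    depth: int,
    read_len: int = 90,
    seed: int = 0,
    error_rate: float = 0.0,
    label: str = "read",
) -> list[tuple[str, str]]:
    """Draw error-free reads with gene probability ~ expression x length and
    uniform start positions (a substitution-error option exists for stress
    tests)."""
    rng = np.random.default_rng(seed)
    expression = np.asarray(expression, dtype=float)
    if expression.min() < 0 or not expression.any():
        raise ValueError("expression must be nonnegative and not all zero")
    eligible = np.array([t.length >= read_len for t in transcripts])
    if not eligible.any():
        raise ValueError(f"no transcript is at least {read_len} bp")
    weights = expression * np.array([t.length for t in transcripts]) * eligible
    probs = weights / weights.sum()
    counts = rng.multinomial(depth, probs)
    reads: list[tuple[str, str]] = []
    idx = 0
    for t, c in zip(transcripts, counts):
        if c == 0:
            continue
        starts = rng.integers(0, t.length - read_len + 1, size=c)
        for s in starts:
            seq = t.seq[s : s + read_len]
            if error_rate > 0:
                seq, _ = _mutate(rng, seq, error_rate)
            reads.append((f"{label}{idx:07d}", seq))
            idx += 1
    return reads


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_annotations_and_topology(
    truth: SyntheticTruth,
    n_terms: int = 40,
    planted_terms: list[str] | None = None,
    seed: int = 0,
    baseline_rate: float = 0.02,
    planted_rate: float = 0.5,
    extra_tm_fraction: float = 0.2,
    secreted_fraction: float = 0.15,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plant term assignments and membrane-topology calls.

    Background term frequencies are uniform; each planted term additionally
    covers planted-up genes at *planted_rate*.  A *secreted_fraction* of the
    shared genes gets a signal peptide with a cleavage site in residues
    16-30; exactly round(k * extra_tm_fraction) of those k SP-positive genes
    receive one extra TM segment outside the signal peptide.

    Returns (assignments, sp_calls, tm_calls) tables keyed by sg_id, and
    records the planted labels in ``truth.genes``.
    """
    rng = np.random.default_rng(seed)
    genes = truth.genes
    universe = [f"T{j:04d}" for j in range(n_terms)]
    if planted_terms is None:
        planted_terms = universe[: max(1, n_terms // 10)]
    unknown = set(planted_terms) - set(universe)
    if unknown:
        raise ValueError(f"planted terms outside the term universe: {unknown}")
    truth.planted_terms = list(planted_terms)

    up_mask = (
        genes["planted_log2"] > 0
        if "planted_log2" in genes
        else pd.Series(False, index=genes.index)
    )
    rows = []
    for gi, gid in enumerate(genes["sg_id"]):
        # every gene gets a couple of uniform background terms
        k = 1 + rng.poisson(1.5)
        for term in sorted(set(rng.choice(universe, size=k))):
            rows.append((gid, term, "synthetic_namespace"))
        for term in planted_terms:
            rate = planted_rate if bool(up_mask.iloc[gi]) else baseline_rate
            if rng.random() < rate:
                rows.append((gid, term, "synthetic_namespace"))
    assignments = pd.DataFrame(
        sorted(set(rows)), columns=["gene_id", "term_id", "namespace"]
    )

    n = len(genes)
    secreted = rng.random(n) < secreted_fraction
    cleavage = rng.integers(16, 31, size=n)
    sp_idx = np.flatnonzero(secreted)
    n_extra = int(round(len(sp_idx) * extra_tm_fraction))
    extra_tm_idx = sp_idx[
        rng.permutation(len(sp_idx))[:n_extra]
    ] if n_extra else np.array([], dtype=int)
    extra_tm = np.zeros(n, dtype=bool)
    extra_tm[extra_tm_idx] = True
    genes["secreted"] = secreted & ~extra_tm
    genes["sp_present"] = secreted
    genes["extra_tm"] = extra_tm
    genes["cleavage_pos"] = np.where(secreted, cleavage, 0)

    sp_rows = [
        (gid, "Y" if sp else "N", int(cl) if sp else 0)
        for gid, sp, cl in zip(genes["sg_id"], secreted, cleavage)
    ]
    sp_calls = pd.DataFrame(sp_rows, columns=["gene_id", "sp_present", "cleavage_pos"])
    tm_rows = [
        (genes["sg_id"].iloc[i], 60, 80) for i in np.sort(extra_tm_idx)
    ]
    tm_calls = pd.DataFrame(tm_rows, columns=["gene_id", "tm_start", "tm_end"])
    return assignments, sp_calls, tm_calls


def simulate_secretome_proteins(
    truth: SyntheticTruth, seed: int = 0, length: int = 140
) -> list[tuple[str, str, str]]:
    """Planted proteins as (sg_id, protein, cds_dna) for SP-labelled and
    unlabelled genes: SP-positive proteins start with a strongly hydrophobic
    N-terminal core, extra-TM proteins carry a 21-residue hydrophobic
    stretch at residues 60-80, everything else is hydrophilic."""
    rng = np.random.default_rng(seed)
    genes = truth.genes
    out = []
    for _, row in genes.iterrows():
        body = list(rng.choice(POLAR, size=length))
        prot = ["M"] + body
        if row.get("sp_present", False):
            core = rng.choice(HYDROPHOBIC, size=12)
            prot[3:15] = list(core)
        if row.get("extra_tm", False):
            tm = rng.choice(HYDROPHOBIC, size=21)
            prot[59:80] = list(tm)
        protein = "".join(prot)
        dna = "".join(_CODON[aa] for aa in protein) + "TAA"
        out.append((row["sg_id"], protein, dna))
    return out


def simulate_qpcr(
    truth: SyntheticTruth,
    genes: list[str],
    intercept: float = 35.0,
    sigma: float = 0.2,
    seed: int = 0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Triplicate Ct values per tissue: Ct = intercept - log2(expression)
    + N(0, sigma), plus a stable reference gene."""
    rng = np.random.default_rng(seed)
    gdf = truth.genes.set_index("sg_id")
    rows = []

    def ct_rows(gid: str, role: str, expr_sg: float, expr_wb: float):
        for tissue, expr in (("SG", expr_sg), ("WB", expr_wb)):
            if expr <= 0:
                raise ValueError(f"gene {gid}: zero expression in {tissue}")
            base = intercept - math.log2(expr)
            cts = base + rng.normal(0.0, sigma, size=n_replicates)
            rows.append([gid, tissue, role] + [round(c, 4) for c in cts])

    ref_expr = float(gdf["expr_wb"].median()) if "expr_wb" in gdf else 100.0
    ct_rows(truth.reference_gene, "reference", ref_expr, ref_expr)
    for gid in genes:
        ct_rows(gid, "target", gdf.loc[gid, "expr_sg"], gdf.loc[gid, "expr_wb"])
    cols = ["gene_id", "tissue", "role"] + [
        f"ct_rep{i + 1}" for i in range(n_replicates)
    ]
    truth.qpcr_intercept, truth.qpcr_sigma = intercept, sigma
    return pd.DataFrame(rows, columns=cols)


def simulate_scenario(
    outdir,
    seed: int = 42,
    n_shared: int = 2000,
    n_unique_each: int = 500,
    n_planted_de: int = 200,
    planted_fold: float = 4.0,
    depth: int = 500_000,
    length_mean: float = 300.0,
    mutation_rate: float = 0.003,
    read_len: int = 90,
    n_terms: int = 40,
    n_qpcr_genes: int = 20,
    qpcr_sigma: float = 0.2,
) -> SyntheticTruth:
    """Generate a full input set under the default study conditions and
    write it to *outdir* (FASTA/FASTQ/TSVs plus truth.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    sg, wb, truth = simulate_transcriptomes(
        n_shared, n_unique_each, length_mean, mutation_rate,
        seed=int(rng.integers(2 ** 31)),
    )
    genes = truth.genes
    n = len(genes)
    base = rng.lognormal(math.log(100.0), 1.0, size=n)
    planted = np.zeros(n)
    de_idx = rng.permutation(n)[:n_planted_de]
    half = n_planted_de // 2
    planted[de_idx[:half]] = math.log2(planted_fold)
    planted[de_idx[half:]] = -math.log2(planted_fold)
    genes["expr_wb"] = base
    genes["expr_sg"] = base * np.power(2.0, planted)
    genes["planted_log2"] = planted

    uniq_expr = rng.lognormal(math.log(100.0), 1.0, size=2 * n_unique_each)
    sg_expr = np.concatenate([genes["expr_sg"].to_numpy(), uniq_expr[:n_unique_each]])
    wb_expr = np.concatenate([genes["expr_wb"].to_numpy(), uniq_expr[n_unique_each:]])

    sg_len = np.array([t.length for t in sg], dtype=float)
    wb_len = np.array([t.length for t in wb], dtype=float)
    w_sg, w_wb = sg_expr * sg_len, wb_expr * wb_len
    genes["expected_count_sg"] = depth * w_sg[:n] / w_sg.sum()
    genes["expected_count_wb"] = depth * w_wb[:n] / w_wb.sum()

    with open(outdir / "sg.fasta", "w") as fh:
        for t in sg:
            fh.write(f">{t.id}\n{t.seq}\n")
    with open(outdir / "wb.fasta", "w") as fh:
        for t in wb:
            fh.write(f">{t.id}\n{t.seq}\n")

    sg_reads = simulate_reads(
        sg, sg_expr, depth, read_len, seed=int(rng.integers(2 ** 31)), label="sgr"
    )
    wb_reads = simulate_reads(
        wb, wb_expr, depth, read_len, seed=int(rng.integers(2 ** 31)), label="wbr"
    )
    write_fastq(sg_reads, outdir / "sg.fastq")
    write_fastq(wb_reads, outdir / "wb.fastq")

    assignments, sp_calls, tm_calls = simulate_annotations_and_topology(
        truth, n_terms=n_terms, seed=int(rng.integers(2 ** 31))
    )
    assignments.to_csv(outdir / "terms.tsv", sep="\t", index=False, header=False)
    sp_calls.to_csv(outdir / "sp.tsv", sep="\t", index=False)
    tm_calls.to_csv(outdir / "tm.tsv", sep="\t", index=False)

    proteins = simulate_secretome_proteins(
        truth, seed=int(rng.integers(2 ** 31))
    )
    with open(outdir / "cds.fasta", "w") as fh:
        for gid, _prot, dna in proteins:
            fh.write(f">{gid}\n{dna}\n")

    # the qPCR validation panel mirrors the study design: genes already
    # called as changed, half in each direction
    n_up = n_qpcr_genes // 2
    qpcr_genes = sorted(
        genes["sg_id"].iloc[i] for i in de_idx[:n_up]
    ) + sorted(
        genes["sg_id"].iloc[i] for i in de_idx[half : half + n_qpcr_genes - n_up]
    )
    ct_table = simulate_qpcr(
        truth, qpcr_genes, sigma=qpcr_sigma, seed=int(rng.integers(2 ** 31))
    )
    ct_table.to_csv(outdir / "ct.tsv", sep="\t", index=False)

    genes.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "planted_terms.txt", "w") as fh:
        fh.write("".join(t + "\n" for t in truth.planted_terms))
    return truth
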