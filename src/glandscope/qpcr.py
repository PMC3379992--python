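"""Relative qPCR quantification (2^-ddCt) and concordance with RPKM calls.

For each gene, replicate threshold cycles (Ct) are averaged per tissue and
per role (target / reference gene), then

    dCt_tissue  = mean Ct(target, tissue) - mean Ct(reference, tissue)
    ddCt        = dCt_SG - dCt_WB
    fold change = 2^(-ddCt)

Amplification efficiency is taken as exact doubling per cycle, which is the
assumption the 2^-ddCt method encodes.  Direction concordance between the
two platforms compares sign(log2 fold change) with sign(log2 RPKM ratio); a
zero on either side is concordant with nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean
from typing import Sequence

__all__ = [
    "QpcrMeasurement",
    "relative_expression",
    "reference_gene_check",
    "direction_concordance",
    "load_ct_table",
    "write_qpcr_tsv",
]

QPCR_HEADER = [
    "gene_id", "ddct", "fold_change", "log2_fold", "rpkm_log2", "concordant",
]


@dataclass
class QpcrMeasurement:
    gene_id: str
    ct_target_sg: list[float]
    ct_target_wb: list[float]
    ct_ref_sg: list[float]
    ct_ref_wb: list[float]
    ddct: float | None = None
    fold_change: float | None = None

    def validate(self) -> None:
        for name, reps in (
            ("ct_target_sg", self.ct_target_sg),
            ("ct_target_wb", self.ct_target_wb),
            ("ct_ref_sg", self.ct_ref_sg),
            ("ct_ref_wb", self.ct_ref_wb),
        ):
            if not reps:
                raise ValueError(f"{self.gene_id}: empty replicate list {name}")
            if any(ct <= 0 for ct in reps):
                raise ValueError(f"{self.gene_id}: nonpositive Ct in {name}")


def relative_expression(m: QpcrMeasurement) -> float:
    """2^-ddCt fold change of the gene in SG relative to WB."""
    m.validate()
    dct_sg = mean(m.ct_target_sg) - mean(m.ct_ref_sg)
    dct_wb = mean(m.ct_target_wb) - mean(m.ct_ref_wb)
    m.ddct = dct_sg - dct_wb
    m.fold_change = 2.0 ** (-m.ddct)
    return m.fold_change


def reference_gene_check(
    rpkm_a: float, rpkm_b: float, max_abs_log2: float = 1.0
) -> tuple[bool, float]:
    """Stability screen for a candidate reference gene from its RPKMs."""
    if rpkm_a <= 0 or rpkm_b <= 0:
        raise ValueError("RPKMs must be positive for the stability check")
    abs_log2 = abs(math.log2(rpkm_a / rpkm_b))
    return abs_log2 < max_abs_log2, abs_log2


def _sign(v: float) -> int:
    return (v > 0) - (v < 0)


def direction_concordance(
    qpcr_fold_changes: Sequence[float], rpkm_log2: Sequence[float]
) -> dict[str, int]:
    """Count genes whose qPCR and RPKM directions of change agree.

    Inputs are index-aligned per gene.  A gene is concordant iff
    sign(log2 fold change) equals sign(log2 RPKM ratio) and neither is zero.
    """
    if len(qpcr_fold_changes) != len(rpkm_log2):
        raise ValueError("fold-change and log2-ratio lists differ in length")
    n_conc = 0
    for fc, lr in zip(qpcr_fold_changes, rpkm_log2):
        if fc <= 0:
            raise ValueError("fold changes must be positive")
        s_q = _sign(math.log2(fc))
        s_r = _sign(lr)
        if s_q != 0 and s_q == s_r:
            n_conc += 1
    return {"n": len(qpcr_fold_changes), "n_concordant": n_conc}


def load_ct_table(path, reference_gene: str) -> list[QpcrMeasurement]:
    """Read a Ct TSV `gene_id tissue role ct_rep1 ct_rep2 ...`.

    ``role`` is ``target`` or ``reference``; ``tissue`` is ``SG`` or ``WB``.
    Reference-gene rows may carry the reference gene's own id; they are
    attached to every target gene.
    """
    targets: dict[str, dict[str, list[float]]] = {}
    refs: dict[str, list[float]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"line {lineno}: expected >=4 tab fields")
            gid, tissue, role = f[0], f[1], f[2]
            if tissue not in ("SG", "WB") or role not in ("target", "reference"):
                raise ValueError(
                    f"line {lineno}: bad tissue/role {tissue!r}/{role!r}"
                )
            cts = [float(v) for v in f[3:] if v]
            if role == "reference" or gid == reference_gene:
                refs.setdefault(tissue, []).extend(cts)
            else:
                if gid not in targets:
                    targets[gid] = {}
                    order.append(gid)
                targets[gid].setdefault(tissue, []).extend(cts)
    if set(refs) != {"SG", "WB"}:
        raise ValueError("reference-gene Cts required for both tissues")
    out = []
    for gid in order:
        tiss = targets[gid]
        if set(tiss) != {"SG", "WB"}:
            raise ValueError(f"gene {gid}: Cts required for both tissues")
        out.append(
            QpcrMeasurement(
                gene_id=gid,
                ct_target_sg=tiss["SG"], ct_target_wb=tiss["WB"],
                ct_ref_sg=refs["SG"], ct_ref_wb=refs["WB"],
            )
        )
    return out


def write_qpcr_tsv(rows: Sequence[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(QPCR_HEADER) + "\n")
        for r in rows:
            fh.write(
                f"{r['gene_id']}\t{r['ddct']:.4f}\t{r['fold_change']:.4f}\t"
                f"{r['log2_fold']:.4f}\t{r['rpkm_log2']:.4f}\t"
                f"{int(r['concordant'])}\n"
            )
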