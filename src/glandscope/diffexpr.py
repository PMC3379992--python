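"""Differential expression between two unreplicated count libraries.

The comparison uses the Audic-Claverie statistic: given ``x`` reads for a
gene in a library of size ``N1``, the probability of observing ``y`` reads
in a second library of size ``N2`` under equal underlying expression is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

i.e., Y | x follows a negative-binomial-shaped conditional distribution.
One-sided p is the smaller tail min(P(Y<=y), P(Y>=y)); the two-sided p is
twice that, clamped at 1.  All tail sums are accumulated in log space.

Calls combine a Benjamini-Hochberg FDR threshold (default 1e-3) with an
absolute log2 RPKM-ratio threshold (default 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .quantify import RegionCounts

__all__ = [
    "DEResult",
    "ac_pvalue",
    "bh_fdr",
    "call_de",
    "annotation_rate",
    "summarize_calls",
    "write_de_tsv",
    "read_de_tsv",
]

DE_HEADER = [
    "pair_id", "sg_rpkm", "wb_rpkm", "log2_ratio", "p_value", "fdr",
    "call", "annotation",
]

HIGHER = "higher_in_sg"
LOWER = "lower_in_sg"
NOT_DE = "not_de"


@dataclass
class DEResult:
    pair_id: str
    x: int
    y: int
    n1: int
    n2: int
    rpkm_sg: float
    rpkm_wb: float
    log2_ratio: float  # nan when both RPKMs are zero
    p_value: float
    fdr: float = math.nan
    call: str = NOT_DE
    ratio_flagged: bool = False  # one-sided zero RPKM was substituted
    annotation: str = ""


def _log_pmf_terms(ys: np.ndarray, x: int, log_r: float, log_1pr: float) -> np.ndarray:
    # log p(y|x) for an array of y
    return (
        ys * log_r
        + gammaln(x + ys + 1)
        - gammaln(x + 1)
        - gammaln(ys + 1)
        - (x + ys + 1) * log_1pr
    )


def ac_pmf(y: int, x: int, n1: int, n2: int) -> float:
    """The conditional probability p(y | x) of the Audic-Claverie model."""
    if x < 0 or y < 0:
        raise ValueError("counts must be nonnegative")
    r = n2 / n1
    term = _log_pmf_terms(np.array([y]), x, math.log(r), math.log1p(r))
    return float(np.exp(term[0]))


def ac_pvalue(x: int, y: int, n1: int, n2: int, sided: str = "two") -> float:
    """Audic-Claverie p-value for counts (x, y) from libraries (n1, n2).

    The lower tail P(Y<=y) is a direct log-space sum; the upper tail is
    summed from y upward until the terms are negligible relative to the
    accumulated tail (the conditional pmf decays geometrically past its
    mode), so small tails never suffer cancellation.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be nonnegative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    r = n2 / n1
    log_r, log_1pr = math.log(r), math.log1p(r)

    lower_terms = _log_pmf_terms(np.arange(y + 1), x, log_r, log_1pr)
    log_lower = float(logsumexp(lower_terms))
    p_lower = min(1.0, math.exp(log_lower))

    # upper tail: sum from y upward in blocks until converged
    block = max(64, 2 * (x + y + 8))
    start = y
    log_chunks: list[float] = []
    while True:
        ys = np.arange(start, start + block)
        terms = _log_pmf_terms(ys, x, log_r, log_1pr)
        log_chunks.append(float(logsumexp(terms)))
        total = float(logsumexp(log_chunks))
        # past the mode the pmf is dominated by a geometric series; stop once
        # the last term can no longer move the sum at double precision
        mean = (x + 1) * r  # conditional mean of Y given x
        if start + block > mean and terms[-1] < total + math.log(1e-18):
            break
        start += block
    p_upper = min(1.0, math.exp(float(logsumexp(log_chunks))))

    one_sided = min(p_lower, p_upper)
    if sided == "one":
        return one_sided
    return min(1.0, 2.0 * one_sided)


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(arr, method="fdr_bh")
    return [float(v) for v in adj]


def call_de(
    counts: Sequence[RegionCounts],
    n1: int,
    n2: int,
    fdr_cut: float = 1.0e-3,
    lfc_cut: float = 1.0,
    annotated_ids: set[str] | None = None,
) -> list[DEResult]:
    """Score all ortholog pairs and call differential expression.

    p-values are adjusted across the full result set before thresholding.
    If exactly one RPKM of a pair is zero, the smallest nonzero RPKM in the
    result set is substituted for the zero side and the row is flagged; if
    both are zero the ratio is undefined and the pair is never called.
    """
    nonzero = [
        v
        for c in counts
        for v in (c.rpkm_sg, c.rpkm_wb)
        if v > 0
    ]
    floor = min(nonzero) if nonzero else math.nan
    results: list[DEResult] = []
    for c in counts:
        flagged = False
        a, b = c.rpkm_sg, c.rpkm_wb
        if a == 0 and b == 0:
            ratio = math.nan
        else:
            if a == 0:
                a, flagged = floor, True
            elif b == 0:
                b, flagged = floor, True
            ratio = math.log2(a / b)
        p = ac_pvalue(c.count_sg, c.count_wb, n1, n2, sided="two")
        results.append(
            DEResult(
                pair_id=c.pair_id, x=c.count_sg, y=c.count_wb,
                n1=n1, n2=n2, rpkm_sg=c.rpkm_sg, rpkm_wb=c.rpkm_wb,
                log2_ratio=ratio, p_value=p, ratio_flagged=flagged,
            )
        )
    for res, adj in zip(results, bh_fdr([r.p_value for r in results])):
        res.fdr = adj
        if math.isnan(res.log2_ratio) or adj >= fdr_cut:
            res.call = NOT_DE
        elif res.log2_ratio >= lfc_cut:
            res.call = HIGHER
        elif res.log2_ratio <= -lfc_cut:
            res.call = LOWER
        else:
            res.call = NOT_DE
        if annotated_ids is not None and res.pair_id in annotated_ids:
            res.annotation = "annotated"
    return results


def annotation_rate(
    calls: Iterable[DEResult], annotated_ids: set[str]
) -> dict[str, dict[str, object]]:
    """Per-call-class annotation counts and percentages (one decimal).

    Percent is reported as None for an empty class.
    """
    out: dict[str, dict[str, object]] = {}
    for cls in (HIGHER, LOWER, NOT_DE):
        members = [r for r in calls if r.call == cls]
        n = len(members)
        n_annot = sum(1 for r in members if r.pair_id in annotated_ids)
        percent = round(100.0 * n_annot / n, 1) if n else None
        out[cls] = {"n": n, "n_annotated": n_annot, "percent": percent}
    return out


def summarize_calls(calls: Iterable[DEResult]) -> dict[str, int]:
    """Partition counts of a DE result set (total = higher + lower)."""
    calls = list(calls)
    higher = sum(1 for r in calls if r.call == HIGHER)
    lower = sum(1 for r in calls if r.call == LOWER)
    return {"de_total": higher + lower, "higher": higher, "lower": lower}


def write_de_tsv(results: Sequence[DEResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(DE_HEADER) + "\n")
        for r in results:
            fh.write(
                f"{r.pair_id}\t{r.rpkm_sg:.6f}\t{r.rpkm_wb:.6f}\t"
                f"{r.log2_ratio:.6f}\t{r.p_value:.6g}\t{r.fdr:.6g}\t"
                f"{r.call}\t{r.annotation}\n"
            )


def read_de_tsv(path) -> list[DEResult]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != DE_HEADER:
            raise ValueError(f"unexpected DE TSV header: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                DEResult(
                    pair_id=f[0], x=0, y=0, n1=0, n2=0,
                    rpkm_sg=float(f[1]), rpkm_wb=float(f[2]),
                    log2_ratio=float(f[3]), p_value=float(f[4]),
                    fdr=float(f[5]), call=f[6], annotation=f[7],
                )
            )
    return out
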