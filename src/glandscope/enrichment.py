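"""Hypergeometric term enrichment of a study gene set against a background.

For a term annotated to M of N background genes and m of n study genes, the
enrichment p-value is the upper tail

    P(X >= m) = 1 - sum_{i < m} C(M, i) C(N-M, n-i) / C(N, n)

for X ~ Hypergeometric(N, M, n).  N and n count genes with at least one
annotation in the tested namespace; terms are tested exactly as assigned (no
ontology-graph propagation).  Following the source protocol, a raw p cut-off
(default 5e-3) flags enrichment; an optional Benjamini-Hochberg adjustment
is available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.special import gammaln

from .diffexpr import bh_fdr

__all__ = [
    "TermAssignment",
    "EnrichmentInput",
    "EnrichmentResult",
    "load_assignments",
    "hypergeom_upper_tail",
    "run_enrichment",
    "write_enrichment_tsv",
]

ENRICH_HEADER = ["term_id", "sg_genes", "wb_genes", "p_value", "description"]


@dataclass(frozen=True)
class TermAssignment:
    gene_id: str
    term_id: str
    namespace: str = ""


@dataclass(frozen=True)
class EnrichmentInput:
    """The four counts of the enrichment test.

    N: background genes with >=1 annotation; n: study genes with >=1
    annotation; M / m: background / study genes annotated to the term.
    """

    N: int
    n: int
    M: int
    m: int

    def validate(self) -> None:
        if not (0 <= self.m <= self.n):
            raise ValueError(f"need 0 <= m <= n, got m={self.m}, n={self.n}")
        if not (self.m <= self.M <= self.N):
            raise ValueError(
                f"need m <= M <= N, got m={self.m}, M={self.M}, N={self.N}"
            )
        if self.n > self.N:
            raise ValueError(f"need n <= N, got n={self.n}, N={self.N}")


@dataclass
class EnrichmentResult:
    term_id: str
    N: int
    n: int
    M: int
    m: int
    p_value: float
    enriched: bool
    namespace: str = ""
    description: str = ""
    fdr: float | None = None


def load_assignments(path) -> list[TermAssignment]:
    """Read a `gene_id<TAB>term_id[<TAB>namespace]` table."""
    out: list[TermAssignment] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected >= 2 tab fields")
            gene, term = fields[0], fields[1]
            ns = fields[2] if len(fields) > 2 else ""
            if (gene, term) in seen:
                continue
            seen.add((gene, term))
            out.append(TermAssignment(gene, term, ns))
    return out


def _log_choose(a: int, b: int) -> float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_upper_tail(inp: EnrichmentInput) -> float:
    """P(X >= m) via a log-gamma evaluation of the hypergeometric pmf.

    The upper tail is summed directly over i = m .. min(n, M), which is
    accurate for small tails; the m = 0 census tail is exactly 1.
    """
    inp.validate()
    if inp.m == 0:
        return 1.0
    N, n, M, m = inp.N, inp.n, inp.M, inp.m
    log_denom = _log_choose(N, n)
    hi = min(n, M)
    log_terms = [
        _log_choose(M, i) + _log_choose(N - M, n - i) - log_denom
        for i in range(m, hi + 1)
        if n - i <= N - M
    ]
    if not log_terms:
        return 0.0
    peak = max(log_terms)
    total = peak + math.log(sum(math.exp(t - peak) for t in log_terms))
    return min(1.0, math.exp(total))


def backsolve_background_size(
    n: int, term_size: int, target_p: float, lo: int = 1000, hi: int = 20000
) -> int:
    """Recover an unprinted background size N from a census term's p-value.

    For a term carried by every one of its M background genes in the study
    set (m = M), the upper tail collapses to the point mass
    prod_{i<M} (n-i)/(N-i); given that printed p this is monotone in N, so
    the integer N whose point mass is closest to *target_p* is recovered by
    scanning [lo, hi].
    """
    best_n, best_err = lo, math.inf
    for N in range(lo, hi + 1):
        p = hypergeom_upper_tail(
            EnrichmentInput(N=N, n=n, M=term_size, m=term_size)
        )
        err = abs(math.log(p) - math.log(target_p))
        if err < best_err:
            best_n, best_err = N, err
    return best_n


def run_enrichment(
    study_genes: set[str],
    background_genes: set[str],
    assignments: Iterable[TermAssignment],
    p_cut: float = 5.0e-3,
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Test every term present in the study set, namespace by namespace.

    Results are sorted by ascending p.  A term seen in the study set but
    absent from the background violates M >= m and is an error.  When
    *adjust* is set, the enriched flag is applied to BH-adjusted values.
    """
    assignments = list(assignments)
    namespaces = sorted({a.namespace for a in assignments})
    results: list[EnrichmentResult] = []
    for ns in namespaces:
        ns_assign = [a for a in assignments if a.namespace == ns]
        bg_genes_ns = {a.gene_id for a in ns_assign} & background_genes
        st_genes_ns = {a.gene_id for a in ns_assign} & study_genes
        if not st_genes_ns or not bg_genes_ns:
            continue
        N, n = len(bg_genes_ns), len(st_genes_ns)
        by_term: dict[str, set[str]] = {}
        for a in ns_assign:
            by_term.setdefault(a.term_id, set()).add(a.gene_id)
        for term, genes in sorted(by_term.items()):
            m = len(genes & st_genes_ns)
            if m == 0:
                continue
            M = len(genes & bg_genes_ns)
            if M < m:
                raise ValueError(
                    f"term {term!r}: {m} study genes but only {M} background "
                    "genes carry it (study set must be drawn from the "
                    "background)"
                )
            p = hypergeom_upper_tail(EnrichmentInput(N=N, n=n, M=M, m=m))
            results.append(
                EnrichmentResult(
                    term_id=term, N=N, n=n, M=M, m=m, p_value=p,
                    enriched=p <= p_cut, namespace=ns,
                )
            )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    if adjust and results:
        adjusted = bh_fdr([r.p_value for r in results])
        for r, q in zip(results, adjusted):
            r.fdr = q
            r.enriched = q <= p_cut
    return results


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ENRICH_HEADER) + "\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.m}\t{r.M}\t{r.p_value:.6g}\t"
                f"{r.description}\n"
            )
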