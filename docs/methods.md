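# Methods

This note records the models, the numerical choices and the open design
decisions behind each stage, and what the synthetic-data generator does and
does not emulate.

## Ortholog pairing

Two de novo assemblies of the same species contain near-identical copies of
shared genes. The pairing stage declares two transcripts the same gene when
a local alignment reaches **identity strictly greater than 0.99 over at
least 150 alignment columns**. Identity is matching columns over total
alignment columns: gap columns count as mismatches, and `N` bases never
count as matches.

The aligner is exact-k-mer seeding (k = 20) followed by banded
Smith–Waterman extension with linear gap costs (match +1, mismatch −2,
gap −3; band = seeded diagonals ± 4). The scoring is deliberately
mismatch-averse so that optimal local alignments of near-identical
orthologs stay contiguous. The original protocol used MegaBLAST with
unstated parameters, so word size, penalties and the gap treatment here are
declared choices, not inferences. Ties are resolved deterministically: the
best cell is the first maximum in (row, column) scan order and traceback
prefers diagonal, then up, then left; the test suite verifies the banded
aligner is exactly equivalent to full quadratic Smith–Waterman on instances
up to 500 bp.

One-to-many conflicts keep the pair with highest identity, then longer
overlap, then lexicographic ids; each gene appears in at most one accepted
pair. Only forward-strand matches are searched by default (assemblies are
assumed consistently oriented); `search_reverse=True` also tries the
reverse complement. All reported coordinates are 1-based inclusive.

A consequence of local alignment worth knowing: a mismatch within ~2 bp of
an alignment end can be trimmed at equal or better score, so pairs whose
excess mismatches sit at the extreme ends are recovered slightly more often
than a fixed-window mismatch count predicts. The recovery property test
accounts for this by using a 99% binomial band rather than an equality.

## Read counting and RPKM

Each library is mapped to its own side of the clipped regions (tissue reads
to the tissue-side sequences, whole-body reads to the whole-body side), by
exact substring matching on either strand of the read. Rationale for exact
matching: the generator's reads are error-free and the clipped regions are
the reads' own source sequences; a `max_mismatches` option (brute-force
scan) exists for stress tests. A read whose sequence occurs in two or more
distinct regions is discarded as ambiguous — near-identical paralogs must
not be double counted — and ambiguous reads are excluded from the library
size. `total_mapped` is therefore the number of uniquely assigned reads
over the clipped-region set only, and it is both the RPKM denominator
(RPKM = 10⁹·C/(N·L)) and the library size of the count statistic. The
conservation identity (assigned + ambiguous + unmapped = total reads) is
enforced by test.

## Differential expression

The Audic–Claverie conditional distribution of the second count given the
first,

    p(y|x) = (N₂/N₁)^y (x+y)! / (x! y! (1+N₂/N₁)^(x+y+1)),

is evaluated in log space (log-gamma terms). The lower tail P(Y ≤ y) is a
direct log-sum-exp; the upper tail is summed from y upward in blocks until
the last term is 10⁻¹⁸ below the accumulated sum — past the conditional
mode the pmf decays geometrically, so small tails are computed directly and
never by 1 − CDF cancellation. One-sided p is the smaller tail; two-sided
doubles it with a clamp at 1 (the protocol does not state sidedness; tail
doubling is the declared choice). The suite checks the implementation
against an independent negative-binomial tail oracle at relative tolerance
10⁻⁹ for all x, y ≤ 50 and library ratios 0.5/1/2.

A note on symmetry: under this definition the two-sided p is **not**
exactly invariant to swapping the libraries together with the counts (the
conditioning variable changes); the exact identity that does hold,
p(y|x; N₁,N₂) = (N₁/N₂)·p(x|y; N₂,N₁), is what the tests assert. The
statistic is conservative for discrete counts; its null rejection rate at
0.05 is verified to stay at or below nominal over 10,000 simulated null
pairs.

FDR control is Benjamini–Hochberg (the protocol names only "FDR"; BH is
the standard step-up for roughly independent tests), delegated to
`statsmodels.stats.multitest` behind the module surface and cross-checked
against a naive quadratic implementation. Calls: `higher_in_sg` iff
FDR < 10⁻³ and log₂(RPKM ratio) ≥ 1; `lower_in_sg` symmetric; otherwise
`not_de`. Adjustment happens across the full result set before any call.

Zero counts: if exactly one RPKM of a pair is zero, the smallest nonzero
RPKM in the result set is substituted for the zero side and the row is
flagged (the ratio is then a conservative bound, not an estimate); if both
are zero the ratio is undefined and the pair is never called.

## Term enrichment

N and n count genes with ≥ 1 annotation in the tested namespace
(background and study respectively); M and m count the genes carrying the
term. P(X ≥ m) is summed directly over the upper tail via log-gamma
binomial coefficients. Terms are tested exactly as assigned — no
ontology-graph propagation or level slimming; pre-rolled assignments are
the caller's responsibility. The enriched flag applies the raw p ≤ 5·10⁻³
cut-off of the source protocol; a BH-adjusted variant exists but is off by
default. A term present in the study set but absent from the background
violates m ≤ M and is an error: the study set must be drawn from the
background.

`backsolve_background_size` exists because a census term (m = M) collapses
the upper tail to the point mass Π_{i<M}(n−i)/(N−i), which is monotone in
N — so an unprinted background size can be recovered approximately from a
printed census p-value. The suite uses this only as a cross-consistency
check between printed enrichment rows, at order-of-magnitude tolerance.

## Secretome triage

CDS extraction is homology-first: the lowest-E BLASTx hit (ties: highest
bit score) fixes the reading frame and anchors the coding region; the CDS
is the surrounding in-frame stop-free stretch, started at the first
upstream in-frame ATG when one exists. Without hits, the fallback is the
longest ORF over all six frames with a 30-codon minimum — a deliberate,
declared stand-in for a dedicated coding-region HMM, adequate for the
synthetic proteins here. A CDS with no in-frame start codon is marked
5′-incomplete, and such proteins are excluded from secretome calling
outright (verdict `incomplete_5p`): a signal peptide cannot be assessed
without the true N-terminus. This makes explicit a filtering that otherwise
happens silently through failed signal-peptide predictions.

The retention rule: signal peptide present and either zero TM segments, or
exactly one TM segment that coincides with the signal peptide. "Coincides"
is operationalized as interval overlap with residues 1..cleavage−1, since
no numeric rule is stated in the protocol. The accounting identity
secreted = SP-positive-complete − removed-by-TM holds on any batch.

External predictors are consumed as files (SignalP 3.0 short format — the
D-score decision and Ymax position are used; TMHMM short format; or
canonical TSVs) and never executed. The bundled hydropathy predictor
(Kyte–Doolittle window scans) exists only so the triage can run
self-contained in tests; it is co-designed with the generator's planted
proteins and makes no claim about real sequences.

Homolog filtering against a reference secretome keeps the best hit per
query at E ≤ 10⁻⁵ (ties: higher bit score).

## qPCR

2^(−ΔΔCt) with amplification efficiency fixed at exact doubling, replicates
summarized by the arithmetic mean of Ct. Concordance compares
sign(log₂ fold change) with sign(log₂ RPKM ratio); a zero on either side
(fold change exactly 1, or ratio exactly 0) is concordant with nothing —
ties count as discordant. Reference-gene stability is screened by
|log₂(RPKM_A/RPKM_B)| < 1.

## Synthetic data

What the generator emulates: two assemblies sharing near-identical
orthologs (i.i.d. per-base substitutions at rate 0.003 — comfortably inside
the > 99% identity gate for typical lengths), transcript lengths from a
150 bp-shifted log-normal with mean ≈ 300 bp (echoing the study's mean
unigene length of 297 bp), 90 bp error-free reads drawn with probability
proportional to expression × length and uniform starts, base expression
log-normal (median 100, σ = 1 on the log scale), planted 4-fold changes
(half up, half down), uniformly-assigned background terms with planted
terms covering the up-regulated genes at rate 0.5 vs 0.02 baseline,
secreted labels on 15% of genes (cleavage sites in residues 16–30) with an
extra TM planted on exactly round(0.2·k) of the k SP-positive genes, and
Ct values Ct = 35 − log₂(expression) + N(0, 0.2 cycles) in triplicate. The
default scenario is 2,000 shared genes, 500 assembly-unique genes per side,
and two libraries of 500,000 reads — at that depth a median gene collects
roughly 200 reads per library, so planted 4-fold changes are comfortably
detectable, while the lognormal left tail still exercises the low-count
regime. The 20-gene qPCR panel is drawn from the planted changes (half per
direction), mirroring the validation design of assaying already-called
genes.

What it does not emulate — and hence what passing tests do not show about
real data: sequencing errors and quality scores (an error-rate option
exists but defaults off), amplification bias of SMART-style protocols
(which compresses observed ratios), assembly artifacts (chimeras,
fragmented or redundant unigenes), paralogy (unique genes are independent
random sequences, so cross-mapping ambiguity is essentially absent rather
than merely rare), realistic ontology structure (terms are independent
labels, not a DAG), and real signal-peptide sequence diversity.

Determinism: every generator takes a seed and the scenario writer derives
per-stage sub-seeds from one master seed; identical seeds produce bitwise
identical files, and the pipeline itself is deterministic given its inputs.

## Problem sizes used by the test suite

The session-scoped end-to-end fixture runs the default scenario exactly as
the acceptance script does (2,000 pairs, 2 × 500,000 reads). Distributional
property tests use the smallest sizes at which their bands are meaningful:
400 pairs for recovery-vs-binomial, 10,000 null pairs for the type-I check,
1,000 pairs for the mutation-count oracle, 60 genes × 60,000 reads for the
Poisson sampling band. Oracle-equivalence grids are exhaustive (all
x, y ≤ 50 for the count statistic; all of C(12,6) draws for the
hypergeometric enumeration).

## Known limitations

- The pairing stage is a stand-in for MegaBLAST with declared parameters;
  identity over alignment columns can differ from BLAST's reported identity
  on gapped alignments.
- Exact-match read counting is correct for the generator's error-free reads
  but would undercount on real data; the mismatch-tolerant path is a slow
  reference implementation, not a production mapper.
- The longest-ORF fallback under-calls CDSs relative to a trained
  coding-region model on real transcripts.
- Enrichment treats gene–term assignments as flat labels; studies using
  ontology levels must pre-roll their assignments.
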