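"""End-to-end orchestration: pair -> quantify -> de -> enrich -> secretome
-> qpcr, with a YAML config, structured logging and a summary report."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from . import diffexpr, enrichment, pairing, qpcr, quantify, secretome

log = logging.getLogger("glandscope")

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All inputs, outputs and thresholds of one pipeline run.

    Threshold defaults are the protocol's: ortholog pairs at identity
    > 0.99 over >= 150 bp, DE at FDR < 1e-3 and |log2 ratio| >= 1,
    enrichment at p <= 5e-3, homolog filtering at E <= 1e-5.
    """

    sg_fasta: str = ""
    wb_fasta: str = ""
    sg_reads: str = ""
    wb_reads: str = ""
    terms: str = ""
    cds_fasta: str = ""
    sp_topology: str = ""
    tm_topology: str = ""
    ct_table: str = ""
    homologs: str = ""
    annotated_ids: str = ""
    reference_gene: str = ""
    outdir: str = "glandscope_out"
    min_identity: float = 0.99
    min_overlap: int = 150
    max_mismatches: int = 0
    fdr: float = 1.0e-3
    lfc: float = 1.0
    enrich_p: float = 5.0e-3
    e_cut: float = 1.0e-5
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must lie in (0, 1]")
        for name in ("min_overlap",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fdr", "lfc", "enrich_p", "e_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _require(path: str, stage: str) -> Path:
    p = Path(path)
    if not path or not p.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: required input missing: {path!r}"
        )
    return p


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage in order and return the summary report.

    Optional stages (enrichment, secretome, qPCR) run only when their
    inputs are configured.  Each stage writes its TSV before the next
    starts, so earlier outputs survive a later failure.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"thresholds": {
        "min_identity": config.min_identity, "min_overlap": config.min_overlap,
        "fdr": config.fdr, "lfc": config.lfc, "enrich_p": config.enrich_p,
        "e_cut": config.e_cut, "seed": config.seed,
    }}

    # --- pair ---------------------------------------------------------
    sg = pairing.load_transcripts(_require(config.sg_fasta, "pair"))
    wb = pairing.load_transcripts(_require(config.wb_fasta, "pair"))
    pairs = pairing.find_ortholog_pairs(
        sg, wb, config.min_identity, config.min_overlap
    )
    sg_by_id = {t.id: t for t in sg}
    wb_by_id = {t.id: t for t in wb}
    regions = [
        pairing.clip_overlap(p, sg_by_id[p.sg_id], wb_by_id[p.wb_id])
        for p in pairs
    ]
    pairing.write_pairs_tsv(pairs, outdir / "pairs.tsv")
    pairing.write_regions_fasta(regions, outdir / "regions.fasta")
    report["pairs_found"] = len(pairs)
    log.info("pair: %d ortholog pairs", len(pairs))
    if not pairs:
        raise RuntimeError("stage 'pair': no ortholog pairs found")

    # --- quantify -----------------------------------------------------
    sg_lib = quantify.load_reads(_require(config.sg_reads, "quantify"), "SG")
    wb_lib = quantify.load_reads(_require(config.wb_reads, "quantify"), "WB")
    counts, sg_summary, wb_summary = quantify.quantify_pairs(
        regions, sg_lib, wb_lib, config.max_mismatches
    )
    quantify.write_counts_tsv(counts, outdir / "counts.tsv")
    report["mapping"] = {
        "sg": vars(sg_summary), "wb": vars(wb_summary),
    }
    log.info(
        "quantify: SG %d/%d mapped (%d ambiguous), WB %d/%d mapped (%d ambiguous)",
        sg_summary.mapped, sg_summary.total_reads, sg_summary.ambiguous,
        wb_summary.mapped, wb_summary.total_reads, wb_summary.ambiguous,
    )

    # --- differential expression -------------------------------------
    annotated: set[str] = set()
    if config.annotated_ids:
        with open(_require(config.annotated_ids, "de")) as fh:
            annotated = {line.strip() for line in fh if line.strip()}
    sg_id_of_pair = {p.pair_id: p.sg_id for p in pairs}
    annotated_pairs = {
        pid for pid, sid in sg_id_of_pair.items() if sid in annotated
    }
    de = diffexpr.call_de(
        counts, sg_lib.total_mapped, wb_lib.total_mapped,
        config.fdr, config.lfc, annotated_pairs or None,
    )
    diffexpr.write_de_tsv(de, outdir / "de.tsv")
    report["de"] = diffexpr.summarize_calls(de)
    if annotated:
        rates = diffexpr.annotation_rate(de, annotated_pairs)
        report["annotation_rates"] = {
            cls: rates[cls] for cls in (diffexpr.HIGHER, diffexpr.LOWER)
        }
    log.info("de: %(de_total)d called (%(higher)d high / %(lower)d low)", report["de"])

    # --- enrichment ---------------------------------------------------
    if config.terms:
        assignments = enrichment.load_assignments(_require(config.terms, "enrich"))
        study = {
            sg_id_of_pair[r.pair_id] for r in de if r.call == diffexpr.HIGHER
        }
        background = {p.sg_id for p in pairs}
        results = enrichment.run_enrichment(
            study, background, assignments, config.enrich_p
        )
        enrichment.write_enrichment_tsv(results, outdir / "enrichment.tsv")
        report["enrichment"] = {
            "terms_tested": len(results),
            "terms_enriched": sum(r.enriched for r in results),
            "enriched_terms": [r.term_id for r in results if r.enriched],
        }
        log.info("enrich: %d terms enriched", report["enrichment"]["terms_enriched"])

    # --- secretome ----------------------------------------------------
    if config.cds_fasta:
        cds_transcripts = pairing.load_transcripts(
            _require(config.cds_fasta, "secretome")
        )
        topology = secretome.load_topology(
            _require(config.sp_topology, "secretome") if config.sp_topology else None,
            _require(config.tm_topology, "secretome") if config.tm_topology else None,
        )
        cdss = []
        for t in cds_transcripts:
            cds = secretome.extract_cds(t)
            if cds is None:
                log.info("secretome: no CDS for %s, skipped", t.id)
                continue
            cdss.append(cds)
        verdicts, summary = secretome.triage_batch(cdss, topology)
        with open(outdir / "secretome.tsv", "w") as fh:
            fh.write("gene_id\tverdict\treason\n")
            for v in verdicts:
                fh.write(f"{v.gene_id}\t{v.verdict}\t{v.reason}\n")
        report["secretome"] = summary
        if config.homologs:
            hits = secretome.read_blast_tabular(
                _require(config.homologs, "secretome")
            )
            best = secretome.filter_homologs(hits, config.e_cut)
            best.to_csv(outdir / "homologs.tsv", sep="\t", index=False)
            report["secretome"]["homolog_queries"] = int(best["query"].nunique())
        log.info("secretome: %(secreted)d secreted of %(sp_positive_complete)d SP+",
                 report["secretome"])

    # --- qPCR ---------------------------------------------------------
    if config.ct_table:
        measurements = qpcr.load_ct_table(
            _require(config.ct_table, "qpcr"), config.reference_gene
        )
        log2_by_sg = {
            sg_id_of_pair[r.pair_id]: r.log2_ratio
            for r in de
            if not math.isnan(r.log2_ratio)
        }
        rows = []
        folds, ratios = [], []
        for m in measurements:
            if m.gene_id not in log2_by_sg:
                continue
            fc = qpcr.relative_expression(m)
            lr = log2_by_sg[m.gene_id]
            folds.append(fc)
            ratios.append(lr)
            rows.append(
                {
                    "gene_id": m.gene_id, "ddct": m.ddct, "fold_change": fc,
                    "log2_fold": math.log2(fc), "rpkm_log2": lr,
                    "concordant": (fc > 1) == (lr > 0) and fc != 1 and lr != 0,
                }
            )
        conc = qpcr.direction_concordance(folds, ratios)
        qpcr.write_qpcr_tsv(rows, outdir / "qpcr.tsv")
        report["qpcr"] = conc
        log.info("qpcr: %(n_concordant)d/%(n)d concordant", conc)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
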