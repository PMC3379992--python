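"""Shared fixtures: small handcrafted inputs and one full synthetic run.

The full scenario (2,000 shared ortholog pairs, 500 assembly-unique genes
per side, 200 planted 4-fold changes, two libraries of 500,000 90 bp reads)
is generated and pushed through the whole pipeline once per session; tests
that evaluate recovery against the planted truth share its outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glandscope.pipeline import PipelineConfig, run_pipeline
from glandscope.simulate import simulate_scenario

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    simdir = tmp_path_factory.mktemp("sim")
    outdir = tmp_path_factory.mktemp("out")
    truth = simulate_scenario(simdir, seed=101)
    cfg = PipelineConfig(
        sg_fasta=str(simdir / "sg.fasta"),
        wb_fasta=str(simdir / "wb.fasta"),
        sg_reads=str(simdir / "sg.fastq"),
        wb_reads=str(simdir / "wb.fastq"),
        terms=str(simdir / "terms.tsv"),
        cds_fasta=str(simdir / "cds.fasta"),
        sp_topology=str(simdir / "sp.tsv"),
        tm_topology=str(simdir / "tm.tsv"),
        ct_table=str(simdir / "ct.tsv"),
        reference_gene=truth.reference_gene,
        outdir=str(outdir),
    )
    report = run_pipeline(cfg)
    return {
        "simdir": simdir,
        "outdir": outdir,
        "truth": truth,
        "report": report,
        "config": cfg,
    }


@pytest.fixture(scope="session")
def default_de_table(default_run) -> pd.DataFrame:
    de = pd.read_csv(default_run["outdir"] / "de.tsv", sep="\t")
    de["sg_id"] = de["pair_id"].str.split("|").str[0]
    truth = default_run["truth"].genes
    counts = pd.read_csv(default_run["outdir"] / "counts.tsv", sep="\t")
    return truth.merge(de, on="sg_id", how="left").merge(
        counts[["pair_id", "count_sg", "count_wb"]], on="pair_id", how="left"
    )
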