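"""Shared fixtures: small simulated worlds reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from retrotrace import sequencing as seqn
from retrotrace.models import random_te_model
from retrotrace.scenarios import annotation_truth, copy_number_truth
from retrotrace.workflow import PipelineConfig, run_stage


@pytest.fixture(scope="session")
def te_model():
    return random_te_model("Ty4", np.random.default_rng(11))


@pytest.fixture(scope="session")
def small_world(tmp_path_factory):
    """A 6-strain single-species world with genomes, reads, and alignments."""
    d = tmp_path_factory.mktemp("small_world")
    truth = copy_number_truth(n_strains=6, seed=3)
    genomes = seqn.emit_genomes(truth, bg_length=40_000, seed=11)
    strain = truth.strains[0]
    g = genomes[strain]
    fastq, _ = seqn.simulate_reads(g, 50.0, 100, 0.01, seed=5, out_path=d / f"{strain}.fastq")
    bam = seqn.emit_alignments(fastq, g, truth.te_models, d / f"{strain}.bam")
    return {
        "truth": truth,
        "genomes": genomes,
        "strain": strain,
        "fastq": fastq,
        "bam": bam,
        "dir": d,
    }


@pytest.fixture(scope="session")
def annotation_world():
    """An 8-strain world containing FLEs, truncated copies, and solo LTRs."""
    truth = annotation_truth(n_strains=8, seed=2)
    genomes = seqn.emit_genomes(truth, bg_length=40_000, seed=9)
    return {"truth": truth, "genomes": genomes}


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run over the two-species HTT world."""
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(outdir=str(outdir), seed=1, n_per_species=12)
    manifests = run_stage("all", cfg)
    return {"cfg": cfg, "outdir": outdir, "manifests": manifests}
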