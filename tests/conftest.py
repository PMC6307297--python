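import numpy as np
import pytest

from heartlnc.candidate_filter import ExpressionMatrix
from heartlnc.genome_model import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptModel,
)
from heartlnc.pipeline import simulate_bundle
from heartlnc.synthetic_data import (
    SimulationConfig,
    simulate_annotation,
    simulate_expression,
)


def make_transcript(
    tid="t1",
    gid="g1",
    biotype="lncRNA_candidate",
    chrom="chr1",
    start=1000,
    strand="+",
    exon_lengths=(200, 300),
    intron=500,
    cds_length=0,
):
    """Small helper: a transcript with the given exon/intron block lengths."""
    exons = []
    pos = start
    for ln in exon_lengths:
        exons.append(GenomicInterval(chrom, pos, pos + ln, strand))
        pos += ln + intron
    span = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
    return TranscriptModel(tid, gid, biotype, span, tuple(exons), cds_length=cds_length)


def make_gene(gid="g1", biotype="protein_coding", transcripts=None, **kwargs):
    if transcripts is None:
        transcripts = (make_transcript(tid=f"{gid}.t1", gid=gid, biotype=biotype, **kwargs),)
    return GeneModel(gid, biotype, tuple(transcripts))


def make_matrix(rows, samples=("heart_E10.5", "heart_E13.5", "heart_adult", "brain_adult")):
    """rows: dict transcript_id -> sequence of fpkm aligned with samples."""
    import pandas as pd

    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(samples))
    return ExpressionMatrix.from_dataframe(df)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def sim_data(sim_config):
    annotation, truth = simulate_annotation(sim_config)
    matrix = simulate_expression(annotation, truth, sim_config)
    return annotation, truth, matrix


@pytest.fixture(scope="session")
def bundle(tmp_path_factory, sim_config):
    outdir = tmp_path_factory.mktemp("bundle")
    run_config = simulate_bundle(sim_config, outdir)
    return outdir, run_config


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
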