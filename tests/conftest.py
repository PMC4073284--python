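"""Shared fixtures: toy transcripts, tag factories, small simulations."""

import numpy as np
import pytest

from rbpreg.clip_reads import ClipTag
from rbpreg.genome_model import GeneIndex, GenomicInterval, TranscriptModel
from rbpreg.synthetic_data import SimulationConfig, make_genome


@pytest.fixture
def two_exon_plus():
    """Plus-strand transcript: exons [0,100) and [200,300), CDS 50-250."""
    return TranscriptModel(
        gene_id="GA",
        transcript_id="GA.t1",
        chrom="chr1",
        strand="+",
        exons=[(0, 100), (200, 300)],
        cds_start=50,
        cds_end=250,
    )


@pytest.fixture
def two_exon_minus():
    """Same coordinates on the minus strand (UTR labels swap)."""
    return TranscriptModel(
        gene_id="GB",
        transcript_id="GB.t1",
        chrom="chr1",
        strand="-",
        exons=[(0, 100), (200, 300)],
        cds_start=50,
        cds_end=250,
    )


def make_tag(chrom="chr1", start=0, end=None, strand="+", rep="R1",
             barcode="AAAAAA", deletions=(), count=1, read_id="r0"):
    if end is None:
        end = start + 40
    return ClipTag(
        interval=GenomicInterval(chrom, start, end, strand),
        replicate_id=rep,
        barcode=barcode,
        deletion_offsets=tuple(deletions),
        collapsed_count=count,
        read_id=read_id,
    )


@pytest.fixture
def tag_factory():
    return make_tag


@pytest.fixture
def small_genome():
    cfg = SimulationConfig(seed=42, n_genes=8, n_sites=4)
    return cfg, make_genome(cfg)


@pytest.fixture
def gene_index(small_genome):
    _, genome = small_genome
    return GeneIndex(genome.models)


def random_tags(rng, n, chroms=("chr1",), span=2000, rep_ids=("R1", "R2")):
    """Random tag set for brute-force oracle comparisons."""
    tags = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(20, 60))
        n_dels = int(rng.integers(0, 3))
        dels = tuple(sorted(set(int(x) for x in rng.integers(0, length, n_dels))))
        tags.append(
            make_tag(
                chrom=str(rng.choice(list(chroms))),
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
                rep=str(rng.choice(list(rep_ids))),
                barcode="".join(rng.choice(list("ACGT"), 6)),
                deletions=dels,
                read_id=f"r{i:05d}",
            )
        )
    return tags
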