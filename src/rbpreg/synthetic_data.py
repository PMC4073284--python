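"""Synthetic inputs with ground truth for every pipeline stage.

Generates a toy genome annotation, CLIP tag pileups with planted binding
sites, crosslink deletions and PCR duplicates, cassette-exon junction
reads at set inclusion rates, negative-binomial dose-response count
matrices for two wild-type clones and one mutant clone, and exponential
decay time courses.  Everything is driven by a single integer seed and
is deterministic; truth tables accompany each output so downstream
modules can be validated without re-simulation.

Scales are chosen to exercise the statistics (site coverage around 40,
triplicate junction depth 200, 2000-gene count matrices), not to mimic
genome-scale sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clip_reads import ClipTag
from .genome_model import GenomicInterval, TranscriptModel, derive_regions
from .splicing import CassetteEvent

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All knobs for the synthetic study, with study-condition defaults."""

    seed: int
    # genome
    n_genes: int = 30
    exon_count_range: tuple[int, int] = (4, 7)
    exon_length_mean: int = 250
    exon_length_min: int = 120
    intron_length_mean: int = 700
    intron_length_min: int = 200
    last_exon_extra: int = 400  # lengthens the 3'UTR-bearing exon
    intergenic_gap: int = 2000
    # CLIP
    replicates: tuple[str, ...] = ("R1", "R2")
    n_sites: int = 20
    site_regions: tuple[str, ...] = ("3UTR", "intron")
    site_tag_rate: float = 20.0  # Poisson mean tags per site per replicate
    background_rate: float = 2.0  # Poisson mean background tags per gene per replicate
    intergenic_rate: float = 0.0  # Poisson mean tags per intergenic gap per replicate
    tag_length_range: tuple[int, int] = (30, 50)
    deletion_prob: float = 0.3
    background_deletion_prob: float = 0.01
    duplication_mean: float = 3.0
    plant_polyu: bool = True
    index_to_replicate: Mapping[str, str] = field(
        default_factory=lambda: {"ACGTAC": "R1", "TGCATG": "R2"}
    )
    # cassette exons
    n_cassette_events: int = 40
    n_regulated_events: int = 20  # half included, half excluded
    regulated_delta_i: float = 0.4
    null_ir: float = 0.5
    junction_depth: int = 200
    rnaseq_replicates: int = 3
    # dose response
    n_dose_genes: int = 2000
    n_up: int = 40
    n_down: int = 30
    doses: tuple[float, ...] = (0.0, 5.0, 10.0, 50.0, 100.0, 250.0)
    dose_replicates: int = 3  # matches the triplicate RNA-seq design
    nb_dispersion: float = 0.1
    lowest_dose_log2fc: float = 2.0  # clearly detectable: 4-fold at lowest dose
    base_mean_range: tuple[float, float] = (50.0, 2000.0)
    library_size_sd: float = 0.25
    clones: tuple[str, str, str] = ("WT6", "WT10", "MUT3")
    # decay
    decay_half_lives: Mapping[str, float] = field(
        default_factory=lambda: {
            "WT6_Ctrl": 2.3,
            "WT6_Dox": 9.8,
            "WT10_Ctrl": 2.4,
            "WT10_Dox": 5.4,
            "MUT3_Ctrl": 2.1,
            "MUT3_Dox": 2.2,
        }
    )
    decay_timepoints: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0)
    decay_noise_sd: float = 0.05
    decay_replicates: int = 3

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class Genome:
    models: list[TranscriptModel]
    sequences: dict[str, str]

    def gene(self, gene_id: str) -> TranscriptModel:
        return next(m for m in self.models if m.gene_id == gene_id)


def _lengths(rng, n, mean, minimum):
    return (minimum + rng.exponential(mean - minimum, size=n)).astype(int)


def make_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> Genome:
    """Deterministic toy genome on a single chromosome.

    Every transcript carries a 5'UTR, CDS and 3'UTR (CDS runs from the
    middle of the first exon to an interior point of the last exon) and
    has at least one intron; exon counts >= 3 keep cassette-event hosts
    available.  Strands alternate so both orientations are exercised.
    """
    rng = rng if rng is not None else config.rng()
    models = []
    cursor = config.intergenic_gap
    for i in range(config.n_genes):
        n_exons = int(rng.integers(*config.exon_count_range, endpoint=True))
        exon_lens = _lengths(rng, n_exons, config.exon_length_mean, config.exon_length_min)
        intron_lens = _lengths(
            rng, n_exons - 1, config.intron_length_mean, config.intron_length_min
        )
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            exon_lens[-1] += config.last_exon_extra
        else:
            exon_lens[0] += config.last_exon_extra
        exons = []
        pos = cursor
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        # CDS: middle of 5'-most exon to interior of 3'-most exon
        if strand == "+":
            cds_start = exons[0][0] + (exons[0][1] - exons[0][0]) // 2
            cds_end = exons[-1][0] + max(
                1, (exons[-1][1] - exons[-1][0]) // 4
            )
        else:
            cds_end = exons[-1][0] + (exons[-1][1] - exons[-1][0]) // 2 + 1
            cds_start = exons[0][1] - max(1, (exons[0][1] - exons[0][0]) // 4)
        models.append(
            TranscriptModel(
                gene_id=f"G{i:04d}",
                transcript_id=f"G{i:04d}.t1",
                chrom="chrS",
                strand=strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
        cursor = pos + config.intergenic_gap
    seq = "".join(rng.choice(_BASES, size=cursor + config.intergenic_gap))
    return Genome(models, {"chrS": seq})


def write_genome(genome: Genome, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the annotation (GTF) and chromosome sequence (FASTA)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gtf = out_dir / "annotation.gtf"
    fasta = out_dir / "genome.fa"
    with open(gtf, "w", encoding="utf-8") as fh:
        for m in genome.models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\trbpreg_sim\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.cds_start is not None:
                for s, e in m.exons:
                    cs, ce = max(s, m.cds_start), min(e, m.cds_end)
                    if cs < ce:
                        fh.write(
                            f"{m.chrom}\trbpreg_sim\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t.\t{attrs}\n"
                        )
    with open(fasta, "w", encoding="utf-8") as fh:
        for chrom, seq in sorted(genome.sequences.items()):
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i: i + 80] + "\n")
    return gtf, fasta


@dataclass
class PlantedSite:
    gene_id: str
    chrom: str
    position: int  # crosslink position (deletion center)
    strand: str
    region: str


@dataclass
class ClipSimResult:
    aligned_reads: list[ClipTag]  # pre-dedup; one entry per PCR copy
    sites: list[PlantedSite]
    n_unique_tags: dict[str, int]  # per replicate, truth after collapse
    n_aligned_reads: dict[str, int]
    n_intergenic_tags: int


def _pick_site_position(model: TranscriptModel, region: str) -> int | None:
    regions = derive_regions(model)
    ivs = regions.get(region, [])
    ivs = [iv for iv in ivs if len(iv) >= 80]
    if not ivs:
        return None
    iv = max(ivs, key=len)
    return (iv.start + iv.end) // 2


def simulate_clip(
    genome: Genome, config: SimulationConfig, rng: np.random.Generator
) -> ClipSimResult:
    """Plant binding sites and emit duplicated, deletion-bearing reads.

    Tags are a mixture of site-enriched and uniform gene background per
    replicate; PCR duplicates share alignment start and degenerate
    barcode; deletions concentrate at the planted crosslink position
    with the configured probability.  When ``plant_polyu`` is set the
    genome sequence around each site center is overwritten with a T run
    (the DNA-space image of a U-rich footprint).
    """
    sites: list[PlantedSite] = []
    candidates = [m for m in genome.models]
    ri = 0
    for m in candidates:
        if len(sites) >= config.n_sites:
            break
        region = config.site_regions[ri % len(config.site_regions)]
        pos = _pick_site_position(m, region)
        if pos is None:
            continue
        sites.append(PlantedSite(m.gene_id, m.chrom, pos, m.strand, region))
        ri += 1
    if config.plant_polyu and sites:
        for chrom in genome.sequences:
            arr = list(genome.sequences[chrom])
            for s in sites:
                if s.chrom == chrom:
                    # U-rich in transcript orientation: genomic T on the
                    # plus strand, genomic A on the minus strand
                    base = "T" if s.strand == "+" else "A"
                    arr[s.position - 4: s.position + 5] = base * 9
            genome.sequences[chrom] = "".join(arr)

    lmin, lmax = config.tag_length_range
    aligned: list[ClipTag] = []
    used_keys: set[tuple] = set()
    n_unique = {r: 0 for r in config.replicates}
    n_reads = {r: 0 for r in config.replicates}
    n_intergenic = 0
    read_serial = 0

    def fresh_barcode(rep: str, chrom: str, start: int, strand: str) -> str:
        while True:
            bc = "".join(rng.choice(_BASES, size=6))
            key = (rep, chrom, start, strand, bc)
            if key not in used_keys:
                used_keys.add(key)
                return bc

    def emit(rep, chrom, start, length, strand, deletions):
        nonlocal read_serial
        bc = fresh_barcode(rep, chrom, start, strand)
        n_unique[rep] += 1
        n_copies = int(rng.geometric(1.0 / config.duplication_mean))
        for _ in range(n_copies):
            aligned.append(
                ClipTag(
                    interval=GenomicInterval(chrom, start, start + length, strand),
                    replicate_id=rep,
                    barcode=bc,
                    deletion_offsets=tuple(deletions),
                    collapsed_count=1,
                    read_id=f"read{read_serial:07d}",
                )
            )
            read_serial += 1
            n_reads[rep] += 1

    for rep in config.replicates:
        for s in sites:
            n = rng.poisson(config.site_tag_rate)
            for _ in range(n):
                length = int(rng.integers(lmin, lmax, endpoint=True))
                offset = int(rng.integers(3, length - 3))
                start = s.position - offset
                dels = [offset] if rng.random() < config.deletion_prob else []
                emit(rep, s.chrom, start, length, s.strand, dels)
        for m in genome.models:
            n = rng.poisson(config.background_rate)
            span = m.span
            for _ in range(n):
                length = int(rng.integers(lmin, lmax, endpoint=True))
                start = int(rng.integers(span.start, max(span.start + 1, span.end - length)))
                dels = (
                    [int(rng.integers(0, length))]
                    if rng.random() < config.background_deletion_prob
                    else []
                )
                emit(rep, m.chrom, start, length, m.strand, dels)
        if config.intergenic_rate > 0:
            spans = sorted((m.span.start, m.span.end) for m in genome.models)
            gaps = []
            prev = 0
            for s0, e0 in spans:
                if s0 - prev > 200:
                    gaps.append((prev, s0))
                prev = max(prev, e0)
            for lo, hi in gaps:
                n = rng.poisson(config.intergenic_rate)
                for _ in range(n):
                    length = int(rng.integers(lmin, lmax, endpoint=True))
                    start = int(rng.integers(lo, max(lo + 1, hi - length)))
                    strand = "+" if rng.random() < 0.5 else "-"
                    rep_pick = config.replicates[int(rng.integers(len(config.replicates)))]
                    emit(rep_pick, "chrS", start, length, strand, [])
                    n_intergenic += 1
    return ClipSimResult(aligned, sites, n_unique, n_reads, n_intergenic)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def raw_reads_fastq(
    sim: ClipSimResult,
    genome: Genome,
    config: SimulationConfig,
    rng: np.random.Generator,
    path: str | Path,
) -> dict[str, int]:
    """Write protocol-layout FASTQ for the simulated aligned reads.

    Each record is index + degenerate barcode + insert + polyA tail; the
    insert is the genomic sequence of the tag (reverse-complemented on
    the minus strand) with deleted bases removed.  Returns per-replicate
    read counts (the demultiplexing truth table).
    """
    rep_to_index = {v: k for k, v in config.index_to_replicate.items()}
    counts = {r: 0 for r in config.replicates}
    with open(path, "w", encoding="utf-8") as fh:
        for t in sim.aligned_reads:
            seq = genome.sequences[t.interval.chrom][t.interval.start: t.interval.end]
            seq = "".join(
                b for i, b in enumerate(seq) if i not in set(t.deletion_offsets)
            )
            if t.interval.strand == "-":
                seq = seq.translate(_COMPLEMENT)[::-1]
            tail = "A" * int(rng.integers(8, 16))
            full = rep_to_index[t.replicate_id] + t.barcode + seq + tail
            fh.write(f"@{t.read_id}\n{full}\n+\n{'I' * len(full)}\n")
            counts[t.replicate_id] += 1
    return counts


# ---------------------------------------------------------------------------
# cassette exons


@dataclass
class CassetteSim:
    events: list[CassetteEvent]
    truth_ir: dict[str, dict[str, float]]  # event_id -> condition -> IR
    truth_class: dict[str, str]  # event_id -> included/excluded/null
    junction_reads: pd.DataFrame
    condition_design: dict[str, str]  # sample -> condition


def make_cassette_events(
    genome: Genome, config: SimulationConfig
) -> list[CassetteEvent]:
    """One event per host gene with >= 3 exons (first exon triple)."""
    events = []
    for m in genome.models:
        if len(events) >= config.n_cassette_events:
            break
        if len(m.exons) < 3:
            continue
        e1, e2, e3 = m.exons[0], m.exons[1], m.exons[2]
        events.append(
            CassetteEvent(
                event_id=f"ev_{m.gene_id}",
                gene_id=m.gene_id,
                chrom=m.chrom,
                strand=m.strand,
                up_exon=e1,
                ca_exon=e2,
                down_exon=e3,
            )
        )
    return events


def simulate_junction_reads(
    events: Sequence[CassetteEvent],
    config: SimulationConfig,
    rng: np.random.Generator,
    treatment: str = "induced",
    control: str = "control",
) -> CassetteSim:
    """Binomial junction counts at planted inclusion rates.

    The first ``n_regulated_events`` alternate included (+dI) and
    excluded (-dI) with reciprocal truth IRs centered on 0.5; the rest
    are null (equal IR in both conditions).  Counts are drawn per
    replicate at ``junction_depth``: the two inclusion junctions and the
    skip junction are independent binomials with success probabilities
    IR, IR and 1 - IR.
    """
    half = config.regulated_delta_i / 2
    truth_ir: dict[str, dict[str, float]] = {}
    truth_class: dict[str, str] = {}
    design: dict[str, str] = {}
    for r in range(config.rnaseq_replicates):
        design[f"{treatment}_{r + 1}"] = treatment
        design[f"{control}_{r + 1}"] = control
    rows = []
    for i, ev in enumerate(events):
        if i < config.n_regulated_events:
            if i % 2 == 0:
                ir_t, ir_c = 0.5 + half, 0.5 - half
                truth_class[ev.event_id] = "included"
            else:
                ir_t, ir_c = 0.5 - half, 0.5 + half
                truth_class[ev.event_id] = "excluded"
        else:
            ir_t = ir_c = config.null_ir
            truth_class[ev.event_id] = "null"
        truth_ir[ev.event_id] = {treatment: ir_t, control: ir_c}
        juncs = ev.junctions()
        for sample, cond in design.items():
            ir = truth_ir[ev.event_id][cond]
            d = config.junction_depth
            counts = {
                "inc_up": int(rng.binomial(d, ir)),
                "inc_down": int(rng.binomial(d, ir)),
                "skip": int(rng.binomial(d, 1 - ir)),
            }
            for role, (donor, acceptor) in juncs.items():
                rows.append(
                    {
                        "chrom": ev.chrom,
                        "donor": donor,
                        "acceptor": acceptor,
                        "strand": ev.strand,
                        "sample": sample,
                        "count": counts[role],
                    }
                )
    frame = pd.DataFrame(
        rows, columns=["chrom", "donor", "acceptor", "strand", "sample", "count"]
    )
    return CassetteSim(list(events), truth_ir, truth_class, frame, design)


def simulate_splice_binding_tags(
    events: Sequence[CassetteEvent],
    event_ids: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
    n_tags_per_replicate: int = 8,
    intron_offset_max: int = 60,
) -> list[ClipTag]:
    """CLIP tags planted just inside the CA-exon acceptor intron.

    Used to exercise the binding-splicing association: only the listed
    events receive tags, upstream of the cassette exon's acceptor site
    in transcript orientation.
    """
    lmin, lmax = config.tag_length_range
    chosen = {e for e in event_ids}
    tags = []
    serial = 0
    for ev in events:
        if ev.event_id not in chosen:
            continue
        # CA acceptor: intron1/CA boundary on +, CA/intron2 boundary on -
        if ev.strand == "+":
            boundary = ev.ca_exon[0]
            lo, hi = boundary - intron_offset_max, boundary - 5
        else:
            boundary = ev.ca_exon[1]
            lo, hi = boundary + 5, boundary + intron_offset_max
        for rep in config.replicates:
            for _ in range(n_tags_per_replicate):
                length = int(rng.integers(lmin, lmax, endpoint=True))
                center = int(rng.integers(min(lo, hi), max(lo, hi)))
                start = center - length // 2
                tags.append(
                    ClipTag(
                        interval=GenomicInterval(ev.chrom, start, start + length, ev.strand),
                        replicate_id=rep,
                        barcode="".join(rng.choice(_BASES, size=6)),
                        read_id=f"splice_tag{serial:06d}",
                    )
                )
                serial += 1
    return tags


# ---------------------------------------------------------------------------
# dose response


@dataclass
class DoseSim:
    counts: pd.DataFrame  # genes x samples
    design: pd.DataFrame  # sample, clone, dose
    truth_up: list[str]
    truth_down: list[str]


def simulate_dose_counts(
    config: SimulationConfig,
    rng: np.random.Generator,
    gene_ids: Sequence[str] | None = None,
) -> DoseSim:
    """Negative-binomial count matrices for the three-clone dose design.

    Planted UP/DOWN genes (a random subset) respond in the wild-type
    clones only, with a saturating log2 effect proportional to
    log1p(dose) scaled so the lowest nonzero dose already shows
    ``lowest_dose_log2fc``.  Library sizes vary lognormally to exercise
    normalization.  ``gene_ids`` optionally names the first rows (e.g.
    with annotation gene ids, so screens can be joined with binding
    tables).
    """
    n = config.n_dose_genes
    genes = [f"g{i:05d}" for i in range(n)]
    if gene_ids is not None:
        for i, gid in enumerate(gene_ids[: n]):
            genes[i] = gid
    planted = rng.choice(n, size=config.n_up + config.n_down, replace=False)
    direction = np.zeros(n)
    direction[planted[: config.n_up]] = 1.0
    direction[planted[config.n_up:]] = -1.0
    truth_up = [genes[i] for i in sorted(planted[: config.n_up])]
    truth_down = [genes[i] for i in sorted(planted[config.n_up:])]
    lo, hi = config.base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    doses = np.array(config.doses)
    d_low = min(d for d in doses if d > 0)
    beta_max = config.lowest_dose_log2fc * np.log1p(doses.max()) / np.log1p(d_low)

    samples, clones_col, doses_col = [], [], []
    columns = {}
    disp = config.nb_dispersion
    nb_n = 1.0 / disp
    for clone in config.clones:
        is_wt = clone != config.clones[2]
        for dose in doses:
            effect = (
                direction * beta_max * np.log1p(dose) / np.log1p(doses.max())
                if is_wt
                else np.zeros(n)
            )
            for r in range(config.dose_replicates):
                sample = f"{clone}_d{dose:g}_r{r + 1}"
                sf = float(np.exp(rng.normal(0.0, config.library_size_sd)))
                mu = base * (2.0 ** effect) * sf
                p = nb_n / (nb_n + mu)
                columns[sample] = rng.negative_binomial(nb_n, p)
                samples.append(sample)
                clones_col.append(clone)
                doses_col.append(dose)
    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    design = pd.DataFrame(
        {"sample": samples, "clone": clones_col, "dose": doses_col}
    )
    return DoseSim(counts, design, truth_up, truth_down)


# ---------------------------------------------------------------------------
# decay


def simulate_decay(
    config: SimulationConfig, rng: np.random.Generator, gene_id: str = "target1"
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Exponential decay courses with multiplicative lognormal noise.

    Rows at t = 0 are fixed at 1 (the data are defined as t0-normalized).
    Returns the tidy time-course table and the truth half-lives.
    """
    rows = []
    for cond, t_half in config.decay_half_lives.items():
        for rep in range(1, config.decay_replicates + 1):
            for t in config.decay_timepoints:
                value = 2.0 ** (-t / t_half)
                if t > 0 and config.decay_noise_sd > 0:
                    value *= float(np.exp(rng.normal(0.0, config.decay_noise_sd)))
                rows.append(
                    {
                        "gene": gene_id,
                        "condition": cond,
                        "replicate": f"rep{rep}",
                        "time_hr": t,
                        "value": value,
                    }
                )
    df = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "time_hr", "value"])
    return df, dict(config.decay_half_lives)
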