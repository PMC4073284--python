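"""End-to-end orchestration with deterministic, atomically written outputs.

The default parameter block encodes the analysis thresholds used
throughout: biological complexity 2, cluster tags >= 10, peak height >=
10, reproducibility p <= 0.01, CIMS k >= 5 at FDR <= 0.01, splicing
|dI| >= 0.2 at Fisher p <= 0.05 with >= 10 junction reads, binding call
tags >= 10 in BC2 tags >= 5 clusters, screen p < 0.01 in both wild-type
clones with mutant p > 0.05, and strong binders > 100 tags per
transcript.  Any override is recorded in the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clip_clusters import (
    annotate_clusters,
    apply_stringency_tiers,
    build_clusters,
    clusters_to_frame,
    region_distribution,
    tags_per_transcript,
)
from .clip_reads import collapse_duplicates, count_unique_tags, write_tags
from .cims import (
    base_composition_enrichment,
    cims_fdr,
    collect_deletion_sites,
    extract_footprints,
    sites_to_frame,
)
from .decay import compare_half_lives, estimate_half_life, fits_to_frame, series_from_frame
from .dose_response import (
    DoseDesign,
    dose_correlation,
    integrate_binding,
    screen_targets,
    size_factor_normalize,
)
from .genome_model import GeneIndex, write_tsv
from .splicing import (
    bound_exon,
    call_regulated_exons,
    complexity_map,
    count_junction_reads,
    delta_i,
    events_to_frame,
    fisher_splice_test,
)
from .synthetic_data import (
    SimulationConfig,
    make_cassette_events,
    make_genome,
    simulate_clip,
    simulate_decay,
    simulate_dose_counts,
    simulate_junction_reads,
    simulate_splice_binding_tags,
    write_genome,
)

log = logging.getLogger("rbpreg")


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    sim: SimulationConfig | None = None
    # cluster tiers
    min_tags_t1: int = 2
    min_tags_t2: int = 10
    min_peak: int = 10
    alpha_peak: float = 0.01
    alpha_repro: float = 0.01
    # CIMS
    cims_min_k: int = 5
    cims_max_fdr: float = 0.01
    n_permutations: int = 100
    # splicing
    splice_min_reads: int = 10
    splice_min_delta_i: float = 0.2
    splice_alpha: float = 0.05
    bound_min_cluster_tags: int = 5
    bound_min_total_tags: int = 10
    # dose screen
    screen_alpha_wt: float = 0.01
    screen_alpha_mut: float = 0.05
    screen_lowest_dose_fc: float = 0.585
    strong_binder_threshold: int = 100

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim = SimulationConfig(seed=cfg.seed, **sim_raw)
        return cfg


def _atomic_write_tsv(df: pd.DataFrame, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        write_tsv(df, tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _param_hash(config: PipelineConfig) -> str:
    params = dataclasses.asdict(config)
    params.pop("out_dir", None)  # a location, not an analysis parameter
    blob = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the synthetic bundle and write the result set.

    Outputs land in ``config.out_dir``: tag/cluster BED tables, the CIMS
    table, splicing calls, complexity-map matrices, target gene lists,
    binder integration and half-lives, plus a run manifest enabling
    byte-identical re-runs.  Stage outputs are written atomically, so a
    partial failure leaves prior stage outputs intact.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    rng = np.random.default_rng(config.seed)
    results: dict = {}

    log.info("stage genome: %d genes", sim.n_genes)
    genome = make_genome(sim, rng)
    clip = simulate_clip(genome, sim, rng)
    write_genome(genome, out)
    index = GeneIndex(genome.models)

    log.info("stage dedup: %d aligned reads", len(clip.aligned_reads))
    tags = collapse_duplicates(clip.aligned_reads)
    write_tags(tags, out / "tags.bed")
    tag_summary = count_unique_tags(tags, index)
    _atomic_write_tsv(tag_summary, out / "tag_summary.tsv")
    results["n_unique_tags"] = {
        r: int(n) for r, n in zip(tag_summary["replicate"], tag_summary["n_tags"])
    }

    log.info("stage clusters")
    clusters = build_clusters(tags)
    annotate_clusters(clusters, index, list(sim.replicates), config.alpha_repro)
    tiers = apply_stringency_tiers(
        clusters,
        n_replicates=len(sim.replicates),
        min_tags_t1=config.min_tags_t1,
        min_tags_t2=config.min_tags_t2,
        min_peak=config.min_peak,
        alpha_peak=config.alpha_peak,
        alpha_repro=config.alpha_repro,
    )
    _atomic_write_tsv(clusters_to_frame(clusters, tiers), out / "clusters.tsv")
    region_frame, _ = region_distribution(tiers, index)
    _atomic_write_tsv(region_frame, out / "region_distribution.tsv")
    results["tier_sizes"] = {k: len(v) for k, v in tiers.items()}

    log.info("stage cims")
    candidates = collect_deletion_sites(tags)
    annotated, reproducible = cims_fdr(
        candidates,
        tags,
        n_permutations=config.n_permutations,
        seed=config.seed,
        min_k=config.cims_min_k,
        max_fdr=config.cims_max_fdr,
    )
    _atomic_write_tsv(sites_to_frame(annotated), out / "cims_candidates.tsv")
    _atomic_write_tsv(sites_to_frame(reproducible), out / "cims_reproducible.tsv")
    results["n_cims_candidates"] = len(annotated)
    results["n_cims_reproducible"] = len(reproducible)
    if reproducible:
        fps = extract_footprints(reproducible, genome.sequences)
        bg_rng = np.random.default_rng(config.seed + 1)
        chrom = reproducible[0].chrom
        seq = genome.sequences[chrom]
        bg = [
            seq[p: p + 21]
            for p in bg_rng.integers(0, len(seq) - 21, size=max(50, len(fps)))
        ]
        enrich = base_composition_enrichment([w for _, w, _ in fps], bg)
        results["cims_u_enrichment"] = enrich

    log.info("stage splicing")
    events = make_cassette_events(genome, sim)
    cassette = simulate_junction_reads(events, sim, rng)
    count_junction_reads(cassette.junction_reads, cassette.events)
    splice_tags = simulate_splice_binding_tags(
        cassette.events,
        [e for e, c in cassette.truth_class.items() if c == "included"],
        sim,
        rng,
    )
    splice_clusters = build_clusters(splice_tags)
    included, excluded = [], []
    for ev in cassette.events:
        delta_i(ev, cassette.condition_design, "induced", "control")
        fisher_splice_test(ev, cassette.condition_design, "induced", "control")
        bound_exon(
            ev,
            splice_clusters,
            n_replicates=len(sim.replicates),
            min_cluster_tags=config.bound_min_cluster_tags,
            min_total_tags=config.bound_min_total_tags,
        )
    included, excluded = call_regulated_exons(
        cassette.events,
        min_reads=config.splice_min_reads,
        min_abs_delta_i=config.splice_min_delta_i,
        alpha=config.splice_alpha,
    )
    _atomic_write_tsv(events_to_frame(cassette.events), out / "splicing_events.tsv")
    results["n_included"] = len(included)
    results["n_excluded"] = len(excluded)
    results["n_bound_included"] = sum(e.bound for e in included)
    results["n_bound_excluded"] = sum(e.bound for e in excluded)
    cmap_rows = []
    for label, evs in (("included", included), ("excluded", excluded)):
        profiles = complexity_map(evs, splice_tags)
        for boundary, prof in profiles.items():
            for off, val in zip(prof["offsets"], prof["value"]):
                cmap_rows.append(
                    {"class": label, "boundary": boundary, "offset": int(off), "value": float(val)}
                )
    _atomic_write_tsv(pd.DataFrame(cmap_rows), out / "complexity_map.tsv")

    log.info("stage dose screen")
    dose = simulate_dose_counts(
        sim, rng, gene_ids=[m.gene_id for m in genome.models]
    )
    normalized, factors = size_factor_normalize(dose.counts)
    design = DoseDesign.from_frame(dose.design, wt_clones=sim.clones[:2], mut_clone=sim.clones[2])
    correlations = dose_correlation(
        normalized, design, use_log_dose=True, use_log_expression=True
    )
    up, down, table = screen_targets(
        normalized,
        design,
        correlations,
        alpha_wt=config.screen_alpha_wt,
        alpha_mut=config.screen_alpha_mut,
        lowest_dose_fc=config.screen_lowest_dose_fc,
    )
    table.insert(0, "gene", table.index)
    _atomic_write_tsv(table.reset_index(drop=True), out / "dose_screen.tsv")
    (out / "up_genes.txt").write_text("\n".join(up) + "\n", encoding="utf-8")
    (out / "down_genes.txt").write_text("\n".join(down) + "\n", encoding="utf-8")
    results["n_up"] = len(up)
    results["n_down"] = len(down)
    binder_totals = tags_per_transcript(clusters, n_replicates=len(sim.replicates))
    results["binding_integration"] = integrate_binding(
        up, down, binder_totals, config.strong_binder_threshold
    )

    log.info("stage decay")
    decay_df, decay_truth = simulate_decay(sim, rng)
    series = series_from_frame(decay_df)
    fits = [estimate_half_life(s) for s in series]
    _atomic_write_tsv(fits_to_frame(fits), out / "half_lives.tsv")
    by_cond = {s.condition_id: s for s in series}
    comparisons = []
    for clone in ("WT6", "WT10", "MUT3"):
        a, b = by_cond.get(f"{clone}_Ctrl"), by_cond.get(f"{clone}_Dox")
        if a is None or b is None:
            continue
        comp = compare_half_lives(a, b, seed=config.seed)
        comparisons.append(
            {
                "clone": clone,
                "fold_change": comp.fold_change,
                "ci_low": comp.ci_low,
                "ci_high": comp.ci_high,
            }
        )
    _atomic_write_tsv(pd.DataFrame(comparisons), out / "half_life_comparisons.tsv")
    results["half_life_fold_changes"] = {
        c["clone"]: c["fold_change"] for c in comparisons
    }

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "parameter_hash": _param_hash(config),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results
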