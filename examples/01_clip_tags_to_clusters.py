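"""From raw CLIP evidence to tiered binding-site clusters.

Simulates a small genome with planted binding sites, collapses PCR
duplicates into unique tags, merges tags into clusters, and applies the
four stringency tiers (replicate support, tag count, peak height
significance, replicate balance).
"""

from rbpreg.clip_clusters import (
    annotate_clusters,
    apply_stringency_tiers,
    build_clusters,
    region_distribution,
)
from rbpreg.clip_reads import collapse_duplicates, count_unique_tags
from rbpreg.genome_model import GeneIndex
from rbpreg.synthetic_data import SimulationConfig, make_genome, simulate_clip

cfg = SimulationConfig(seed=7)
rng = cfg.rng()
genome = make_genome(cfg, rng)
sim = simulate_clip(genome, cfg, rng)
print(f"{len(sim.aligned_reads)} aligned reads from {cfg.n_sites} planted sites")

tags = collapse_duplicates(sim.aligned_reads)
index = GeneIndex(genome.models)
print(count_unique_tags(tags, index).to_string(index=False))
print("-> PCR duplicates removed via (replicate, position, barcode) keys;")
print("   the genic fraction is the share of tags inside annotated genes.")

clusters = build_clusters(tags)
annotate_clusters(clusters, index, list(cfg.replicates))
tiers = apply_stringency_tiers(clusters)
print({k: len(v) for k, v in tiers.items()})
print("-> nested tiers T1..T4; planted sites survive every filter while")
print("   scattered background drops out.")

frame, _ = region_distribution(tiers, index)
print(frame[frame.n_clusters > 0].to_string(index=False))
print("-> region mix of the retained binding sites (3'UTR and intron here,")
print("   by construction of the planted sites).")
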