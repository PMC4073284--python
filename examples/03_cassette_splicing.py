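"""Cassette-exon inclusion statistics and the binding-splicing map.

Junction reads quantify each event's inclusion rate (IR); dI is the
difference in mean IR between conditions; events pass with >= 10
junction reads, |dI| >= 0.2 and Fisher p <= 0.05.  The normalized
complexity map locates binding around the composite exon-intron
boundaries.
"""

import numpy as np

from rbpreg.splicing import (
    bound_exon,
    call_regulated_exons,
    complexity_map,
    count_junction_reads,
    delta_i,
    fisher_splice_test,
)
from rbpreg.clip_clusters import build_clusters
from rbpreg.synthetic_data import (
    SimulationConfig,
    make_cassette_events,
    make_genome,
    simulate_junction_reads,
    simulate_splice_binding_tags,
)

cfg = SimulationConfig(seed=21)
rng = cfg.rng()
genome = make_genome(cfg, rng)
events = make_cassette_events(genome, cfg)
sim = simulate_junction_reads(events, cfg, rng)
count_junction_reads(sim.junction_reads, sim.events)

included_truth = [e for e, c in sim.truth_class.items() if c == "included"]
tags = simulate_splice_binding_tags(events, included_truth, cfg, rng)
clusters = build_clusters(tags)

for ev in sim.events:
    delta_i(ev, sim.condition_design, "induced", "control")
    fisher_splice_test(ev, sim.condition_design, "induced", "control")
    bound_exon(ev, clusters)

included, excluded = call_regulated_exons(sim.events)
print(f"{len(included)} included / {len(excluded)} excluded events called "
      f"(truth: {len(included_truth)} / "
      f"{sum(c == 'excluded' for c in sim.truth_class.values())})")
print(f"bound among included: {sum(e.bound for e in included)}, "
      f"among excluded: {sum(e.bound for e in excluded)}")
print("-> binding was planted upstream of the cassette acceptor of included")
print("   events only, so only those carry the binding flag.")

profiles = complexity_map(included, tags)
peaks = {b: float(p["value"].max()) for b, p in profiles.items()}
print({b: round(v, 2) for b, v in peaks.items()})
print("-> the included-event profile peaks at the CA acceptor boundary;")
print("   a value of 1.0 means every event has a tag at that offset.")
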