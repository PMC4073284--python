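"""Cassette-exon inclusion statistics, screening, binding association."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rbpreg.clip_clusters import build_clusters
from rbpreg.splicing import (
    CassetteEvent,
    JunctionCounts,
    bound_exon,
    call_regulated_exons,
    complexity_map,
    count_junction_reads,
    delta_i,
    fisher_splice_test,
    inclusion_rate,
)

from conftest import make_tag


def make_event(event_id="ev1", strand="+", chrom="chr1"):
    return CassetteEvent(
        event_id=event_id,
        gene_id="GA",
        chrom=chrom,
        strand=strand,
        up_exon=(0, 200),
        ca_exon=(1000, 1100),
        down_exon=(2000, 2200),
    )


DESIGN = {
    **{f"induced_{i}": "induced" for i in (1, 2, 3)},
    **{f"control_{i}": "control" for i in (1, 2, 3)},
}


class TestCountJunctionReads:
    def test_direct_match(self):
        ev = make_event()
        evidence = pd.DataFrame(
            [
                {"chrom": "chr1", "donor": 200, "acceptor": 1000, "strand": "+",
                 "sample": "s1", "count": 20},
                {"chrom": "chr1", "donor": 1100, "acceptor": 2000, "strand": "+",
                 "sample": "s1", "count": 40},
                {"chrom": "chr1", "donor": 200, "acceptor": 2000, "strand": "+",
                 "sample": "s1", "count": 10},
            ]
        )
        unmatched = count_junction_reads(evidence, [ev])
        c = ev.counts["s1"]
        assert (c.inc_up, c.inc_down, c.skip) == (20, 40, 10)
        assert unmatched == 0

    def test_off_by_one_is_unmatched(self):
        ev = make_event()
        evidence = pd.DataFrame(
            [{"chrom": "chr1", "donor": 201, "acceptor": 1000, "strand": "+",
              "sample": "s1", "count": 7}]
        )
        assert count_junction_reads(evidence, [ev]) == 7
        assert "s1" not in ev.counts

    def test_minus_strand_role_flip(self):
        ev = make_event(strand="-")
        # on the minus strand the genomic-right junction is 5'CE-CA
        evidence = pd.DataFrame(
            [{"chrom": "chr1", "donor": 1100, "acceptor": 2000, "strand": "-",
              "sample": "s1", "count": 9}]
        )
        count_junction_reads(evidence, [ev])
        assert ev.counts["s1"].inc_up == 9

    def test_malformed_event_rejected(self):
        with pytest.raises(ValueError, match="out of order"):
            CassetteEvent("bad", "G", "chr1", "+", (0, 200), (100, 300), (400, 500))


class TestInclusionRate:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((20, 40, 10), 0.75),
            ((10, 10, 0), 1.0),
            ((0, 0, 30), 0.0),
        ],
    )
    def test_formula(self, counts, expected):
        assert inclusion_rate(JunctionCounts(*counts)) == pytest.approx(expected)

    def test_all_zero_is_nan(self):
        assert math.isnan(inclusion_rate(JunctionCounts(0, 0, 0)))

    def test_scale_invariance(self):
        base = JunctionCounts(12, 18, 6)
        scaled = JunctionCounts(120, 180, 60)
        assert inclusion_rate(base) == pytest.approx(inclusion_rate(scaled))


class TestDeltaI:
    def _with_irs(self, ir_ind, ir_ctrl, depth=100):
        ev = make_event()
        for i, ir in enumerate(ir_ind, 1):
            n_inc = int(round(depth * ir))
            ev.counts[f"induced_{i}"] = JunctionCounts(n_inc, n_inc, depth - n_inc)
        for i, ir in enumerate(ir_ctrl, 1):
            n_inc = int(round(depth * ir))
            ev.counts[f"control_{i}"] = JunctionCounts(n_inc, n_inc, depth - n_inc)
        return ev

    def test_replicate_averaging(self):
        ev = self._with_irs([0.9, 0.88, 0.92], [0.5, 0.52, 0.48])
        d = delta_i(ev, DESIGN, "induced", "control")
        assert d == pytest.approx(0.40, abs=1e-9)

    def test_identical_conditions_zero(self):
        ev = self._with_irs([0.6] * 3, [0.6] * 3)
        assert delta_i(ev, DESIGN, "induced", "control") == pytest.approx(0.0)

    def test_antisymmetric_under_condition_swap(self):
        ev = self._with_irs([0.8, 0.7, 0.75], [0.3, 0.35, 0.4])
        d1 = delta_i(ev, DESIGN, "induced", "control")
        d2 = delta_i(ev, DESIGN, "control", "induced")
        assert d1 == pytest.approx(-d2)

    def test_missing_condition_error(self):
        ev = self._with_irs([0.5], [])
        with pytest.raises(ValueError, match="control"):
            delta_i(ev, DESIGN, "induced", "control")

    def test_simulated_reciprocal_events_recovered(self):
        from rbpreg.synthetic_data import (
            SimulationConfig, make_cassette_events, make_genome,
            simulate_junction_reads,
        )

        cfg = SimulationConfig(
            seed=3, n_genes=30, n_cassette_events=30, n_regulated_events=10,
            junction_depth=200,
        )
        rng = cfg.rng()
        genome = make_genome(cfg, rng)
        sim = simulate_junction_reads(make_cassette_events(genome, cfg), cfg, rng)
        count_junction_reads(sim.junction_reads, sim.events)
        errors = []
        for ev in sim.events:
            d = delta_i(ev, sim.condition_design, "induced", "control")
            truth = (
                sim.truth_ir[ev.event_id]["induced"]
                - sim.truth_ir[ev.event_id]["control"]
            )
            errors.append(d - truth)
        assert abs(float(np.mean(errors))) < 0.05


def fisher_oracle(table):
    """Exhaustive hypergeometric enumeration of the two-sided p."""
    (a, b), (c, d) = table
    n1, n2, k = a + b, c + d, a + c
    rv = stats.hypergeom(n1 + n2, n1, k)
    support = range(max(0, k - n2), min(k, n1) + 1)
    p_obs = rv.pmf(a)
    return sum(rv.pmf(x) for x in support if rv.pmf(x) <= p_obs * (1 + 1e-9))


class TestFisherSpliceTest:
    def _event_with_tables(self, ind, ctrl):
        ev = make_event()
        ev.counts["induced_1"] = JunctionCounts(ind[0], ind[0], ind[1])
        ev.counts["control_1"] = JunctionCounts(ctrl[0], ctrl[0], ctrl[1])
        return ev

    def test_no_association(self):
        ev = make_event()
        ev.counts["induced_1"] = JunctionCounts(5, 5, 10)
        ev.counts["control_1"] = JunctionCounts(5, 5, 10)
        assert fisher_splice_test(ev, DESIGN, "induced", "control") == pytest.approx(1.0)

    def test_perfect_separation_example(self):
        ev = make_event()
        ev.counts["induced_1"] = JunctionCounts(5, 5, 0)
        ev.counts["control_1"] = JunctionCounts(0, 0, 10)
        p = fisher_splice_test(ev, DESIGN, "induced", "control")
        # 2 / C(20, 10)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert p == pytest.approx(1.082509e-5, rel=1e-4)

    def test_zero_margin_convention(self):
        ev = make_event()
        ev.counts["induced_1"] = JunctionCounts(0, 0, 0)
        ev.counts["control_1"] = JunctionCounts(0, 0, 5)
        assert fisher_splice_test(ev, DESIGN, "induced", "control") == 1.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(150):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, 4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            p_scipy = stats.fisher_exact([[a, b], [c, d]])[1]
            assert p_scipy == pytest.approx(fisher_oracle([[a, b], [c, d]]), rel=1e-7)


class TestCallRegulated:
    def _ev(self, di, p, reads):
        ev = make_event(event_id=f"e{di}{p}{reads}")
        per = max(1, reads // 3)
        ev.counts["s1"] = JunctionCounts(per, per, reads - 2 * per)
        ev.delta_i = di
        ev.fisher_p = p
        return ev

    def test_threshold_examples(self):
        included, excluded = call_regulated_exons(
            [
                self._ev(0.4, 0.001, 60),  # passes, included
                self._ev(0.15, 0.0001, 60),  # |dI| too small
                self._ev(-0.5, 0.01, 60),  # passes, excluded
                self._ev(0.4, 0.2, 60),  # p too large
                self._ev(0.4, 0.001, 6),  # too few reads
            ]
        )
        assert [e.delta_i for e in included] == [0.4]
        assert [e.delta_i for e in excluded] == [-0.5]


class TestBoundExon:
    def _bc2_cluster(self, start, n_per_rep):
        tags = [
            make_tag(start=start, end=start + 40, rep=r, read_id=f"{start}{r}{i}")
            for r in ("R1", "R2")
            for i in range(n_per_rep)
        ]
        (cl,) = build_clusters(tags)
        return cl

    def test_single_cluster_in_flanking_intron(self):
        ev = make_event()
        assert bound_exon(ev, [self._bc2_cluster(500, 6)])  # 12 tags in 5'FI

    def test_two_clusters_sum(self):
        ev = make_event()
        clusters = [self._bc2_cluster(500, 3), self._bc2_cluster(1500, 3)]  # 6+6...
        assert bound_exon(ev, clusters)

    def test_bc1_cluster_never_bound(self):
        ev = make_event()
        tags = [make_tag(start=500, end=540, rep="R1", read_id=f"x{i}")
                for i in range(100)]
        (cl,) = build_clusters(tags)
        assert not bound_exon(ev, [cl])

    def test_cluster_outside_span_ignored(self):
        ev = make_event()
        assert not bound_exon(ev, [self._bc2_cluster(5000, 20)])


class TestComplexityMap:
    def test_tags_tiling_flanking_intron(self):
        ev = make_event()  # 5'FI = [200, 1000), length 800, midpoint 400
        tags = [
            make_tag(start=s, end=s + 50, read_id=f"t{s}")
            for s in range(150, 1000, 25)
        ]
        profiles = complexity_map([ev], tags, window=1000, exon_margin=50)
        donor = profiles["5CE_donor"]
        # intron side valid until the midpoint (offset < 400)
        intronic = donor["value"][donor["offsets"] >= 0]
        assert np.all(intronic[:400] == 1.0)
        assert np.all(intronic[400:] == 0.0)

    def test_no_tags_all_zero(self):
        profiles = complexity_map([make_event()], [], window=500)
        for prof in profiles.values():
            assert np.all(prof["value"] == 0.0)

    def test_values_bounded_and_match_coverage_oracle(self):
        rng = np.random.default_rng(4)
        events = [make_event(), make_event(event_id="ev2", strand="-")]
        starts = rng.integers(0, 2200, size=80)
        tags = [
            make_tag(start=int(s), end=int(s) + 45,
                     strand="+" if rng.random() < 0.5 else "-",
                     read_id=f"r{i}")
            for i, s in enumerate(starts)
        ]
        profiles = complexity_map(events, tags, window=300, exon_margin=30)
        for prof in profiles.values():
            assert np.all(prof["value"] >= 0.0) and np.all(prof["value"] <= 1.0)
            # values are multiples of 1/n_events
            assert np.allclose(prof["value"] * len(events),
                               np.round(prof["value"] * len(events)))

    def test_planted_acceptor_binding_localizes(self):
        from rbpreg.synthetic_data import (
            SimulationConfig, make_cassette_events, make_genome,
            simulate_splice_binding_tags,
        )

        cfg = SimulationConfig(seed=6, n_genes=20, n_cassette_events=10)
        rng = cfg.rng()
        genome = make_genome(cfg, rng)
        events = make_cassette_events(genome, cfg)
        tags = simulate_splice_binding_tags(
            events, [e.event_id for e in events], cfg, rng
        )
        profiles = complexity_map(events, tags)
        peak_by_boundary = {b: prof["value"].max() for b, prof in profiles.items()}
        assert max(peak_by_boundary, key=peak_by_boundary.get) == "CA_acceptor"
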