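"""Cluster building, peak statistics, reproducibility, stringency tiers."""

import numpy as np
import pytest
from scipy import stats

from rbpreg.clip_clusters import (
    annotate_clusters,
    apply_stringency_tiers,
    build_clusters,
    peak_height,
    peak_significance,
    region_distribution,
    reproducibility_score,
    tags_per_transcript,
)
from rbpreg.genome_model import GeneIndex

from conftest import make_tag, random_tags


def connected_components_oracle(tags):
    """Brute-force cluster membership via the tag overlap graph."""
    n = len(tags)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = tags[i].interval, tags[j].interval
            if a.chrom == b.chrom and a.strand == b.strand and a.start < b.end and b.start < a.end:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(id(tags[i]))
    return {frozenset(g) for g in groups.values()}


def pileup_oracle(cluster):
    depth = {}
    for t in cluster.member_tags:
        for p in range(t.interval.start, t.interval.end):
            depth[p] = depth.get(p, 0) + 1
    return max(depth.values())


class TestBuildClusters:
    def test_overlap_merges(self):
        tags = [make_tag(start=100, end=130), make_tag(start=120, end=150, read_id="r1")]
        (cl,) = build_clusters(tags)
        assert (cl.interval.start, cl.interval.end) == (100, 150)
        assert cl.total_tags == 2

    def test_abutting_tags_stay_separate(self):
        tags = [make_tag(start=100, end=130), make_tag(start=130, end=160, read_id="r1")]
        assert len(build_clusters(tags)) == 2

    def test_strands_never_merge(self):
        tags = [make_tag(start=100, end=150), make_tag(start=120, end=160, strand="-", read_id="r1")]
        assert len(build_clusters(tags)) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_membership_matches_connected_components(self, seed):
        rng = np.random.default_rng(seed)
        tags = random_tags(rng, 120, span=1500)
        clusters = build_clusters(tags)
        got = {frozenset(id(t) for t in c.member_tags) for c in clusters}
        assert got == connected_components_oracle(tags)
        assert sum(c.total_tags for c in clusters) == len(tags)


class TestPeakHeight:
    def test_full_stack(self):
        tags = [make_tag(start=990, end=1030, read_id=f"r{i}") for i in range(10)]
        (cl,) = build_clusters(tags)
        height, pos = peak_height(cl)
        assert height == 10
        assert pos == 990

    def test_two_stacks_takes_max(self):
        tags = [make_tag(start=0, end=30, read_id=f"a{i}") for i in range(4)]
        tags += [make_tag(start=25, end=60, read_id=f"b{i}") for i in range(7)]
        (cl,) = build_clusters(tags)
        assert peak_height(cl)[0] == 11  # overlap zone depth 4+7
        tags2 = [make_tag(start=0, end=20, read_id=f"a{i}") for i in range(4)]
        tags2 += [make_tag(start=19, end=60, read_id=f"b{i}") for i in range(7)]
        (cl2,) = build_clusters(tags2)
        assert peak_height(cl2)[0] == pileup_oracle(cl2)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_pileup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tags = random_tags(rng, 60, span=400)
        for cl in build_clusters(tags):
            assert cl.peak_height == pileup_oracle(cl)


class TestPeakSignificance:
    def test_strong_peak_tiny_p(self):
        tags = [make_tag(start=0, end=40, read_id=f"r{i}") for i in range(10)]
        (cl,) = build_clusters(tags)
        # lambda = 0.1: gene_tag_total * mean_len / gene_length
        p = peak_significance(cl, gene_tag_total=10, gene_length=4000, mean_tag_length=40)
        assert p == pytest.approx(
            min(1.0, 4000 * stats.poisson.sf(9, 0.1)), rel=1e-12
        )
        assert p < 1e-6

    def test_height_one_at_unit_rate_not_significant(self):
        tags = [make_tag(start=0, end=40)]
        (cl,) = build_clusters(tags)
        assert peak_significance(cl, 100, 4000, 40) == 1.0

    def test_monotone_as_rate_vanishes(self):
        tags = [make_tag(start=0, end=40, read_id=f"r{i}") for i in range(3)]
        (cl,) = build_clusters(tags)
        ps = [
            peak_significance(cl, total, 40_000, 40)
            for total in (1000, 100, 10, 1)
        ]
        assert ps == sorted(ps, reverse=True)

    def test_zero_gene_length_error(self):
        tags = [make_tag(start=0, end=40)]
        (cl,) = build_clusters(tags)
        with pytest.raises(ValueError):
            peak_significance(cl, 10, 0, 40)


class TestReproducibility:
    def _cluster(self, n1, n2):
        tags = [make_tag(start=0, end=40, rep="R1", read_id=f"a{i}") for i in range(n1)]
        tags += [make_tag(start=0, end=40, rep="R2", read_id=f"b{i}") for i in range(n2)]
        (cl,) = build_clusters(tags)
        return cl

    def test_perfect_balance_retained(self):
        cl = self._cluster(10, 10)
        chi2, p = reproducibility_score(cl, {"R1": 100, "R2": 100})
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_skewed_cluster_flagged(self):
        cl = self._cluster(20, 0)
        _, p = reproducibility_score(cl, {"R1": 100, "R2": 100})
        # chi-squared oracle on the same 2x2 table
        chi2_o, p_o, _, _ = stats.chi2_contingency(
            [[20, 80], [0, 100]], correction=False
        )
        assert p == pytest.approx(p_o, rel=1e-12)
        assert p < 0.01

    def test_single_replicate_error(self):
        cl = self._cluster(5, 0)
        with pytest.raises(ValueError, match="2 replicates"):
            reproducibility_score(cl, {"R1": 100})

    def test_small_expected_uses_exact_test(self):
        cl = self._cluster(1, 1)
        _, p = reproducibility_score(cl, {"R1": 1, "R2": 2})
        _, p_fisher = stats.fisher_exact([[1, 0], [1, 1]])
        assert p == pytest.approx(p_fisher)


class TestStringencyTiers:
    def _cluster(self, n1, n2, start=0):
        tags = [
            make_tag(start=start, end=start + 40, rep="R1", read_id=f"a{start}_{i}")
            for i in range(n1)
        ]
        tags += [
            make_tag(start=start, end=start + 40, rep="R2", read_id=f"b{start}_{i}")
            for i in range(n2)
        ]
        return tags

    def test_threshold_membership(self):
        tags = self._cluster(6, 6)  # BC2, 12 tags, peak 12, balanced
        tags += self._cluster(50, 0, start=1000)  # BC1, 50 tags
        clusters = build_clusters(tags)
        gene_totals = {"G1": {"R1": 6, "R2": 6}, "G2": {"R1": 50, "R2": 0}}
        for c, gene in zip(sorted(clusters, key=lambda c: c.interval.start), ("G1", "G2")):
            c.gene_id = gene
            c.peak_p = 0.0001
            c.repro_chi2, c.repro_p = reproducibility_score(
                c, gene_totals[gene]
            )
        tiers = apply_stringency_tiers(clusters)
        bc2 = next(c for c in clusters if c.bc == 2)
        bc1 = next(c for c in clusters if c.bc == 1)
        assert all(bc2 in tier for tier in tiers.values())
        assert all(bc1 not in tier for tier in tiers.values())

    @pytest.mark.parametrize("seed", [0, 5])
    def test_nesting_monotone(self, seed):
        rng = np.random.default_rng(seed)
        tags = random_tags(rng, 400, span=3000)
        clusters = build_clusters(tags)
        for c in clusters:
            c.gene_id = "G"
            c.peak_p = float(rng.random())
            c.repro_p = float(rng.random())
        tiers = apply_stringency_tiers(clusters)
        assert len(tiers["T1"]) >= len(tiers["T2"]) >= len(tiers["T3"]) >= len(tiers["T4"])


class TestRegionDistribution:
    def test_proportions_sum_to_one(self, small_genome, gene_index):
        cfg, genome = small_genome
        from rbpreg.synthetic_data import simulate_clip
        from rbpreg.clip_reads import collapse_duplicates

        rng = cfg.rng()
        sim = simulate_clip(genome, cfg, rng)
        tags = collapse_duplicates(sim.aligned_reads)
        clusters = build_clusters(tags)
        annotate_clusters(clusters, gene_index, list(cfg.replicates))
        tiers = apply_stringency_tiers(clusters)
        frame, hists = region_distribution(tiers, gene_index)
        for tier, grp in frame.groupby("tier"):
            if grp["n_clusters"].sum():
                assert grp["proportion"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_planted_3utr_only(self, two_exon_plus):
        index = GeneIndex([two_exon_plus])
        tags = [make_tag(start=255, end=290, rep=r, read_id=f"{r}{i}")
                for r in ("R1", "R2") for i in range(3)]
        clusters = build_clusters(tags)
        annotate_clusters(clusters, index, ["R1", "R2"])
        tiers = apply_stringency_tiers(clusters, min_tags_t2=2)
        frame, _ = region_distribution({"T1": tiers["T1"]}, index)
        row = frame[(frame.tier == "T1") & (frame.region == "3UTR")]
        assert float(row["proportion"].iloc[0]) == 1.0


class TestTagsPerTranscript:
    def _bc2_cluster(self, n_per_rep, start, gene):
        tags = [
            make_tag(start=start, end=start + 40, rep=r, read_id=f"{gene}{start}{r}{i}")
            for r in ("R1", "R2")
            for i in range(n_per_rep)
        ]
        (cl,) = build_clusters(tags)
        cl.gene_id = gene
        return cl

    def test_strong_binder_sum(self):
        clusters = [
            self._bc2_cluster(30, 0, "GA"),  # 60 tags
            self._bc2_cluster(25, 1000, "GA"),  # 50 tags
        ]
        totals = tags_per_transcript(clusters)
        assert totals["GA"] == 110
        assert totals["GA"] > 100  # strong binder

    def test_bc1_cluster_excluded(self):
        tags = [make_tag(start=0, end=40, rep="R1", read_id=f"x{i}") for i in range(500)]
        (cl,) = build_clusters(tags)
        cl.gene_id = "GB"
        assert tags_per_transcript([cl])["GB"] == 0

    @pytest.mark.parametrize("seed", [21])
    def test_matches_brute_force_summation(self, seed):
        rng = np.random.default_rng(seed)
        clusters = []
        for i in range(50):
            n = int(rng.integers(1, 20))
            clusters.append(self._bc2_cluster(n, 100 * i, f"G{int(rng.integers(5))}"))
        totals = tags_per_transcript(clusters, min_tags=10)
        expected = {}
        for c in clusters:
            if c.bc == 2 and c.total_tags >= 10:
                expected[c.gene_id] = expected.get(c.gene_id, 0) + c.total_tags
        assert dict(totals) == expected
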