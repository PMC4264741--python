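"""Streaming hard clustering, support cutoff and breakpoint intervals."""

import numpy as np
import pytest

from svcall.alignments import InsertSizeModel
from svcall.clustering import (
    DiscordantCluster,
    breakpoint_intervals,
    cluster_discordant,
    filter_by_support,
    is_member,
    min_support_cutoff,
)

from oracles import (
    brute_force_cluster,
    mk_pair,
    partition_of,
    random_cluster_instance,
)


def _cluster(mu_alpha, mu_beta, mu_is=13_000.0, strands=("+", "-")):
    c = DiscordantCluster(
        cluster_id="c0", chrom1="chr1", chrom2="chr1",
        strand1=strands[0], strand2=strands[1],
        mu_alpha=mu_alpha, mu_beta=mu_beta, mu_is=mu_is,
    )
    c.alphas, c.betas, c.member_ids = [int(mu_alpha)], [int(mu_beta)], ["seed"]
    return c


class TestIsMember:
    def test_identity_case(self):
        c = _cluster(1000, 9000)
        p = mk_pair("p", 1000, 9000, insert=13_000)
        assert is_member(p, c, sigma_is=10)

    def test_alpha_just_outside_two_sigma(self):
        c = _cluster(1000, 9000)
        p = mk_pair("p", 1021, 9000, insert=13_000)
        assert not is_member(p, c, sigma_is=10)  # 21 > 2*10
        assert is_member(mk_pair("q", 1020, 9000, insert=13_000), c, sigma_is=10)

    def test_strand_signature_mismatch(self):
        c = _cluster(1000, 9000)
        p = mk_pair("p", 1000, 9000, strand1="+", strand2="+", insert=13_000)
        assert not is_member(p, c, sigma_is=10)

    def test_insert_similarity_required_same_chrom(self):
        c = _cluster(1000, 9000, mu_is=13_000)
        p = mk_pair("p", 1000, 9000, insert=14_000)
        assert not is_member(p, c, sigma_is=100)


class TestClusterDiscordant:
    def test_single_tight_group(self, fr_model):
        pairs = [mk_pair(i, 10_000 + 40 * i, 24_000 + 40 * i) for i in range(5)]
        clusters = cluster_discordant(pairs, fr_model)
        assert len(clusters) == 1
        assert clusters[0].support == 5
        assert clusters[0].mu_alpha == pytest.approx(np.mean([p.alpha for p in pairs]))

    def test_two_distant_groups(self, fr_model):
        pairs = [mk_pair(i, 10_000 + 10 * i, 24_000 + 10 * i) for i in range(4)]
        off = int(10 * fr_model.sigma_is)
        pairs += [mk_pair(10 + i, 10_000 + off + 10 * i, 24_000 + off + 10 * i)
                  for i in range(4)]
        clusters = cluster_discordant(pairs, fr_model)
        assert len(clusters) == 2
        assert [c.support for c in clusters] == [4, 4]

    def test_unsorted_stream_raises(self, fr_model):
        pairs = [mk_pair(0, 5000, 20_000), mk_pair(1, 1000, 16_000)]
        with pytest.raises(ValueError, match="not sorted"):
            cluster_discordant(pairs, fr_model)

    def test_assignment_uniqueness(self, small_sim, small_sim_model):
        from svcall.alignments import split_by_discordancy

        _, disc = split_by_discordancy(small_sim.records, small_sim_model)
        clusters = cluster_discordant(disc, small_sim_model)
        assert sum(c.support for c in clusters) == len(disc)
        seen = [m for c in clusters for m in c.member_ids]
        assert len(seen) == len(set(seen))

    def test_mean_containment(self, small_sim, small_sim_model):
        from svcall.alignments import split_by_discordancy

        _, disc = split_by_discordancy(small_sim.records, small_sim_model)
        for c in cluster_discordant(disc, small_sim_model):
            assert min(c.alphas) <= c.mu_alpha <= max(c.alphas)
            assert min(c.betas) <= c.mu_beta <= max(c.betas)

    def test_determinism(self, fr_model):
        rng = np.random.default_rng(9)
        pairs, model = random_cluster_instance(rng)
        a = cluster_discordant(pairs, model)
        b = cluster_discordant(pairs, model)
        assert [(c.cluster_id, tuple(c.member_ids)) for c in a] == [
            (c.cluster_id, tuple(c.member_ids)) for c in b
        ]

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_reference(self, seed):
        """Streaming engine with eviction == literal full-scan clusterer."""
        rng = np.random.default_rng(1000 + seed)
        pairs, model = random_cluster_instance(rng)
        streamed = cluster_discordant(pairs, model)
        reference = brute_force_cluster(pairs, model)
        assert partition_of(streamed) == partition_of(reference)
        ref_means = {frozenset(c["members"]): (c["mu_alpha"], c["mu_beta"])
                     for c in reference}
        for c in streamed:
            mu = ref_means[frozenset(c.member_ids)]
            assert c.mu_alpha == pytest.approx(mu[0])
            assert c.mu_beta == pytest.approx(mu[1])

    def test_six_implanted_deletions_recovered(self):
        """~200 scattered discordant pairs around 6 deletions -> 6 clusters."""
        rng = np.random.default_rng(21)
        sigma = 300.0
        model = InsertSizeModel(3000.0, sigma, "FR", 3.0, 1000)
        centers = [(50_000 * (i + 1), 50_000 * (i + 1) + 12_000) for i in range(6)]
        pairs = []
        i = 0
        for ca, cb in centers:
            for _ in range(33):
                a = int(ca + rng.normal(0, sigma / 2))
                b = int(cb + rng.normal(0, sigma / 2))
                pairs.append(mk_pair(i, a, b, insert=b + 50 - a))
                i += 1
        pairs.sort(key=lambda p: p.alpha)
        clusters = filter_by_support(cluster_discordant(pairs, model), 3)
        assert len(clusters) == 6
        for c, (ca, _) in zip(sorted(clusters, key=lambda c: c.mu_alpha), centers):
            assert abs(c.mu_alpha - ca) <= 2 * sigma


class TestSupportCutoff:
    @pytest.mark.parametrize("cov,floor,expected", [
        (0, 2, 2), (30, 2, 3), (100, 4, 10), (9, 2, 2), (1000, 2, 100),
    ])
    def test_heuristic(self, cov, floor, expected):
        assert min_support_cutoff(cov, floor) == expected

    def test_negative_coverage_raises(self):
        with pytest.raises(ValueError):
            min_support_cutoff(-1)

    def test_filter_counts_and_identity(self, fr_model):
        clusters = []
        for i, n in enumerate((1, 1, 2, 5)):
            c = _cluster(1000 * i, 9000 * i)
            c.member_ids = [f"m{i}_{j}" for j in range(n)]
            clusters.append(c)
        assert len(filter_by_support(clusters, 2)) == 2
        assert filter_by_support(clusters, 1) == clusters

    def test_filter_monotone(self, fr_model):
        rng = np.random.default_rng(31)
        pairs, model = random_cluster_instance(rng)
        clusters = cluster_discordant(pairs, model)
        prev = None
        for cutoff in (1, 2, 3, 5, 8):
            ids = {c.cluster_id for c in filter_by_support(clusters, cutoff)}
            if prev is not None:
                assert ids <= prev
            prev = ids


class TestBreakpointIntervals:
    def test_hand_computed_construction(self, fr_model):
        pairs = [mk_pair(i, 1000, 9000, insert=8050) for i in range(4)]
        cluster = cluster_discordant(pairs, fr_model)[0]
        left, right = breakpoint_intervals(cluster, fr_model, read_len=50)
        assert (left.lo, left.hi) == (1050, 4000)
        # enumeration of junction positions consistent with all members shows
        # the junction can sit exactly at min(beta), hence the +1 bound
        assert (right.lo, right.hi) == (6050, 9001)

    def test_fallback_window_width(self):
        model = InsertSizeModel(40.0, 10.0, "FR", 3.0, 100)  # median < read length
        pairs = [mk_pair(i, 1000, 9000, insert=8050) for i in range(3)]
        cluster = cluster_discordant(pairs, model)[0]
        left, right = breakpoint_intervals(cluster, model, read_len=50)
        assert left.hi - left.lo == 40  # 4 sigma
        assert right.hi - right.lo == 40

    def test_support_one_raises(self, fr_model):
        c = _cluster(1000, 9000)
        with pytest.raises(ValueError):
            breakpoint_intervals(c, fr_model, read_len=50)

    def test_true_breakpoints_inside_intervals_on_simulation(
        self, small_sim, small_sim_model
    ):
        """Each implanted junction is contained in a surviving cluster's CIs."""
        from svcall.alignments import split_by_discordancy
        from svcall.clustering import min_support_cutoff

        _, disc = split_by_discordancy(small_sim.records, small_sim_model)
        genome = sum(l for _, l in small_sim.contigs)
        phys = len(small_sim.records) * small_sim_model.median_is / genome
        cutoff = max(2, min_support_cutoff(phys))
        clusters = filter_by_support(
            cluster_discordant(disc, small_sim_model), cutoff
        )
        for sv in small_sim.manifest.svs:
            if sv.svtype == "INS" and sv.length >= small_sim_model.median_is:
                continue
            bp1, bp2 = sv.breakpoints[0], sv.breakpoints[-1]
            hit = False
            for c in clusters:
                left, right = breakpoint_intervals(c, small_sim_model, 50)
                for l, r in ((left, right), (right, left)):
                    if (l.chrom == bp1[0] and bp1[1] in l
                            and r.chrom == bp2[0] and bp2[1] in r):
                        hit = True
            assert hit, f"{sv.sv_id} ({sv.svtype}) not covered by any cluster CI"
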