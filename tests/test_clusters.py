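import numpy as np
import pytest

import etanet as e
from etanet.clusters import COVERAGE_STEP

from conftest import chain_from, uniform_surface


def ranks_for(chain, values):
    return e.ETRanking.from_ranks(chain.id, {
        int(s): float(v) for s, v in zip(chain.seq_numbers, values)
    })


class TestIdentifyClusters:
    def test_one_component_when_all_linked(self):
        chain = chain_from([[4.0 * i, 0, 0] for i in range(6)])
        ranks = ranks_for(chain, range(1, 7))
        clusters = e.identify_clusters(chain, ranks, uniform_surface(chain), 1.0)
        assert len(clusters) == 1
        assert clusters[0].members == frozenset(range(1, 7))

    def test_distant_groups_split_and_sort_by_best_rank(self):
        pts = [[0, 0, 0], [4, 0, 0], [50, 0, 0], [54, 0, 0]]
        chain = chain_from(pts)
        # rank-1 residue lives in the distant group
        ranks = ranks_for(chain, [3, 4, 1, 2])
        clusters = e.identify_clusters(chain, ranks, uniform_surface(chain), 1.0)
        assert len(clusters) == 2
        assert clusters[0].members == frozenset({3, 4})  # holds the rank-1 residue

    def test_components_equal_transitive_closure_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            pts = rng.uniform(0, 30, size=(30, 3))
            chain = chain_from(pts)
            ranks = ranks_for(chain, rng.permutation(30) + 1)
            clusters = e.identify_clusters(
                chain, ranks, uniform_surface(chain), 1.0, link_cutoff=8.0
            )
            # brute-force union-find over the <=8 A relation
            parent = list(range(30))

            def find(i):
                while parent[i] != i:
                    i = parent[i]
                return i

            for i in range(30):
                for j in range(i):
                    if np.linalg.norm(pts[i] - pts[j]) <= 8.0:
                        parent[find(i)] = find(j)
            expected = {}
            for i in range(30):
                expected.setdefault(find(i), set()).add(i + 1)
            assert {frozenset(m) for m in expected.values()} == {
                c.members for c in clusters
            }

    def test_membership_grows_with_coverage(self):
        rng = np.random.default_rng(4)
        chain = chain_from(rng.uniform(0, 25, size=(40, 3)))
        ranks = ranks_for(chain, rng.permutation(40) + 1)
        surface = uniform_surface(chain)
        for low, high in [(0.2, 0.5), (0.5, 0.9)]:
            small = set().union(
                *[c.members for c in e.identify_clusters(chain, ranks, surface, low)] or [set()]
            )
            big = set().union(
                *[c.members for c in e.identify_clusters(chain, ranks, surface, high)]
            )
            assert small <= big

    def test_cluster_cm_is_member_mean(self):
        chain = chain_from([[0, 0, 0], [4, 0, 0], [0, 4, 0]])
        ranks = ranks_for(chain, [1, 2, 3])
        (cluster,) = e.identify_clusters(chain, ranks, uniform_surface(chain), 1.0)
        np.testing.assert_allclose(cluster.cm, np.mean(chain.coords, axis=0))


def patch(center, n, spacing=4.0):
    """A connected line of n points starting at center."""
    cx, cy, cz = center
    return [[cx + spacing * i, cy, cz] for i in range(n)]


class TestPrimaryCluster:
    def test_planted_patch_selected_at_formation(self):
        pts = patch((0, 0, 0), 12) + patch((100, 0, 0), 30)
        chain = chain_from(pts)
        ranks = ranks_for(chain, list(range(1, 13)) + list(range(13, 43)))
        primary = e.select_primary_cluster(chain, ranks, uniform_surface(chain))
        assert primary.members <= set(range(1, 13))
        assert len(primary.members) >= 11
        assert primary.best_rank == 1.0

    def test_fewer_than_eleven_surface_residues_yields_no_template(self):
        chain = chain_from(patch((0, 0, 0), 10))
        ranks = ranks_for(chain, range(1, 11))
        with pytest.raises(e.NoTemplateError):
            e.select_primary_cluster(chain, ranks, uniform_surface(chain))
        assert e.make_templates(chain, ranks, uniform_surface(chain), "6R") == []

    def test_earlier_forming_patch_wins(self):
        # patch A: ranks 1-11 of 100 -> forms at ~0.11; patch B: ranks 40-50
        pts = patch((0, 0, 0), 11) + patch((100, 0, 0), 11) + patch((200, 0, 0), 78)
        chain = chain_from(pts)
        values = list(range(1, 12)) + list(range(40, 51)) + (
            list(range(12, 40)) + list(range(51, 101))
        )
        ranks = ranks_for(chain, values)
        primary = e.select_primary_cluster(chain, ranks, uniform_surface(chain))
        assert primary.members == frozenset(range(1, 12))
        assert primary.formation_threshold == pytest.approx(0.11)


class TestAdditionalClusters:
    def make(self, secondary_values):
        pts = patch((0, 0, 0), 12) + patch((100, 0, 0), 6) + patch((200, 0, 0), 40)
        chain = chain_from(pts)
        # primary patch ranks 2..13, secondary per test, decoys worst
        values = list(range(2, 14)) + secondary_values + list(range(20, 60))
        return chain, ranks_for(chain, values)

    def test_secondary_with_global_best_rank_is_returned(self):
        chain, ranks = self.make([1, 14, 15, 16, 17, 18])
        surface = uniform_surface(chain)
        primary = e.select_primary_cluster(chain, ranks, surface)
        extra = e.select_additional_clusters(chain, ranks, surface, primary)
        assert any(c.best_rank == 1.0 for c in extra)

    def test_worse_than_primary_worst_excluded_for_all_comparators(self):
        chain, ranks = self.make([61, 62, 63, 64, 65, 66])
        surface = uniform_surface(chain)
        primary = e.select_primary_cluster(chain, ranks, surface)
        for comparator in ("best", "median", "worst"):
            extra = e.select_additional_clusters(
                chain, ranks, surface, primary, comparator=comparator
            )
            assert not any(c.members >= frozenset(range(13, 19)) for c in extra)

    def test_comparator_strictness_ordering(self):
        # secondary best rank (3) beats the primary median but not its best (2)
        chain, ranks = self.make([3, 14, 15, 16, 17, 18])
        surface = uniform_surface(chain)
        primary = e.select_primary_cluster(chain, ranks, surface)
        median_hits = e.select_additional_clusters(
            chain, ranks, surface, primary, comparator="median"
        )
        best_hits = e.select_additional_clusters(
            chain, ranks, surface, primary, comparator="best"
        )
        assert any(3.0 == c.best_rank for c in median_hits)
        assert not any(3.0 == c.best_rank for c in best_hits)


class TestPickTemplate:
    def test_cluster_of_exactly_five_uses_all_members(self):
        chain = chain_from(patch((0, 0, 0), 5))
        ranks = ranks_for(chain, [5, 4, 3, 2, 1])
        (cluster,) = e.identify_clusters(chain, ranks, uniform_surface(chain), 1.0)
        template = e.pick_template(cluster, chain, ranks, 5)
        assert set(template.positions) == set(range(1, 6))

    def test_center_first_then_seq_number_breaks_corner_ties(self):
        # square of equal-rank corners around a better-ranked center
        pts = [[4, 4, 0], [-4, 4, 0], [-4, -4, 0], [4, -4, 0], [0, 0, 0]]
        chain = chain_from(pts)
        ranks = ranks_for(chain, [2, 2, 2, 2, 1])
        (cluster,) = e.identify_clusters(chain, ranks, uniform_surface(chain), 1.0)
        template = e.pick_template(cluster, chain, ranks, 5)
        assert template.positions[0] == 5  # best rank nearest the center
        # all corners equidistant from every midpoint: seq-number order
        assert template.positions[1:] == (1, 2, 3, 4)

    def test_five_residue_template_is_prefix_of_six(self, single_bench):
        for pid in list(single_bench.proteins)[:6]:
            rec = single_bench.proteins[pid]
            t6 = e.make_templates(rec.chain, rec.ranks, rec.surface, "6R")
            t5 = e.make_templates(rec.chain, rec.ranks, rec.surface, "5R")
            assert t6 and t5
            assert t6[0].positions[:5] == t5[0].positions

    def test_deterministic(self, single_bench):
        rec = single_bench.proteins["sy05A"]
        runs = [
            tuple(
                t.positions
                for t in e.make_templates(rec.chain, rec.ranks, rec.surface, "M6R")
            )
            for _ in range(3)
        ]
        assert runs[0] == runs[1] == runs[2]

    def test_undersized_cluster_errors(self):
        chain = chain_from(patch((0, 0, 0), 4))
        ranks = ranks_for(chain, range(1, 5))
        (cluster,) = e.identify_clusters(chain, ranks, uniform_surface(chain), 1.0)
        with pytest.raises(ValueError, match="cannot yield"):
            e.pick_template(cluster, chain, ranks, 5)


class TestTypeVariants:
    def make_template(self):
        chain = chain_from(patch((0, 0, 0), 6), aas="ASDGKL")
        ranks = ranks_for(chain, range(1, 7))
        (cluster,) = e.identify_clusters(chain, ranks, uniform_surface(chain), 1.0)
        return chain, e.pick_template(cluster, chain, ranks, 6)

    def test_identical_rows_keep_native_only(self):
        chain, template = self.make_template()
        msa = [("q", chain.sequence)] + [(f"h{i}", chain.sequence) for i in range(3)]
        out = e.template_type_variants(template, chain, msa)
        for pos, allowed in zip(out.positions, out.allowed_types):
            assert allowed == frozenset({chain.aa_of(pos)})

    def test_variant_requires_two_occurrences(self):
        chain, template = self.make_template()
        # T at position 2 appears once, C twice
        msa = [
            ("q", "ASDGKL"),
            ("h1", "ATDGKL"),
            ("h2", "ACDGKL"),
            ("h3", "ACDGKL"),
        ]
        out = e.template_type_variants(template, chain, msa)
        allowed = dict(zip(out.positions, out.allowed_types))
        assert "C" in allowed[2] and "T" not in allowed[2]

    def test_gapped_rows_do_not_count(self):
        chain, template = self.make_template()
        msa = [
            ("q", "ASDGKL"),
            ("h1", "AC-GKL"),
            ("h2", "AC-GKL"),
        ]
        out = e.template_type_variants(template, chain, msa)
        allowed = dict(zip(out.positions, out.allowed_types))
        assert allowed[2] == frozenset({"S"})

    def test_generated_msa_supported_variants(self, small_bench):
        rec = small_bench.proteins["sy00A"]
        site = small_bench.sites["sy00A"][0].positions
        msa = e.generate_msa(rec.chain, n_rows=10, substitution_rate=0.3,
                             seed=5, site_positions=site)
        templates = e.make_templates(rec.chain, rec.ranks, rec.surface, "6R", msa=msa)
        assert templates
        for pos, allowed in zip(templates[0].positions, templates[0].allowed_types):
            assert rec.chain.aa_of(pos) in allowed


class TestMakeTemplates:
    def test_multiple_mode_degenerates_to_single_without_second_cluster(
        self, single_bench
    ):
        rec = single_bench.proteins["sy01A"]
        assert len(e.make_templates(rec.chain, rec.ranks, rec.surface, "M6R")) == 1

    def test_two_site_fixture_yields_two_templates_per_mode(self, two_bench):
        uncorrupted = sorted(set(two_bench.proteins) - two_bench.corrupted)
        rec = two_bench.proteins[uncorrupted[0]]
        m5 = e.make_templates(rec.chain, rec.ranks, rec.surface, "M5R")
        single = e.make_templates(rec.chain, rec.ranks, rec.surface, "6R")
        assert len(m5) == 2
        assert len(single) == 1

    def test_templates_recover_planted_sites(self, two_bench):
        pid = sorted(set(two_bench.proteins) - two_bench.corrupted)[0]
        rec = two_bench.proteins[pid]
        planted = {frozenset(s.positions) for s in two_bench.sites[pid]}
        produced = {
            frozenset(t.positions)
            for t in e.make_templates(rec.chain, rec.ranks, rec.surface, "M6R")
        }
        assert produced == planted
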