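from itertools import combinations
from math import comb

import numpy as np
import pytest

import snpanel as sp
from snpanel.panel_search import InfeasiblePoolError, PanelError
from snpanel.synthetic_data import simulate_candidate_pool

A = frozenset("A")
C = frozenset("C")
R = frozenset("AG")
Y = frozenset("CT")


class TestIncompatible:
    def test_distinct_bases(self):
        assert sp.incompatible(A, C)

    def test_overlapping_ambiguity_not_incompatible(self):
        assert not sp.incompatible(R, A)

    def test_disjoint_ambiguity_codes(self):
        assert sp.incompatible(R, Y)

    def test_empty_set_rejected(self):
        with pytest.raises(PanelError):
            sp.incompatible(frozenset(), A)


class TestExtractCandidates:
    def test_panel6_pool_positions(self, panel6_pool, fixtures):
        assert [c.position for c in panel6_pool] == fixtures["panel6"]["pool_positions"]

    def test_degeneracy_outranks_fewer_states(self):
        # position 1 has 3 distinct states, position 2 only 2: pos 1 first
        profs = [
            sp.profile_from_string("AC", "O1"),
            sp.profile_from_string("CC", "O2"),
            sp.profile_from_string("GT", "O3"),
        ]
        pool = sp.extract_candidates(profs, frame=None, max_per_otu=1)
        assert pool[0].degeneracy == 3
        assert pool[0].position == 1

    def test_nonsilent_ranks_first_for_every_sponsor(self):
        # codon 1 differs non-silently (ATT Ile vs GTT Val); codons 2-6 are
        # silent third-position changes
        s1 = "ATT" + "CTT" * 5
        s2 = "GTT" + "CTC" * 5
        profs = [sp.profile_from_string(s1, "O1"), sp.profile_from_string(s2, "O2")]
        frame = sp.infer_frame(profs)
        pool = sp.extract_candidates(profs, frame, max_per_otu=3)
        nonsilent = [c for c in pool if not c.silent]
        assert len(nonsilent) == 1 and nonsilent[0].position == 1
        assert pool[0].sponsors == {"O1", "O2"}

    def test_cap_limits_per_otu_contribution(self):
        # 30 silent equal-degeneracy differences: each OTU keeps the 25
        # smallest positions; identical sets, pool size 25
        s1 = "A" * 30 + "T" * 10
        s2 = "G" * 30 + "T" * 10
        profs = [sp.profile_from_string(s1, "O1"), sp.profile_from_string(s2, "O2")]
        pool = sp.extract_candidates(profs, frame=None, max_per_otu=25)
        assert len(pool) == 25
        assert [c.position for c in pool] == list(range(1, 26))

    def test_indistinguishable_otus_error(self):
        profs = [sp.profile_from_string("ACGT", "O1"), sp.profile_from_string("ACGT", "O2")]
        with pytest.raises(PanelError, match="indistinguishable"):
            sp.extract_candidates(profs, frame=None)


class TestPairDiffs:
    def test_empty_panel_zero_matrix(self, panel6_profiles):
        diff = sp.pair_diffs([], panel6_profiles)
        assert np.all(diff == 0)

    def test_full_pool_counts(self, panel6_profiles):
        diff = sp.pair_diffs([1, 2, 3, 4, 5, 6], panel6_profiles)
        # order A, B, C: AB=3, AC=3, BC=6
        assert diff[0, 1] == 3 and diff[0, 2] == 3 and diff[1, 2] == 6

    def test_matches_per_position_recount(self):
        rng = np.random.default_rng(0)
        profs = [
            sp.profile_from_string("".join(rng.choice(list("ACGTRY"), 20)), f"O{i}")
            for i in range(4)
        ]
        positions = [1, 4, 7, 13, 20]
        diff = sp.pair_diffs(positions, profs)
        for i, j in combinations(range(4), 2):
            manual = sum(
                1 for p in positions
                if not (profs[i].base_sets[p - 1] & profs[j].base_sets[p - 1])
            )
            assert diff[i, j] == manual


class TestExhaustiveMinPanel:
    def test_panel6_k3_needs_all_six(self, panel6_pool):
        panel = sp.exhaustive_min_panel(panel6_pool, k=3)
        assert len(panel) == 6
        assert panel.achieved_min >= 3

    def test_panel6_k1_size_two(self, panel6_pool):
        panel = sp.exhaustive_min_panel(panel6_pool, k=1)
        assert len(panel) == 2

    def test_two_otus_minimal_size_is_k(self):
        profs = [sp.profile_from_string("AAAAA", "O1"), sp.profile_from_string("GGGGG", "O2")]
        pool = sp.extract_candidates(profs, frame=None)
        for k in (1, 2, 3):
            assert len(sp.exhaustive_min_panel(pool, k=k)) == k

    def test_one_position_separates_all(self):
        profs = [sp.profile_from_string("A", "O1"), sp.profile_from_string("C", "O2"),
                 sp.profile_from_string("G", "O3")]
        pool = sp.extract_candidates(profs, frame=None)
        assert len(sp.exhaustive_min_panel(pool, k=1)) == 1

    def test_guard_on_pool_size(self):
        pool = simulate_candidate_pool(4, 25, seed=0)
        with pytest.raises(PanelError, match="guard"):
            sp.exhaustive_min_panel(pool, k=1, max_pool_size=20)


class TestSearchPanel:
    def test_finds_panel6_minimum_when_covering_space(self, panel6_pool):
        panel = sp.search_panel(panel6_pool, k=3, trials=comb(6, 6) + 100, seed=1)
        assert set(panel.positions) == {1, 2, 3, 4, 5, 6}

    def test_infeasible_pool_names_limiting_pair(self):
        profs = [sp.profile_from_string("AATTT", "O1"), sp.profile_from_string("GGTTT", "O2")]
        pool = sp.extract_candidates(profs, frame=None)
        with pytest.raises(InfeasiblePoolError, match="2 incompatible"):
            sp.search_panel(pool, k=3)

    def test_postcondition_achieved_min(self):
        pool = simulate_candidate_pool(8, 30, seed=3)
        panel = sp.search_panel(pool, k=3, trials=5000, seed=2)
        assert panel.achieved_min >= 3
        assert np.all(panel.diff_matrix == panel.diff_matrix.T)
        assert np.all(np.diag(panel.diff_matrix) == 0)

    def test_determinism(self):
        pool = simulate_candidate_pool(10, 40, seed=4)
        p1 = sp.search_panel(pool, k=3, trials=3000, seed=9)
        p2 = sp.search_panel(pool, k=3, trials=3000, seed=9)
        assert p1.positions == p2.positions
        assert p1.metadata == p2.metadata

    def test_start_size_respected(self):
        pool = simulate_candidate_pool(5, 20, seed=5)
        panel = sp.search_panel(pool, k=1, trials=2000, start_size=4, seed=1)
        assert len(panel) >= 4
        assert panel.metadata["sizes_attempted"][0] == 4

    def test_matches_exhaustive_on_random_instances(self):
        rng = np.random.default_rng(6)
        for trial in range(30):
            n_otus = int(rng.integers(3, 7))
            pool = simulate_candidate_pool(n_otus, int(rng.integers(6, 14)),
                                           seed=int(rng.integers(1, 10_000)))
            k = int(rng.integers(1, 4))
            try:
                exact = sp.exhaustive_min_panel(pool, k=k)
            except InfeasiblePoolError:
                continue
            trials = comb(len(pool), len(exact))
            found = sp.search_panel(pool, k=k, trials=trials, seed=trial)
            assert len(found) == len(exact)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            pool = simulate_candidate_pool(4, 12, seed=int(rng.integers(1, 10_000)))
            sizes = []
            for k in (1, 2, 3, 4):
                try:
                    sizes.append(len(sp.exhaustive_min_panel(pool, k=k)))
                except InfeasiblePoolError:
                    sizes.append(None)
            present = [s for s in sizes if s is not None]
            assert all(b >= a for a, b in zip(present, present[1:]))

    def test_joint_panel_no_larger_than_group_union(self):
        """Searching over all OTUs jointly is no more expensive than
        concatenating per-group panels (the economy of a combined search):
        two 3-OTU groups whose diagnostic regions also separate cross-group
        pairs, so the union of group panels is feasible for the joint task."""
        g1 = {f"A{i}": b * 10 + "T" * 10 for i, b in enumerate("ACG", 1)}
        g2 = {f"B{i}": "T" * 10 + b * 10 for i, b in enumerate("ACG", 1)}
        all_profiles = [
            sp.profile_from_string(seq, name) for name, seq in sorted({**g1, **g2}.items())
        ]
        joint_pool = sp.extract_candidates(all_profiles, frame=None)
        joint = sp.search_panel(joint_pool, k=2, trials=200_000, seed=1)
        union: set[int] = set()
        for group in (g1, g2):
            profs = [sp.profile_from_string(seq, name) for name, seq in sorted(group.items())]
            gp = sp.search_panel(sp.extract_candidates(profs, frame=None), k=2,
                                 trials=200_000, seed=1)
            union |= set(gp.positions)
        assert joint.achieved_min >= 2
        assert len(joint) <= len(union)


class TestValidatePanel:
    def test_search_result_passes(self):
        pool = simulate_candidate_pool(6, 25, seed=9)
        panel = sp.search_panel(pool, k=3, trials=5000, seed=3)
        profiles = [
            sp.profile_from_string(
                "".join(next(iter(c.states[o])) for c in pool), o
            )
            for o in sorted({o for c in pool for o in c.states}, key=str)
        ]
        # positions in profile coordinates are pool indices + 1
        remap = {c.position: i + 1 for i, c in enumerate(pool)}
        panel_remap = sp.Panel(
            positions=tuple(remap[p] for p in panel.positions),
            k_target=3, otu_ids=panel.otu_ids,
            diff_matrix=panel.diff_matrix, achieved_min=panel.achieved_min,
        )
        report = sp.validate_panel(panel_remap, profiles, 3)
        assert report["passes"] and report["achieved_min"] >= 3

    def test_dropping_a_position_from_minimal_panel_fails(self, panel6_pool, panel6_profiles):
        panel = sp.exhaustive_min_panel(panel6_pool, k=3)
        crippled = sp.Panel(
            positions=panel.positions[:-1], k_target=3, otu_ids=panel.otu_ids,
            diff_matrix=panel.diff_matrix, achieved_min=panel.achieved_min,
        )
        report = sp.validate_panel(crippled, panel6_profiles, 3)
        assert not report["passes"]
        assert report["achieved_min"] < 3

    def test_pairwise_comparison_count(self):
        assert comb(182, 2) == 16471  # bookkeeping the reports rely on
        pool = simulate_candidate_pool(6, 20, seed=10)
        panel = sp.search_panel(pool, k=1, trials=2000, seed=1)
        profiles = [
            sp.profile_from_string("".join(next(iter(c.states[o])) for c in pool), o)
            for o in sorted({o for c in pool for o in c.states}, key=str)
        ]
        remap = {c.position: i + 1 for i, c in enumerate(pool)}
        panel = sp.Panel(
            positions=tuple(remap[p] for p in panel.positions),
            k_target=1, otu_ids=panel.otu_ids,
            diff_matrix=panel.diff_matrix, achieved_min=panel.achieved_min,
        )
        report = sp.validate_panel(panel, profiles, 1)
        assert report["n_pairwise_comparisons"] == comb(6, 2)

    def test_group_means_split_within_between(self, panel6_pool, panel6_profiles):
        panel = sp.exhaustive_min_panel(panel6_pool, k=1)
        groups = {"A": "g1", "B": "g1", "C": "g2"}
        report = sp.validate_panel(panel, panel6_profiles, 1, groups=groups)
        assert "g1" in report["within_group_mean"]
        assert "g1/g2" in report["between_group_mean"]
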