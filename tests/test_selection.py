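import itertools
from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syncom_select.profiles import build_profile_matrix
from syncom_select.selection import (
    TaxonomyRecord,
    enumerate_candidates,
    functional_redundancy,
    group_score,
    iterative_select,
    parse_gtdbtk_classification,
    rank_candidates,
    read_gtdbtk_summary,
    score_genome,
    shortlist,
    taxonomic_filter,
    SelectionTrace,
)
from syncom_select.weighting import WeightVector, build_weight_vector

from conftest import pf, profile

W0 = WeightVector.zero()


def brute_force_score(genome_pfams, remaining, weights):
    """Independent scorer: plain sum over the intersection."""
    total = 0.0
    for p in genome_pfams:
        if p in remaining:
            total += 1.0 + weights[p]
    return total


class TestScoreGenome:
    def test_weighted_match(self):
        wv = build_weight_vector(set(), {pf(2)})
        s = score_genome(profile("g", 1, 2, 5), profile("s", 1, 2, 3, 4), wv)
        assert s == pytest.approx(2.0012)

    def test_empty_genome(self):
        assert score_genome(profile("g"), profile("s", 1), W0) == 0.0

    def test_identity_zero_weights(self):
        p = profile("s", 1, 2, 3)
        assert score_genome(p, p, W0) == 3.0

    def test_mismatches_contribute_nothing(self):
        wv = build_weight_vector({pf(9)}, {pf(9)})
        assert score_genome(profile("g", 9), profile("s", 1), wv) == 0.0


class TestIterativeSelect:
    def test_hand_run_greedy_with_tie_breaks(self):
        sample = profile("s", 1, 2, 3, 4)
        genomes = build_profile_matrix(
            [profile("G1", 1, 2), profile("G2", 3), profile("G3", 2, 3)]
        )
        trace = iterative_select(sample, genomes, W0, depth=2)
        assert [(g, s) for g, s, _ in trace.picks] == [("G1", 2.0), ("G2", 1.0)]

    def test_single_genome_equal_to_sample(self):
        sample = profile("s", 1, 2)
        genomes = build_profile_matrix([profile("G1", 1, 2)])
        trace = iterative_select(sample, genomes, W0, depth=5)
        assert trace.genome_ids == ["G1"]

    def test_disjoint_genomes_early_stop(self):
        sample = profile("s", 1)
        genomes = build_profile_matrix([profile("G1", 2), profile("G2", 3)])
        trace = iterative_select(sample, genomes, W0, depth=5)
        assert trace.picks == ()

    def test_depth_below_one_rejected(self):
        genomes = build_profile_matrix([profile("G1", 1)])
        with pytest.raises(ValueError):
            iterative_select(profile("s", 1), genomes, W0, depth=0)

    @given(data=st.data())
    @settings(max_examples=40, deadline=None)
    def test_greedy_pick_matches_brute_force_argmax(self, data):
        universe = list(range(1, 16))
        n_genomes = data.draw(st.integers(2, 8))
        genome_sets = [
            data.draw(st.sets(st.sampled_from(universe)), label=f"g{i}")
            for i in range(n_genomes)
        ]
        sample_set = data.draw(st.sets(st.sampled_from(universe), min_size=1), label="sample")
        weighted = data.draw(st.sets(st.sampled_from(universe)), label="weighted")
        wv = build_weight_vector({pf(n) for n in weighted}, set())
        genomes = build_profile_matrix(
            [profile(f"G{i:02d}", *s) for i, s in enumerate(genome_sets)]
        )
        sample = profile("s", *sample_set)
        trace = iterative_select(sample, genomes, wv, depth=5)

        # replay with an independent brute-force argmax at every iteration
        remaining = {pf(n) for n in sample_set}
        available = {f"G{i:02d}": {pf(n) for n in s} for i, s in enumerate(genome_sets)}
        for gid, score, n_new in trace.picks:
            scores = {
                g: brute_force_score(ps, remaining, wv) for g, ps in available.items()
            }
            best = max(scores.values())
            assert score == pytest.approx(best)
            assert gid == min(g for g, s in scores.items() if s == pytest.approx(best))
            assert n_new == len(available[gid] & remaining)
            prev = len(remaining)
            remaining -= available.pop(gid)
            if score > 0:
                assert len(remaining) < prev  # coverage strictly decreases


def trace(sample_id, *gids):
    return SelectionTrace(sample_id=sample_id, picks=tuple((g, 1.0, 1) for g in gids))


class TestShortlist:
    def test_inclusive_boundary(self):
        traces = [trace(f"s{i}", "A") for i in range(2)] + [trace(f"t{i}") for i in range(4)]
        assert shortlist(traces, 1 / 3) == {"A"}  # 2/6 >= 1/3

    def test_below_threshold_dropped(self):
        traces = [trace("s0", "A")] + [trace(f"t{i}") for i in range(5)]
        assert shortlist(traces, 1 / 3) == set()  # 1/6 < 1/3

    def test_single_trace(self):
        assert shortlist([trace("s", "A", "B")]) == {"A", "B"}

    def test_no_traces_rejected(self):
        with pytest.raises(ValueError):
            shortlist([])


class TestEnumerateCandidates:
    def test_18_choose_10(self):
        ids = [f"G{i:02d}" for i in range(18)]
        assert sum(1 for _ in enumerate_candidates(ids, 10)) == 43_758

    def test_4_choose_2(self):
        combos = list(enumerate_candidates(["a", "b", "c", "d"], 2))
        assert len(combos) == 6
        assert combos == sorted(combos)  # deterministic lexicographic order

    def test_k_choose_k(self):
        assert list(enumerate_candidates(["a", "b"], 2)) == [("a", "b")]

    def test_too_few_strains_suggests_lower_threshold(self):
        with pytest.raises(ValueError, match="prevalence threshold"):
            enumerate_candidates(["a"], 2)

    def test_cap_exceeded(self):
        with pytest.raises(ValueError, match="cap"):
            enumerate_candidates([f"G{i}" for i in range(30)], 15, cap=1000)

    @pytest.mark.parametrize("n", range(1, 13))
    def test_binomial_counts(self, n):
        ids = [f"G{i:02d}" for i in range(n)]
        for k in range(1, n + 1):
            combos = list(enumerate_candidates(ids, k, cap=None))
            assert len(combos) == comb(n, k)
            assert len(set(combos)) == len(combos)


def taxa(labels: dict[str, str]) -> list[TaxonomyRecord]:
    return [
        TaxonomyRecord(genome_id=g, ranks={"species": s, "genus": s.split()[0] if s else ""})
        for g, s in labels.items()
    ]


class TestTaxonomicFilter:
    def test_same_species_filtered(self):
        tax = taxa({"a": "Phocaeicola vulgatus", "b": "Phocaeicola vulgatus"})
        assert list(taxonomic_filter([("a", "b")], tax)) == []

    def test_distinct_species_pass(self):
        tax = taxa({"a": "Species one", "b": "Species two"})
        assert list(taxonomic_filter([("a", "b")], tax)) == [("a", "b")]

    def test_empty_labels_never_collide(self):
        tax = taxa({"a": "", "b": ""})
        assert list(taxonomic_filter([("a", "b")], tax)) == [("a", "b")]

    def test_missing_record_names_genome(self):
        tax = taxa({"a": "Species one"})
        with pytest.raises(KeyError, match="b"):
            list(taxonomic_filter([("a", "b")], tax))

    def test_other_level(self):
        tax = taxa({"a": "Genus one", "b": "Genus two"})
        assert list(taxonomic_filter([("a", "b")], tax, level="genus")) == []

    def test_unknown_level(self):
        with pytest.raises(ValueError, match="level"):
            list(taxonomic_filter([("a",)], taxa({"a": "x"}), level="strain"))


class TestGtdbtkParsing:
    def test_classification_string(self):
        rec = parse_gtdbtk_classification(
            "g1", "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;"
            "f__Bacteroidaceae;g__Phocaeicola;s__Phocaeicola vulgatus"
        )
        assert rec.ranks["species"] == "Phocaeicola vulgatus"
        assert rec.ranks["domain"] == "Bacteria"

    def test_unassigned_species(self):
        rec = parse_gtdbtk_classification("g1", "d__Bacteria;s__")
        assert rec.label("species") == ""

    def test_summary_file(self, tmp_path):
        path = tmp_path / "gtdbtk.summary.tsv"
        path.write_text(
            "user_genome\tclassification\tother\n"
            "g1\td__Bacteria;s__Foo bar\tx\n"
        )
        recs = read_gtdbtk_summary(path)
        assert recs[0].genome_id == "g1"
        assert recs[0].ranks["species"] == "Foo bar"

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("genome\tlineage\ng1\tx\n")
        with pytest.raises(ValueError, match="missing required column"):
            read_gtdbtk_summary(path)


class TestFunctionalRedundancy:
    def test_hand_count(self):
        pct, hist = functional_redundancy([profile("a", 1, 2), profile("b", 2, 3)])
        assert pct == pytest.approx(200 / 3)
        assert hist == {1: 2, 2: 1}

    def test_single_member(self):
        pct, _ = functional_redundancy([profile("a", 1, 2)])
        assert pct == 100.0

    def test_identical_members(self):
        pct, hist = functional_redundancy([profile("a", 1), profile("b", 1)])
        assert pct == 0.0
        assert hist == {2: 1}

    def test_no_members_rejected(self):
        with pytest.raises(ValueError):
            functional_redundancy([])


class TestGroupScore:
    def test_single_sample_identity(self):
        genomes = build_profile_matrix([profile("a", 1, 2), profile("b", 3)])
        samples = build_profile_matrix([profile("s", 1, 2, 3)])
        cand = group_score(["a", "b"], genomes, samples, W0)
        assert cand.group_score == 3.0
        assert cand.combined_profile.pfams == {pf(1), pf(2), pf(3)}

    def test_mean_over_samples(self):
        genomes = build_profile_matrix([profile("a", 1, 2), profile("b", 3)])
        samples = build_profile_matrix(
            [profile("s1", 1, 2), profile("s2", 2, 3, 4)], universe=[pf(i) for i in (1, 2, 3, 4)]
        )
        cand = group_score(["a", "b"], genomes, samples, W0)
        assert cand.group_score == pytest.approx(2.0)

    def test_redundant_member_leaves_score_unchanged(self):
        genomes = build_profile_matrix(
            [profile("a", 1, 2), profile("b", 3), profile("c", 1)]
        )
        samples = build_profile_matrix([profile("s", 1, 2, 3)])
        without = group_score(["a", "b"], genomes, samples, W0)
        with_c = group_score(["a", "b", "c"], genomes, samples, W0)
        assert with_c.group_score == without.group_score

    def test_no_samples_rejected(self):
        genomes = build_profile_matrix([profile("a", 1)])
        samples = build_profile_matrix([], universe=[pf(1)])
        with pytest.raises(ValueError):
            group_score(["a"], genomes, samples, W0)

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_adding_member_never_decreases_score(self, data):
        universe = list(range(1, 11))
        sets = [data.draw(st.sets(st.sampled_from(universe)), label=f"g{i}") for i in range(4)]
        sample_set = data.draw(st.sets(st.sampled_from(universe), min_size=1), label="s")
        genomes = build_profile_matrix(
            [profile(f"G{i}", *s) for i, s in enumerate(sets)], universe=[pf(n) for n in universe]
        )
        samples = build_profile_matrix(
            [profile("s", *sample_set)], universe=[pf(n) for n in universe]
        )
        base = group_score(["G0", "G1"], genomes, samples, W0).group_score
        more = group_score(["G0", "G1", "G2"], genomes, samples, W0).group_score
        assert more >= base


class TestRankCandidates:
    def make(self, members, score):
        genomes = build_profile_matrix([profile(m, 1) for m in members])
        samples = build_profile_matrix([profile("s", 1)])
        cand = group_score(members, genomes, samples, W0)
        object.__setattr__(cand, "group_score", score)
        return cand

    def test_descending_order(self):
        cands = [self.make([m], s) for m, s in [("a", 3.0), ("b", 5.0), ("c", 4.0)]]
        ranked = rank_candidates(cands)
        assert [c.group_score for c in ranked] == [5.0, 4.0, 3.0]

    def test_tie_broken_lexicographically(self):
        cands = [self.make([m], 1.0) for m in ("b", "a")]
        ranked = rank_candidates(cands)
        assert [c.members for c in ranked] == [("a",), ("b",)]

    def test_top_k_truncation(self):
        cands = [self.make([f"g{i:02d}"], float(i)) for i in range(20)]
        ranked = rank_candidates(cands, top_k=5)
        assert len(ranked) == 5
        assert ranked[0].group_score == 19.0

    def test_exhaustive_tiny_instance_matches_brute_force(self, rng):
        # 6 genomes, size 2, 1 sample: the top candidate must equal the
        # argmax over all 15 pairs computed by direct set arithmetic
        universe = [pf(n) for n in range(1, 13)]
        gsets = {f"G{i}": set(rng.choice(universe, size=5, replace=False)) for i in range(6)}
        genomes = build_profile_matrix(
            [profile(g).__class__(g, frozenset(s)) for g, s in gsets.items()], universe=universe
        )
        sample_set = set(rng.choice(universe, size=8, replace=False))
        samples = build_profile_matrix(
            [profile("s").__class__("s", frozenset(sample_set))], universe=universe
        )
        cands = [
            group_score(pair, genomes, samples, W0)
            for pair in itertools.combinations(sorted(gsets), 2)
        ]
        ranked = rank_candidates(cands)

        def oracle(pair):
            return len((gsets[pair[0]] | gsets[pair[1]]) & sample_set)

        best_score = max(oracle(p) for p in itertools.combinations(sorted(gsets), 2))
        assert ranked[0].group_score == best_score
        assert oracle(ranked[0].members) == best_score
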