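"""CNA genotype filtering, the genome similarity metric M (against a per-bp
bitmap oracle), chromosome recurrence and UPGMA clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from moevo import (
    CNAProfile,
    chromosome_similarity,
    genome_similarity,
    genotype_filter,
    recurrence_test,
    similarity_matrix,
    upgma_cluster,
)
from moevo.cna import merge_intervals

TOY_GENOME = {"chr1": 10_000, "chr2": 8_000, "chr3": 6_000}


def segments(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tumor_cn", "normal_cn"])


def profile(sample, events, genome=TOY_GENOME):
    events = {
        c: {state: merge_intervals(iv) for state, iv in by_state.items()}
        for c, by_state in events.items()
    }
    return CNAProfile(sample, events, dict(genome))


def bitmap_oracle(p1, p2, genome):
    """Per-bp reimplementation of the state-matched Jaccard metric."""
    total = 0.0
    for chrom, length in genome.items():
        masks = {}
        for p, tag in ((p1, 1), (p2, 2)):
            for state in ("del", "dup"):
                m = np.zeros(length, dtype=bool)
                for s, e in p.intervals(chrom, state):
                    m[s:e] = True
                masks[(tag, state)] = m
        shared = (
            (masks[(1, "dup")] & masks[(2, "dup")]).sum()
            + (masks[(1, "del")] & masks[(2, "del")]).sum()
        )
        union = sum(masks[k].sum() for k in masks) - shared
        if union > 0:
            total += shared / union
    return total


class TestGenotypeFilter:
    def test_thresholds(self):
        segs = segments(
            [
                ("chr1", 0, 1000, 3.1, 2.0),   # kept, dup
                ("chr1", 2000, 3000, 1.0, 1.5),  # dropped: normal outside band
                ("chr1", 4000, 5000, 2.15, 2.0),  # dropped: diff <= 0.2
                ("chr2", 0, 1000, 1.2, 2.0),   # kept, del
            ]
        )
        p = genotype_filter(segs, "s1", TOY_GENOME)
        assert p.intervals("chr1", "dup") == [(0, 1000)]
        assert p.intervals("chr1", "del") == []
        assert p.intervals("chr2", "del") == [(0, 1000)]

    def test_sex_chromosomes_dropped(self):
        segs = segments([("chrX", 0, 1000, 3.0, 2.0), ("Y", 0, 500, 1.0, 2.0)])
        assert genotype_filter(segs, "s1", TOY_GENOME).chroms_with_events() == []

    def test_malformed_rows_rejected_rowwise(self, caplog):
        segs = segments(
            [("chr1", 500, 100, 3.0, 2.0), ("chr1", 0, 1000, 3.0, 2.0)]
        )
        with caplog.at_level("WARNING"):
            p = genotype_filter(segs, "s1", TOY_GENOME)
        assert p.intervals("chr1", "dup") == [(0, 1000)]
        assert "malformed segment" in caplog.text

    def test_overlapping_same_state_segments_merged(self):
        segs = segments(
            [("chr1", 0, 600, 3.0, 2.0), ("chr1", 400, 1000, 3.2, 2.0)]
        )
        p = genotype_filter(segs, "s1", TOY_GENOME)
        assert p.intervals("chr1", "dup") == [(0, 1000)]


class TestChromosomeSimilarity:
    def test_identity(self):
        a = profile("a", {"chr1": {"dup": [(0, 100)]}})
        b = profile("b", {"chr1": {"dup": [(0, 100)]}})
        assert chromosome_similarity(a, b, "chr1") == 1.0

    def test_partial_overlap(self):
        a = profile("a", {"chr1": {"dup": [(0, 100)]}})
        b = profile("b", {"chr1": {"dup": [(50, 150)]}})
        assert chromosome_similarity(a, b, "chr1") == pytest.approx(1 / 3)

    def test_cross_state_overlap_counts_only_in_denominator(self):
        a = profile("a", {"chr1": {"dup": [(0, 100)]}})
        b = profile("b", {"chr1": {"del": [(0, 100)]}})
        assert chromosome_similarity(a, b, "chr1") == 0.0

    def test_empty_chromosome_scores_zero(self):
        a = profile("a", {})
        assert chromosome_similarity(a, a, "chr1") == 0.0

    def test_symmetry_and_bounds(self, rng):
        for _ in range(20):
            a = random_profile("a", rng)
            b = random_profile("b", rng)
            for chrom in TOY_GENOME:
                s_ab = chromosome_similarity(a, b, chrom)
                assert s_ab == chromosome_similarity(b, a, chrom)
                assert 0.0 <= s_ab <= 1.0

    def test_invariant_to_splitting_intervals(self):
        whole = profile("a", {"chr1": {"dup": [(0, 1000)]}})
        split = profile("a2", {"chr1": {"dup": [(0, 400), (400, 1000)]}})
        other = profile("b", {"chr1": {"dup": [(200, 700)], "del": [(800, 900)]}})
        assert chromosome_similarity(whole, other, "chr1") == pytest.approx(
            chromosome_similarity(split, other, "chr1")
        )


def random_profile(sample, rng, genome=TOY_GENOME):
    events = {}
    for chrom, length in genome.items():
        by_state = {"dup": [], "del": []}
        # dups in the first half, dels in the second: states stay disjoint
        for state, lo, hi in (("dup", 0, length // 2), ("del", length // 2, length)):
            for _ in range(rng.integers(0, 3)):
                s = int(rng.integers(lo, hi - 10))
                e = int(rng.integers(s + 1, hi))
                by_state[state].append((s, e))
        if by_state["dup"] or by_state["del"]:
            events[chrom] = by_state
    return profile(sample, events, genome)


class TestGenomeSimilarity:
    def test_identical_profiles_count_event_chromosomes(self):
        ev = {"chr1": {"dup": [(0, 500)]}, "chr2": {"del": [(100, 300)]}}
        a, b = profile("a", ev), profile("b", ev)
        assert genome_similarity(a, b) == 2.0

    def test_disjoint_profiles_score_zero(self):
        a = profile("a", {"chr1": {"dup": [(0, 100)]}})
        b = profile("b", {"chr2": {"dup": [(0, 100)]}})
        assert genome_similarity(a, b) == 0.0

    def test_matches_bitmap_oracle_on_random_profiles(self, rng):
        for _ in range(50):
            a = random_profile("a", rng)
            b = random_profile("b", rng)
            assert genome_similarity(a, b) == pytest.approx(
                bitmap_oracle(a, b, TOY_GENOME), abs=1e-12
            )


class TestRecurrence:
    def cohort(self, rng, n=6):
        profiles = []
        for i in range(n):
            events = {"chr1": {"dup": [(0, TOY_GENOME["chr1"])], "del": []}}
            # occasional unrelated noise elsewhere
            if rng.random() < 0.5:
                chrom = rng.choice(["chr2", "chr3"])
                s = int(rng.integers(0, 3000))
                events[chrom] = {"dup": [], "del": [(s, s + 500)]}
            profiles.append(profile(f"s{i}", events))
        return profiles

    def test_enriched_chromosome_detected(self, rng):
        result = recurrence_test(self.cohort(rng), "cancer")
        by_chrom = result.set_index("chrom")
        assert by_chrom.loc["chr1", "p_value"] < 0.01
        assert (by_chrom.drop("chr1")["p_value"] > 0.05).all()

    def test_identical_events_everywhere_not_significant(self):
        ev = {c: {"dup": [(0, L)], "del": []} for c, L in TOY_GENOME.items()}
        profiles = [profile(f"s{i}", ev) for i in range(5)]
        result = recurrence_test(profiles, "cap")
        assert (result["p_value"] >= 0.5).all()

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            recurrence_test([profile("a", {}), profile("b", {})])

    def test_invariant_to_chromosome_relabeling(self, rng):
        profiles = self.cohort(rng)
        mapping = {"chr1": "chr3", "chr2": "chr1", "chr3": "chr2"}
        relabeled = [
            profile(
                p.sample_id,
                {mapping[c]: ev for c, ev in p.events.items()},
                {mapping[c]: L for c, L in TOY_GENOME.items()},
            )
            for p in profiles
        ]
        a = recurrence_test(profiles, "t").set_index("chrom")["p_value"]
        b = recurrence_test(relabeled, "t").set_index("chrom")["p_value"]
        for old, new in mapping.items():
            assert a[old] == pytest.approx(b[new])

    def test_sample_mode_also_flags_enrichment(self, rng):
        result = recurrence_test(self.cohort(rng), "cancer", mode="samples")
        assert result.set_index("chrom").loc["chr1", "p_value"] < 0.05


def brute_force_upgma(dist):
    """Textbook UPGMA on a dense matrix; returns sorted merge heights."""
    clusters = {i: [i] for i in range(len(dist))}
    d = {(i, j): dist[i][j] for i in clusters for j in clusters if i < j}
    heights = []
    next_id = len(dist)
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        merged = clusters[i] + clusters[j]
        del clusters[i], clusters[j]
        d = {k: v for k, v in d.items() if i not in k and j not in k}
        for k in clusters:
            pairs = [(a, b) for a in clusters[k] for b in merged]
            d[(min(k, next_id), max(k, next_id))] = float(
                np.mean([dist[a][b] for a, b in pairs])
            )
        clusters[next_id] = merged
        next_id += 1
    return heights


class TestUpgma:
    def test_identical_pair_merges_first(self):
        ev = {"chr1": {"dup": [(0, 500)]}}
        profiles = [profile("a", ev), profile("b", ev),
                    profile("c", {"chr2": {"del": [(0, 500)]}})]
        sm = similarity_matrix(profiles)
        Z, labels = upgma_cluster(sm.M, kind="similarity")
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == 0.0

    def test_all_equal_distances_tie_break_by_index(self):
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        Z, _ = upgma_cluster(d)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            upgma_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_merge_heights_match_brute_force(self, rng):
        for _ in range(5):
            d = rng.uniform(0.1, 2.0, size=(6, 6))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            Z, _ = upgma_cluster(d)
            assert Z[:, 2] == pytest.approx(brute_force_upgma(d.tolist()))


class TestSimilarityMatrix:
    def test_diagonal_per_chromosome_is_one_where_events_exist(self, rng):
        profiles = [random_profile(f"s{i}", rng) for i in range(4)]
        sm = similarity_matrix(profiles)
        for i, p in enumerate(profiles):
            for chrom in p.chroms_with_events():
                assert sm.per_chrom[chrom].iloc[i, i] == 1.0
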