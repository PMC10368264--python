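"""Pairwise alignment identity, chimera detection, greedy clustering."""

import numpy as np
import pytest

from rbcltrace.cluster_chimera import (
    Cluster,
    UniqueSeq,
    align_pair,
    dereplicate,
    detect_chimeras,
    greedy_cluster,
    remove_chimeras,
)
from rbcltrace.seqio import SeqRecord


def _brute_overlap_optima(a: str, b: str) -> set[tuple[int, int]]:
    """Exhaustive ungapped oracle: all score-optimal (matches, columns) pairs.

    Enumerates every ungapped segment pair (offset plus window trimming),
    which covers the optimum for substitution-only cases: replacing a
    mismatch column (-2) by an insertion+deletion pair (-4) never helps.
    Returns the set of (matches, columns) achieving the maximal score, so
    the caller can accept any optimal-alignment tie the DP picks.
    """
    best_score = None
    optima: set[tuple[int, int]] = set()
    for off in range(-(len(b) - 1), len(a)):
        a0, b0 = max(off, 0), max(-off, 0)
        span = min(len(a) - a0, len(b) - b0)
        eq = [a[a0 + i] == b[b0 + i] and a[a0 + i] != "N" for i in range(span)]
        for start in range(span):
            m = 0
            for end in range(start + 1, span + 1):
                m += eq[end - 1]
                n = end - start
                score = m - 2 * (n - m)
                if best_score is None or score > best_score:
                    best_score = score
                    optima = {(m, n)}
                elif score == best_score:
                    optima.add((m, n))
    return optima


class TestAlignPair:
    def test_identical(self):
        r = align_pair("ACGTACGT", "ACGTACGT")
        assert r.identity == 1.0 and r.columns == 8

    def test_single_substitution(self):
        r = align_pair("ACGTACGT", "ACGAACGT")
        assert r.identity == pytest.approx(7 / 8)

    def test_terminal_overhangs_excluded(self):
        r = align_pair("ACGTACGT", "CGTACG")
        assert r.identity == 1.0
        assert r.columns == 6

    def test_masked_primer_tails_ignored(self):
        core = "CACGAGGAAGTCTCGCGCTGCCATATTAGGGTTTGATGCC"
        r = align_pair("N" * 20 + core + "N" * 10, "GGGG" + core + "TTTT")
        assert r.identity == 1.0
        assert r.columns == len(core)

    def test_n_matches_nothing(self):
        r = align_pair("ACGTNACGT", "ACGTTACGT")
        assert r.matches == 8
        assert r.identity == pytest.approx(8 / 9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")

    def test_matches_bruteforce_oracle_on_substitution_pairs(self):
        rng = np.random.default_rng(5)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for _ in range(25):
            ref = rng.choice(bases, size=60).tobytes().decode()
            # cut a fragment and substitute a couple of bases
            start = int(rng.integers(0, 20))
            frag = list(ref[start : start + 40])
            for pos in rng.choice(len(frag), size=2, replace=False):
                frag[pos] = "ACGT"[int(rng.integers(4))]
            frag = "".join(frag)
            got = align_pair(frag, ref)
            assert (got.matches, got.columns) in _brute_overlap_optima(frag, ref)


class TestDereplicate:
    def test_merges_identical_and_tracks_samples(self):
        reads = [
            ("s1", SeqRecord("r1", "ACGTACGTACGT")),
            ("s2", SeqRecord("r2", "ACGTACGTACGT")),
            ("s1", SeqRecord("r3", "TTTTACGTACGT")),
        ]
        uniques = dereplicate(reads)
        assert len(uniques) == 2
        top = next(u for u in uniques if u.abundance == 2)
        assert top.rep_id == "r1"
        assert top.per_sample == {"s1": 1, "s2": 1}


def _mutate_positions(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestDetectChimeras:
    def _parents(self, rng, length=200, divergence=0.10):
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        a = rng.choice(bases, size=length).tobytes().decode()
        k = max(1, int(divergence * length))
        positions = rng.choice(length, size=k, replace=False)
        b = _mutate_positions(a, positions, rng)
        return a, b

    def test_constructed_chimera_flagged(self):
        rng = np.random.default_rng(2)
        a, b = self._parents(rng)
        chim = a[:100] + b[100:]
        uniques = [
            UniqueSeq(a, "parentA", 8, {"s": 8}),
            UniqueSeq(b, "parentB", 8, {"s": 8}),
            UniqueSeq(chim, "query", 2, {"s": 2}),
        ]
        report = detect_chimeras(uniques)
        assert report.flagged == {"query"}
        assert set(report.details["query"]) == {"parentA", "parentB"}

    def test_identical_to_parent_not_flagged(self):
        rng = np.random.default_rng(3)
        a, b = self._parents(rng)
        uniques = [
            UniqueSeq(a, "parentA", 8, {"s": 8}),
            UniqueSeq(b, "parentB", 8, {"s": 8}),
            UniqueSeq(a, "query", 2, {"s": 2}),
        ]
        # identical sequences would have been dereplicated; simulate a copy
        # with one error so it stays unique but is clearly single-parent
        uniques[2] = UniqueSeq(_mutate_positions(a, [5], rng), "query", 2, {"s": 2})
        report = detect_chimeras(uniques)
        assert report.flagged == set()

    def test_most_abundant_never_flagged(self):
        rng = np.random.default_rng(4)
        a, b = self._parents(rng)
        chim = a[:100] + b[100:]
        uniques = [
            UniqueSeq(chim, "top", 100, {"s": 100}),
            UniqueSeq(a, "pa", 8, {"s": 8}),
            UniqueSeq(b, "pb", 8, {"s": 8}),
        ]
        report = detect_chimeras(uniques)
        assert "top" not in report.flagged

    def test_abundance_skew_required(self):
        rng = np.random.default_rng(6)
        a, b = self._parents(rng)
        chim = a[:100] + b[100:]
        uniques = [
            UniqueSeq(a, "pa", 3, {"s": 3}),
            UniqueSeq(b, "pb", 3, {"s": 3}),
            UniqueSeq(chim, "query", 2, {"s": 2}),  # parents < 2x query
        ]
        report = detect_chimeras(uniques)
        assert report.flagged == set()


class TestGreedyCluster:
    def test_identical_reads_one_cluster(self):
        uniques = dereplicate(
            [("s1", SeqRecord(f"r{i}", "ACGT" * 20)) for i in range(10)]
        )
        clusters = greedy_cluster(uniques)
        assert len(clusters) == 1
        assert clusters[0].size == 10

    def test_two_groups_at_90pct_identity_two_clusters(self):
        rng = np.random.default_rng(7)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        a = rng.choice(bases, size=150).tobytes().decode()
        positions = rng.choice(150, size=15, replace=False)
        b = _mutate_positions(a, positions, rng)
        reads = [("s", SeqRecord(f"a{i}", a)) for i in range(5)]
        reads += [("s", SeqRecord(f"b{i}", b)) for i in range(4)]
        clusters = greedy_cluster(dereplicate(reads))
        assert len(clusters) == 2
        assert sorted(c.size for c in clusters) == [4, 5]

    def test_members_within_threshold_of_centroid(self, small_db, decoys):
        from rbcltrace.synthetic_data import CommunitySpec, simulate_sample

        species = [lin for _, _, lin in small_db.records][:3]
        spec = CommunitySpec(
            sample_id="s",
            proportions=dict(zip(species, (0.5, 0.3, 0.2))),
            n_reads=300,
            host_fraction=0.0,
            chimera_fraction=0.0,
            per_base_error=0.005,
            seed=21,
        )
        reads, _ = simulate_sample(spec, small_db, decoys)
        uniques = dereplicate(("s", r) for r in reads)
        clusters = greedy_cluster(uniques)
        by_seq = {u.sequence: u for u in uniques}
        seq_of_rep = {u.rep_id: u.sequence for u in uniques}
        for c in clusters:
            for rep_id in c.member_ids:
                res = align_pair(seq_of_rep[rep_id], c.centroid.sequence)
                assert res.identity >= 0.97

    def test_cluster_count_matches_sources(self, small_db, decoys):
        """Reads from k references at 10% divergence: k major clusters map 1:1."""
        from rbcltrace.synthetic_data import CommunitySpec, simulate_sample

        species = [lin for _, _, lin in small_db.records][:4]
        spec = CommunitySpec(
            sample_id="s",
            proportions=dict(zip(species, (0.25, 0.25, 0.25, 0.25))),
            n_reads=600,
            host_fraction=0.0,
            chimera_fraction=0.0,
            per_base_error=0.005,
            seed=23,
        )
        reads, _ = simulate_sample(spec, small_db, decoys)
        clusters = greedy_cluster(dereplicate(("s", r) for r in reads))
        assert len(clusters) >= 4
        largest = sorted(clusters, key=lambda c: -c.size)[:4]
        matched_refs = set()
        for c in largest:
            hits = [
                (align_pair(c.centroid.sequence, seq).identity, rid)
                for rid, seq, _ in small_db.records
            ]
            ident, rid = max(hits)
            assert ident >= 0.98
            matched_refs.add(rid)
        assert len(matched_refs) == 4

    def test_conservation_and_determinism(self):
        rng = np.random.default_rng(9)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        base = rng.choice(bases, size=120).tobytes().decode()
        reads = []
        for i in range(40):
            s = _mutate_positions(base, rng.choice(120, size=int(rng.integers(0, 4)), replace=False), rng)
            reads.append(("s", SeqRecord(f"r{i}", s)))
        uniques = dereplicate(reads)
        report = detect_chimeras(uniques)
        survivors = remove_chimeras(uniques, report)
        clusters = greedy_cluster(survivors)
        assert sum(c.size for c in clusters) + report.n_flagged_reads == 40
        again = greedy_cluster(remove_chimeras(uniques, detect_chimeras(uniques)))
        assert [(c.cluster_id, c.centroid.sequence, c.per_sample_counts) for c in clusters] == [
            (c.cluster_id, c.centroid.sequence, c.per_sample_counts) for c in again
        ]
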