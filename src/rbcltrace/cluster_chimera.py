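"""Pairwise alignment, de-novo chimera removal and greedy 97% centroid clustering.

The aligner is a semi-global (free end gap) affine-gap DP under
match=+1, mismatch=-2, gap open=-2, gap extend=-1, with ``N`` matching
nothing.  Identity is identical aligned positions divided by alignment
columns, where internal gaps count as columns and terminal overhangs are
excluded.  Because terminal overhangs are excluded, a score-optimal
alignment of two unrelated sequences can be a short perfect overlap with
identity near 1; every consumer of identity therefore also checks how much
of the shorter sequence the alignment covers (``columns``) before acting
on it.

Chimera detection is a deliberately simplified de-novo two-parent test:
a query is chimeric when some two-segment model built from more-abundant
(>= 2x, the standard abundance-skew rule) previously accepted sequences
explains the query at >= 97% identity while beating the best single parent
by at least 0.8 percentage points of identity (the classic de-novo
minimum-divergence default).

Clustering is greedy first-match centroid assignment in centroid creation
order, processing sequences by decreasing abundance (ties: decreasing
length, then lexicographic id), emulating cluster_fast-style behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SeqRecord

__all__ = [
    "AlignmentResult",
    "align_pair",
    "UniqueSeq",
    "dereplicate",
    "ChimeraReport",
    "detect_chimeras",
    "Cluster",
    "greedy_cluster",
    "KmerIndex",
]

MATCH = 1
MISMATCH = -2
GAP_OPEN = -2
GAP_EXTEND = -1

_ALPHABET = "ACGTN"


def _substitution_matrix():
    mat = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            # N matches nothing, not even another N
            mat[a, b] = MATCH if (a == b and a != "N") else MISMATCH
    return mat


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _substitution_matrix()
    aligner.open_internal_gap_score = GAP_OPEN
    aligner.extend_internal_gap_score = GAP_EXTEND
    if mode == "overlap":
        # Terminal gaps free on both sequences, including "jagged" ends
        # where both sequences dangle: with every prefix/suffix trimmable
        # at zero cost this is exactly local alignment.
        aligner.mode = "local"
    elif mode == "fit":
        # second sequence (b) must be fully aligned; first (a) may dangle
        aligner.end_deletion_score = 0.0
        aligner.open_end_insertion_score = GAP_OPEN
        aligner.extend_end_insertion_score = GAP_EXTEND
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")
    return aligner


_ALIGNERS = {"overlap": _make_aligner("overlap"), "fit": _make_aligner("fit")}


@dataclass
class AlignmentResult:
    """Summary of one pairwise alignment.

    ``identity`` = matches / columns over the aligned core (terminal
    overhangs excluded, internal gap positions counted as columns).
    ``a_span``/``b_span`` are half-open coordinate ranges of the aligned
    core on each input sequence.
    """

    score: float
    identity: float
    columns: int
    matches: int
    a_span: tuple[int, int]
    b_span: tuple[int, int]


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_N_BYTE = ord("N")


def _walk_alignment(a: str, b: str, coords: np.ndarray):
    """Classify alignment segments; return (matches, columns, spans, match positions on a).

    ``coords`` is the Biopython coordinates array: row 0 indexes ``a``
    (target), row 1 indexes ``b`` (query).
    """
    a_arr = _as_bytes(a)
    b_arr = _as_bytes(b)
    segs = []
    for j in range(coords.shape[1] - 1):
        a0, a1 = int(coords[0, j]), int(coords[0, j + 1])
        b0, b1 = int(coords[1, j]), int(coords[1, j + 1])
        da, db = a1 - a0, b1 - b0
        if da == 0 and db == 0:
            continue
        segs.append((a0, a1, b0, b1, da > 0 and db > 0))
    diag = [i for i, s in enumerate(segs) if s[4]]
    if not diag:
        return 0, 0, (0, 0), (0, 0), np.zeros(len(a), dtype=bool)
    first, last = diag[0], diag[-1]
    matches = 0
    columns = 0
    match_pos = np.zeros(len(a), dtype=bool)
    for a0, a1, b0, b1, is_diag in segs[first : last + 1]:
        if is_diag:
            eq = (a_arr[a0:a1] == b_arr[b0:b1]) & (a_arr[a0:a1] != _N_BYTE)
            matches += int(eq.sum())
            match_pos[a0:a1] = eq
            columns += a1 - a0
        else:
            columns += max(a1 - a0, b1 - b0)
    a_span = (segs[first][0], segs[last][1])
    b_span = (segs[first][2], segs[last][3])
    return matches, columns, a_span, b_span, match_pos


def _strip_terminal_n(seq: str) -> tuple[str, int]:
    """Remove leading/trailing N runs (masked primer); return (core, offset)."""
    start = 0
    while start < len(seq) and seq[start] == "N":
        start += 1
    end = len(seq)
    while end > start and seq[end - 1] == "N":
        end -= 1
    return seq[start:end], start


def align_pair(a: str, b: str, mode: str = "overlap") -> AlignmentResult:
    """Align two sequences and summarise score/identity/coverage.

    ``mode="overlap"``: terminal gaps free on both sequences (the default,
    used for clustering and database search).  ``mode="fit"``: sequence
    ``b`` must be aligned end-to-end while ``a`` may dangle (used to ask
    whether a reference could spuriously match inside a long decoy).

    Terminal N runs (masked primer sites) are stripped before aligning:
    they can match nothing, and leaving them in would force the DP to
    treat real terminal overhangs as internal gaps.
    """
    if not a or not b:
        raise ValueError("align_pair requires non-empty sequences")
    a_core, a_off = _strip_terminal_n(a)
    b_core, b_off = _strip_terminal_n(b)
    if not a_core or not b_core:
        return AlignmentResult(0.0, 0.0, 0, 0, (a_off, a_off), (b_off, b_off))
    aln = _ALIGNERS[mode].align(a_core, b_core)[0]
    matches, columns, a_span, b_span, _ = _walk_alignment(a_core, b_core, aln.coordinates)
    identity = matches / columns if columns else 0.0
    return AlignmentResult(
        score=float(aln.score),
        identity=identity,
        columns=columns,
        matches=matches,
        a_span=(a_span[0] + a_off, a_span[1] + a_off),
        b_span=(b_span[0] + b_off, b_span[1] + b_off),
    )


def match_profile(query: str, parent: str) -> np.ndarray:
    """Boolean per-position array: query position aligned to an equal base."""
    q_core, q_off = _strip_terminal_n(query)
    p_core, _ = _strip_terminal_n(parent)
    out = np.zeros(len(query), dtype=bool)
    if not q_core or not p_core:
        return out
    aln = _ALIGNERS["overlap"].align(q_core, p_core)[0]
    *_, match_pos = _walk_alignment(q_core, p_core, aln.coordinates)
    out[q_off : q_off + len(q_core)] = match_pos
    return out


# ---------------------------------------------------------------------------
# dereplication


@dataclass
class UniqueSeq:
    """A dereplicated sequence: identical reads merged, abundance = copies."""

    sequence: str
    rep_id: str  # id of the first read carrying this sequence
    abundance: int
    per_sample: dict[str, int] = field(default_factory=dict)

    @property
    def nonn_length(self) -> int:
        return len(self.sequence) - self.sequence.count("N")


def dereplicate(reads: Iterable[tuple[str, SeqRecord]]) -> list[UniqueSeq]:
    """Merge identical sequences across samples.

    ``reads`` yields (sample_id, record) pairs.  Output order follows first
    occurrence; consumers sort by abundance as needed.
    """
    table: dict[str, UniqueSeq] = {}
    for sample_id, rec in reads:
        u = table.get(rec.sequence)
        if u is None:
            table[rec.sequence] = UniqueSeq(rec.sequence, rec.id, 1, {sample_id: 1})
        else:
            u.abundance += 1
            u.per_sample[sample_id] = u.per_sample.get(sample_id, 0) + 1
    return list(table.values())


def _greedy_order(uniques: Sequence[UniqueSeq]) -> list[int]:
    return sorted(
        range(len(uniques)),
        key=lambda i: (-uniques[i].abundance, -len(uniques[i].sequence), uniques[i].rep_id),
    )


# ---------------------------------------------------------------------------
# k-mer candidate screen


class KmerIndex:
    """Inverted k-mer index used as an alignment-free candidate screen.

    Correctness is defined by the DP aligner regardless: the screen only
    skips sequence pairs that share no exact k-mer, which at the identity
    levels that matter (>= 97% over >= 60 bases) essentially never happens.
    """

    def __init__(self, k: int = 12):
        self.k = k
        self._index: dict[str, list[int]] = {}

    def kmers(self, seq: str) -> set[str]:
        k = self.k
        return {
            seq[i : i + k]
            for i in range(len(seq) - k + 1)
            if "N" not in seq[i : i + k]
        }

    def add(self, idx: int, seq: str) -> None:
        for kmer in self.kmers(seq):
            self._index.setdefault(kmer, []).append(idx)

    def candidates(self, seq: str) -> list[int]:
        hits: set[int] = set()
        for kmer in self.kmers(seq):
            hits.update(self._index.get(kmer, ()))
        return sorted(hits)

    def candidate_spans(self, seq: str) -> dict[int, tuple[int, int]]:
        """Per candidate: (shared k-mer count, spanned length on ``seq``).

        The span (first to last shared k-mer position) lower-bounds the
        alignable overlap up to edge erosion by mismatches, letting callers
        skip candidates that cannot meet a coverage floor.
        """
        k = self.k
        first: dict[int, int] = {}
        last: dict[int, int] = {}
        count: dict[int, int] = {}
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            for idx in self._index.get(kmer, ()):
                if idx not in first:
                    first[idx] = i
                last[idx] = i
                count[idx] = count.get(idx, 0) + 1
        return {idx: (count[idx], last[idx] + k - first[idx]) for idx in count}


# ---------------------------------------------------------------------------
# chimera detection


@dataclass
class ChimeraReport:
    flagged: set[str]                  # rep_ids flagged chimeric
    n_tested: int = 0
    n_flagged_reads: int = 0           # total abundance of flagged uniques
    details: dict[str, tuple[str, str]] = field(default_factory=dict)  # rep_id -> parents


def detect_chimeras(
    uniques: Sequence[UniqueSeq],
    abskew: float = 2.0,
    min_model_identity: float = 0.97,
    min_divergence: float = 0.008,
    max_parents: int = 8,
    k: int = 12,
    min_parent_coverage: float = 0.9,
    parent_core_fraction: float = 1 / 16,
) -> ChimeraReport:
    """Flag two-parent chimeras among dereplicated sequences.

    Sequences are processed in decreasing abundance; each query is tested
    against previously accepted sequences at >= ``abskew`` times its
    abundance.  A query is chimeric when the best two-segment (parent A
    prefix + parent B suffix, breakpoint free) model reaches
    ``min_model_identity`` over the query's non-N positions and beats the
    best single parent by ``min_divergence``.

    Candidate parents must additionally (a) span >= ``min_parent_coverage``
    of the query — an amplification parent covers its whole product,
    whereas unrelated fragments tiling parts of the query could otherwise
    assemble spurious two-segment models — and (b) belong to the abundant
    core of the candidate set (>= ``parent_core_fraction`` of the most
    abundant covering candidate): true parents are among the most abundant
    templates, while intermediate-abundance lookalikes are
    disproportionately artifacts (duplicated chimeras, error variants)
    whose presence would hide the divergence signal.
    """
    order = _greedy_order(uniques)
    flagged: set[str] = set()
    details: dict[str, tuple[str, str]] = {}
    parent_index = KmerIndex(k)
    parent_ids: list[int] = []
    n_tested = 0
    n_flagged_reads = 0

    for idx in order:
        q = uniques[idx]
        qseq = q.sequence
        denom = q.nonn_length
        is_chimera = False
        spans = parent_index.candidate_spans(qseq)
        cand = [j for j in spans if uniques[j].abundance >= abskew * q.abundance]
        if cand:
            top_ab = max(uniques[j].abundance for j in cand)
            cand = [
                j for j in cand if uniques[j].abundance >= parent_core_fraction * top_ab
            ]
        # profile only the closest candidates (most shared k-mers); a true
        # parent shares a long exact segment and always ranks near the top
        cand.sort(key=lambda j: (-spans[j][0], uniques[j].rep_id))
        cand = cand[: max(12, 2 * max_parents)]
        if len(cand) >= 2 and denom > 0:
            n_tested += 1
            # coverage is judged on the aligned match span: a real
            # amplification parent extends across the whole product (the
            # divergent segment still scores positively), whereas an
            # unrelated fragment that merely tiles part of the query stops
            # at its own end.  2-k-mer slack absorbs edge erosion.
            cover = min_parent_coverage * denom - 2 * k
            profiles = []
            for j in cand:
                prof = match_profile(qseq, uniques[j].sequence)
                hits = np.flatnonzero(prof)
                if hits.size == 0 or hits[-1] + 1 - hits[0] < cover:
                    continue
                profiles.append((int(prof.sum()), j, prof))
            profiles.sort(key=lambda t: (-t[0], uniques[t[1]].rep_id))
            top = profiles[:max_parents]
            id_top = top[0][0] / denom if top else 0.0
            best_model = 0
            best_pair: Optional[tuple[int, int]] = None
            cums = [(j, np.concatenate(([0], np.cumsum(prof)))) for _, j, prof in top]
            for ai in range(len(cums)):
                ja, cum_a = cums[ai]
                for bi in range(len(cums)):
                    if ai == bi:
                        continue
                    jb, cum_b = cums[bi]
                    total_b = int(cum_b[-1])
                    model = int(np.max(cum_a + (total_b - cum_b)))
                    if model > best_model:
                        best_model = model
                        best_pair = (ja, jb)
            id_model = best_model / denom
            if (
                id_model >= min_model_identity
                and id_model - id_top >= min_divergence
            ):
                is_chimera = True
                flagged.add(q.rep_id)
                n_flagged_reads += q.abundance
                assert best_pair is not None
                details[q.rep_id] = (
                    uniques[best_pair[0]].rep_id,
                    uniques[best_pair[1]].rep_id,
                )
        if not is_chimera and q.abundance >= abskew:
            parent_index.add(idx, qseq)
            parent_ids.append(idx)

    return ChimeraReport(
        flagged=flagged,
        n_tested=n_tested,
        n_flagged_reads=n_flagged_reads,
        details=details,
    )


def remove_chimeras(
    uniques: Sequence[UniqueSeq], report: ChimeraReport
) -> list[UniqueSeq]:
    return [u for u in uniques if u.rep_id not in report.flagged]


# ---------------------------------------------------------------------------
# greedy centroid clustering


@dataclass
class Cluster:
    """A greedy cluster: centroid sequence plus per-sample member counts."""

    cluster_id: str
    centroid: SeqRecord
    per_sample_counts: dict[str, int] = field(default_factory=dict)
    member_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return sum(self.per_sample_counts.values())

    def add(self, u: UniqueSeq) -> None:
        for sample, n in u.per_sample.items():
            self.per_sample_counts[sample] = self.per_sample_counts.get(sample, 0) + n
        self.member_ids.append(u.rep_id)


def greedy_cluster(
    uniques: Sequence[UniqueSeq],
    threshold: float = 0.97,
    min_coverage: float = 0.8,
    k: int = 12,
) -> list[Cluster]:
    """Greedy first-match centroid clustering at ``threshold`` identity.

    A sequence joins the first existing centroid (creation order) whose
    alignment reaches ``threshold`` identity over at least ``min_coverage``
    of the shorter sequence's non-N length; otherwise it founds a new
    centroid.  Per-sample counts accumulate member abundances.
    """
    order = _greedy_order(uniques)
    clusters: list[Cluster] = []
    centroid_nonn: list[int] = []
    index = KmerIndex(k)
    # slack (3 k-mer widths) absorbs span erosion by mismatches near the
    # overlap edges; candidates whose shared-k-mer span cannot reach the
    # coverage floor even with that slack are skipped without alignment
    span_slack = 3 * k
    for idx in order:
        u = uniques[idx]
        joined = False
        spans = index.candidate_spans(u.sequence)
        for ci in sorted(spans):
            c = clusters[ci]
            min_len = min(u.nonn_length, centroid_nonn[ci])
            required = min_coverage * min_len
            if spans[ci][1] < required - span_slack:
                continue
            res = align_pair(u.sequence, c.centroid.sequence)
            if res.identity >= threshold and res.columns >= required:
                c.add(u)
                joined = True
                break
        if not joined:
            cid = f"C{len(clusters):05d}"
            c = Cluster(cluster_id=cid, centroid=SeqRecord(cid, u.sequence))
            c.add(u)
            index.add(len(clusters), u.sequence)
            centroid_nonn.append(u.nonn_length)
            clusters.append(c)
    return clusters
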