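"""Centroid classification against the local reference database.

Each centroid is aligned against every reference; alignment scores are
converted to bit scores and e-values with the standard Karlin-Altschul
constants for +1/-2 nucleotide scoring (lambda = 1.33, K = 0.621):

    bit = (lambda * S - ln K) / ln 2,    E = m * n * 2^(-bit)

with m the query length and n the total database length.  Hits with
e-value >= 0.01 are discarded at the search stage; surviving hits are
filtered for identity > 95% and e-value < 1e-5 (strict inequalities), and
all hits tied at the smallest e-value feed the last-common-ancestor rule:
tied best hits naming different lineages are resolved to the deepest rank
prefix they share.  Centroids with no accepted hit are checked against
the host decoy (identity >= 0.80 over >= 60 columns => host), modelling
the follow-up alignment of unassigned clusters to the host genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .cluster_chimera import AlignmentResult, Cluster, KmerIndex, align_pair
from .seqio import EMPTY_LINEAGE, Lineage, RANKS, ReferenceDB, SeqRecord

__all__ = [
    "KARLIN_LAMBDA",
    "KARLIN_K",
    "Hit",
    "Assignment",
    "Searcher",
    "search",
    "filter_hits",
    "lca",
    "classify",
]

KARLIN_LAMBDA = 1.33
KARLIN_K = 0.621

SEARCH_EVALUE_MAX = 0.01
HIT_MIN_IDENTITY = 0.95
HIT_EVALUE_MAX = 1e-5
HOST_MIN_IDENTITY = 0.80
HOST_MIN_COLUMNS = 60


def bit_score(score: float) -> float:
    return (KARLIN_LAMBDA * score - math.log(KARLIN_K)) / math.log(2.0)


def evalue(score: float, query_length: int, db_length: int) -> float:
    return query_length * db_length * 2.0 ** (-bit_score(score))


@dataclass
class Hit:
    cluster_id: str
    ref_id: str
    score: float
    bit_score: float
    evalue: float
    identity: float
    alignment: Optional[AlignmentResult] = None


@dataclass
class Assignment:
    cluster_id: str
    lineage: Lineage
    supporting_hits: list[str] = field(default_factory=list)
    status: str = "unassigned"  # assigned | unassigned | host
    best_evalue: Optional[float] = None
    best_identity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status == "assigned" and self.lineage.depth < 1:
            raise ValueError("assigned status requires at least a phylum")
        if self.status == "host" and not self.lineage.is_empty():
            raise ValueError("host status requires an empty lineage")


class Searcher:
    """Reusable database searcher with an optional k-mer candidate screen.

    The screen only skips references sharing no exact k-mer with the
    query; any hit able to pass the downstream 95%-identity filter shares
    many, so screening does not change accepted results.
    """

    def __init__(self, db: ReferenceDB, prescreen: bool = True, k: int = 12):
        if len(db) == 0:
            raise ValueError("reference database is empty")
        self.db = db
        self.db_length = db.total_length()
        self.prescreen = prescreen
        self._index: Optional[KmerIndex] = None
        if prescreen:
            self._index = KmerIndex(k)
            for i, (_, seq, _) in enumerate(db.records):
                self._index.add(i, seq)

    def search(self, centroid: SeqRecord, evalue_max: float = SEARCH_EVALUE_MAX) -> list[Hit]:
        if not centroid.sequence.strip("N"):
            raise ValueError(f"centroid {centroid.id!r} has no alignable (non-N) sequence")
        if self._index is not None:
            indices = self._index.candidates(centroid.sequence)
        else:
            indices = range(len(self.db.records))
        hits = []
        m = len(centroid.sequence)
        for i in indices:
            ref_id, ref_seq, _ = self.db.records[i]
            res = align_pair(centroid.sequence, ref_seq)
            if res.score <= 0:
                continue
            e = evalue(res.score, m, self.db_length)
            if e >= evalue_max:
                continue
            hits.append(
                Hit(
                    cluster_id=centroid.id,
                    ref_id=ref_id,
                    score=res.score,
                    bit_score=bit_score(res.score),
                    evalue=e,
                    identity=res.identity,
                    alignment=res,
                )
            )
        hits.sort(key=lambda h: (-h.score, h.evalue, h.ref_id))
        return hits


def search(
    centroid: SeqRecord, db: ReferenceDB, evalue_max: float = SEARCH_EVALUE_MAX
) -> list[Hit]:
    """Align a centroid against every reference; keep hits with e-value < 0.01."""
    return Searcher(db, prescreen=False).search(centroid, evalue_max)


def filter_hits(
    hits: Sequence[Hit],
    min_identity: float = HIT_MIN_IDENTITY,
    evalue_max: float = HIT_EVALUE_MAX,
) -> list[Hit]:
    """Apply the strict identity/e-value filters and keep the tied-best set.

    Hits with identity <= ``min_identity`` or e-value >= ``evalue_max``
    are dropped; among survivors, duplicates per reference keep the
    smallest e-value, and all hits tied at the minimal e-value are
    returned (the tie set feeding the LCA rule).
    """
    best_per_ref: dict[str, Hit] = {}
    for h in hits:
        if h.identity <= min_identity or h.evalue >= evalue_max:
            continue
        cur = best_per_ref.get(h.ref_id)
        if cur is None or h.evalue < cur.evalue:
            best_per_ref[h.ref_id] = h
    if not best_per_ref:
        return []
    min_e = min(h.evalue for h in best_per_ref.values())
    tie = [h for h in best_per_ref.values() if h.evalue == min_e]
    tie.sort(key=lambda h: h.ref_id)
    return tie


def lca(lineages: Sequence[Lineage]) -> Lineage:
    """Deepest rank prefix shared by all lineages (their last common ancestor)."""
    if not lineages:
        raise ValueError("lca of empty lineage list")
    names = [lin.as_tuple() for lin in lineages]
    shared = []
    for i in range(len(RANKS)):
        column = {t[i] for t in names}
        if len(column) == 1 and None not in column:
            shared.append(names[0][i])
        else:
            break
    return Lineage(*shared, *([None] * (len(RANKS) - len(shared))))


def _host_check(
    centroid: SeqRecord,
    decoys: Sequence[SeqRecord],
    decoy_index: Optional[KmerIndex],
    min_identity: float,
    min_columns: int,
) -> bool:
    if decoy_index is not None:
        indices = decoy_index.candidates(centroid.sequence)
    else:
        indices = range(len(decoys))
    for i in indices:
        res = align_pair(centroid.sequence, decoys[i].sequence)
        if res.identity >= min_identity and res.columns >= min_columns:
            return True
    return False


def classify(
    clusters: Sequence[Cluster],
    db: ReferenceDB,
    host_decoys: Sequence[SeqRecord] = (),
    min_identity: float = HIT_MIN_IDENTITY,
    evalue_max: float = HIT_EVALUE_MAX,
    search_evalue_max: float = SEARCH_EVALUE_MAX,
    host_min_identity: float = HOST_MIN_IDENTITY,
    host_min_columns: int = HOST_MIN_COLUMNS,
    prescreen: bool = True,
) -> tuple[list[Assignment], dict]:
    """Classify every centroid: search -> filter -> LCA, else host check.

    Returns the assignments plus a stats dict including the fraction of
    non-plant centroids mapping to the host decoy.
    """
    searcher = Searcher(db, prescreen=prescreen)
    decoy_index: Optional[KmerIndex] = None
    if prescreen and host_decoys:
        decoy_index = KmerIndex(12)
        for i, rec in enumerate(host_decoys):
            decoy_index.add(i, rec.sequence)
    assignments: list[Assignment] = []
    n_host = 0
    n_unassigned = 0
    for cluster in clusters:
        hits = searcher.search(cluster.centroid, evalue_max=search_evalue_max)
        tie = filter_hits(hits, min_identity=min_identity, evalue_max=evalue_max)
        if tie:
            lineage = lca([db.lineage(h.ref_id) for h in tie])
            assignments.append(
                Assignment(
                    cluster_id=cluster.cluster_id,
                    lineage=lineage,
                    supporting_hits=[h.ref_id for h in tie],
                    status="assigned",
                    best_evalue=tie[0].evalue,
                    best_identity=max(h.identity for h in tie),
                )
            )
            continue
        if host_decoys and _host_check(
            cluster.centroid, host_decoys, decoy_index, host_min_identity, host_min_columns
        ):
            n_host += 1
            status = "host"
        else:
            n_unassigned += 1
            status = "unassigned"
        assignments.append(
            Assignment(cluster_id=cluster.cluster_id, lineage=EMPTY_LINEAGE, status=status)
        )
    n_nonplant = n_host + n_unassigned
    stats = {
        "n_clusters": len(clusters),
        "n_assigned": len(clusters) - n_nonplant,
        "n_host": n_host,
        "n_unassigned": n_unassigned,
        "host_fraction_of_nonplant": (n_host / n_nonplant) if n_nonplant else float("nan"),
        "karlin_lambda": KARLIN_LAMBDA,
        "karlin_k": KARLIN_K,
    }
    return assignments, stats
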