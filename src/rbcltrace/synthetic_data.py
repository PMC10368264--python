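"""Ground-truth generators for every pipeline input.

Emulates the situation the pipeline is built for: bulk milk libraries in
which the great majority of reads are host (bovine) DNA and the plant
fraction consists of short, fragmented, error-bearing rbcL amplicon
copies from the cows' diet, plus a small admixture of two-parent PCR
chimeras.

Reference amplicons carry the real rbcL primer sites at both ends
(forward primer + variable region + reverse-complemented reverse primer)
so that primer trimming behaves exactly as on real amplicons.  Reads are
fragments of the amplicon: a uniform fragment length is drawn and the
fragment is cut at a uniform start; fragments at least as long as the
amplicon return the whole amplicon, which is what makes exact duplicates
(and hence the abundance signal the de-novo chimera detector needs)
appear at realistic rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cluster_chimera import align_pair
from .seqio import Lineage, ReferenceDB, SeqRecord

__all__ = [
    "RBCL_FORWARD_PRIMER",
    "RBCL_REVERSE_PRIMER",
    "CommunitySpec",
    "GroundTruth",
    "make_reference_db",
    "make_host_decoy",
    "simulate_sample",
]

# Locus-specific rbcL primer pair (Illumina overhangs removed).  The reverse
# primer carries one purine ambiguity (R = A/G).
RBCL_FORWARD_PRIMER = "ATGTCACCACAAACAGAGACTAAAGC"
RBCL_REVERSE_PRIMER = "GTAAAATCAAGTCCACCRCG"

_COMPLEMENT = str.maketrans("ACGTNRYKMSWBDHV", "TGCANYRMKSWVHDB")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _resolve_iupac(seq: str, rng: np.random.Generator) -> str:
    table = {"R": "AG", "Y": "CT", "K": "GT", "M": "AC", "S": "CG", "W": "AT"}
    return "".join(
        c if c in "ACGTN" else table[c][rng.integers(len(table[c]))] for c in seq
    )


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``rate``.

    A substituted base is always changed (drawn from the 3 other bases).
    """
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode("ascii")


@dataclass
class CommunitySpec:
    """Per-sample simulation parameters: the community and the noise model."""

    sample_id: str
    proportions: dict[Lineage, float]
    n_reads: int = 10_000
    host_fraction: float = 0.8
    chimera_fraction: float = 0.03
    per_base_error: float = 0.005
    fragment_length: tuple[int, int] = (60, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total!r}, expected 1")
        if self.fragment_length[0] < 60:
            raise ValueError("fragment_length min must be >= 60 (shorter reads are all filtered)")
        if self.host_fraction + self.chimera_fraction >= 1:
            raise ValueError("host_fraction + chimera_fraction must be < 1")
        if not (0 <= self.per_base_error <= 0.05):
            raise ValueError("per_base_error must be in [0, 0.05]")


@dataclass
class GroundTruth:
    """Per-read origin labels plus the true per-sample plant proportions."""

    origins: dict[str, str] = field(default_factory=dict)  # read_id -> label
    true_proportions: dict[str, dict[Lineage, float]] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> None:
        overlap = self.origins.keys() & other.origins.keys()
        if overlap:
            raise ValueError(f"duplicate read ids across samples: {sorted(overlap)[:3]}")
        self.origins.update(other.origins)
        self.true_proportions.update(other.true_proportions)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\torigin\n")
            for rid, origin in self.origins.items():
                fh.write(f"{rid}\t{origin}\n")


def _lineage_tree(n_taxa: int) -> list[Lineage]:
    """Species lineages over a fixed single-phylum tree.

    All simulated taxa are plants, hence a single phylum: two genera per
    family, two species per genus, truncated to ``n_taxa``.
    """
    lineages = []
    i = 0
    while len(lineages) < n_taxa:
        fam = f"Family{i // 4 + 1:02d}"
        gen = f"Genus{i // 2 + 1:02d}"
        sp = f"Genus{i // 2 + 1:02d} species{i % 2 + 1}"
        lineages.append(Lineage("Streptophyta", fam, gen, sp))
        i += 1
    return lineages


def make_reference_db(
    n_taxa: int,
    seq_length: int = 230,
    divergence: float = 0.10,
    seed: int = 0,
) -> ReferenceDB:
    """Generate a small rbcL-like reference database with known lineages.

    One amplicon per species: forward primer site + variable region +
    reverse-complemented reverse primer site, ``seq_length`` bases in
    total.  Species sequences are mutated independently from a common
    ancestral variable region at rate ``divergence / 2`` per site, so any
    two species differ by ~``divergence``.  If the realised pairwise
    identity between any two references exceeds 0.97 (the clustering
    radius), a warning is recorded in the DB metadata.
    """
    if n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    if not (0.03 <= divergence <= 0.30):
        raise ValueError("divergence must be in [0.03, 0.30]")
    rng = np.random.default_rng(seed)
    fwd = RBCL_FORWARD_PRIMER
    var_len = seq_length - len(fwd) - len(RBCL_REVERSE_PRIMER)
    if var_len < 40:
        raise ValueError(f"seq_length {seq_length} leaves <40 variable bases between primer sites")
    ancestor = _random_seq(var_len, rng)
    lineages = _lineage_tree(n_taxa)
    records = []
    for i, lin in enumerate(lineages):
        rev_site = reverse_complement(_resolve_iupac(RBCL_REVERSE_PRIMER, rng))
        variable = _mutate(ancestor, divergence / 2.0, rng)
        records.append((f"ref{i + 1:03d}", fwd + variable + rev_site, lin))
    db = ReferenceDB(records=records)
    warnings = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            res = align_pair(records[i][1], records[j][1])
            if res.identity >= 0.97:
                warnings.append(
                    f"references {records[i][0]} and {records[j][0]} share "
                    f"identity {res.identity:.3f} >= 0.97 clustering radius"
                )
    if warnings:
        db.metadata["warnings"] = warnings
    return db


def make_host_decoy(
    n_seqs: int = 3,
    length: int = 2000,
    seed: int = 0,
    db: Optional[ReferenceDB] = None,
    max_attempts: int = 50,
) -> list[SeqRecord]:
    """Random host decoy sequences sharing < 70% identity with every reference.

    Similarity is measured by fitting each reference end-to-end into the
    decoy (the question that matters: could a reference spuriously map
    there).  Candidates failing the bound are rejection-sampled.
    """
    rng = np.random.default_rng(seed)
    decoys: list[SeqRecord] = []
    for i in range(n_seqs):
        for attempt in range(max_attempts):
            seq = _random_seq(length, rng)
            if db is not None:
                worst = max(
                    align_pair(seq, ref_seq, mode="fit").identity
                    for _, ref_seq, _ in db.records
                )
                if worst >= 0.70:
                    continue
            decoys.append(SeqRecord(f"host{i + 1:02d}", seq))
            break
        else:
            raise RuntimeError(
                "could not draw a decoy with < 70% identity to all references; "
                "use longer or more divergent decoys"
            )
    return decoys


def _cut_fragment(
    amplicon: str, fragment_length: tuple[int, int], rng: np.random.Generator
) -> str:
    lo, hi = fragment_length
    flen = int(rng.integers(lo, hi + 1))
    if flen >= len(amplicon):
        return amplicon
    start = int(rng.integers(0, len(amplicon) - flen + 1))
    return amplicon[start : start + flen]


def _quality_for(seq: str, per_base_error: float) -> list[int]:
    # flat phred such that the expected-error rate equals per_base_error
    q = 60 if per_base_error <= 0 else min(60, round(-10.0 * math.log10(per_base_error)))
    return [q] * len(seq)


def simulate_sample(
    spec: CommunitySpec,
    db: ReferenceDB,
    host: Sequence[SeqRecord],
) -> tuple[list[SeqRecord], GroundTruth]:
    """Simulate one sample's FASTQ records with per-read ground truth.

    Each read is host (probability ``host_fraction``), chimeric
    (``chimera_fraction``) or plant; plant reads are fragments of the
    amplicon of a species drawn from ``proportions``; chimeras join a
    prefix of one community amplicon to the suffix of another at a
    breakpoint uniform in the middle 80%, with parents drawn
    abundance-weighted.  Substitution errors apply i.i.d. at
    ``per_base_error`` and the flat quality string encodes that rate.
    """
    species_index = db.species_index()
    missing = [str(l) for l in spec.proportions if l not in species_index]
    if missing:
        raise ValueError(f"proportions reference unknown taxa: {missing}")
    if spec.host_fraction > 0 and not host:
        raise ValueError("host_fraction > 0 but no host decoy sequences given")

    rng = np.random.default_rng(spec.seed)
    lineages = list(spec.proportions.keys())
    probs = np.array([spec.proportions[l] for l in lineages], dtype=float)
    probs = probs / probs.sum()
    amplicons = [db.sequence(species_index[l]) for l in lineages]
    ref_ids = [species_index[l] for l in lineages]

    reads: list[SeqRecord] = []
    truth = GroundTruth()
    truth.true_proportions[spec.sample_id] = dict(spec.proportions)
    for i in range(spec.n_reads):
        rid = f"{spec.sample_id}_r{i:06d}"
        u = rng.random()
        if u < spec.host_fraction:
            src = host[int(rng.integers(len(host)))]
            frag = _cut_fragment(src.sequence, spec.fragment_length, rng)
            origin = "host"
        elif u < spec.host_fraction + spec.chimera_fraction:
            a, b = rng.choice(len(lineages), size=2, replace=True, p=probs)
            while b == a and len(lineages) > 1:
                b = int(rng.choice(len(lineages), p=probs))
            amp_a, amp_b = amplicons[int(a)], amplicons[int(b)]
            L = min(len(amp_a), len(amp_b))
            k = int(rng.integers(int(0.1 * L), int(0.9 * L) + 1))
            frag = amp_a[:k] + amp_b[k:]
            origin = f"chimera:{ref_ids[int(a)]}|{ref_ids[int(b)]}"
        else:
            s = int(rng.choice(len(lineages), p=probs))
            frag = _cut_fragment(amplicons[s], spec.fragment_length, rng)
            origin = f"species:{lineages[s]}"
        frag = _mutate(frag, spec.per_base_error, rng)
        reads.append(SeqRecord(rid, frag, _quality_for(frag, spec.per_base_error)))
        truth.origins[rid] = origin
    return reads, truth
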