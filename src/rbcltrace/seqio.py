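"""Readers/writers for FASTA/FASTQ/TSV inputs and the canonical in-memory records.

All sequence records are plain uppercase DNA over ``{A, C, G, T, N}``.
Quality scores are phred+33 throughout (modern Illumina); phred+64 is not
supported.  FASTQ/FASTA readers are gzip-transparent (detected by magic
bytes, not file extension).

The parsers here are deliberately strict: ambiguity codes other than ``N``
are rejected at parse time so that downstream identity computations are
unambiguous, and malformed records fail hard with the record id and line
number rather than being silently skipped.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "SeqRecord",
    "Lineage",
    "ReferenceDB",
    "SampleSheet",
    "RANKS",
    "read_fastq",
    "read_fasta",
    "write_fastq",
    "write_fasta",
    "read_taxonomy_table",
    "write_taxonomy_table",
    "read_sample_sheet",
]

RANKS = ("phylum", "family", "genus", "species")

_VALID_BASES = set("ACGTN")
# Accepted on input (case-insensitive); U is normalised to T.
_INPUT_BASES = set("ACGTNU" + "acgtnu")

PHRED_OFFSET = 33


class SeqFormatError(ValueError):
    """Raised on malformed FASTA/FASTQ/taxonomy input."""


@dataclass
class SeqRecord:
    """A single sequence with optional per-base phred quality."""

    id: str
    sequence: str
    quality: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqFormatError("record id must be non-empty")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise SeqFormatError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Lineage:
    """An ordered phylum > family > genus > species taxonomic path.

    Ranks are filled top-down: a rank may be named only if every rank above
    it is named.  The all-empty lineage is the "unassigned" lineage.
    """

    phylum: Optional[str] = None
    family: Optional[str] = None
    genus: Optional[str] = None
    species: Optional[str] = None

    def __post_init__(self) -> None:
        names = self.as_tuple()
        seen_gap = False
        for rank, name in zip(RANKS, names):
            if name is None or name == "":
                seen_gap = True
            elif seen_gap:
                raise SeqFormatError(
                    f"rank gap at {self.gap_rank()}: {names!r} violates "
                    "top-down filling (a rank may be named only if all "
                    "ranks above it are named)"
                )

    def gap_rank(self) -> str:
        names = self.as_tuple()
        for rank, name in zip(RANKS, names):
            if not name:
                return rank
        return ""

    def as_tuple(self) -> tuple[Optional[str], ...]:
        return (self.phylum, self.family, self.genus, self.species)

    @property
    def depth(self) -> int:
        """Number of named ranks (0 = unassigned, 4 = species-level)."""
        return sum(1 for n in self.as_tuple() if n)

    def is_empty(self) -> bool:
        return self.depth == 0

    def name_at(self, level: str) -> Optional[str]:
        if level not in RANKS:
            raise ValueError(f"unknown taxonomic level {level!r}")
        return getattr(self, level) or None

    def truncate(self, depth: int) -> "Lineage":
        names = [n if i < depth else None for i, n in enumerate(self.as_tuple())]
        return Lineage(*names)

    def __str__(self) -> str:
        return "/".join(n for n in self.as_tuple() if n) or "UN"


EMPTY_LINEAGE = Lineage()


@dataclass
class ReferenceDB:
    """A local reference database: ref_id -> (sequence, Lineage).

    Stands in for a curated collection of rbcL barcode sequences with known
    lineages.  Every record must carry at least a phylum.
    """

    records: list[tuple[str, str, Lineage]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ref_id, seq, lin in self.records:
            if ref_id in seen:
                raise SeqFormatError(f"duplicate ref_id {ref_id!r} in reference DB")
            seen.add(ref_id)
            if not seq:
                raise SeqFormatError(f"reference {ref_id!r} has empty sequence")
            if lin.depth < 1:
                raise SeqFormatError(
                    f"reference {ref_id!r} lineage must name at least a phylum"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def sequence(self, ref_id: str) -> str:
        return self._by_id()[ref_id][0]

    def lineage(self, ref_id: str) -> Lineage:
        return self._by_id()[ref_id][1]

    def _by_id(self) -> dict[str, tuple[str, Lineage]]:
        cache = self.metadata.get("_index")
        if cache is None or len(cache) != len(self.records):
            cache = {rid: (seq, lin) for rid, seq, lin in self.records}
            self.metadata["_index"] = cache
        return cache

    def total_length(self) -> int:
        return sum(len(seq) for _, seq, _ in self.records)

    def species_index(self) -> dict[Lineage, str]:
        """Map species-level lineage -> ref_id (requires unique species)."""
        out: dict[Lineage, str] = {}
        for rid, _, lin in self.records:
            if lin.depth == 4:
                if lin in out:
                    raise SeqFormatError(f"species {lin} maps to multiple references")
                out[lin] = rid
        return out

    @classmethod
    def from_files(cls, fasta_path, taxonomy_path) -> "ReferenceDB":
        lineages = read_taxonomy_table(taxonomy_path)
        records = []
        for rec in read_fasta(fasta_path):
            if rec.id not in lineages:
                raise SeqFormatError(f"reference {rec.id!r} missing from taxonomy table")
            records.append((rec.id, rec.sequence, lineages[rec.id]))
        return cls(records=records)

    def to_files(self, fasta_path, taxonomy_path) -> None:
        write_fasta((SeqRecord(rid, seq) for rid, seq, _ in self.records), fasta_path)
        write_taxonomy_table(
            {rid: lin for rid, _, lin in self.records}, taxonomy_path
        )


@dataclass
class SampleSheet:
    """sample_id -> (fastq path, group label such as province)."""

    samples: list[tuple[str, str, str]]  # (sample_id, fastq, group)

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.samples]
        if len(set(ids)) != len(ids):
            raise SeqFormatError("duplicate sample_id in sample sheet")
        for sid, _, group in self.samples:
            if not group:
                raise SeqFormatError(f"sample {sid!r} has empty group label")

    @property
    def sample_ids(self) -> list[str]:
        return [s[0] for s in self.samples]

    def fastq(self, sample_id: str) -> str:
        return dict((s, f) for s, f, _ in self.samples)[sample_id]

    def group(self, sample_id: str) -> str:
        return dict((s, g) for s, _, g in self.samples)[sample_id]

    @property
    def groups(self) -> dict[str, str]:
        return {s: g for s, _, g in self.samples}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tfastq\tgroup\n")
            for sid, fq, group in self.samples:
                fh.write(f"{sid}\t{fq}\t{group}\n")


# ---------------------------------------------------------------------------
# low-level IO


def _open_maybe_gzip(path) -> IO[str]:
    """Open text file, transparently decompressing gzip (magic-byte sniff)."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def _normalise_sequence(seq: str, rec_id: str, line_no: int) -> str:
    bad = set(seq) - _INPUT_BASES
    if bad:
        raise SeqFormatError(
            f"record {rec_id!r} near line {line_no}: invalid sequence "
            f"characters {sorted(bad)!r} (only A/C/G/T/N/U accepted)"
        )
    return seq.upper().replace("U", "T")


def read_fastq(path) -> Iterator[SeqRecord]:
    """Yield SeqRecords from a (possibly gzipped) 4-line FASTQ file."""
    with _open_maybe_gzip(path) as fh:
        line_no = 0
        while True:
            header = fh.readline()
            if not header:
                return
            line_no += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise SeqFormatError(f"line {line_no}: expected '@' FASTQ header, got {header[:20]!r}")
            rec_id = header[1:].split()[0] if len(header) > 1 else ""
            seq_line = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual_line = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise SeqFormatError(
                    f"record {rec_id!r} near line {line_no}: missing '+' separator"
                )
            line_no += 3
            seq = _normalise_sequence(seq_line, rec_id, line_no)
            if len(qual_line) != len(seq):
                raise SeqFormatError(
                    f"record {rec_id!r} near line {line_no}: quality length "
                    f"{len(qual_line)} != sequence length {len(seq)}"
                )
            quality = [ord(c) - PHRED_OFFSET for c in qual_line]
            if any(q < 0 for q in quality):
                raise SeqFormatError(
                    f"record {rec_id!r} near line {line_no}: phred score below 0 "
                    "(input must be phred+33)"
                )
            yield SeqRecord(rec_id, seq, quality)


def read_fasta(path) -> Iterator[SeqRecord]:
    """Yield SeqRecords (quality absent) from a '>'-delimited FASTA file.

    Wrapped sequence lines are joined; lowercase is uppercased; U becomes T.
    """
    with _open_maybe_gzip(path) as fh:
        rec_id: Optional[str] = None
        chunks: list[str] = []
        start_line = 0
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if rec_id is not None:
                    yield SeqRecord(rec_id, "".join(chunks))
                rec_id = line[1:].split()[0] if len(line) > 1 else ""
                if not rec_id:
                    raise SeqFormatError(f"line {line_no}: empty FASTA header")
                chunks = []
                start_line = line_no
            else:
                if rec_id is None:
                    raise SeqFormatError(f"line {line_no}: sequence before first '>' header")
                chunks.append(_normalise_sequence(line, rec_id, line_no))
        if rec_id is not None:
            yield SeqRecord(rec_id, "".join(chunks))


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.quality is None:
                raise SeqFormatError(f"record {rec.id!r} has no quality; cannot write FASTQ")
            qual = "".join(chr(q + PHRED_OFFSET) for q in rec.quality)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def read_taxonomy_table(path) -> dict[str, Lineage]:
    """Read a 5-column TSV (ref_id, phylum, family, genus, species).

    Empty cells denote unnamed ranks.  Lineages must satisfy the top-down
    invariant; duplicate ref_ids or rank gaps are hard errors naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    expected = ["ref_id", *RANKS]
    if list(df.columns) != expected:
        raise SeqFormatError(
            f"taxonomy table columns {list(df.columns)!r} != expected {expected!r}"
        )
    out: dict[str, Lineage] = {}
    for i, row in df.iterrows():
        ref_id = row["ref_id"]
        if ref_id in out:
            raise SeqFormatError(f"taxonomy row {i + 2}: duplicate ref_id {ref_id!r}")
        try:
            lin = Lineage(*(row[r] or None for r in RANKS))
        except SeqFormatError as exc:
            raise SeqFormatError(f"taxonomy row {i + 2} ({ref_id!r}): {exc}") from None
        out[ref_id] = lin
    return out


def write_taxonomy_table(lineages: dict[str, Lineage], path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_id\t" + "\t".join(RANKS) + "\n")
        for ref_id, lin in lineages.items():
            cells = [n or "" for n in lin.as_tuple()]
            fh.write(ref_id + "\t" + "\t".join(cells) + "\n")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    expected = ["sample_id", "fastq", "group"]
    if list(df.columns) != expected:
        raise SeqFormatError(
            f"sample sheet columns {list(df.columns)!r} != expected {expected!r}"
        )
    return SampleSheet(samples=[tuple(row) for row in df.itertuples(index=False)])
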