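"""Primer removal and quality filtering.

Trimming follows "anywhere" adapter semantics: internal, 5'-overhanging
and 3'-overhanging primer occurrences are all eligible, with a minimum
overlap of 5 bases, up to 2 removal rounds per read, a 10% mismatch
tolerance over the matched bases, and masking (to N) rather than cutting
by default.  Both the forward primer and the reverse-complemented reverse
primer are searched; IUPAC ambiguity codes in primers match their base
sets.

Quality filtering trims low-quality 3' tails (phred < 20 by default),
then drops reads shorter than 60 bases, then drops reads whose
expected-error rate E/len = (sum of 10^(-q/10)) / len exceeds 1%
(strictly greater; the boundary read is kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seqio import SeqRecord
from .synthetic_data import RBCL_FORWARD_PRIMER, RBCL_REVERSE_PRIMER, reverse_complement

__all__ = [
    "TrimConfig",
    "QCConfig",
    "TrimReport",
    "trim_primers",
    "quality_filter",
    "preprocess_reads",
    "PreprocessReport",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "K": "GT", "M": "AC", "S": "CG", "W": "AT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def default_primers() -> list[str]:
    return [RBCL_FORWARD_PRIMER, reverse_complement(RBCL_REVERSE_PRIMER)]


@dataclass
class TrimConfig:
    primers: list[str] = field(default_factory=default_primers)
    min_overlap: int = 5
    max_rounds: int = 2
    min_length_after_trim: int = 35
    mask: bool = True  # mask-adapter behaviour; False = cut with flanking tail
    max_error_rate: float = 0.10

    def __post_init__(self) -> None:
        if self.min_overlap < 1 or self.max_rounds < 1:
            raise ValueError("min_overlap and max_rounds must be >= 1")


@dataclass
class QCConfig:
    min_length: int = 60
    max_expected_error_rate: float = 0.01
    three_prime_quality_floor: int = 20

    def __post_init__(self) -> None:
        if self.min_length <= 0 or self.max_expected_error_rate <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class TrimReport:
    n_trims: int = 0
    discarded: bool = False
    spans: list[tuple[int, int]] = field(default_factory=list)


class _PrimerMatcher:
    """Precomputed per-position allowed-byte tables for one primer."""

    def __init__(self, primer: str):
        self.primer = primer.upper()
        L = len(self.primer)
        # read N counts as a mismatch against everything, so 'N' is never allowed
        self.lut = np.zeros((L, 256), dtype=bool)
        for i, c in enumerate(self.primer):
            for base in _IUPAC[c]:
                self.lut[i, ord(base)] = True

    def occurrences(self, seq_arr: np.ndarray, min_overlap: int, max_rate: float):
        """Return (mismatch_rate, read_start, read_end) candidate occurrences.

        One vectorised pass covers internal, 5'-overhanging and
        3'-overhanging offsets: the read is padded with L-1 sentinel bytes
        on both sides (matching nothing), and the per-offset overlap length
        normalises the mismatch count to matched bases only.
        """
        L = self.lut.shape[0]
        n = len(seq_arr)
        if n == 0:
            return []
        pad = np.zeros(L - 1, dtype=np.uint8)
        padded = np.concatenate([pad, seq_arr, pad])
        windows = np.lib.stride_tricks.sliding_window_view(padded, L)
        matches = self.lut[np.arange(L)[None, :], windows].sum(axis=1)
        # window i places the primer at read coordinate s = i - (L - 1)
        s = np.arange(len(windows)) - (L - 1)
        overlap = np.minimum(s + L, n) - np.maximum(s, 0)
        valid = overlap >= min_overlap
        rates = np.full(len(windows), np.inf)
        rates[valid] = (overlap[valid] - matches[valid]) / overlap[valid]
        out = []
        for i in np.nonzero(rates <= max_rate)[0]:
            start = int(max(s[i], 0))
            out.append((float(rates[i]), start, int(min(s[i] + L, n))))
        return out


def _matchers(cfg: TrimConfig) -> list[_PrimerMatcher]:
    cached = getattr(cfg, "_matchers", None)
    if cached is None:
        cached = [_PrimerMatcher(p) for p in cfg.primers]
        object.__setattr__(cfg, "_matchers", cached)
    return cached


def trim_primers(read: SeqRecord, cfg: TrimConfig) -> tuple[SeqRecord, TrimReport]:
    """Mask or cut up to ``cfg.max_rounds`` best primer occurrences.

    The best occurrence is the one with the fewest mismatches per matched
    base; ties break to the leftmost.  In cut mode the primer is removed
    together with the flank on the side of the nearer read end; reads
    shorter than ``min_length_after_trim`` after cutting are flagged
    discarded (masking never shortens the read).
    """
    report = TrimReport()
    seq = read.sequence
    qual = list(read.quality) if read.quality is not None else None
    for _ in range(cfg.max_rounds):
        if not seq:
            break
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        best: Optional[tuple[float, int, int]] = None
        for m in _matchers(cfg):
            for cand in m.occurrences(arr, cfg.min_overlap, cfg.max_error_rate):
                if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                    best = cand
        if best is None:
            break
        _, start, end = best
        report.n_trims += 1
        report.spans.append((start, end))
        if cfg.mask:
            seq = seq[:start] + "N" * (end - start) + seq[end:]
        else:
            mid = (start + end) / 2.0
            if mid <= len(seq) / 2.0:
                seq = seq[end:]
                if qual is not None:
                    qual = qual[end:]
            else:
                seq = seq[:start]
                if qual is not None:
                    qual = qual[:start]
    if not cfg.mask and len(seq) < cfg.min_length_after_trim:
        report.discarded = True
    return SeqRecord(read.id, seq, qual), report


def quality_filter(read: SeqRecord, cfg: QCConfig) -> tuple[bool, SeqRecord, str]:
    """3'-trim low-quality tails, then apply length and expected-error filters.

    Returns (keep, trimmed read, reason) where reason is "" when kept.
    """
    if read.quality is None:
        raise ValueError(f"record {read.id!r} has no quality scores; FASTQ required")
    qual = np.asarray(read.quality)
    end = len(qual)
    while end > 0 and qual[end - 1] < cfg.three_prime_quality_floor:
        end -= 1
    trimmed = SeqRecord(read.id, read.sequence[:end], list(read.quality[:end]))
    if end < cfg.min_length:
        return False, trimmed, "length"
    expected_errors = float(np.sum(10.0 ** (-qual[:end] / 10.0)))
    if expected_errors / end > cfg.max_expected_error_rate:
        return False, trimmed, "error_rate"
    return True, trimmed, ""


@dataclass
class PreprocessReport:
    n_in: int = 0
    n_out: int = 0
    n_trimmed: int = 0
    n_dropped_trim: int = 0
    n_dropped_length: int = 0
    n_dropped_error_rate: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def preprocess_reads(
    reads, trim_cfg: Optional[TrimConfig] = None, qc_cfg: Optional[QCConfig] = None
):
    """Run trim + QC over an iterable of reads; returns (kept reads, report)."""
    trim_cfg = trim_cfg or TrimConfig()
    qc_cfg = qc_cfg or QCConfig()
    report = PreprocessReport()
    kept: list[SeqRecord] = []
    for read in reads:
        report.n_in += 1
        trimmed, trep = trim_primers(read, trim_cfg)
        if trep.n_trims:
            report.n_trimmed += 1
        if trep.discarded:
            report.n_dropped_trim += 1
            continue
        ok, final, reason = quality_filter(trimmed, qc_cfg)
        if not ok:
            if reason == "length":
                report.n_dropped_length += 1
            else:
                report.n_dropped_error_rate += 1
            continue
        report.n_out += 1
        kept.append(final)
    return kept, report
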