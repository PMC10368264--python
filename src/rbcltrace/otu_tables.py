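"""Per-level OTU tables with low-count binning and dominance labelling.

Assignments are compacted into taxa x samples count matrices at each
taxonomic level.  A reserved "UN" row collects host/unassigned clusters,
clusters whose LCA lineage is truncated above the level, and (after
filtering) any entry with fewer than 5 reads.  Entries representing more
than 1% of a sample's assigned (non-UN) reads are labelled dominant; the
comparator is strict by default and switchable to >= for the summary
convention used in some figure captions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .seqio import RANKS
from .taxonomy_assign import Assignment

__all__ = [
    "UN",
    "OTUTable",
    "compact",
    "filter_low_count",
    "flag_dominant",
    "summarize_levels",
    "build_all_levels",
]

UN = "UN"

LOW_COUNT_THRESHOLD = 5
DOMINANCE_THRESHOLD = 0.01

_LEVEL_DEPTH = {level: i + 1 for i, level in enumerate(RANKS)}


@dataclass
class OTUTable:
    """A taxa x samples integer count matrix at one taxonomic level."""

    level: str
    counts: pd.DataFrame  # index: taxon names + "UN"; columns: sample ids
    dominant: Optional[pd.DataFrame] = None  # boolean, same shape, set by flag_dominant

    def __post_init__(self) -> None:
        if self.level not in RANKS:
            raise ValueError(f"unknown taxonomic level {self.level!r}")
        if UN not in self.counts.index:
            raise ValueError("OTU table must carry a reserved UN row")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxa(self) -> list[str]:
        return [t for t in self.counts.index if t != UN]

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def assigned_totals(self) -> pd.Series:
        return self.counts.drop(index=UN).sum(axis=0)


def compact(
    assignments: Sequence[Assignment],
    cluster_counts: pd.DataFrame,
    level: str,
) -> OTUTable:
    """Sum per-sample cluster counts into the taxon named at ``level``.

    Clusters with host/unassigned status, or whose lineage is truncated
    above ``level`` (e.g. a family-level LCA in a species table), count
    towards UN.
    """
    if level not in RANKS:
        raise ValueError(f"unknown taxonomic level {level!r}")
    depth = _LEVEL_DEPTH[level]
    by_cluster = {a.cluster_id: a for a in assignments}
    missing = [c for c in cluster_counts.index if c not in by_cluster]
    if missing:
        raise ValueError(f"clusters without assignment: {missing[:3]}")
    rows: dict[str, pd.Series] = {}
    un = pd.Series(0, index=cluster_counts.columns, dtype=int)
    for cluster_id, counts in cluster_counts.iterrows():
        a = by_cluster[cluster_id]
        name = a.lineage.name_at(level) if a.status == "assigned" else None
        if a.status != "assigned" or a.lineage.depth < depth or name is None:
            un = un + counts
        else:
            rows[name] = rows.get(name, pd.Series(0, index=cluster_counts.columns, dtype=int)) + counts
    taxa = sorted(rows)
    data = {t: rows[t] for t in taxa}
    data[UN] = un
    table = pd.DataFrame(data).T.astype(int)
    table = table.loc[taxa + [UN], list(cluster_counts.columns)]
    return OTUTable(level=level, counts=table)


def filter_low_count(table: OTUTable, min_count: int = LOW_COUNT_THRESHOLD) -> OTUTable:
    """Bin per-entry counts below ``min_count`` into UN; totals conserved.

    Entries with exactly ``min_count`` reads are kept (the rule removes
    entries having *less than* ``min_count`` reads).  Taxon rows left all
    zero are dropped.
    """
    counts = table.counts.copy()
    body = counts.drop(index=UN)
    low = (body > 0) & (body < min_count)
    moved = body.where(low, 0).sum(axis=0)
    body = body.mask(low, 0)
    body = body.loc[(body != 0).any(axis=1)]
    counts = pd.concat([body, counts.loc[[UN]] + moved.astype(int)])
    return OTUTable(level=table.level, counts=counts.astype(int))


def flag_dominant(
    table: OTUTable,
    threshold: float = DOMINANCE_THRESHOLD,
    strict: bool = True,
) -> OTUTable:
    """Label entries exceeding ``threshold`` of the sample's assigned reads.

    The denominator is the sample's assigned (non-UN) reads; UN is never
    dominant.  ``strict=True`` uses count/assigned > threshold (the prose
    rule); ``strict=False`` uses >= (the figure-caption convention).
    """
    denom = table.assigned_totals()
    flags = pd.DataFrame(False, index=table.counts.index, columns=table.counts.columns)
    for sample in table.samples:
        if denom[sample] == 0:
            continue  # no assigned reads: nothing can be dominant
        frac = table.counts.loc[table.taxa, sample] / denom[sample]
        hit = frac > threshold if strict else frac >= threshold
        flags.loc[table.taxa, sample] = hit
    out = OTUTable(level=table.level, counts=table.counts.copy(), dominant=flags)
    return out


def _n_taxa(table: OTUTable) -> int:
    body = table.counts.drop(index=UN)
    return int(((body != 0).any(axis=1)).sum())


def summarize_levels(
    raw_tables: dict[str, OTUTable],
    filtered_tables: dict[str, OTUTable],
) -> pd.DataFrame:
    """Per-level raw / post-filter / dominant OTU counts.

    A taxon counts as dominant when flagged in at least one sample.
    Output rows follow phylum -> species order.
    """
    rows = []
    for level in RANKS:
        raw = raw_tables[level]
        filt = filtered_tables[level]
        if filt.dominant is None:
            filt = flag_dominant(filt)
        dominant_any = filt.dominant.loc[filt.taxa].any(axis=1)
        rows.append(
            {
                "level": level,
                "raw_otus": _n_taxa(raw),
                "otus_after_filter": _n_taxa(filt),
                "dominant_otus": int(dominant_any.sum()),
            }
        )
    return pd.DataFrame(rows).set_index("level")


def build_all_levels(
    assignments: Sequence[Assignment],
    cluster_counts: pd.DataFrame,
    min_count: int = LOW_COUNT_THRESHOLD,
    threshold: float = DOMINANCE_THRESHOLD,
    strict: bool = True,
) -> tuple[dict[str, OTUTable], dict[str, OTUTable], pd.DataFrame]:
    """Compact, filter and flag at all four levels; returns (raw, filtered, summary)."""
    raw = {level: compact(assignments, cluster_counts, level) for level in RANKS}
    filtered = {
        level: flag_dominant(filter_low_count(t, min_count), threshold, strict)
        for level, t in raw.items()
    }
    summary = summarize_levels(raw, filtered)
    return raw, filtered, summary
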