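"""Alpha/beta diversity treating each sample as an isolated ecosystem.

Shannon entropy is reported in nats; Simpson as the Gini-Simpson
complement 1 - sum(p_i^2) (the raw concentration sum is exposed as well).
Rarefaction uses the exact hypergeometric expectation of richness at
reduced depth, evaluated in log space.  Beta diversity is Bray-Curtis,
ordinated by classical (metric) multidimensional scaling, i.e. principal
coordinates analysis.  Group differences in alpha indices are tested by
one-way fixed-effects ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "shannon",
    "simpson",
    "simpson_concentration",
    "bray_curtis",
    "distance_matrix",
    "rarefaction_curve",
    "pcoa",
    "PCoAResult",
    "anova_by_group",
    "alpha_table",
]


def _counts(v) -> np.ndarray:
    arr = np.asarray(list(v.values()) if isinstance(v, Mapping) else v, dtype=float)
    if arr.ndim != 1 or (arr < 0).any():
        raise ValueError("abundance vector must be 1-D and non-negative")
    return arr


def _proportions(v) -> np.ndarray:
    arr = _counts(v)
    total = arr.sum()
    if total <= 0:
        raise ValueError("abundance vector has no positive entries")
    return arr[arr > 0] / total


def shannon(v) -> float:
    """Shannon entropy H = -sum(p_i ln p_i), natural log."""
    p = _proportions(v)
    return float(-(p * np.log(p)).sum())


def simpson_concentration(v) -> float:
    """Simpson concentration sum(p_i^2)."""
    p = _proportions(v)
    return float((p * p).sum())


def simpson(v) -> float:
    """Gini-Simpson diversity D = 1 - sum(p_i^2)."""
    return 1.0 - simpson_concentration(v)


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity sum|u_i - v_i| / sum(u_i + v_i).

    ``u`` and ``v`` must be indexed over the same taxon union (mappings are
    aligned by key; missing keys count as zero).
    """
    if isinstance(u, Mapping) or isinstance(v, Mapping):
        keys = sorted(set(u) | set(v))
        ua = np.array([float(u.get(k, 0)) for k in keys])
        va = np.array([float(v.get(k, 0)) for k in keys])
    else:
        ua, va = _counts(u), _counts(v)
        if ua.shape != va.shape:
            raise ValueError("abundance vectors must share the same taxa")
    denom = (ua + va).sum()
    if denom <= 0:
        raise ValueError("both abundance vectors are empty")
    return float(np.abs(ua - va).sum() / denom)


def distance_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis over the columns (samples) of a taxa x samples table."""
    samples = list(table.columns)
    n = len(samples)
    d = np.zeros((n, n))
    arr = table.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(arr[:, i], arr[:, j])
    return pd.DataFrame(d, index=samples, columns=samples)


def rarefaction_curve(v, step: int = 100) -> list[tuple[int, float]]:
    """Expected richness E[S_n] at subsample sizes n = 1, 1+step, ... and N.

    E[S_n] = sum_i [1 - C(N - n_i, n) / C(N, n)], the exact hypergeometric
    expectation, evaluated with log-gamma for numerical stability.
    """
    counts = _counts(v)
    counts = counts[counts > 0].astype(int)
    N = int(counts.sum())
    if N < 1:
        raise ValueError("rarefaction requires at least one read")
    depths = list(range(1, N, step))
    if not depths or depths[-1] != N:
        depths.append(N)
    out = []
    for n in depths:
        terms = np.zeros(len(counts))
        feasible = (N - counts) >= n
        ni = counts[feasible]
        if ni.size:
            log_ratio = (
                gammaln(N - ni + 1)
                - gammaln(N - ni - n + 1)
                - (gammaln(N + 1) - gammaln(N - n + 1))
            )
            terms[feasible] = np.exp(log_ratio)
        expected = float((1.0 - terms).sum())
        out.append((n, expected))
    return out


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame       # samples x axes
    explained: np.ndarray           # fraction of positive eigenvalue mass per axis
    eigenvalues: np.ndarray         # kept (non-negative) eigenvalues
    negative_eigenvalue_magnitude: float


def pcoa(distances: pd.DataFrame, k: int = 2) -> PCoAResult:
    """Classical scaling of a distance matrix (principal coordinates).

    Double-centres B = -1/2 J D^2 J, eigendecomposes, and keeps the top-k
    non-negative eigenpairs; coordinates are eigenvectors scaled by the
    square roots of their eigenvalues.  Negative eigenvalues (non-Euclidean
    distances) are truncated and their total magnitude reported.  If fewer
    than ``k`` positive eigenvalues exist, fewer axes are returned.
    """
    D = distances.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-9 * max(1.0, float(np.abs(eigval).max()))
    positive = eigval > tol
    neg_mass = float(np.abs(eigval[eigval < -tol]).sum())
    kept = min(k, int(positive.sum()))
    vals = eigval[:kept]
    coords = eigvec[:, :kept] * np.sqrt(vals)
    # deterministic sign convention: largest-magnitude loading positive
    for j in range(kept):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    total_pos = float(eigval[positive].sum())
    explained = vals / total_pos if total_pos > 0 else np.zeros(kept)
    coord_df = pd.DataFrame(
        coords, index=distances.index, columns=[f"PCo{j + 1}" for j in range(kept)]
    )
    return PCoAResult(
        coordinates=coord_df,
        explained=explained,
        eigenvalues=vals,
        negative_eigenvalue_magnitude=neg_mass,
    )


def anova_by_group(values: Mapping[str, float], groups: Mapping[str, str]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of per-sample index values across groups.

    Returns (F, p) with df = (g - 1, n - g).  Requires >= 2 groups and at
    least one group with >= 2 observations; all-degenerate (zero
    within-group variance everywhere with equal means) inputs raise.
    """
    by_group: dict[str, list[float]] = {}
    for sample, value in values.items():
        by_group.setdefault(groups[sample], []).append(value)
    arrays = [np.asarray(v, dtype=float) for v in by_group.values()]
    if len(arrays) < 2:
        raise ValueError("ANOVA requires at least two groups")
    if max(len(a) for a in arrays) < 2:
        raise ValueError("ANOVA requires at least one group with >= 2 observations")
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0:
        grand = np.concatenate(arrays).mean()
        if all(np.isclose(a.mean(), grand) for a in arrays):
            return 0.0, 1.0
        raise ValueError("degenerate ANOVA: zero within-group variance everywhere")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def alpha_table(filtered_tables: dict[str, "pd.DataFrame | object"]) -> pd.DataFrame:
    """Per-sample Shannon/Simpson at each level from filtered, UN-excluded tables."""
    from .otu_tables import OTUTable, UN

    rows = []
    for level, table in filtered_tables.items():
        counts = table.counts.drop(index=UN) if isinstance(table, OTUTable) else table
        for sample in counts.columns:
            vec = counts[sample].to_numpy(dtype=float)
            if vec.sum() <= 0:
                continue
            rows.append(
                {
                    "sample": sample,
                    "level": level,
                    "shannon": shannon(vec),
                    "simpson": simpson(vec),
                }
            )
    return pd.DataFrame(rows, columns=["sample", "level", "shannon", "simpson"])
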