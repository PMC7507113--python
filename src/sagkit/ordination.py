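"""COG-category profiles, classical-scaling ordination, and group tests.

Each genome is summarized as the percentage of its assigned COGs falling
in each of the 25 functional categories; genomes below 30% estimated
completeness or lacking a near-full-length 16S gene are excluded.
Ordination is classical scaling (principal coordinates) of Euclidean
distances between the percent rows, computed by eigen-decomposition of
the centered Gram matrix — equivalent to PCA of the centered matrix.
Group separation along a coordinate is tested with the two-sided
Wilcoxon rank-sum test (exact by enumeration for small samples,
midrank-tie-corrected normal approximation otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd

from .constants import COG_CATEGORIES

__all__ = [
    "CogMatrix", "OrdinationResult", "RankSumResult",
    "build_cog_matrix", "filter_genomes", "ordinate",
    "ranksum_test", "group_separation",
]


@dataclass
class CogMatrix:
    """Genomes x 25 COG-category relative abundances (percent)."""

    values: pd.DataFrame            # columns = COG_CATEGORIES, rows sum to 100
    group: pd.Series                # group label per genome
    completeness_pct: pd.Series
    ssu_len: pd.Series              # longest detected 16S per genome (nt)

    def __post_init__(self):
        assert list(self.values.columns) == list(COG_CATEGORIES)


@dataclass
class OrdinationResult:
    genome_ids: list[str]
    coordinates: np.ndarray         # genomes x axes
    eigenvalues: np.ndarray         # nonincreasing
    variance_explained: np.ndarray
    loadings: np.ndarray            # categories x axes


@dataclass(frozen=True)
class RankSumResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float                # rank-sum of group a
    p_value: float
    method: str                     # exact | normal


def build_cog_matrix(
    annotations: list[dict],
    metadata: dict[str, dict] | None = None,
) -> CogMatrix:
    """Aggregate annotation rows into per-genome COG percentages.

    Rows without a COG category are not counted; genomes with zero
    assigned COGs are excluded with a warning. ``metadata`` may carry
    ``group``, ``completeness_pct`` and ``ssu_len`` per genome id.
    """
    counts: dict[str, np.ndarray] = {}
    cat_index = {c: i for i, c in enumerate(COG_CATEGORIES)}
    for r in annotations:
        gid = r["genome_id"]
        vec = counts.setdefault(gid, np.zeros(len(COG_CATEGORIES)))
        cat = r.get("cog_category")
        if cat is None or cat == "":
            continue
        if cat not in cat_index:
            raise ValueError(f"unknown COG category letter {cat!r}")
        vec[cat_index[cat]] += 1
    meta = metadata or {}
    rows, ids = [], []
    for gid, vec in counts.items():
        total = vec.sum()
        if total == 0:
            warnings.warn(f"genome {gid} has no assigned COGs; excluded")
            continue
        rows.append(100.0 * vec / total)
        ids.append(gid)
    values = pd.DataFrame(rows, index=ids, columns=list(COG_CATEGORIES))
    return CogMatrix(
        values=values,
        group=pd.Series({g: meta.get(g, {}).get("group", "all") for g in ids}),
        completeness_pct=pd.Series(
            {g: float(meta.get(g, {}).get("completeness_pct", np.nan))
             for g in ids}),
        ssu_len=pd.Series(
            {g: float(meta.get(g, {}).get("ssu_len", 0.0)) for g in ids}),
    )


def filter_genomes(
    matrix: CogMatrix,
    min_completeness: float = 30.0,
    min_ssu_len: int = 1200,
) -> CogMatrix:
    """Keep genomes with completeness >= threshold and a long-enough 16S."""
    keep = [
        g for g in matrix.values.index
        if matrix.completeness_pct[g] >= min_completeness
        and matrix.ssu_len[g] >= min_ssu_len
    ]
    return CogMatrix(
        values=matrix.values.loc[keep],
        group=matrix.group.loc[keep],
        completeness_pct=matrix.completeness_pct.loc[keep],
        ssu_len=matrix.ssu_len.loc[keep],
    )


def ordinate(matrix: CogMatrix | pd.DataFrame, n_axes: int = 2,
             transform: str = "none") -> OrdinationResult:
    """Classical scaling of Euclidean distances between percent rows.

    Eigen-decomposition of the centered Gram matrix; coordinates are
    eigenvectors scaled by sqrt(eigenvalue), ordered by nonincreasing
    eigenvalue. Sign convention: the first nonzero entry of each axis's
    category loading vector is positive. Axes beyond the matrix rank are
    zero-filled with a warning. ``transform='hellinger'`` ordinates
    sqrt(row proportions) instead of raw percentages.
    """
    X = matrix.values if isinstance(matrix, CogMatrix) else matrix
    ids = list(X.index)
    A = X.to_numpy(dtype=float)
    if transform == "hellinger":
        A = np.sqrt(A / 100.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    n = A.shape[0]
    if n < 3:
        raise ValueError("ordination needs at least 3 genomes")
    Xc = A - A.mean(axis=0, keepdims=True)
    G = Xc @ Xc.T
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    tol = max(1e-9, 1e-12 * max(evals.max(), 1.0))
    evals = np.where(evals > tol, evals, 0.0)
    rank = int(np.sum(evals > 0))
    if n_axes > rank:
        warnings.warn(
            f"requested {n_axes} axes but rank is {rank}; extra axes zero")
    coords = np.zeros((n, n_axes))
    loadings = np.zeros((A.shape[1], n_axes))
    for a in range(min(n_axes, rank)):
        u = evecs[:, a]
        lam = evals[a]
        coord = u * np.sqrt(lam)
        load = Xc.T @ u / np.sqrt(lam)
        nz = np.flatnonzero(np.abs(load) > 1e-12)
        if nz.size and load[nz[0]] < 0:
            load = -load
            coord = -coord
        coords[:, a] = coord
        loadings[:, a] = load
    total = evals.sum()
    var = evals[:n_axes] / total if total > 0 else np.zeros(n_axes)
    if len(var) < n_axes:
        var = np.pad(var, (0, n_axes - len(var)))
    return OrdinationResult(
        genome_ids=ids,
        coordinates=coords,
        eigenvalues=evals[:n_axes] if n_axes <= len(evals)
        else np.pad(evals, (0, n_axes - len(evals))),
        variance_explained=var,
        loadings=loadings,
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum

def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size)
    sorted_v = pooled[order]
    i = 0
    r = 1
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        mid = (r + r + (j - i)) / 2.0
        ranks[order[i : j + 1]] = mid
        r += j - i + 1
        i = j + 1
    return ranks


def ranksum_test(
    x, y, exact_max_n: int = 8, labels: tuple[str, str] = ("x", "y")
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test on two samples.

    The statistic is the rank-sum of the first sample over the pooled
    midranks. When both samples have at most ``exact_max_n`` members the
    null distribution is enumerated exactly over all assignments of the
    pooled ranks; otherwise a normal approximation with midrank tie
    correction is used (no continuity correction). Two-sided p is the
    probability of a rank-sum at least as far from its null mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    W = float(ranks[:n].sum())
    N = n + m
    mu = n * (N + 1) / 2.0
    dev = abs(W - mu)
    if n <= exact_max_n and m <= exact_max_n:
        count = 0
        total = comb(N, n)
        for idx in combinations(range(N), n):
            w = ranks[list(idx)].sum()
            if abs(w - mu) >= dev - 1e-12:
                count += 1
        p = count / total
        method = "exact"
    else:
        _, t_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(t_counts**3 - t_counts) / (N * (N - 1))
        var = n * m / 12.0 * ((N + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = dev / sqrt(var)
            p = 2.0 * 0.5 * (1.0 - erf(z / sqrt(2.0)))
            p = min(1.0, p)
        method = "normal"
    return RankSumResult(labels[0], labels[1], n, m, W, p, method)


def group_separation(
    coords: np.ndarray,
    groups,
    axis: int = 0,
    genome_ids: list[str] | None = None,
) -> list[RankSumResult]:
    """Pairwise rank-sum tests between groups on one ordination axis.

    Groups with fewer than 2 members are skipped with a warning.
    """
    groups = pd.Series(list(groups))
    vals = np.asarray(coords)[:, axis]
    by: dict[str, np.ndarray] = {
        g: vals[np.asarray(groups == g)] for g in sorted(groups.unique())
    }
    usable = {}
    for g, v in by.items():
        if v.size < 2:
            warnings.warn(f"group {g!r} has fewer than 2 members; skipped")
        else:
            usable[g] = v
    out = []
    for a, b in combinations(sorted(usable), 2):
        out.append(ranksum_test(usable[a], usable[b], labels=(a, b)))
    return out
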