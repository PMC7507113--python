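"""Co-sort (heterogeneous DNA source) detection and cohort enrichment.

Two independent detectors flag a SAG as a putative co-sort — a well that
received more than one cell:

* the marker detector: a census of 56 universal single-copy marker
  proteins; markers present in extra copies indicate admixed genomes,
  flagged when the contamination estimate reaches 10%;
* the 16S detector: two near-full-length 16S genes with confident,
  discordant phylum-level assignments.

Cohort-level enrichment is quantified by a chi-square test of
independence on the groups x {co-sort, single} table, decomposed into
per-cell Pearson residuals and percent contributions to the statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import MARKER_SET
from .ssu import SsuClassification

__all__ = [
    "MarkerCensus", "CosortFlags", "ChiSquareDecomposition",
    "marker_census", "flag_cosorts", "chisq_decomposition",
]


@dataclass(frozen=True)
class MarkerCensus:
    genome_id: str
    found: int
    duplicated: int
    completeness_pct: float
    contamination_pct: float


@dataclass(frozen=True)
class CosortFlags:
    sag_id: str
    by_markers: bool
    by_ssu: bool
    group: str


@dataclass
class ChiSquareDecomposition:
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    p_value: float
    residuals: np.ndarray          # Pearson residuals (O-E)/sqrt(E)
    pct_contribution: np.ndarray   # 100 * residual^2 / X^2
    row_labels: list[str]
    col_labels: list[str]


def marker_census(
    marker_ids: list[str],
    genome_id: str = "genome",
    marker_set: tuple[str, ...] = MARKER_SET,
) -> MarkerCensus:
    """Single-copy marker census: completeness and contamination.

    Completeness is the percentage of the marker set found at least once;
    contamination is extra copies (total copies minus distinct markers
    found) as a percentage of the set size. Identifiers outside the
    marker set are ignored with a warning.
    """
    n_set = len(marker_set)
    known = set(marker_set)
    counts: dict[str, int] = {}
    for m in marker_ids:
        if m not in known:
            warnings.warn(f"marker id {m!r} outside the marker set; ignored")
            continue
        counts[m] = counts.get(m, 0) + 1
    found = len(counts)
    total_copies = sum(counts.values())
    return MarkerCensus(
        genome_id=genome_id,
        found=found,
        duplicated=sum(1 for c in counts.values() if c >= 2),
        completeness_pct=100.0 * found / n_set,
        contamination_pct=100.0 * (total_copies - found) / n_set,
    )


def flag_cosorts(
    census: MarkerCensus,
    ssu: list[SsuClassification],
    min_ssu_len: int = 1000,
    conf_floor: float = 80.0,
    contam_threshold: float = 10.0,
    group: str = "all",
) -> CosortFlags:
    """Apply both co-sort detectors to one SAG.

    ``by_markers``: marker contamination >= ``contam_threshold`` percent.
    ``by_ssu``: at least two 16S hits longer than ``min_ssu_len`` with
    confidence >= ``conf_floor`` and *different* phylum assignments.
    """
    by_markers = census.contamination_pct >= contam_threshold
    confident = [
        c for c in ssu
        if c.hit is not None
        and c.hit.length_nt > min_ssu_len
        and c.confidence >= conf_floor
    ]
    phyla = {c.phylum for c in confident}
    by_ssu = len(confident) >= 2 and len(phyla) >= 2
    return CosortFlags(
        sag_id=census.genome_id,
        by_markers=by_markers,
        by_ssu=by_ssu,
        group=group,
    )


def chisq_decomposition(
    observed,
    row_labels: list[str] | None = None,
    col_labels: list[str] | None = None,
) -> ChiSquareDecomposition:
    """Pearson chi-square test with residual decomposition.

    expected_ij = row_i * col_j / N; X^2 = sum (O-E)^2/E with
    df = (r-1)(c-1) and no continuity correction; p from the upper tail
    of the chi-square distribution. Each cell's percent contribution is
    100 * residual^2 / X^2, so contributions sum to 100 when X^2 > 0.
    """
    O = np.asarray(observed, dtype=float)
    if O.ndim != 2 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("observed must be a table with >=2 rows and columns")
    if np.any(O < 0) or not np.allclose(O, np.round(O)):
        raise ValueError("observed must contain nonnegative integer counts")
    rows = O.sum(axis=1)
    cols = O.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row or column margin: expected counts undefined")
    N = O.sum()
    E = np.outer(rows, cols) / N
    resid = (O - E) / np.sqrt(E)
    x2 = float(np.sum(resid**2))
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(stats.chi2.sf(x2, df))
    pct = 100.0 * resid**2 / x2 if x2 > 0 else np.zeros_like(resid)
    return ChiSquareDecomposition(
        observed=O, expected=E, statistic=x2, df=df, p_value=p,
        residuals=resid, pct_contribution=pct,
        row_labels=row_labels or [f"r{i}" for i in range(O.shape[0])],
        col_labels=col_labels or [f"c{j}" for j in range(O.shape[1])],
    )
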