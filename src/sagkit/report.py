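"""Cohort-level summaries: percentages, plate abundances, box statistics,
pairwise diameter tests, and effective complete-genome estimates.

The printed-percentage helper :func:`pct` is the arithmetic backbone of
all headline rates (e.g. 770 of 4,829 SAGs -> 16%), rounding half away
from zero to the requested number of decimals. Effective complete
genomes is the sum of per-SAG completeness fractions: 492 partial
genomes at a mean completeness of 33% carry the information of ~162
randomly sampled complete genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .ordination import RankSumResult, ranksum_test

__all__ = [
    "BoxStats", "pct", "plate_abundance", "boxstats",
    "cumulative_complete_genomes", "pairwise_diameter_tests",
    "cosort_count_table",
]


@dataclass(frozen=True)
class BoxStats:
    group: str
    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def pct(numerator: int, denominator: int, decimals: int = 0) -> float:
    """Percentage rounded half away from zero to ``decimals`` places."""
    if denominator == 0:
        raise ZeroDivisionError("pct denominator must be nonzero")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def plate_abundance(
    table: pd.DataFrame,
    plate_id: str,
    subsample_n: int | None = None,
    seed: int = 0,
    group_col: str = "group",
    plate_col: str = "plate_id",
) -> pd.Series:
    """Per-group fraction of SAGs on one plate, optionally subsampled.

    Subsampling is without replacement and seeded; fractions sum to 1.
    """
    plate = table[table[plate_col] == plate_id]
    if len(plate) == 0:
        raise ValueError(f"plate {plate_id!r} is empty or absent")
    if subsample_n is not None:
        if subsample_n > len(plate):
            raise ValueError("subsample_n exceeds plate size")
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(plate), size=subsample_n, replace=False)
        plate = plate.iloc[np.sort(idx)]
    fracs = plate[group_col].value_counts(normalize=True).sort_index()
    return fracs


def boxstats(values, group: str = "all") -> BoxStats:
    """Tukey box-plot statistics with type-7 (linear) quartiles.

    Whiskers are Q1 - 1.5*IQR and Q3 + 1.5*IQR; values outside them are
    listed as outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("boxstats needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo = q1 - 1.5 * iqr
    hi = q3 + 1.5 * iqr
    outliers = tuple(float(x) for x in v[(v < lo) | (v > hi)])
    return BoxStats(group, int(v.size), float(med), float(q1), float(q3),
                    float(iqr), float(lo), float(hi), outliers)


def cumulative_complete_genomes(completeness_pcts) -> float:
    """Effective number of complete genomes: sum of completeness / 100."""
    v = np.asarray(list(completeness_pcts), dtype=float)
    if v.size == 0:
        return 0.0
    if np.any(v < 0) or np.any(v > 100):
        raise ValueError("completeness percentages must lie in [0, 100]")
    return float(round(v.sum() / 100.0, 1))


def pairwise_diameter_tests(
    diameters: pd.Series,
    groups: pd.Series,
    focal_group: str,
    alpha: float = 0.05,
) -> tuple[list[RankSumResult], int, int]:
    """Rank-sum tests of one group's cell diameters against every other.

    Returns the per-pair results, the number of comparison groups, and
    how many pairs fall below ``alpha`` — the "smaller than most other
    phyla (k/n with p < 0.05)" machinery.
    """
    others = sorted(g for g in groups.unique() if g != focal_group)
    focal = np.asarray(diameters[groups == focal_group], dtype=float)
    results = []
    n_sig = 0
    for g in others:
        other = np.asarray(diameters[groups == g], dtype=float)
        if focal.size < 2 or other.size < 2:
            continue
        r = ranksum_test(focal, other, labels=(focal_group, g))
        results.append(r)
        if r.p_value < alpha:
            n_sig += 1
    return results, len(results), n_sig


def cosort_count_table(
    flags: list, detector: str = "by_markers"
) -> pd.DataFrame:
    """Groups x {cosort, single} counts from per-SAG co-sort flags."""
    rows = {}
    for f in flags:
        hit = getattr(f, detector)
        rec = rows.setdefault(f.group, [0, 0])
        rec[0 if hit else 1] += 1
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["cosort", "single"])
    return df.sort_index()
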