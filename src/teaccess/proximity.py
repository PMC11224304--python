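"""Distance distributions between region sets, stratified peak-score
comparisons and pairwise co-occupancy correlations.

Distances are unsigned, edge-to-edge, zero on overlap and restricted to
the same chromosome; intervals with no same-chromosome partner are dropped
from the comparison with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, nearest_distance, shuffle_regions
from .stats import rank_sum_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceComparison:
    median_real: float
    median_shuffled: float
    p: float
    n_real: int
    n_shuffled: int


def distance_comparison(
    tes: Sequence[GenomicInterval],
    motifs: Sequence[GenomicInterval],
    universe: Sequence[GenomicInterval],
    n_shuffles: int = 1,
    included_fraction: float = 0.9,
    seed: int = 0,
) -> DistanceComparison:
    """Nearest motif distance of real TEs vs length-matched shuffled TEs.

    By default a single shuffle replicate forms the background (matching a
    one-to-one comparison); with ``n_shuffles > 1`` the shuffled distances
    are pooled. The two distance samples are compared by a two-sided
    rank-sum test.
    """
    if not motifs:
        raise ValueError("motifs must be non-empty")
    real = nearest_distance(list(tes), list(motifs))["distance"]
    shuffles = shuffle_regions(
        list(tes), list(universe), n_shuffles,
        included_fraction=included_fraction, seed=seed,
    )
    pooled: List[float] = []
    for shuf in shuffles:
        pooled.extend(nearest_distance(shuf, list(motifs))["distance"].tolist())
    shuffled = pd.Series(pooled)

    n_drop = int(real.isna().sum() + shuffled.isna().sum())
    if n_drop:
        logger.info("distance_comparison: dropped %d intervals with no "
                    "same-chromosome motif", n_drop)
    real = real.dropna()
    shuffled = shuffled.dropna()
    if real.empty or shuffled.empty:
        raise ValueError("no finite distances to compare")
    _, p = rank_sum_test(real.values, shuffled.values, alternative="two-sided")
    return DistanceComparison(
        median_real=float(real.median()),
        median_shuffled=float(shuffled.median()),
        p=p,
        n_real=len(real),
        n_shuffled=len(shuffled),
    )


def score_comparison(
    profiles: pd.DataFrame, factor: str
) -> tuple:
    """Rank-sum comparison of a factor's peak scores between regulatory
    regions with and without a tissue-specific TE.

    ``profiles`` has one row per region, a boolean ``has_liver_te`` column
    and one score column per factor. Returns (rank-sum statistic,
    two-sided p, median with-TE, median without-TE).
    """
    if factor not in profiles.columns:
        raise ValueError(f"unknown factor {factor!r}")
    if "has_liver_te" not in profiles.columns:
        raise ValueError("profiles need a 'has_liver_te' column")
    with_te = profiles.loc[profiles["has_liver_te"].astype(bool), factor].values
    without = profiles.loc[~profiles["has_liver_te"].astype(bool), factor].values
    if len(with_te) == 0 or len(without) == 0:
        raise ValueError("both strata must be non-empty")
    stat, p = rank_sum_test(with_te, without, alternative="two-sided")
    return stat, p, float(np.median(with_te)), float(np.median(without))


def cooccupancy_matrix(
    profiles: pd.DataFrame, factors: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Pairwise Spearman correlation matrix of factor peak scores."""
    if factors is None:
        factors = [c for c in profiles.columns if c != "has_liver_te"]
    if len(profiles) < 3:
        raise ValueError("need >= 3 profiles")
    sub = profiles[list(factors)].astype(float)
    zero_var = [f for f in factors if sub[f].nunique() <= 1]
    if zero_var:
        raise ValueError(f"zero-variance factors: {zero_var}")
    mat = sub.corr(method="spearman")
    np.fill_diagonal(mat.values, 1.0)
    return mat
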