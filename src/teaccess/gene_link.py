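"""Linking TEs to genes, factor target-gene calling, set statistics and
single-sample signature scoring.

The signature score deliberately substitutes the kernel-ecdf gene-set
variation score used in cohort studies with two exactly-testable
single-sample scores that preserve its ranking semantics: a weighted
running-sum rank enrichment (ssGSEA-style, weight exponent 0.25 on
normalized ranks) and a z-mean score. This is the package's one declared
methodological substitution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import GenomicInterval, TEAnnotation, TSSRecord


@dataclass
class GeneLink:
    gene_id: str
    tss: TSSRecord
    linked_te_ids: List[str] = field(default_factory=list)
    is_te_associated: bool = False
    is_factor_target: bool = False


def assign_te_genes(
    tes: Sequence[TEAnnotation],
    tss_catalog: Sequence[TSSRecord],
    window: int = 10_000,
) -> pd.DataFrame:
    """Flag genes with >= 1 TE overlapping ``[tss - window, tss + window)``.

    Returns a frame indexed by gene_id with columns ``linked_te_ids``
    (list) and ``is_te_associated``.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    by_chrom: Dict[str, List[TEAnnotation]] = {}
    for te in tes:
        by_chrom.setdefault(te.interval.chrom, []).append(te)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda t: t.interval.start)
    rows = []
    for rec in tss_catalog:
        lo = max(0, rec.pos - window)
        hi = rec.pos + window
        linked: List[str] = []
        for te in by_chrom.get(rec.chrom, []):
            if te.interval.start >= hi:
                break
            if te.interval.end > lo:
                linked.append(te.interval.name)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "linked_te_ids": linked,
                "is_te_associated": bool(linked),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def call_factor_targets(
    peaks: Sequence[GenomicInterval],
    tss_catalog: Sequence[TSSRecord],
    window: int = 10_000,
    min_score: float = 200.0,
) -> Set[str]:
    """Genes with a peak of score > ``min_score`` within TSS +/- window."""
    if window <= 0:
        raise ValueError("window must be > 0")
    strong = [pk for pk in peaks if pk.score > min_score]
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for pk in strong:
        by_chrom.setdefault(pk.chrom, []).append(pk)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)
    targets: Set[str] = set()
    for rec in tss_catalog:
        lo = max(0, rec.pos - window)
        hi = rec.pos + window
        for pk in by_chrom.get(rec.chrom, []):
            if pk.start >= hi:
                break
            if pk.end > lo:
                targets.add(rec.gene_id)
                break
    return targets


@dataclass(frozen=True)
class VennStats:
    n_a: int
    n_b: int
    n_intersect: int
    percent_a_in_b: float


def venn_stats(set_a: Iterable[str], set_b: Iterable[str]) -> VennStats:
    """Overlap counts of two gene sets and the percentage of A found in B,
    rounded to one decimal (half away from zero)."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    pct = 0.0 if not a else math.floor(inter / len(a) * 1000.0 + 0.5) / 10.0
    return VennStats(len(a), len(b), inter, pct)


# ---------------------------------------------------------------------------
# single-sample signature scoring
# ---------------------------------------------------------------------------

def _rank_running_sum(expr: np.ndarray, in_set: np.ndarray, weight: float) -> float:
    """Weighted running-sum enrichment for one sample.

    Genes are walked from highest to lowest expression; set genes step the
    hit curve up by their normalized-rank weight ``((N - j) / N) ** weight``
    and other genes step the miss curve by 1/(N - n_set). The score is the
    mean gap between the two cumulative curves.
    """
    n = len(expr)
    order = np.lexsort((np.arange(n), -expr))  # descending, stable
    hits = in_set[order]
    w = ((n - np.arange(n)) / n) ** weight
    hit_w = np.where(hits, w, 0.0)
    hit_total = hit_w.sum()
    miss_step = 1.0 / (n - hits.sum())
    p_hit = np.cumsum(hit_w) / hit_total
    p_miss = np.cumsum(np.where(hits, 0.0, miss_step))
    return float((p_hit - p_miss).mean())


def signature_score(
    expr: pd.DataFrame,
    gene_set: Iterable[str],
    method: str = "rank_ssgsea",
    weight: float = 0.25,
) -> pd.Series:
    """Per-sample enrichment of ``gene_set`` in the expression matrix
    (genes x samples).

    ``rank_ssgsea`` is rank-based and therefore invariant to strictly
    monotone per-sample transforms; ``zmean`` averages per-gene z-scores
    (across samples) over the set.
    """
    genes = set(gene_set)
    present = [g for g in expr.index if g in genes]
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    if method == "rank_ssgsea":
        in_set = expr.index.isin(present).astype(bool)
        if in_set.all():
            raise ValueError("signature covers every gene; enrichment undefined")
        vals = expr.values
        scores = [
            _rank_running_sum(vals[:, j], in_set, weight)
            for j in range(vals.shape[1])
        ]
        return pd.Series(scores, index=expr.columns, name="score")
    if method == "zmean":
        sub = expr.loc[present]
        sd = sub.std(axis=1, ddof=0).replace(0.0, np.nan)
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0).fillna(0.0)
        return z.mean(axis=0).rename("score")
    raise ValueError(f"unknown scoring method {method!r}")


def correlate_profiles(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> Tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)
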