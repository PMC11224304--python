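"""Shuffled-background enrichment of peak catalogs on a query region set.

For each catalog entry (one transcriptional regulator or histone mark) the
observed count of query regions overlapping the entry is compared with the
mean overlap proportion across constrained shuffles of the query within the
universe (the merged TRR set), via a two-sided binomial test with tail
doubling. A query region counts as overlapping when, for some catalog
region, the shared bases reach ``max(1, fraction * length)`` of either the
query or the catalog region (OR rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, shuffle_regions
from .stats import adjust_pvalues, binom_two_sided

#: Continuity constant in the log2 ratio, avoids infinities at zero counts.
LOG2_RATIO_C = 0.5


@dataclass(frozen=True)
class EnrichmentResult:
    catalog_name: str
    n_query: int
    observed: int
    expected_prop: float
    log2_ratio: float
    p: float
    q: float = float("nan")
    degenerate: bool = False  # catalog entirely outside the shuffle universe


class _CatalogIndex:
    """Start-sorted per-chromosome arrays for overlap queries."""

    def __init__(self, regions: Sequence[GenomicInterval]):
        self.by_chrom: Dict[str, tuple] = {}
        tmp: Dict[str, List[GenomicInterval]] = {}
        for iv in regions:
            tmp.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in tmp.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            starts = np.asarray([iv.start for iv in ivs], dtype=np.int64)
            ends = np.asarray([iv.end for iv in ivs], dtype=np.int64)
            self.by_chrom[chrom] = (starts, ends, np.maximum.accumulate(ends))

    def query_overlaps(self, iv: GenomicInterval, fq: float, fc: float) -> bool:
        entry = self.by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, ends, prefix_max_end = entry
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        # walk left-wards; prefix max of ends prunes once nothing can overlap
        req_q = max(1.0, fq * len(iv))
        for j in range(hi - 1, -1, -1):
            if prefix_max_end[j] <= iv.start:
                break
            ov = min(int(ends[j]), iv.end) - max(int(starts[j]), iv.start)
            if ov <= 0:
                continue
            req_c = max(1.0, fc * (int(ends[j]) - int(starts[j])))
            if ov >= req_q or ov >= req_c:
                return True
        return False


def count_overlapping_queries(
    query: Sequence[GenomicInterval],
    catalog_entry: Sequence[GenomicInterval],
    min_frac_query: float = 0.01,
    min_frac_catalog: float = 0.01,
) -> int:
    """Number of query regions overlapping the catalog entry (OR rule)."""
    for f in (min_frac_query, min_frac_catalog):
        if not (0 < f <= 1):
            raise ValueError("overlap fractions must be in (0, 1]")
    index = _CatalogIndex(catalog_entry)
    return sum(
        index.query_overlaps(iv, min_frac_query, min_frac_catalog) for iv in query
    )


def enrichment_test(
    query: Sequence[GenomicInterval],
    catalog: Mapping[str, Sequence[GenomicInterval]],
    universe: Sequence[GenomicInterval],
    n_shuffles: int = 500,
    included_fraction: float = 0.9,
    seed: int = 0,
    min_frac_query: float = 0.01,
    min_frac_catalog: float = 0.01,
    adjust: str = "BY",
) -> pd.DataFrame:
    """Enrichment of every catalog entry on the query region set.

    One set of shuffles is generated and reused for every entry. Returns a
    frame sorted by adjusted p then descending log2 ratio, with columns
    (catalog, n_query, observed, expected_prop, log2_ratio, p, q,
    degenerate).
    """
    if not query:
        raise ValueError("query must be non-empty")
    for name, entry in catalog.items():
        if not len(entry):
            raise ValueError(f"catalog entry {name!r} is empty")
    n_query = len(query)
    shuffles = shuffle_regions(
        query, universe, n_shuffles, included_fraction=included_fraction, seed=seed
    )
    rows = []
    for name in catalog:
        index = _CatalogIndex(catalog[name])
        observed = sum(
            index.query_overlaps(iv, min_frac_query, min_frac_catalog) for iv in query
        )
        shuffle_props = [
            sum(
                index.query_overlaps(iv, min_frac_query, min_frac_catalog)
                for iv in shuf
            )
            / n_query
            for shuf in shuffles
        ]
        p0 = float(np.mean(shuffle_props))
        p = binom_two_sided(observed, n_query, p0)
        log2_ratio = math.log2(
            (observed + LOG2_RATIO_C) / (n_query * p0 + LOG2_RATIO_C)
        )
        rows.append(
            {
                "catalog": name,
                "n_query": n_query,
                "observed": observed,
                "expected_prop": p0,
                "log2_ratio": log2_ratio,
                "p": p,
                "degenerate": p0 == 0.0 and observed == 0,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = adjust_pvalues(df["p"], adjust)
    df = df.sort_values(["q", "log2_ratio"], ascending=[True, False], kind="stable")
    return df.reset_index(drop=True)


def extract_point_values(
    points: pd.DataFrame, regions: Sequence[GenomicInterval]
) -> Dict[str, np.ndarray]:
    """Values of points (columns chrom, pos, value) inside each region.

    Membership is half-open: ``start <= pos < end``. Returns a mapping
    region name -> array of values (possibly empty).
    """
    required = {"chrom", "pos", "value"}
    if not required.issubset(points.columns):
        raise ValueError(f"points frame needs columns {sorted(required)}")
    by_chrom = {
        chrom: grp.sort_values("pos")
        for chrom, grp in points.groupby("chrom", sort=False)
    }
    out: Dict[str, np.ndarray] = {}
    for iv in regions:
        grp = by_chrom.get(iv.chrom)
        if grp is None:
            out[iv.name] = np.array([])
            continue
        pos = grp["pos"].values
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        out[iv.name] = grp["value"].values[lo:hi].astype(float)
    return out
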