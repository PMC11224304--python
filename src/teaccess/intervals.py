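"""Genomic-interval engine: windows, intersection, merging, constrained
shuffling and nearest-distance.

All coordinates are 0-based, half-open (BED convention). GTF-style 1-based
inputs are converted on read by :mod:`teaccess.io`. Strand is ignored for
overlap and distance computations; it only matters when extracting a TSS
from a gene record (gene start on ``+``, gene end on ``-``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

GenomeDict = Dict[str, int]

#: RepeatMasker family -> class lookup for the major TE families analysed.
#: Both TcMar-Tigger and TcMar-Mariner are accepted in the DNA class.
REPEAT_FAMILY_CLASS: Dict[str, str] = {
    "Alu": "SINE",
    "MIR": "SINE",
    "L1": "LINE",
    "L2": "LINE",
    "ERV1": "LTR",
    "ERVL": "LTR",
    "ERVL-MaLR": "LTR",
    "hAT-Charlie": "DNA",
    "TcMar-Tigger": "DNA",
    "TcMar-Mariner": "DNA",
}

DEFAULT_ALLOWED_FAMILIES = frozenset(REPEAT_FAMILY_CLASS)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional metadata."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                f"({self.name!r}): require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r} for {self.name!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TEAnnotation:
    """A RepeatMasker-style transposable-element annotation."""

    interval: GenomicInterval
    repeat_class: str
    repeat_family: str
    sw_score: int

    def __post_init__(self) -> None:
        if self.sw_score < 0:
            raise ValueError(f"sw_score must be >= 0 for {self.interval.name!r}")
        expected = REPEAT_FAMILY_CLASS.get(self.repeat_family)
        if expected is not None and expected != self.repeat_class:
            raise ValueError(
                f"repeat family {self.repeat_family!r} belongs to class "
                f"{expected!r}, not {self.repeat_class!r}"
            )


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site for one gene."""

    gene_id: str
    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative TSS position for {self.gene_id!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be + or - for {self.gene_id!r}")


def validate_genome(genome: GenomeDict) -> None:
    for chrom, length in genome.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def make_trr(
    tss: Sequence[TSSRecord],
    flank: int,
    genome: GenomeDict,
    merge: bool = True,
) -> List[GenomicInterval]:
    """Build transcriptional regulatory regions (TSS +/- ``flank``).

    Each record yields ``[pos - flank, pos + flank)`` clipped to the
    chromosome. With ``merge`` the overlapping/book-ended windows are
    unioned; otherwise per-TSS provenance is retained in the interval name.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    validate_genome(genome)
    out: List[GenomicInterval] = []
    for rec in tss:
        if rec.chrom not in genome:
            raise KeyError(
                f"TSS record {rec.gene_id!r} on unknown chromosome {rec.chrom!r}"
            )
        clen = genome[rec.chrom]
        start = max(0, rec.pos - flank)
        end = min(clen, rec.pos + flank)
        if start >= end:  # TSS at/beyond chromosome end after clipping
            raise ValueError(f"TRR for {rec.gene_id!r} is empty after clipping")
        out.append(GenomicInterval(rec.chrom, start, end, name=rec.gene_id))
    if merge:
        return merge_intervals(out)
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.name))
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Union overlapping and book-ended intervals per chromosome.

    Matches ``bedtools merge`` with the default distance of 0.
    """
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # book-ended intervals merge too
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def _merged_arrays(intervals: Iterable[GenomicInterval]) -> Dict[str, np.ndarray]:
    """chrom -> (2, n) array of merged starts/ends, sorted."""
    out: Dict[str, np.ndarray] = {}
    for iv in merge_intervals(intervals):
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))  # type: ignore
    return {c: np.asarray(v, dtype=np.int64).T for c, v in out.items()}


def overlaps_any(iv: GenomicInterval, arrays: Mapping[str, np.ndarray]) -> bool:
    """True if ``iv`` shares >= 1 base with the merged region arrays."""
    arr = arrays.get(iv.chrom)
    if arr is None:
        return False
    starts, ends = arr
    i = np.searchsorted(starts, iv.end)  # first region starting at/after iv.end
    return i > 0 and ends[i - 1] > iv.start


def intersect_te_trr(
    tes: Sequence[TEAnnotation],
    trrs: Sequence[GenomicInterval],
    min_sw: int = 100,
    allowed_families: frozenset = DEFAULT_ALLOWED_FAMILIES,
) -> List[TEAnnotation]:
    """TEs passing the alignment-score/family filters that touch a TRR.

    Keeps TEs with ``sw_score > min_sw``, family in ``allowed_families`` and
    at least one base of overlap with some TRR (any-overlap rule).
    """
    if not allowed_families:
        raise ValueError("allowed_families must be non-empty")
    arrays = _merged_arrays(trrs)
    kept = [
        te
        for te in tes
        if te.sw_score > min_sw
        and te.repeat_family in allowed_families
        and overlaps_any(te.interval, arrays)
    ]
    kept.sort(key=lambda te: (te.interval.chrom, te.interval.start, te.interval.name))
    return kept


def nearest_distance(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Edge-to-edge distance from every ``a`` interval to the nearest ``b``.

    Distance is 0 on overlap, NaN when the chromosome has no ``b`` interval.
    Returns a frame with columns ``name`` and ``distance`` in ``a`` order.
    """
    if not b:
        raise ValueError("b must be non-empty")
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    indexed: Dict[str, tuple] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        starts = np.asarray([iv.start for iv in ivs], dtype=np.int64)
        ends = np.asarray([iv.end for iv in ivs], dtype=np.int64)
        prefix_max_end = np.maximum.accumulate(ends)
        indexed[chrom] = (starts, prefix_max_end)
    names, dists = [], []
    for iv in a:
        names.append(iv.name)
        idx = indexed.get(iv.chrom)
        if idx is None:
            dists.append(np.nan)
            continue
        starts, prefix_max_end = idx
        i = np.searchsorted(starts, iv.end)  # b[i:] start at/after iv.end
        best = math.inf
        if i > 0:
            left_end = prefix_max_end[i - 1]
            if left_end > iv.start:
                best = 0  # overlap
            else:
                best = iv.start - int(left_end)
        if best > 0 and i < len(starts):
            best = min(best, int(starts[i]) - iv.end)
        dists.append(float(best))
    return pd.DataFrame({"name": names, "distance": dists})


# ---------------------------------------------------------------------------
# constrained shuffling
# ---------------------------------------------------------------------------

def _feasible_bounds(
    length: int,
    req: int,
    seg_start: np.ndarray,
    seg_end: np.ndarray,
    seg_chrom_len: Optional[np.ndarray],
) -> tuple:
    """Per-segment inclusive [lo, hi] start bounds for a region of ``length``
    required to keep >= ``req`` bases inside the segment."""
    lo = seg_start - (length - req)
    hi = seg_end - req
    lo = np.maximum(lo, 0)
    if seg_chrom_len is not None:
        hi = np.minimum(hi, seg_chrom_len - length)
    counts = np.maximum(hi - lo + 1, 0)
    return lo, hi, counts


def shuffle_regions(
    query: Sequence[GenomicInterval],
    universe: Sequence[GenomicInterval],
    n_shuffles: int,
    included_fraction: float = 0.9,
    seed: int = 0,
    genome: Optional[GenomeDict] = None,
) -> List[List[GenomicInterval]]:
    """Relocate each query region uniformly within the universe.

    Every shuffle preserves the multiset of query lengths. Each placed
    region keeps at least ``included_fraction`` of its bases inside a single
    universe segment; placement is uniform over all feasible start positions
    (segments weighted by their feasible-position count), so regions may
    move between chromosomes. Identical seed gives identical output.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not (0 < included_fraction <= 1):
        raise ValueError("included_fraction must be in (0, 1]")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    segs = merge_intervals(universe)
    seg_chrom = [s.chrom for s in segs]
    seg_start = np.asarray([s.start for s in segs], dtype=np.int64)
    seg_end = np.asarray([s.end for s in segs], dtype=np.int64)
    seg_clen = None
    if genome is not None:
        validate_genome(genome)
        seg_clen = np.asarray([genome[c] for c in seg_chrom], dtype=np.int64)

    rng = np.random.default_rng(seed)
    shuffles: List[List[Optional[GenomicInterval]]] = [
        [None] * len(query) for _ in range(n_shuffles)
    ]
    for qi, iv in enumerate(query):
        length = len(iv)
        req = math.ceil(included_fraction * length)
        lo, hi, counts = _feasible_bounds(length, req, seg_start, seg_end, seg_clen)
        total = int(counts.sum())
        if total == 0:
            raise ValueError(
                f"query region {iv.name!r} ({iv.chrom}:{iv.start}-{iv.end}) "
                f"cannot be placed within the universe at "
                f"included_fraction={included_fraction}"
            )
        seg_idx = rng.choice(len(segs), size=n_shuffles, p=counts / total)
        offs = rng.random(n_shuffles)
        for si in range(n_shuffles):
            k = int(seg_idx[si])
            start = int(lo[k] + math.floor(offs[si] * counts[k]))
            shuffles[si][qi] = GenomicInterval(
                seg_chrom[k], start, start + length, name=iv.name, score=iv.score
            )
    return [list(s) for s in shuffles]  # type: ignore[arg-type]


def total_bases(intervals: Iterable[GenomicInterval]) -> int:
    """Number of distinct bases covered (after merging)."""
    return sum(len(iv) for iv in merge_intervals(intervals))
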