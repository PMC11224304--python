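"""Readers and writers for the plain-text dialects the pipeline exchanges.

Formats: chrom.sizes, BED6, an "rmsk-bed" dialect (BED6 + repeat class,
family columns; the BED score column carries the Smith-Waterman score),
GTF-lite gene records, 4-column bedGraph, TSV matrices, gene-set lists and
clinical tables. All writers emit sorted, tab-separated, newline-terminated
files; lines starting with ``#`` or ``track`` are skipped on read.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import (
    GenomeDict,
    GenomicInterval,
    REPEAT_FAMILY_CLASS,
    TEAnnotation,
    TSSRecord,
)

#: chrom -> (starts, ends, values) sorted non-overlapping runs.
SignalTrack = Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]


def _data_lines(path) -> List[List[str]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("track"):
            continue
        rows.append(line.rstrip("\n").split("\t"))
    return rows


# -- chrom.sizes -------------------------------------------------------------

def read_chrom_sizes(path) -> GenomeDict:
    genome: GenomeDict = {}
    for row in _data_lines(path):
        genome[row[0]] = int(row[1])
    return genome


def write_chrom_sizes(genome: GenomeDict, path) -> None:
    lines = [f"{c}\t{genome[c]}\n" for c in sorted(genome)]
    Path(path).write_text("".join(lines))


# -- BED6 --------------------------------------------------------------------

def read_bed(path) -> List[GenomicInterval]:
    out = []
    for row in _data_lines(path):
        name = row[3] if len(row) > 3 else "."
        score = float(row[4]) if len(row) > 4 else 0.0
        strand = row[5] if len(row) > 5 else "."
        out.append(GenomicInterval(row[0], int(row[1]), int(row[2]), name, score, strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.name))
    with open(path, "w") as fh:
        for iv in ivs:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


# -- rmsk-bed (BED6 + repeat_class + repeat_family) --------------------------

def read_rmsk_bed(path) -> List[TEAnnotation]:
    out = []
    for row in _data_lines(path):
        iv = GenomicInterval(row[0], int(row[1]), int(row[2]), row[3],
                             float(row[4]), row[5])
        out.append(
            TEAnnotation(iv, repeat_class=row[6], repeat_family=row[7],
                         sw_score=int(float(row[4])))
        )
    return out


def write_rmsk_bed(tes: Sequence[TEAnnotation], path) -> None:
    tes = sorted(tes, key=lambda t: (t.interval.chrom, t.interval.start, t.interval.name))
    with open(path, "w") as fh:
        for te in tes:
            iv = te.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{te.sw_score}\t"
                f"{iv.strand}\t{te.repeat_class}\t{te.repeat_family}\n"
            )


# -- GTF-lite ----------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def read_gtf_genes(path) -> List[TSSRecord]:
    """Read ``feature == gene`` records and extract strand-aware TSS.

    GTF coordinates are 1-based inclusive; the TSS is the gene start on the
    ``+`` strand and the gene end on the ``-`` strand, converted to 0-based.
    """
    out = []
    for row in _data_lines(path):
        if row[2] != "gene":
            continue
        m = _GENE_ID_RE.search(row[8])
        if m is None:
            raise ValueError(f"GTF record without gene_id attribute: {row}")
        start1, end1, strand = int(row[3]), int(row[4]), row[6]
        pos = start1 - 1 if strand == "+" else end1 - 1
        out.append(TSSRecord(m.group(1), row[0], pos, strand))
    return out


def write_gtf_genes(
    genes: Sequence[Tuple[str, str, int, int, str]], path, source: str = "teaccess"
) -> None:
    """Write (gene_id, chrom, start0, end0, strand) tuples as GTF gene rows."""
    rows = sorted(genes, key=lambda g: (g[1], g[2], g[0]))
    with open(path, "w") as fh:
        for gene_id, chrom, start0, end0, strand in rows:
            fh.write(
                f"{chrom}\t{source}\tgene\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t"
                f'gene_id "{gene_id}";\n'
            )


# -- bedGraph ----------------------------------------------------------------

def read_bedgraph(path) -> SignalTrack:
    by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
    for row in _data_lines(path):
        by_chrom.setdefault(row[0], []).append((int(row[1]), int(row[2]), float(row[3])))
    track: SignalTrack = {}
    for chrom, runs in by_chrom.items():
        runs.sort()
        arr = np.asarray(runs, dtype=float)
        track[chrom] = (
            arr[:, 0].astype(np.int64),
            arr[:, 1].astype(np.int64),
            arr[:, 2],
        )
    return track


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track):
            starts, ends, values = track[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:g}\n")


# -- tables ------------------------------------------------------------------

def read_tsv_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_tsv_matrix(df: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t")


def read_sample_groups(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], comment="#")
    return df.set_index("sample")["group"]


def write_sample_groups(groups: pd.Series, path) -> None:
    groups.rename_axis("sample").to_frame("group").to_csv(
        path, sep="\t", header=False
    )


def read_gene_set(path) -> List[str]:
    return [r[0] for r in _data_lines(path)]


def write_gene_set(genes: Sequence[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_clinical(path) -> pd.DataFrame:
    """Clinical TSV: sample, time, event[, score]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"clinical table must have columns {sorted(required)}")
    return df


def write_clinical(df: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)
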