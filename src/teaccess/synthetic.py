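"""Seeded generator for a complete toy cohort study: genome, TE catalog,
multi-tissue accessibility tracks, peak catalogs, motif occurrences,
expression and survival — with the statistical structure the analysis
pipeline assumes.

The generator emulates a pan-tissue chromatin-accessibility atlas: a
planted subset of TEs inside transcriptional regulatory regions is more
accessible in one tissue group (multiplicative shift), a repressor-factor
peak catalog preferentially hits the planted TEs, motifs cluster near
them, the expression of planted-TE-associated genes tracks a per-sample
latent activity that also drives survival, and the repressor's own
expression runs opposite to it. The emitted files use exactly the dialects
the pipeline readers consume, and a JSON manifest records the ground
truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from . import io as tio
from .intervals import (
    GenomicInterval,
    REPEAT_FAMILY_CLASS,
    TEAnnotation,
    TSSRecord,
    make_trr,
    merge_intervals,
    overlaps_any,
    _merged_arrays,
)
from .gene_link import assign_te_genes

#: family -> (mixture weight, typical length in bp)
FAMILY_MIX: Dict[str, Tuple[float, int]] = {
    "Alu": (0.30, 300),
    "MIR": (0.20, 200),
    "L1": (0.15, 600),
    "L2": (0.10, 250),
    "ERV1": (0.05, 400),
    "ERVL": (0.05, 400),
    "ERVL-MaLR": (0.05, 350),
    "hAT-Charlie": (0.05, 300),
    "TcMar-Tigger": (0.05, 250),
}


@dataclass
class SimConfig:
    """Parameter bundle for one synthetic study; fully determined by seed."""

    seed: int = 1
    n_chroms: int = 3
    chrom_length: int = 2_000_000
    n_genes: int = 200
    n_tes: int = 2_000
    sw_mean: float = 300.0
    sw_frac_below_100: float = 0.10
    group_labels: Tuple[str, ...] = (
        "liver", "lung", "breast", "colon", "kidney", "brain"
    )
    samples_per_group: int = 8
    target_group: str = "liver"
    n_planted: int = 50
    access_effect: float = 8.0  # multiplicative signal shift, planted x target
    baseline_log_mean: float = math.log(10.0)
    baseline_sigma: float = 0.5
    noise_sigma: float = 0.5
    trr_flank: int = 10_000
    peak_factors: Tuple[str, ...] = (
        "KDM1A", "HNF4A", "ZMYM3", "H3K4me1", "H3K27ac", "CTCF"
    )
    planted_factor: str = "KDM1A"
    peak_hit_rate: float = 0.7
    peak_background_rate: float = 0.05
    peak_width: int = 400
    peak_jitter: int = 100
    motif_name: str = "ZMYM3"
    motif_offset_mean: float = 300.0  # geometric-tailed distance from a planted TE
    motif_width: int = 10
    n_background_motifs: int = 200
    n_cohort: int = 300
    expr_effect: float = 1.5  # log2-expression shift per unit latent score
    repressor_effect: float = 1.0
    expr_noise_sigma: float = 1.0
    hazard_beta: float = -0.8  # log-hazard of the high-score stratum
    cutpoint_quantile: float = 0.4  # planted survival threshold on the latent score
    baseline_hazard: float = 1.0 / 36.0  # events per month
    censor_rate: float = 0.3

    def validate(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_genes", "n_tes",
                     "samples_per_group", "n_cohort", "motif_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sw_frac_below_100", "peak_hit_rate",
                     "peak_background_rate", "censor_rate", "cutpoint_quantile"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_planted < 0 or self.n_planted > self.n_tes:
            raise ValueError("n_planted must lie in [0, n_tes]")
        if self.target_group not in self.group_labels:
            raise ValueError("target_group must be one of group_labels")


@dataclass
class StudyBundle:
    """In-memory counterpart of the emitted file bundle."""

    config: SimConfig
    genome: Dict[str, int]
    genes: List[Tuple[str, str, int, int, str]]  # gene_id, chrom, start0, end0, strand
    tss: List[TSSRecord]
    tes: List[TEAnnotation]
    tracks: Dict[str, tio.SignalTrack]
    groups: pd.Series
    peak_catalog: Dict[str, List[GenomicInterval]]
    motifs: List[GenomicInterval]
    expression: pd.DataFrame
    clinical: pd.DataFrame
    manifest: dict


def _gamma_shape_for_sw(mean: float, frac_below_100: float) -> Tuple[float, float]:
    """Gamma(shape, scale) with the given mean and P(X < 100)."""

    def objective(a: float) -> float:
        return sps.gamma.cdf(100.0, a, scale=mean / a) - frac_below_100

    shape = optimize.brentq(objective, 0.05, 80.0, xtol=1e-10)
    return shape, mean / shape


def _place_non_overlapping(
    rng: np.random.Generator,
    genome: Dict[str, int],
    lengths: np.ndarray,
    chroms: List[str],
) -> List[Tuple[str, int, int]]:
    """Greedy rejection sampling of non-overlapping intervals."""
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in genome}
    placed: List[Tuple[str, int, int]] = []
    for length, chrom in zip(lengths, chroms):
        clen = genome[chrom]
        for _ in range(200):
            start = int(rng.integers(0, clen - length))
            end = start + int(length)
            occ = occupied[chrom]
            i = bisect_left(occ, (start, end))
            if (i > 0 and occ[i - 1][1] > start) or (i < len(occ) and occ[i][0] < end):
                continue
            insort(occ, (start, end))
            placed.append((chrom, start, end))
            break
        else:
            raise ValueError(
                "could not place all TEs without overlap; genome too crowded"
            )
    return placed


def simulate_study(config: SimConfig, outdir: Optional[Path] = None) -> StudyBundle:
    """Generate the full study; optionally write the file bundle.

    Identical seed (and config) gives a byte-identical bundle.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    chrom_names = sorted(genome)

    # -- genes ---------------------------------------------------------------
    genes: List[Tuple[str, str, int, int, str]] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    gid = 0
    for ci, chrom in enumerate(chrom_names):
        n_c = per_chrom[ci]
        for k in range(n_c):
            gid += 1
            centre = int((k + 0.5) * config.chrom_length / n_c)
            tss_pos = int(
                np.clip(centre + rng.integers(-5_000, 5_001), 1,
                        config.chrom_length - 2)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            body = int(rng.integers(5_000, 20_001))
            if strand == "+":
                start0 = tss_pos
                end0 = min(config.chrom_length, tss_pos + body)
            else:
                end0 = tss_pos + 1
                start0 = max(0, end0 - body)
            genes.append((f"G{gid:04d}", chrom, start0, end0, strand))
    tss = [
        TSSRecord(g, c, s if st == "+" else e - 1, st) for g, c, s, e, st in genes
    ]
    trr_universe = make_trr(tss, config.trr_flank, genome, merge=True)
    trr_arrays = _merged_arrays(trr_universe)

    # -- TE catalog ----------------------------------------------------------
    fam_names = list(FAMILY_MIX)
    fam_w = np.array([FAMILY_MIX[f][0] for f in fam_names])
    fam_idx = rng.choice(len(fam_names), size=config.n_tes, p=fam_w / fam_w.sum())
    lengths = np.array(
        [
            int(np.clip(rng.lognormal(math.log(FAMILY_MIX[fam_names[i]][1]), 0.3),
                        80, 2_000))
            for i in fam_idx
        ]
    )
    te_chroms = [chrom_names[i] for i in rng.integers(0, config.n_chroms,
                                                      size=config.n_tes)]
    positions = _place_non_overlapping(rng, genome, lengths, te_chroms)
    shape, scale = _gamma_shape_for_sw(config.sw_mean, config.sw_frac_below_100)
    sw = rng.gamma(shape, scale, size=config.n_tes)

    tes: List[TEAnnotation] = []
    for i, (chrom, start, end) in enumerate(positions):
        fam = fam_names[fam_idx[i]]
        iv = GenomicInterval(chrom, start, end, name=f"TE{i + 1:05d}",
                             strand="+" if rng.random() < 0.5 else "-")
        tes.append(TEAnnotation(iv, REPEAT_FAMILY_CLASS[fam], fam, int(sw[i])))

    # planted TEs: inside the TRR universe, guaranteed past the SW filter
    in_trr = [i for i, te in enumerate(tes) if overlaps_any(te.interval, trr_arrays)]
    if len(in_trr) < config.n_planted:
        raise ValueError("not enough TEs inside TRRs to plant the target subset")
    planted_idx = sorted(rng.choice(in_trr, size=config.n_planted, replace=False))
    f100 = sps.gamma.cdf(100.0, shape, scale=scale)
    for i in planted_idx:
        u = f100 + rng.random() * (1.0 - f100)
        sw_i = int(sps.gamma.ppf(u, shape, scale=scale))
        tes[i] = dataclasses.replace(tes[i], sw_score=max(101, sw_i))
    planted_ids = [tes[i].interval.name for i in planted_idx]
    planted_set = set(planted_ids)

    # -- accessibility tracks ------------------------------------------------
    samples = [
        f"{g}_{k + 1}" for g in config.group_labels
        for k in range(config.samples_per_group)
    ]
    groups = pd.Series(
        [s.rsplit("_", 1)[0] for s in samples], index=samples, name="group"
    )
    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_sigma, config.n_tes)
    )
    noise = np.exp(
        rng.normal(0.0, config.noise_sigma, size=(config.n_tes, len(samples)))
    )
    values = baseline[:, None] * noise
    is_planted = np.array([te.interval.name in planted_set for te in tes])
    is_target = (groups.values == config.target_group)
    values[np.ix_(is_planted, is_target)] *= config.access_effect

    tracks: Dict[str, tio.SignalTrack] = {}
    order = np.lexsort(
        ([te.interval.start for te in tes], [te.interval.chrom for te in tes])
    )
    for j, sample in enumerate(samples):
        track: tio.SignalTrack = {}
        for chrom in chrom_names:
            idx = [i for i in order if tes[i].interval.chrom == chrom]
            track[chrom] = (
                np.array([tes[i].interval.start for i in idx], dtype=np.int64),
                np.array([tes[i].interval.end for i in idx], dtype=np.int64),
                np.round(values[idx, j], 4),
            )
        tracks[sample] = track

    # -- peak catalogs -------------------------------------------------------
    peak_catalog: Dict[str, List[GenomicInterval]] = {}
    half = config.peak_width // 2
    for factor in config.peak_factors:
        peaks: List[GenomicInterval] = []
        for i, te in enumerate(tes):
            hit = rng.random() < config.peak_background_rate
            strong = False
            if factor == config.planted_factor and is_planted[i]:
                strong = rng.random() < config.peak_hit_rate
            if not (hit or strong):
                continue
            centre = (te.interval.start + te.interval.end) // 2 + int(
                rng.integers(-config.peak_jitter, config.peak_jitter + 1)
            )
            start = int(np.clip(centre - half, 0, genome[te.interval.chrom] - 1))
            end = int(min(genome[te.interval.chrom], start + config.peak_width))
            mean_score = 400.0 if strong else 150.0
            score = float(np.round(rng.lognormal(math.log(mean_score), 0.3), 2))
            peaks.append(
                GenomicInterval(te.interval.chrom, start, end,
                                name=f"{factor}_pk{len(peaks) + 1:04d}", score=score)
            )
        peak_catalog[factor] = peaks

    # -- motif occurrences ---------------------------------------------------
    motifs: List[GenomicInterval] = []
    for i in planted_idx:
        te = tes[i]
        offset = int(rng.geometric(1.0 / config.motif_offset_mean))
        if rng.random() < 0.5:
            start = te.interval.end + offset
        else:
            start = te.interval.start - offset - config.motif_width
        start = int(np.clip(start, 0, genome[te.interval.chrom] - config.motif_width))
        motifs.append(
            GenomicInterval(te.interval.chrom, start, start + config.motif_width,
                            name=config.motif_name)
        )
    for _ in range(config.n_background_motifs):
        chrom = chrom_names[int(rng.integers(0, config.n_chroms))]
        start = int(rng.integers(0, genome[chrom] - config.motif_width))
        motifs.append(
            GenomicInterval(chrom, start, start + config.motif_width,
                            name=config.motif_name)
        )

    # -- expression & survival cohort ---------------------------------------
    planted_tes = [tes[i] for i in planted_idx]
    sig_table = assign_te_genes(planted_tes, tss, window=config.trr_flank)
    signature_genes = sorted(sig_table.index[sig_table["is_te_associated"]])

    cohort = [f"T{k + 1:03d}" for k in range(config.n_cohort)]
    latent = rng.normal(0.0, 1.0, config.n_cohort)
    gene_ids = [g[0] for g in genes]
    base = rng.normal(6.0, 1.0, len(gene_ids))
    sig_mask = np.array([g in set(signature_genes) for g in gene_ids])
    log2x = (
        base[:, None]
        + np.where(sig_mask[:, None], config.expr_effect, 0.0) * latent[None, :]
        + rng.normal(0.0, config.expr_noise_sigma, (len(gene_ids), config.n_cohort))
    )
    expr = pd.DataFrame(
        np.round(2.0**log2x, 4), index=gene_ids, columns=cohort
    )
    repressor = config.planted_factor
    rep_log2 = (
        6.0 - config.repressor_effect * latent
        + rng.normal(0.0, 0.5, config.n_cohort)
    )
    expr.loc[repressor] = np.round(2.0**rep_log2, 4)

    thr = float(np.quantile(latent, config.cutpoint_quantile))
    high = latent > thr
    rate = config.baseline_hazard * np.exp(config.hazard_beta * high)
    t_event = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        c_rate = config.baseline_hazard * config.censor_rate / (1 - config.censor_rate)
        t_censor = rng.exponential(1.0 / c_rate, config.n_cohort)
    else:
        t_censor = np.full(config.n_cohort, np.inf)
    time = np.round(np.minimum(t_event, t_censor), 3)
    event = (t_event <= t_censor).astype(int)
    clinical = pd.DataFrame({"sample": cohort, "time": time, "event": event})

    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "planted_te_ids": planted_ids,
        "signature_genes": signature_genes,
        "planted_factor": config.planted_factor,
        "true_cutpoint_quantile": config.cutpoint_quantile,
        "true_latent_threshold": thr,
        "n_events": int(event.sum()),
    }

    bundle = StudyBundle(
        config=config, genome=genome, genes=genes, tss=tss, tes=tes,
        tracks=tracks, groups=groups, peak_catalog=peak_catalog, motifs=motifs,
        expression=expr, clinical=clinical, manifest=manifest,
    )
    if outdir is not None:
        write_bundle(bundle, Path(outdir))
    return bundle


def write_bundle(bundle: StudyBundle, outdir: Path) -> None:
    outdir = Path(outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    tio.write_chrom_sizes(bundle.genome, outdir / "chrom.sizes")
    tio.write_rmsk_bed(bundle.tes, outdir / "tes.rmsk.bed")
    tio.write_gtf_genes(bundle.genes, outdir / "genes.gtf")
    tio.write_sample_groups(bundle.groups, outdir / "groups.tsv")
    for sample, track in bundle.tracks.items():
        tio.write_bedgraph(track, outdir / "tracks" / f"{sample}.bedgraph")
    for factor, peaks in bundle.peak_catalog.items():
        tio.write_bed(peaks, outdir / "peaks" / f"{factor}.bed")
    tio.write_bed(bundle.motifs, outdir / "motifs.bed")
    tio.write_tsv_matrix(bundle.expression, outdir / "expression.tsv")
    tio.write_clinical(bundle.clinical, outdir / "clinical.tsv")
    (outdir / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n"
    )


def truth_report(
    manifest: dict,
    called_te_ids: Sequence[str],
    enrichment: Optional[pd.DataFrame] = None,
    cutpoint: Optional[float] = None,
    scores: Optional[pd.Series] = None,
    run_seed: Optional[int] = None,
) -> dict:
    """Compare pipeline outputs with the generator's ground truth.

    Reports planted-TE precision/recall, the enrichment rank of the planted
    factor, and the maxstat cutpoint error in percentile units. Precision is
    reported as None (missing) when nothing was called.
    """
    if run_seed is not None and run_seed != manifest["seed"]:
        raise ValueError(
            f"manifest seed {manifest['seed']} does not match run seed {run_seed}"
        )
    planted = set(manifest["planted_te_ids"])
    called = set(called_te_ids)
    tp = len(called & planted)
    report: dict = {
        "n_called": len(called),
        "n_planted": len(planted),
        "precision": (tp / len(called)) if called else None,
        "recall": (tp / len(planted)) if planted else None,
    }
    if enrichment is not None:
        ranks = {name: r + 1 for r, name in enumerate(enrichment["catalog"])}
        factor = manifest["planted_factor"]
        report["planted_factor_rank"] = ranks.get(factor)
        row = enrichment[enrichment["catalog"] == factor]
        report["planted_factor_log2_ratio"] = (
            float(row["log2_ratio"].iloc[0]) if len(row) else None
        )
    if cutpoint is not None and scores is not None:
        pct = float(np.mean(scores.values <= cutpoint))
        report["cutpoint_percentile"] = 100.0 * pct
        report["cutpoint_percentile_error"] = abs(
            100.0 * pct - 100.0 * manifest["true_cutpoint_quantile"]
        )
    return report
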