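# teaccess

Tissue-specific accessible transposable elements (TEs) in transcriptional
regulatory regions: discovery, enrichment, gene linkage and prognosis.

Transposable elements can persist as cis-regulatory elements that recruit
transcription factors and chromatin modifiers. `teaccess` is a tested,
reusable implementation of the computational chain used to study such
elements in a tissue-of-interest (the motivating case is liver and
hepatocellular carcinoma): it

1. defines **transcriptional regulatory regions** (TRR = TSS ± 10 kb) and
   restricts RepeatMasker TEs (major SINE/LINE/LTR/DNA families,
   Smith–Waterman score > 100) to those regions;
2. builds a TE × sample accessibility matrix from coverage tracks and
   calls **tissue-specific accessible TEs** by the consensus of two tests:
   a conserved-marker procedure (one-sided rank-sum of the target group
   against every other group, combined by the maximum p, with the minimum
   per-group log2 fold change) and an empirical-Bayes **moderated linear
   model** (residual variances shrunk toward a scaled inverse-chi-square
   prior fitted via digamma/trigamma moments; moderated t with d + d0 df;
   log-odds B statistic);
3. quantifies **regulator and histone-mark enrichment** on the called TEs
   against constrained shuffles of the query within the TRR universe
   (lengths preserved, ≥ 90% inclusion), with a two-sided binomial test,
   `log2((k + ½)/(n·p0 + ½))` effect sizes and BY/BH adjustment;
4. links TEs to genes (≥ 1 TE within 10 kb of the TSS), calls factor
   **target genes** (peak score > 200 within ± 10 kb of the TSS), computes
   the overlap statistics, and scores cohort samples against the TE gene
   signature with a single-sample rank enrichment (ssGSEA-style) or
   z-mean score;
5. evaluates prognosis with Kaplan–Meier curves, log-rank tests and a
   **maximally selected rank-statistic cutpoint** (the split of a
   continuous score maximizing |(O − E)/√V|, with the naive p flagged as
   selection-biased and an optional seeded permutation p);
6. compares TE–motif distance distributions against shuffled TEs and
   peak scores between regulatory regions with and without called TEs.

A seeded synthetic-study generator (`teaccess.synthetic`) produces a
complete toy cohort — genome, TE catalog, gene annotation, multi-tissue
bedGraph tracks, peak catalogs, motifs, expression and survival — with
planted ground truth, so the whole chain runs and is validated at desk
scale. See `docs/methods.md` for the model details and assumptions.

## Worked example

```sh
teaccess simulate --seed 1 --outdir scratch/sim
python analysis/01_simulate.py      # same study, plus a summary table
python analysis/02_run_pipeline.py
python analysis/03_enrichment.py
```

The default study has 2,000 TEs across a 6 Mb genome, 6 tissue groups × 8
accessibility tracks, and 50 planted liver-specific TEs. The drivers print
(numbers from the run at seed 1):

```
n_trr_tes: 1221           # TEs in TRRs passing family/SW filters
n_specific_tes: 49        # dual-test consensus calls
precision_vs_planted: 1.0
recall_vs_planted: 0.98
top factor: KDM1A (log2 ratio 4.80, q = 2.81e-46)
```

i.e. the consensus caller recovers 49/50 planted TEs with no false
positives, and the planted repressor catalog ranks first by adjusted
enrichment q. Downstream drivers report the gene-set overlap
(41 TE-associated genes, 28 of them repressor targets, 68.3%), the
signature-vs-repressor expression correlation (r = −0.713), the survival
split (naive log-rank p = 1.8e-07 at a cutpoint 3 percentile points from
the planted threshold) and the motif proximity contrast (median 236 bp
real vs 5,059 bp shuffled, p = 5.5e-15).

The same pipeline runs on real data from the shell: point a YAML config
(`RunConfig` fields: input paths plus every threshold) at your own
chrom.sizes, rmsk-style TE BED, GTF genes, bedGraph tracks, peak BEDs,
motif BED, expression TSV and clinical TSV, then

```sh
teaccess all --config config.yaml --outdir results/run --seed 1
```

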