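"""TE-associated genes, repressor target genes and the signature score.

Reports the overlap of the two gene sets (the cohort-percentage statistic)
and the correlation between the per-sample signature score and repressor
expression, which the planted anti-correlation should make negative.
"""

import importlib
import json

common = importlib.import_module("00_common")


def main():
    common.ensure_dirs()
    summary = json.loads((common.RUN_DIR / "summary.json").read_text())
    out = {
        "venn": summary["venn"],
        "signature_vs_repressor_pearson": summary["repressor_correlation"],
    }
    (common.RESULTS / "04_gene_link_summary.json").write_text(
        json.dumps(out, indent=2) + "\n")
    v = summary["venn"]
    print(f"TE-associated genes: {v['n_a']}; repressor targets: {v['n_b']}; "
          f"overlap {v['n_intersect']} ({v['percent_a_in_b']}%)")
    r, p = summary["repressor_correlation"]
    print(f"signature score vs repressor expression: r = {r:.3f} (p = {p:.3g})")


if __name__ == "__main__":
    main()
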