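"""Motif proximity and co-occupancy around the called TEs.

Distances from called TEs to motif occurrences versus a length-matched
shuffled TE set, the with/without-TE peak-score comparison in regulatory
regions, and the pairwise factor co-occupancy (Spearman) matrix.
"""

import importlib
import json

import pandas as pd

common = importlib.import_module("00_common")


def main():
    common.ensure_dirs()
    summary = json.loads((common.RUN_DIR / "summary.json").read_text())
    cooc = pd.read_csv(common.RUN_DIR / "cooccupancy.tsv", sep="\t",
                       comment="#", index_col=0)
    cooc.to_csv(common.RESULTS / "06_cooccupancy.tsv", sep="\t")
    out = {
        "distance": summary["distance"],
        "score_comparison": summary["score_comparison"],
    }
    (common.RESULTS / "06_proximity_summary.json").write_text(
        json.dumps(out, indent=2) + "\n")
    d = summary["distance"]
    print(f"median TE-motif distance: real {d['median_real']:.0f} bp vs "
          f"shuffled {d['median_shuffled']:.0f} bp (p = {d['p']:.3g})")
    s = summary["score_comparison"]
    print(f"repressor peak score, TRRs with vs without specific TEs: "
          f"median {s['median_with_te']:.0f} vs {s['median_without_te']:.0f} "
          f"(p = {s['p']:.3g})")
    print("co-occupancy (Spearman):")
    print(cooc.round(2).to_string())


if __name__ == "__main__":
    main()
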