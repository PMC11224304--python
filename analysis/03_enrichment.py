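"""Regulator/histone-mark enrichment on the called tissue-specific TEs.

Reads the persisted enrichment table (500 constrained shuffles within the
TRR universe, two-sided binomial test, BY adjustment) and reports the
ranked factors; the planted repressor should top the list.
"""

import importlib

import pandas as pd

common = importlib.import_module("00_common")


def main():
    common.ensure_dirs()
    enr = pd.read_csv(common.RUN_DIR / "enrichment.tsv", sep="\t", comment="#")
    enr.to_csv(common.RESULTS / "03_enrichment.tsv", sep="\t", index=False)
    print(enr.to_string(index=False))
    top = enr.iloc[0]
    print(f"\ntop factor: {top['catalog']} "
          f"(log2 ratio {top['log2_ratio']:.2f}, q = {top['q']:.3g})")


if __name__ == "__main__":
    main()
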