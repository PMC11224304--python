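"""Shared paths and helpers for the analysis drivers.

Bulky intermediates (the simulated file bundle, full per-element tables)
live under scratch/; the small summary tables each driver reports go to
results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
SIM_DIR = SCRATCH / "sim"
RUN_DIR = SCRATCH / "run"
RESULTS = ROOT / "results"

SEED = 1


def ensure_dirs():
    for d in (SCRATCH, RESULTS):
        d.mkdir(parents=True, exist_ok=True)


def run_config():
    from teaccess.pipeline import config_for_bundle_dir

    if not SIM_DIR.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    return config_for_bundle_dir(SIM_DIR, seed=SEED)


def load_manifest():
    import json

    return json.loads((SIM_DIR / "manifest.json").read_text())
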