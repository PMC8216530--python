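"""Shared paths and study configuration for the numbered analysis scripts.

Scripts run in order from the repository root (``python analysis/01_...``);
bulky intermediates live under scratch/, summary tables under results/.
"""
from pathlib import Path

from sulakit.config import default_config

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 42
#: Deployment design scaled to ~1/3 of the field effort: enough birds per
#: group for UD overlap and repeatability while keeping a laptop-scale run.
CONFIG = default_config(seed=SEED, scale=0.35)

for p in (SCRATCH, RESULTS):
    p.mkdir(parents=True, exist_ok=True)
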