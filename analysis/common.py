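"""Shared run configuration for the numbered analysis scripts.

All scripts operate on one pipeline run directory (large intermediates,
kept out of version control) and publish small summary tables under
``results/``.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from retrotrace.workflow import PipelineConfig

REPO = Path(__file__).resolve().parent.parent
RUN_DIR = REPO / "scratch" / "analysis_run"
RESULTS = REPO / "results"


def get_config(seed: int | None = None) -> PipelineConfig:
    cfg = PipelineConfig(outdir=str(RUN_DIR))
    if seed is not None:
        cfg.seed = seed
    RESULTS.mkdir(exist_ok=True)
    return cfg


def parse_seed(description: str) -> int:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    return parser.parse_args().seed
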