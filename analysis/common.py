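"""Shared run configuration for the numbered analysis scripts.

Every script rebuilds the simulated inputs deterministically from this one
config, so the stages can be run independently and still agree.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from lakephotochem.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def default_config(seed: int = 1) -> RunConfig:
    """The study-scale run: 37 lakes, 30 years monthly, three bands."""
    return RunConfig(seed=seed, n_lakes=37, months=360, n_surrogates=199)


def parse_args(description: str) -> argparse.Namespace:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--outdir", type=Path, default=RESULTS)
    return p.parse_args()
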