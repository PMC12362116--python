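"""Shared plumbing for the numbered analysis scripts.

The demonstration cohort is the package's realistic default: 26
participants, visits at baseline / month 3 / every 6 months with monotone
dropout, full-resolution 768x768 lesion rasters, and device-like
integer-dB measurements censored to [0, 20].  Seed 7 everywhere, so every
script regenerates identical data.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from perilesion.lesions import annotate_dataset
from perilesion.simulate import SimulationConfig, simulate_cohort

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

DEMO_SEED = 7


def demo_config() -> SimulationConfig:
    return SimulationConfig(rng_seed=DEMO_SEED)


def demo_cohort():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # late-visit lesions may clip
        return simulate_cohort(demo_config())


def demo_annotated() -> pd.DataFrame:
    """Annotated demo cohort, cached as CSV under scratch/."""
    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / "annotated_demo.csv"
    if cache.exists():
        return pd.read_csv(cache)
    cohort = demo_cohort()
    annotated = annotate_dataset(cohort.records, cohort.masks, cohort.grid)
    annotated.to_csv(cache, index=False)
    return annotated
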