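"""Shared configuration for the analysis drivers.

All drivers operate on the same synthetic study cohort: 300 bulk tumor
samples, 500 genes, 5 immune cell types, three planted immune subtypes
(B = immune-hot, best survival), regenerated deterministically from SEED.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from icikit.synthetic import simulate_cohort, simulate_maf

SEED = 2020
RESULTS = Path(__file__).resolve().parent.parent / "results"


def get_cohort():
    return simulate_cohort(seed=SEED)


def get_maf(cohort, score=None):
    """Somatic mutations whose burden tracks the given per-sample score
    (the ICI score once computed; the hot-subtype indicator before then)."""
    if score is None:
        score = (cohort.truth_subtype == "B").astype(float)
    return simulate_maf(cohort, score, tmb_slope=0.5, seed=SEED)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
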