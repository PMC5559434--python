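#!/usr/bin/env python
"""Simulate the synthetic NFP cohort.

Draws couple-level covariates (ages, fertile-window length, intercourse
frequency, previous pregnancies, prior hormonal contraception), generates
conception outcomes over four fertile windows from the two-state latent
Markov model at the published reference estimates, and writes one daily
symptothermal chart per observed cycle.

Outputs (results/cohort/): couples.csv, panel.csv, charts.csv, manifest.json
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import logging

from fecundlmm.pipeline import RunConfig, run_pipeline

logging.basicConfig(level=logging.INFO, format="%(message)s")

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"

cfg = RunConfig(outdir=str(OUT), seed=7, stages=("simulate",),
                n_couples=800, T_max=4, absorbing=True)
manifest = run_pipeline(cfg)
c = manifest["counts"]["simulate"]
print(f"simulated {c['couples']} couples, {c['cycles']} cycles, "
      f"{c['windows']} fertile windows, {c['conceptions']} conceptions "
      f"({c['conceptions'] / c['couples']:.0%} of couples)")
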