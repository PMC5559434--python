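"""Reproducible simulate -> windows -> fit -> predict pipeline.

A single config seed drives every stage; per-stage sub-seeds are derived
deterministically so re-running a config reproduces every output byte for
byte.  Each run writes a manifest with row counts (mirroring the cohort
filtering narrative) and SHA-256 checksums of the stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_charts, write_charts, write_json
from .lm import PanelData, decode_states, fit_em, forward_backward
from .predict import decline_curve
from .reference import MODEL_COVARIATES, reference_parameters
from .simulate import ChartSpec, CovariateSpec, simulate_cohort
from .windows import (aggregate_covariates, delimit_fertile_window,
                      filter_cycles, windows_to_frame)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("simulate", "windows", "fit", "predict")


@dataclass
class RunConfig:
    """Flat pipeline configuration (round-trips through YAML losslessly)."""

    outdir: str = "runs/default"
    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    # simulate
    n_couples: int = 500
    T_max: int = 4
    absorbing: bool = True
    covariate_spec: dict = field(default_factory=dict)
    chart_spec: dict = field(default_factory=dict)
    # windows
    open_threshold: int = 2
    strict: bool = True
    max_gap_days: int = 1
    # fit
    fit_T: int = 4
    n_starts: int = 20
    tol: float = 1e-8
    max_iter: int = 5000
    compute_se: bool = False
    # predict
    t_max: int = 4
    plot: bool = False

    def to_file(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": list(config.stages), "counts": {}, "files": {}}
    params = reference_parameters()

    if "simulate" in config.stages:
        seed = _stage_seed(config.seed, "simulate")
        cov_spec = CovariateSpec(**config.covariate_spec)
        chart_spec = ChartSpec(**config.chart_spec)
        couples, panel, charts = simulate_cohort(
            config.n_couples, cov_spec, chart_spec, params,
            T_max=config.T_max, seed=seed, absorbing=config.absorbing)
        couples.to_csv(out / "couples.csv", index=False)
        panel.to_panel_frame().to_csv(out / "panel.csv", index=False)
        write_charts(charts, out / "charts.csv")
        manifest["counts"]["simulate"] = {
            "couples": int(len(couples)),
            "cycles": int(len(charts)),
            "windows": int(panel.lengths.sum()),
            "conceptions": int((panel.y == 1).sum()),
        }
        logger.info("simulated %d couples, %d cycles", len(couples), len(charts))

    if "windows" in config.stages:
        charts = read_charts(out / "charts.csv")
        wins = [delimit_fertile_window(c, open_threshold=config.open_threshold,
                                       strict=config.strict,
                                       max_gap_days=config.max_gap_days)
                for c in charts]
        windows_to_frame(wins).to_csv(out / "windows.csv", index=False)
        retained, report = filter_cycles(charts, wins)
        pd.DataFrame([dataclasses.asdict(report)]).to_csv(
            out / "filter_report.csv", index=False)
        logger.info(
            "filter cascade: %d cycles -> %d after protected-intercourse "
            "exclusion -> %d after window-delimitation exclusion -> %d with "
            "intercourse in the fertile window (%d women remaining)",
            report.n_input, report.n_input - report.removed_protected,
            report.n_input - report.removed_protected - report.removed_invalid_window,
            report.n_retained, report.women_remaining)
        couples = pd.read_csv(out / "couples.csv", dtype={"couple_id": str}) \
            if (out / "couples.csv").exists() else None
        if couples is not None:
            couples = couples.rename(columns={"woman_id": "couple_id"})
        agg = aggregate_covariates(retained, couples)
        agg.to_csv(out / "covariates.csv", index=False)
        manifest["counts"]["windows"] = dataclasses.asdict(report)

    if "fit" in config.stages:
        panel_df = pd.read_csv(out / "panel.csv", dtype={"couple_id": str})
        cov_path = out / "covariates.csv"
        cov = pd.read_csv(cov_path if cov_path.exists() else out / "couples.csv",
                          dtype={"couple_id": str})
        if "no_contraception" not in cov.columns and "contraception" in cov.columns:
            cov["no_contraception"] = 1 - cov["contraception"]
        names = [c for c in MODEL_COVARIATES if c in cov.columns]
        # keep only panel rows whose cycles survived the window stage
        if cov_path.exists():
            panel_df = panel_df[panel_df["couple_id"].isin(set(cov["couple_id"]))]
        panel = PanelData.from_frames(panel_df, cov, names).truncated(config.fit_T)
        fit = fit_em(panel, n_random_starts=config.n_starts,
                     seed=_stage_seed(config.seed, "fit"), tol=config.tol,
                     max_iter=config.max_iter, compute_se=config.compute_se)
        write_json(fit.to_dict(), out / "fit.json")
        post = forward_backward(panel, fit.params)
        states = decode_states(panel, fit.params)
        rows = []
        for i in range(panel.n):
            for t in range(panel.lengths[i]):
                rows.append((panel.couple_ids[i], t + 1,
                             float(post.gamma[i, t, 0]),
                             float(post.gamma[i, t, 1]), int(states[i, t])))
        pd.DataFrame(rows, columns=["couple_id", "window", "gamma_1",
                                    "gamma_2", "state"]) \
            .to_csv(out / "decoded.csv", index=False)
        manifest["counts"]["fit"] = {"couples": panel.n,
                                     "windows": int(panel.lengths.sum())}
        logger.info("fit: loglik=%.3f converged=%s", fit.loglik, fit.converged)

    if "predict" in config.stages:
        panel_df = pd.read_csv(out / "panel.csv", dtype={"couple_id": str})
        cov_path = out / "covariates.csv"
        cov = pd.read_csv(cov_path if cov_path.exists() else out / "couples.csv",
                          dtype={"couple_id": str})
        if "no_contraception" not in cov.columns and "contraception" in cov.columns:
            cov["no_contraception"] = 1 - cov["contraception"]
        names = [c for c in MODEL_COVARIATES if c in cov.columns]
        if cov_path.exists():
            panel_df = panel_df[panel_df["couple_id"].isin(set(cov["couple_id"]))]
        panel = PanelData.from_frames(panel_df, cov, names)
        curve = decline_curve(panel, range(1, config.t_max + 1),
                              n_random_starts=min(config.n_starts, 5),
                              seed=_stage_seed(config.seed, "predict"))
        curve.to_frame().to_csv(out / "decline_curve.csv", index=False)
        if config.plot:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(5, 3.5))
            ax.plot(curve.T_values, curve.avg_prob, "o-")
            ax.set_xlabel("number of fertile windows")
            ax.set_ylabel("avg predicted P(state 2)")
            fig.tight_layout()
            fig.savefig(out / "decline_curve.png", dpi=120)
            plt.close(fig)
        manifest["counts"]["predict"] = {"T_fitted": curve.T_values}

    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    write_json(manifest, out / "manifest.json")
    return manifest
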