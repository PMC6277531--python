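"""End-to-end orchestration: simulate/load -> clean -> analyze -> report CSVs.

Every stage's table is written under the output directory together with a
JSON manifest (configuration, seed, package version, filter log) sufficient
to reproduce the run bit-for-bit.  All randomness is seeded from the single
master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cleaning import apply_consort, summarize
from .compare import bootstrap_table, concordance
from .doseroc import ctd_threshold_table
from .frailty import hazard_table
from .roc import logistic_threshold_table
from .simulate import SimConfig, simulate_cohort
from .survival import km_curve, logrank

__all__ = ["RunConfig", "run_pipeline", "load_tables"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Pipeline configuration; ``input_dir=None`` simulates a cohort."""

    output_dir: str | Path = "ctdroc_output"
    input_dir: str | Path | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    horizon_mg: float = 500.0
    n_boot: int = 1000
    seed: int = 0
    alpha: float = 0.05
    run_cox: bool = True
    run_bootstrap: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.horizon_mg <= 0:
            raise ValueError("horizon must be positive")


def load_tables(input_dir: str | Path):
    d = Path(input_dir)
    paths = {name: d / f"{name}.csv"
             for name in ("participants", "biomarkers", "challenges")}
    for name, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing input table: {p}")
    return tuple(pd.read_csv(p) for p in paths.values())


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a dict of in-memory results.

    Stage order: simulate (optional), clean + summarize, dose-to-reaction
    survival + log-rank, frailty Cox hazard table, logistic ROC thresholds,
    dose-dependent ROC thresholds, bootstrap AUC comparison, threshold
    concordance.  Any stage failure propagates with partial outputs already
    on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_dir is None:
        sim = config.sim.replace(seed=config.seed)
        participants, biomarkers, challenges = simulate_cohort(sim)
        _write(participants, out / "participants.csv")
        _write(biomarkers, out / "biomarkers.csv")
        _write(challenges, out / "challenges.csv")
        sim_used: SimConfig | None = sim
    else:
        participants, biomarkers, challenges = load_tables(config.input_dir)
        sim_used = None

    records, flog = apply_consort(challenges, biomarkers, participants)
    _write(records, out / "analysis_records.csv")
    _write(flog.to_frame(), out / "filter_log.csv")

    summary = summarize(records)
    _write(summary, out / "challenge_summary.csv")

    curves = []
    for food, grp in records.groupby("food", sort=True):
        curve = km_curve(grp["dose_mg"], grp["event"])
        cf = curve.to_frame()
        cf.insert(0, "food", food)
        cf["median_ctd"] = curve.median_ctd
        curves.append(cf)
    _write(pd.concat(curves, ignore_index=True), out / "survival_curves.csv")
    lr = logrank(records["dose_mg"], records["event"], records["food"])
    _write(pd.DataFrame([{
        "test": "equality_of_curves_across_foods",
        "statistic": lr.statistic, "df": lr.df, "p_value": lr.p_value,
    }]), out / "logrank_tests.csv")

    results: dict = {"records": records, "filter_log": flog,
                     "summary": summary, "logrank": lr}

    if config.run_cox:
        hz = hazard_table(records)
        _write(hz, out / "hazard_table.csv")
        results["hazard_table"] = hz

    singles, joints = logistic_threshold_table(records)
    _write(singles, out / "logistic_thresholds.csv")
    _write(joints, out / "joint_models.csv")
    results["logistic_thresholds"] = singles
    results["joint_models"] = joints

    ctd = ctd_threshold_table(records, horizon=config.horizon_mg)
    _write(ctd, out / "ctd_thresholds.csv")
    results["ctd_thresholds"] = ctd

    if config.run_bootstrap:
        boot = bootstrap_table(records, n_boot=config.n_boot,
                               seed=config.seed, horizon=config.horizon_mg)
        _write(boot, out / "bootstrap_comparison.csv")
        results["bootstrap"] = boot

    conc_frames = []
    overall = {}
    for pair in (("spt", "sige"), ("spt", "siger")):
        tab, ov = concordance(records, ctd, pair)
        tab.insert(0, "marker_pair", "+".join(pair))
        conc_frames.append(tab)
        overall["+".join(pair)] = ov
    conc = pd.concat(conc_frames, ignore_index=True)
    _write(conc, out / "concordance.csv")
    results["concordance"] = conc
    results["overall_agreement"] = overall

    manifest = {
        "package": "ctdroc",
        "version": __version__,
        "seed": config.seed,
        "horizon_mg": config.horizon_mg,
        "n_boot": config.n_boot,
        "alpha": config.alpha,
        "input_dir": None if config.input_dir is None else str(config.input_dir),
        "sim_config": _jsonable(sim_used) if sim_used is not None else None,
        "filter_log": flog.steps,
        "overall_agreement": overall,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def _jsonable(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
        elif isinstance(v, np.ndarray):
            d[k] = v.tolist()
    return d
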