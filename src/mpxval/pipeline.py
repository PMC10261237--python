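"""End-to-end pipeline: simulate or load a cohort, evaluate, report.

Outputs are a pure function of (inputs, config, seed): re-running the same
configuration produces byte-identical files.  Every stage logs to standard
error with the seed and row counts; errors carry the offending file and
column names.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import yaml

from . import __version__
from .cutoffs import (
    delong_auc,
    optimal_cutoff,
    read_paired_samples,
    roc_points,
    roc_to_frame,
    sweep_cutoffs,
    sweep_to_frame,
)
from .errors import ConfigError, SchemaError
from .mpx import classify_table, read_band_csv
from .qpcr import (
    DEFAULT_ABL1_FLOOR,
    DEFAULT_CONVERSION_FACTOR,
    fit_calibration,
    quantify_table,
    read_calibration_csv,
    read_sample_ct_csv,
)
from .reporting import plot_roc_curve, plot_sweep_profile, summarize_cohort
from .synthetic import default_table4_config, sample_cohort, write_cohort_csv

__all__ = ["run_full_pipeline", "load_config"]

log = logging.getLogger("mpxval")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: pipeline config must be a mapping")
    return cfg


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _simulate_stage(cfg: dict, seed: int, out_dir: Path) -> tuple[list, dict]:
    params = dict(cfg)
    n = int(params.pop("n_patients", 219))
    config = default_table4_config(n, seed=seed, **params)
    cohort = sample_cohort(config)
    path = out_dir / "cohort.csv"
    write_cohort_csv(cohort, path)
    log.info("simulate: n=%d seed=%d -> %s", n, seed, path)
    return list(cohort.samples), {"cohort_csv": str(path), "n": n, "config": asdict(config)}


def _evaluate_stage(pairs: list, cfg: dict, out_dir: Path) -> dict:
    cutoffs = cfg.get("cutoffs")
    level = float(cfg.get("level", 0.95))
    ci_method = cfg.get("ci_method", "wald")
    criterion = cfg.get("criterion", "youden")

    sweep = sweep_cutoffs(pairs, cutoffs)
    sweep_path = out_dir / "sweep.csv"
    sweep_to_frame(sweep).to_csv(sweep_path, index=False, float_format="%.10g")

    curve = roc_points(pairs)
    roc_path = out_dir / "roc.csv"
    roc_to_frame(curve).to_csv(roc_path, index=False, float_format="%.10g")

    est = delong_auc(pairs, level=level, ci_method=ci_method)
    best_cutoff, best = optimal_cutoff(sweep, criterion=criterion)
    auc_payload = {
        "auc": round(est.auc, 3),
        "auc_unrounded": est.auc,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "level": est.level,
        "ci_method": ci_method,
        "n_positive": est.n_positive,
        "n_negative": est.n_negative,
        "optimal_cutoff": best_cutoff,
        "optimal_criterion": criterion,
        "optimal_sensitivity": best.sensitivity,
        "optimal_specificity": best.specificity,
        "optimal_accuracy": best.accuracy,
    }
    auc_path = out_dir / "auc.json"
    _write_json(auc_payload, auc_path)

    summary = summarize_cohort([p.reference_value for p in pairs])
    summary_path = out_dir / "summary.json"
    _write_json(summary.to_dict(), summary_path)

    if cfg.get("plot", False):
        plot_roc_curve(curve, out_dir / "roc.png")
        plot_sweep_profile(sweep, out_dir / "profile.png")

    log.info(
        "evaluate: n=%d cutoffs=%d auc=%.3f optimum=%.3g",
        len(pairs), len(sweep), est.auc, best_cutoff,
    )
    return {
        "sweep_csv": str(sweep_path),
        "roc_csv": str(roc_path),
        "auc_json": str(auc_path),
        "summary_json": str(summary_path),
        "n_samples": len(pairs),
    }


def _quantify_stage(cfg: dict, out_dir: Path) -> dict:
    standards = read_calibration_csv(cfg["calibration_csv"])
    for target in ("BCR_ABL1", "ABL1"):
        if target not in standards:
            raise SchemaError(
                f"{cfg['calibration_csv']}: missing calibration target {target!r}"
            )
    curves = {t: fit_calibration(s) for t, s in standards.items()}
    cts = read_sample_ct_csv(cfg["samples_csv"])
    table = quantify_table(
        cts,
        curves["BCR_ABL1"],
        curves["ABL1"],
        conversion_factor=float(cfg.get("conversion_factor", DEFAULT_CONVERSION_FACTOR)),
        abl1_floor=float(cfg.get("abl1_floor", DEFAULT_ABL1_FLOOR)),
    )
    path = out_dir / "quantified.csv"
    table.to_csv(path, index=False, float_format="%.10g")
    log.info("quantify: %d samples -> %s", len(table), path)
    return {
        "quantified_csv": str(path),
        "n_samples": len(table),
        "curves": {
            t: {"slope": c.slope, "intercept": c.intercept, "r_squared": c.r_squared,
                "efficiency": c.efficiency}
            for t, c in sorted(curves.items())
        },
    }


def _classify_stage(cfg: dict, out_dir: Path) -> dict:
    patterns = read_band_csv(cfg["bands_csv"])
    table = classify_table(
        patterns,
        tolerance=float(cfg.get("tolerance", 0.03)),
        strict_control=bool(cfg.get("strict_control", False)),
    )
    path = out_dir / "transcript_calls.csv"
    table.to_csv(path, index=False)
    log.info("classify: %d lanes -> %s", len(table), path)
    return {"calls_csv": str(path), "n_lanes": len(table)}


def run_full_pipeline(config: dict, output_dir=None) -> dict:
    """Execute the configured stages and return the run manifest.

    ``config`` keys: ``seed``, ``output_dir``, and any of the stage blocks
    ``simulate`` (or ``cohort_csv``), ``quantify``, ``classify``,
    ``evaluate``.  The manifest is also written to ``manifest.json`` beside
    the outputs.
    """
    seed = int(config.get("seed", 0))
    out_dir = Path(output_dir or config.get("output_dir", "mpxval_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "version": __version__, "stages": {}}

    pairs = None
    if "simulate" in config:
        pairs, info = _simulate_stage(config["simulate"] or {}, seed, out_dir)
        manifest["stages"]["simulate"] = info
    elif "cohort_csv" in config:
        pairs = read_paired_samples(config["cohort_csv"])
        manifest["stages"]["load"] = {"cohort_csv": str(config["cohort_csv"]), "n": len(pairs)}
        log.info("load: %d samples from %s", len(pairs), config["cohort_csv"])

    if "quantify" in config:
        manifest["stages"]["quantify"] = _quantify_stage(config["quantify"], out_dir)
    if "classify" in config:
        manifest["stages"]["classify"] = _classify_stage(config["classify"], out_dir)

    if pairs is not None:
        manifest["stages"]["evaluate"] = _evaluate_stage(
            pairs, config.get("evaluate") or {}, out_dir
        )
    elif "evaluate" in config:
        raise ConfigError("evaluate stage requires either a simulate block or cohort_csv")

    _write_json(manifest, out_dir / "manifest.json")
    return manifest
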