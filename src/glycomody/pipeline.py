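"""End-to-end pipeline: simulate -> quantify -> traits -> evaluate.

A run is driven by a single structured config (YAML, CLI-overridable) and
one master seed; each stage draws from a seed derived deterministically
from it, so stages can be re-run in isolation and an identical config
reproduces byte-identical outputs.  Outputs land in a run directory with
a manifest recording the normalized config, its hash, the seeds and the
package version.
"""

from __future__ import annotations

import copy
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import synth
from .chromatogram import Feature, quantifications_to_frame, quantify_chromatogram
from .stats import evaluate_biomarkers, interlab_concordance, qc_cv
from .traits import (
    DEFAULT_DERIVED_MEMBERS,
    DEFAULT_PAIRINGS_ALL,
    DERIVED_TRAIT,
    compute_traits,
    load_pairings,
    normalize_peak_table,
)

__all__ = ["ConfigError", "PipelineError", "DEFAULTS", "validate_config",
           "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every problem found."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "cohort": {
        "n_damaging": 18,
        "n_vus": 5,
        "n_benign": 8,
        "n_none": 289,
        "crp_trait_rho": 0.3,
        "trait_latent_share": 0.6,
    },
    "noise_cv": 0.03,
    "quant": {
        "sigma_edge": 2.0,
        "gpq_min": 0.8,
        "sn_min": 9.0,
        "min_intensity": 0.001,
    },
    "iqr_k": 1.5,
    "pairings_file": None,
    "comparisons": ["damaging:none", "damaging:benign"],
    "qc": {"n_plates": 32, "intra_cv": 0.05, "inter_cv": 0.07},
    "interlab": {"enabled": True, "target_rho": 0.85},
    "render_chromatograms": False,
    "n_rendered_samples": 3,
    "stages": ["simulate", "traits", "evaluate", "qc", "interlab"],
}

_RANGE_CHECKS = [
    (("quant", "gpq_min"), lambda v: 0.0 <= v <= 1.0, "must be in [0, 1]"),
    (("quant", "sn_min"), lambda v: v >= 0, "must be >= 0"),
    (("quant", "sigma_edge"), lambda v: v > 0, "must be > 0"),
    (("quant", "min_intensity"), lambda v: 0.0 < v < 1.0, "must be in (0, 1)"),
    (("iqr_k",), lambda v: v > 0, "must be > 0"),
    (("noise_cv",), lambda v: v >= 0, "must be >= 0"),
    (("cohort", "n_damaging"), lambda v: v >= 0, "must be >= 0"),
    (("cohort", "n_vus"), lambda v: v >= 0, "must be >= 0"),
    (("cohort", "n_benign"), lambda v: v >= 0, "must be >= 0"),
    (("cohort", "n_none"), lambda v: v >= 0, "must be >= 0"),
    (("cohort", "crp_trait_rho"), lambda v: -1.0 <= v <= 1.0, "must be in [-1, 1]"),
    (("qc", "n_plates"), lambda v: v >= 0, "must be >= 0"),
    (("qc", "intra_cv"), lambda v: v >= 0, "must be >= 0"),
    (("qc", "inter_cv"), lambda v: v >= 0, "must be >= 0"),
]


def _merge(defaults: Mapping, user: Mapping, prefix: str,
           warnings_out: list[str]) -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, value in user.items():
        if key not in out:
            warnings_out.append(f"unknown config key {prefix}{key!r} ignored")
            continue
        if isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _merge(out[key], value, f"{prefix}{key}.", warnings_out)
        else:
            out[key] = value
    return out


def _get(cfg: Mapping, path: tuple[str, ...]):
    for key in path:
        cfg = cfg[key]
    return cfg


def validate_config(source=None, overrides: Mapping | None = None
                    ) -> tuple[dict, list[str]]:
    """Load, default-fill and validate a run config.

    ``source`` may be a path to a YAML file, a mapping, or None (pure
    defaults).  Unknown keys produce warnings, not errors; every
    validation error is collected and reported at once in a
    :class:`ConfigError`.  Returns (normalized config, warnings).
    """
    if source is None:
        user: dict = {}
    elif isinstance(source, Mapping):
        user = dict(source)
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ConfigError(["config file must contain a mapping"])
    if overrides:
        user = {**user, **{k: v for k, v in overrides.items() if v is not None}}

    warn_list: list[str] = []
    cfg = _merge(DEFAULTS, user, "", warn_list)
    errors: list[str] = []
    for path, check, msg in _RANGE_CHECKS:
        try:
            value = _get(cfg, path)
            if not check(value):
                errors.append(f"{'.'.join(path)} = {value!r} {msg}")
        except TypeError:
            errors.append(f"{'.'.join(path)} has a non-numeric value")
    if not isinstance(cfg["seed"], int):
        errors.append("seed must be an integer")
    for comp in cfg["comparisons"]:
        if not (isinstance(comp, str) and comp.count(":") == 1):
            errors.append(f"comparison {comp!r} must look like 'case:control'")
    if cfg["pairings_file"] is not None and not Path(cfg["pairings_file"]).exists():
        errors.append(f"pairings_file {cfg['pairings_file']!r} does not exist")
    unknown_stages = set(cfg["stages"]) - {"simulate", "quantify", "traits",
                                           "evaluate", "qc", "interlab"}
    if unknown_stages:
        errors.append(f"unknown stage(s): {sorted(unknown_stages)}")
    if errors:
        raise ConfigError(errors)
    return cfg, warn_list


def _stage_seed(base: int, stage: str) -> int:
    digest = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _chromatogram_layout(peaks: list[str]) -> dict[str, tuple[float, float]]:
    # Evenly spaced apexes over an 8-62 min elution window, constant width.
    rts = np.linspace(8.0, 62.0, len(peaks))
    return {p: (float(rt), 0.06) for p, rt in zip(peaks, rts)}


def run_pipeline(config: Mapping | None = None, out_dir="run",
                 overrides: Mapping | None = None) -> Path:
    """Execute the configured stages and write results to ``out_dir``.

    Produces (depending on enabled stages) ``cohort.csv``,
    ``peak_table.csv``, ``quantification.csv``, ``traits.csv``,
    ``biomarker_report.csv``, ``vus_classification.csv``,
    ``qc_report.csv``, ``interlab.csv`` and ``manifest.json``.  A stage
    failure writes a ``FAILED`` marker naming the stage and re-raises as
    :class:`PipelineError`; completed outputs are retained.
    """
    cfg, cfg_warnings = validate_config(config, overrides)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    stages = cfg["stages"]
    log: list[str] = list(cfg_warnings)
    outputs: list[str] = []
    state: dict[str, Any] = {}

    def save(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, float_format="%.10g")
        outputs.append(name)

    def run_stage(name, fn):
        try:
            fn()
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {name} failed: {exc}\n")
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    def stage_simulate():
        spec = synth.CohortSpec(seed=_stage_seed(seed, "cohort"),
                                **{k: v for k, v in cfg["cohort"].items()})
        cohort = synth.generate_cohort(spec)
        state["cohort"] = cohort
        save(synth.cohort_to_frame(cohort), "cohort.csv")
        table = synth.cohort_to_peak_table(
            cohort, noise_cv=cfg["noise_cv"],
            seed=_stage_seed(seed, "peak_table"))
        state["peak_table"] = table
        save(table, "peak_table.csv")

    def stage_quantify():
        table = state["peak_table"]
        layout = _chromatogram_layout(list(table.columns))
        features = [Feature(p, rt, 0.4) for p, (rt, _) in layout.items()]
        frames = []
        n = min(cfg["n_rendered_samples"], len(table))
        for sid, row in table.iloc[:n].iterrows():
            spec = synth.ChromatogramSpec(
                peaks=[synth.PeakSpec(p, layout[p][0], layout[p][1],
                                      1000.0 * float(row[p]))
                       for p in table.columns],
                noise_sd=0.5, baseline_level=2.0, baseline_drift=0.01,
            )
            chrom = synth.render_chromatogram(
                spec, seed=_stage_seed(seed, f"chrom:{sid}"))
            quants = quantify_chromatogram(
                chrom, features, sigma_edge=cfg["quant"]["sigma_edge"],
                gpq_min=cfg["quant"]["gpq_min"], sn_min=cfg["quant"]["sn_min"])
            frames.append(quantifications_to_frame(quants, sample_id=sid))
        if frames:
            save(pd.concat(frames, ignore_index=True), "quantification.csv")

    def stage_traits():
        if cfg["pairings_file"]:
            pairings, derived = load_pairings(cfg["pairings_file"])
        else:
            pairings, derived = DEFAULT_PAIRINGS_ALL, DEFAULT_DERIVED_MEMBERS
        analysis_peaks = sorted(
            {p for pr in pairings for p in (*pr.fucosylated_peaks,
                                            *pr.nonfucosylated_peaks)})
        normalized, invalid = normalize_peak_table(state["peak_table"],
                                                   analysis_peaks)
        if invalid:
            log.append(f"{len(invalid)} sample(s) with zero analysis-peak total: "
                       f"{invalid[:5]}")
        traits = compute_traits(normalized, pairings, derived)
        state["traits"] = traits
        state["derived_members"] = list(derived)
        save(traits.round(6), "traits.csv")

    def stage_evaluate():
        traits = state["traits"]
        groups = synth.cohort_to_frame(state["cohort"])["group"]
        comparisons = [tuple(c.split(":")) for c in cfg["comparisons"]]
        trait_cols = state["derived_members"] + [DERIVED_TRAIT]
        report, vus = evaluate_biomarkers(
            traits, groups, comparisons=comparisons,
            trait_cols=trait_cols, iqr_k=cfg["iqr_k"])
        save(report, "biomarker_report.csv")
        if len(vus):
            save(vus, "vus_classification.csv")
        state["report"] = report

    def stage_qc():
        standard = state["peak_table"].mean(axis=0)  # pooled-plasma surrogate
        trips = synth.generate_triplicates(
            standard, n_plates=cfg["qc"]["n_plates"],
            intra_cv=cfg["qc"]["intra_cv"], inter_cv=cfg["qc"]["inter_cv"],
            seed=_stage_seed(seed, "qc"))
        if len(trips):
            per_peak, summary = qc_cv(trips)
            save(per_peak, "qc_report.csv")
            log.append(
                f"QC: mean intra-plate CV {summary.mean_intra_cv_pct:.2f}%, "
                f"inter-plate CV {summary.mean_inter_cv_pct:.2f}% over "
                f"{summary.n_peaks_included} peaks with RI > "
                f"{summary.ri_threshold_pct:g}%")

    def stage_interlab():
        if not cfg["interlab"]["enabled"]:
            return
        traits = state["traits"]
        cols = [c for c in traits.columns if c != DERIVED_TRAIT]
        noise = synth.calibrate_second_lab_noise(
            traits[cols[0]].dropna().to_numpy(),
            target_rho=cfg["interlab"]["target_rho"],
            seed=_stage_seed(seed, "interlab_cal"))
        second = synth.generate_second_lab(
            traits[cols], noise_sd=noise, seed=_stage_seed(seed, "interlab"))
        save(interlab_concordance(traits[cols], second), "interlab.csv")

    stage_fns = {
        "simulate": stage_simulate,
        "quantify": stage_quantify,
        "traits": stage_traits,
        "evaluate": stage_evaluate,
        "qc": stage_qc,
        "interlab": stage_interlab,
    }
    ordered = [s for s in ("simulate", "quantify", "traits", "evaluate",
                           "qc", "interlab") if s in stages]
    if cfg["render_chromatograms"] and "quantify" not in ordered:
        ordered.insert(1, "quantify")
    for name in ordered:
        run_stage(name, stage_fns[name])

    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": seed,
        "stage_seeds": {s: _stage_seed(seed, s) for s in
                        ("cohort", "peak_table", "qc", "interlab")},
        "version": __version__,
        "outputs": outputs,
        "log": log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
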