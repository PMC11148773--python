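"""End-to-end orchestration: simulate -> wgii -> stratify -> diffexpr -> ksa2d.

Every stage writes plain-text outputs into the run directory, a structured
log records the filter counts needed to audit the run (features dropped,
pairs before/after the missingness filter, group sizes), and
``provenance.json`` carries the config hash and seed so a rerun with the
same config reproduces byte-identical result tables. Wall-clock timestamps
appear only in the run log, never in result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .coreg import build_pairs, compute_z, fit_mixture, permutation_null, significant_pairs
from .diffexpr import DesignSpec, fit_linear_model, moderate, normalize_ptm
from .errors import ConfigError
from .scores import wgii_table
from .simulate import SimulationConfig, simulate_cohort
from .survival import assign_groups, find_wgii_cutoff

log = logging.getLogger("gicoreg")

STAGES = ("simulate", "wgii", "stratify", "diffexpr", "ksa2d")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    grid_step: float = 0.01
    min_group_fraction: float = 0.1
    adjust: list[str] | None = None
    #: dichotomize at this wGII instead of searching; mirrors selecting the
    #: cutoff on an independent cohort and applying it to this one
    fixed_cutoff: float | None = None
    n_perm: int = 200
    max_missing: int = 6
    fdr_max: float = 0.05
    lfc_k_min: float = 0.05
    lfc_s_min: float = 0.5

    def __post_init__(self):
        stages = {s: True for s in STAGES}
        stages.update(self.stages or {})
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        enabled = [stages[s] for s in STAGES]
        if any(a and not b for a, b in zip(enabled[1:], enabled[:-1])):
            raise ConfigError("a stage cannot run with an earlier stage disabled")
        self.stages = stages
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)
        self.simulation.validate()
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.grid_step <= 0:
            raise ConfigError("grid_step must be positive")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        sim = raw.pop("simulation", {})
        if not isinstance(sim, dict):
            raise ConfigError("simulation block must be a mapping")
        known_sim = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = set(sim) - known_sim
        if bad:
            raise ConfigError(f"unknown simulation keys {sorted(bad)}")
        if "chrom_sizes" in sim:
            sim["chrom_sizes"] = {str(k): int(v) for k, v in sim["chrom_sizes"].items()}
        if "purity_range" in sim:
            sim["purity_range"] = tuple(sim["purity_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys {sorted(bad)}")
        cfg = cls(simulation=SimulationConfig(**sim), **raw)
        if seed is not None:
            cfg = dataclasses.replace(
                cfg, seed=seed, simulation=dataclasses.replace(cfg.simulation, seed=seed)
            )
        return cfg

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        d["simulation"]["purity_range"] = list(d["simulation"]["purity_range"])
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(stream)
    log.setLevel(logging.INFO)
    return handler


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> Path:
    io.write_json(
        {"config_hash": config.config_hash(), "seed": config.seed, "version": __version__},
        outdir / "provenance.json",
    )
    report: dict = {"seed": config.seed, "config_hash": config.config_hash()}

    log.info("stage simulate: n_samples=%d", config.simulation.n_samples)
    cohort = simulate_cohort(config.simulation)
    io.write_segments(cohort.profiles, outdir / "segments.tsv")
    io.write_clinical(cohort.clinical, outdir / "clinical.tsv")
    io.write_matrix(cohort.global_matrix, outdir / "global.tsv")
    io.write_matrix(cohort.phospho_matrix, outdir / "phospho.tsv")
    io.write_ks_table(cohort.ks_table, outdir / "ks_table.tsv")
    io.write_truth(cohort.truth, outdir / "truth.json")
    if not config.stages["wgii"]:
        io.write_json(report, outdir / "report.json")
        return outdir

    wgii = wgii_table(cohort.profiles)
    wgii.to_csv(outdir / "wgii.tsv", sep="\t")
    err = float((wgii["wgii"] - cohort.truth.true_wgii).abs().max())
    report["wgii_max_abs_error"] = err
    log.info("stage wgii: %d samples, max |realized-true| = %.3g", len(wgii), err)
    if not config.stages["stratify"]:
        io.write_json(report, outdir / "report.json")
        return outdir

    if config.fixed_cutoff is None:
        search = find_wgii_cutoff(
            wgii["wgii"],
            cohort.clinical,
            grid_step=config.grid_step,
            min_group_fraction=config.min_group_fraction,
            adjust=config.adjust,
        )
        search.as_frame().to_csv(outdir / "cutoff_pcurve.tsv", sep="\t", index=False)
        cutoff = search.chosen_cutoff
        report["cutoff_min_p"] = float(np.min(search.p_curve))
        report["cutoff_source"] = "search"
    else:
        cutoff = float(config.fixed_cutoff)
        report["cutoff_source"] = "fixed"
    groups = assign_groups(wgii["wgii"], cutoff)
    groups.to_frame().to_csv(outdir / "groups.tsv", sep="\t", index_label="sample_id")
    n_high = int((groups == "high").sum())
    report.update(
        chosen_cutoff=cutoff,
        true_cutoff=config.simulation.true_cutoff,
        n_high=n_high,
        n_low=len(groups) - n_high,
    )
    log.info(
        "stage stratify: cutoff %.3f (%s; true %.3f), groups %d high / %d low",
        cutoff, report["cutoff_source"], config.simulation.true_cutoff,
        n_high, len(groups) - n_high,
    )
    if not config.stages["diffexpr"]:
        io.write_json(report, outdir / "report.json")
        return outdir

    design = DesignSpec(group=groups, purity=cohort.clinical["purity"], mode="groups")
    de_global = moderate(fit_linear_model(cohort.global_matrix, design))
    de_global.table.to_csv(outdir / "diffexpr_global.tsv", sep="\t", index_label="feature_id")
    site_map = {
        f"{s}_{r}{p}": s
        for s, r, p in zip(
            cohort.ks_table["substrate"], cohort.ks_table["residue"], cohort.ks_table["position"]
        )
    }
    phospho_norm, flags = normalize_ptm(cohort.phospho_matrix, cohort.global_matrix, site_map)
    io.write_matrix(phospho_norm, outdir / "phospho_normalized.tsv")
    flags.to_csv(outdir / "ptm_normalization_flags.tsv", sep="\t", index=False)
    de_phospho = moderate(fit_linear_model(phospho_norm, design))
    de_phospho.table.to_csv(outdir / "diffexpr_phospho.tsv", sep="\t", index_label="feature_id")
    report["diffexpr_features_dropped"] = int(len(de_global.dropped) + len(de_phospho.dropped))
    log.info(
        "stage diffexpr: global %d features (%d dropped, d0=%.2f), phospho %d (%d dropped)",
        len(de_global.table), len(de_global.dropped), de_global.df_prior,
        len(de_phospho.table), len(de_phospho.dropped),
    )
    if not config.stages["ksa2d"]:
        io.write_json(report, outdir / "report.json")
        return outdir

    paired = build_pairs(
        cohort.ks_table, cohort.global_matrix, phospho_norm, max_missing=config.max_missing
    )
    log.info("stage ksa2d: filter counts %s", paired.filter_counts)
    purity = cohort.clinical["purity"]
    zpairs = compute_z(paired, groups, purity)
    null_z = permutation_null(paired, groups, purity, n_perm=config.n_perm, seed=config.seed)
    fit = fit_mixture(zpairs, null_z, seed=config.seed)
    sig, per_kinase = significant_pairs(
        fit, zpairs, fdr_max=config.fdr_max, lfc_k_min=config.lfc_k_min, lfc_s_min=config.lfc_s_min
    )
    zpairs.join(fit.table).to_csv(outdir / "pairs.tsv", sep="\t", index_label="pair_id")
    sig.to_csv(outdir / "significant_pairs.tsv", sep="\t", index_label="pair_id")
    per_kinase.to_frame().to_csv(outdir / "kinase_substrate_counts.tsv", sep="\t")
    sig.assign(substrate=paired.pairs.loc[sig.index, "substrate"]).reset_index()[
        ["kinase", "substrate", "site", "fdr"]
    ].to_csv(outdir / "edges.tsv", sep="\t", index=False)
    io.write_json(
        {
            "p0": fit.p0,
            "p0_raw": fit.p0_raw,
            "n_pairs": len(zpairs),
            "n_null": fit.n_null,
            "n_perm": config.n_perm,
            "seed": config.seed,
            "bandwidths_f": [float(b) for b in fit.f.bandwidths_],
            "bandwidths_f0": [float(b) for b in fit.f0.bandwidths_],
            "filter_counts": paired.filter_counts,
        },
        outdir / "mixture.json",
    )

    planted = cohort.truth.planted_pairs
    called = set(sig.index)
    planted_testable = planted & set(zpairs.index)
    tp = len(called & planted)
    report.update(
        p0=fit.p0,
        true_null_fraction=1.0 - config.simulation.planted_fraction,
        n_pairs=len(zpairs),
        n_called=len(called),
        n_planted=len(planted),
        n_planted_testable=len(planted_testable),
        sensitivity=tp / len(planted_testable) if planted_testable else None,
        false_call_fraction=(len(called) - tp) / len(called) if called else 0.0,
    )
    log.info(
        "stage ksa2d: %d pairs, p0=%.3f, %d called, sensitivity=%s",
        len(zpairs), fit.p0, len(called), report["sensitivity"],
    )
    io.write_json(report, outdir / "report.json")
    return outdir
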