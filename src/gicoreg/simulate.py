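"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the downstream analyses assume, so every
stage is testable end-to-end without external data:

* integer copy-number segment profiles over a genome, with a per-sample
  baseline ploidy and a controlled aberrant fraction (the realized wGII of
  the emitted segments matches the per-sample target up to base-pair
  rounding);
* survival times with an exponential hazard multiplied by a configurable
  hazard ratio for samples whose true wGII exceeds a true cutoff,
  independent uniform censoring, and clinical covariates including tumor
  purity (purity is drawn group-shifted so that it confounds expression
  contrasts unless adjusted for);
* Gaussian log2-ratio global-proteome and phosphoproteome matrices with a
  planted fraction of co-regulated kinase-substrate pairs, an additive
  purity component, and completely-at-random missing values;
* the matching kinase-substrate relation table and a ground-truth record.

Planting operates at kinase level: a planted kinase carries the kinase
effect on its protein and the substrate effect on all of its sites, so that
unplanted pairs are genuinely null in both Z coordinates and the planted
fraction equals the fraction of non-null pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .coreg import site_id
from .errors import ConfigError
from .scores import SegmentProfile

#: hg38 autosome lengths (bp), the default simulated genome.
HG38_AUTOSOMES: dict[str, int] = {
    "1": 248_956_422, "2": 242_193_529, "3": 198_295_559, "4": 190_214_555,
    "5": 181_538_259, "6": 170_805_979, "7": 159_345_973, "8": 145_138_636,
    "9": 138_394_717, "10": 133_797_422, "11": 135_086_622, "12": 133_275_309,
    "13": 114_364_328, "14": 107_043_718, "15": 101_991_189, "16": 90_338_345,
    "17": 83_257_441, "18": 80_373_285, "19": 58_617_616, "20": 64_444_167,
    "21": 46_709_983, "22": 50_818_468,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions
    the pipeline is exercised under (cohort of 30, hazard ratio 3 across the
    0.3 wGII cutoff, effects of 1 / 1.5 log2 units on kinase / substrate)."""

    n_samples: int = 30
    chrom_sizes: dict[str, int] = field(default_factory=lambda: dict(HG38_AUTOSOMES))
    baseline_ploidy: int = 2
    #: per-sample target aberrant fraction; scalar, sequence, or None to draw
    #: uniformly from (0.05, 0.6) so the cohort straddles the cutoff
    aberrant_fraction: float | list[float] | None = None
    hazard_ratio: float = 3.0
    true_cutoff: float = 0.3
    median_survival_months: float = 36.0
    censoring_fraction: float = 0.3
    #: number of background (non-kinase, non-substrate) proteins in the
    #: global proteome matrix
    n_features: int = 200
    n_kinases: int = 100
    substrates_per_kinase: int = 10
    planted_fraction: float = 0.1
    effect_size_kinase: float = 1.0
    effect_size_substrate: float = 1.5
    noise_sd: float = 0.5
    purity_range: tuple[float, float] = (0.4, 0.9)
    #: sd of the per-feature purity slope (log2 units per unit purity)
    purity_effect_sd: float = 0.3
    missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_samples < 1 or self.n_kinases < 1 or self.substrates_per_kinase < 1:
            raise ConfigError("counts must be >= 1")
        if self.n_features < 0:
            raise ConfigError("n_features must be >= 0")
        if not self.chrom_sizes:
            raise ConfigError("chrom_sizes must be non-empty")
        if any(v <= 0 for v in self.chrom_sizes.values()):
            raise ConfigError("chromosome lengths must be positive")
        if self.baseline_ploidy < 1:
            raise ConfigError("baseline_ploidy must be >= 1")
        if not 0 <= self.planted_fraction <= 1:
            raise ConfigError(f"planted_fraction out of range: {self.planted_fraction}")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError(f"missing_rate out of range: {self.missing_rate}")
        if not 0 <= self.censoring_fraction < 1:
            raise ConfigError(f"censoring_fraction out of range: {self.censoring_fraction}")
        if self.hazard_ratio <= 0:
            raise ConfigError("hazard_ratio must be positive")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        lo, hi = self.purity_range
        if not (0 < lo < hi <= 1):
            raise ConfigError(f"purity_range must satisfy 0 < lo < hi <= 1, got {self.purity_range}")
        if self.aberrant_fraction is not None:
            af = np.atleast_1d(np.asarray(self.aberrant_fraction, dtype=np.float64))
            if ((af < 0) | (af > 1)).any():
                raise ConfigError("aberrant_fraction must lie in [0, 1]")
        return self

    def sample_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(self.n_samples)]


@dataclass
class GroundTruth:
    """What the generator actually planted, for truth-vs-result reporting."""

    true_wgii: pd.Series
    true_group: pd.Series
    planted_pairs: set[str]
    true_effects: dict[str, tuple[float, float]]


def _aberrant_targets(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.aberrant_fraction is None:
        return rng.uniform(0.05, 0.6, size=config.n_samples)
    af = np.atleast_1d(np.asarray(config.aberrant_fraction, dtype=np.float64))
    if len(af) == 1:
        return np.full(config.n_samples, af[0])
    if len(af) != config.n_samples:
        raise ConfigError("aberrant_fraction length must equal n_samples")
    return af


def _aberrant_copy_number(baseline: int, rng: np.random.Generator) -> int:
    choices = [c for c in (baseline - 2, baseline - 1, baseline + 1, baseline + 2) if c >= 0]
    return int(rng.choice(choices))


def _chromosome_segments(
    length: int, target_frac: float, baseline: int, rng: np.random.Generator
) -> tuple[list[tuple[int, int, int]], int]:
    """Segments of one chromosome as (start0, end0, copy_number) half-open
    0-based intervals; returns (segments, aberrant base pairs).

    The chromosome is cut at 1-19 random breakpoints; whole segments are
    aberrated greedily in random order while they fit under the target, then
    one remaining segment is split so the aberrant length equals
    round(target * length) exactly.
    """
    k = int(rng.integers(2, 21))
    n_cuts = min(k - 1, length - 1)
    if n_cuts > 0:
        # duplicates are merely dropped: fewer cuts, still a valid tiling
        cuts = np.unique(rng.integers(1, length, size=n_cuts))
    else:
        cuts = np.array([], dtype=np.int64)
    bounds = np.concatenate([[0], cuts, [length]]).astype(np.int64)
    segs = [(int(bounds[i]), int(bounds[i + 1])) for i in range(len(bounds) - 1)]

    target_len = int(round(target_frac * length))
    order = rng.permutation(len(segs))
    aberrant = [False] * len(segs)
    remaining = target_len
    for i in order:
        seg_len = segs[i][1] - segs[i][0]
        if seg_len <= remaining:
            aberrant[i] = True
            remaining -= seg_len
    out: list[tuple[int, int, int]] = []
    for i, (s, e) in enumerate(segs):
        if aberrant[i]:
            out.append((s, e, _aberrant_copy_number(baseline, rng)))
        elif remaining > 0 and (e - s) > remaining:
            out.append((s, s + remaining, _aberrant_copy_number(baseline, rng)))
            out.append((s + remaining, e, baseline))
            remaining = 0
        else:
            out.append((s, e, baseline))
    return sorted(out), target_len


def gen_segments(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[SegmentProfile], pd.Series]:
    """Per-sample copy-number segment profiles plus the true wGII values.

    Segments per chromosome are non-overlapping, sorted, and tile the
    chromosome exactly; the realized per-chromosome aberrant fraction equals
    the per-sample target up to one base pair of rounding, so the true wGII
    (mean over chromosomes) matches the realized one.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    targets = _aberrant_targets(config, rng)
    profiles = []
    true_wgii = {}
    for sid, target in zip(config.sample_ids(), targets):
        rows = []
        chrom_fracs = []
        for chrom, length in config.chrom_sizes.items():
            segs, aberrant_len = _chromosome_segments(
                int(length), float(target), config.baseline_ploidy, rng
            )
            chrom_fracs.append(aberrant_len / length)
            for s0, e0, cn in segs:
                rows.append({"chrom": chrom, "start": s0 + 1, "end": e0, "copy_number": cn})
        profiles.append(SegmentProfile(sample_id=sid, segments=pd.DataFrame(rows)))
        true_wgii[sid] = float(np.mean(chrom_fracs))
    return profiles, pd.Series(true_wgii, name="true_wgii")


def _censoring_horizon(lambda0: float, target: float) -> float:
    """Horizon c of U(0, c) censoring giving the target censored fraction
    under the baseline exponential hazard: solves (1-exp(-l*c))/(l*c) = target."""
    if target <= 0:
        return np.inf
    g = lambda x: (1.0 - np.exp(-x)) / x - target
    x = brentq(g, 1e-9, 1e6)
    return x / lambda0


def gen_survival(
    true_wgii: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Clinical table with survival driven by the true wGII group.

    Event times are exponential; samples with true wGII above
    ``config.true_cutoff`` have their hazard multiplied by
    ``config.hazard_ratio``. Censoring is independent uniform, calibrated to
    ``config.censoring_fraction`` under the baseline hazard. Purity is drawn
    group-shifted (high-wGII samples toward the top of ``purity_range``) so
    that it acts as a genuine confounder downstream; age, gender, race and
    stage are independent fillers.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    w = pd.Series(true_wgii, dtype=np.float64)
    n = len(w)
    high = (w > config.true_cutoff).to_numpy()
    lambda0 = np.log(2.0) / config.median_survival_months
    hazard = lambda0 * np.where(high, config.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    horizon = _censoring_horizon(lambda0, config.censoring_fraction)
    t_cens = rng.uniform(0.0, horizon, size=n) if np.isfinite(horizon) else np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(np.int64)

    lo, hi = config.purity_range
    span = hi - lo
    purity = np.where(
        high,
        rng.uniform(lo + 0.3 * span, hi, size=n),
        rng.uniform(lo, lo + 0.7 * span, size=n),
    )
    age = np.clip(np.round(rng.normal(60.0, 10.0, size=n)), 30, 90).astype(np.int64)
    gender = rng.choice(["male", "female"], size=n)
    race = rng.choice(["white", "black", "asian", "other"], size=n, p=[0.7, 0.15, 0.1, 0.05])
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.4, 0.25, 0.2, 0.15])
    return pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": age,
            "gender": gender,
            "race": race,
            "stage": stage,
            "purity": np.round(purity, 6),
        },
        index=w.index.rename("sample_id"),
    )


def gen_omics(
    config: SimulationConfig,
    groups: pd.Series,
    purity: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Global and phospho matrices, the relation table, and the ground truth.

    The global matrix holds kinase proteins, the substrate parent proteins
    (null background for PTM residual normalization), and
    ``config.n_features`` extra background proteins; the phospho matrix
    holds one row per substrate site. Planted kinases get a mean shift of
    ``effect_size_kinase`` in the high group, their sites
    ``effect_size_substrate``; every feature additionally carries a random
    purity slope, and values are set missing completely at random at
    ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    groups = pd.Series(groups).astype(str)
    levels = set(groups.unique())
    if levels != {"high", "low"}:
        raise ConfigError(f"groups must take exactly the levels high/low, got {sorted(levels)}")
    samples = groups.index
    n = len(samples)
    if purity is None:
        purity = pd.Series(rng.uniform(*config.purity_range, size=n), index=samples)
    purity = pd.Series(purity, dtype=np.float64).loc[samples]
    high = (groups == "high").to_numpy(dtype=np.float64)
    purity_c = purity.to_numpy() - purity.to_numpy().mean()

    kinases = [f"KIN{i:04d}" for i in range(config.n_kinases)]
    n_planted = int(round(config.planted_fraction * config.n_kinases))
    planted_kinases = set(rng.choice(kinases, size=n_planted, replace=False)) if n_planted else set()

    ks_rows = []
    residues = np.array(["S", "T", "Y"])
    for i, kin in enumerate(kinases):
        for j in range(config.substrates_per_kinase):
            sub = f"SP{i:04d}x{j:02d}"
            res = str(rng.choice(residues, p=[0.6, 0.3, 0.1]))
            pos = int(rng.integers(1, 1000))
            ks_rows.append(
                {"kinase": kin, "substrate": sub, "residue": res, "position": pos,
                 "modification": "phosphorylation"}
            )
    ks_table = pd.DataFrame(ks_rows)
    ks_table["site"] = [
        site_id(s, r, p) for s, r, p in zip(ks_table["substrate"], ks_table["residue"], ks_table["position"])
    ]

    background = [f"BG{i:04d}" for i in range(config.n_features)]
    global_rows = kinases + list(ks_table["substrate"]) + background
    g_values = rng.normal(0.0, config.noise_sd, size=(len(global_rows), n))
    g_slopes = rng.normal(0.0, config.purity_effect_sd, size=len(global_rows))
    g_values += np.outer(g_slopes, purity_c)
    kin_planted_mask = np.array([r in planted_kinases for r in global_rows])
    g_values[kin_planted_mask] += config.effect_size_kinase * high

    p_values = rng.normal(0.0, config.noise_sd, size=(len(ks_table), n))
    p_slopes = rng.normal(0.0, config.purity_effect_sd, size=len(ks_table))
    p_values += np.outer(p_slopes, purity_c)
    site_planted_mask = ks_table["kinase"].isin(planted_kinases).to_numpy()
    p_values[site_planted_mask] += config.effect_size_substrate * high

    if config.missing_rate > 0:
        g_values[rng.random(g_values.shape) < config.missing_rate] = np.nan
        p_values[rng.random(p_values.shape) < config.missing_rate] = np.nan

    global_matrix = pd.DataFrame(g_values, index=pd.Index(global_rows, name="feature_id"), columns=samples)
    phospho_matrix = pd.DataFrame(
        p_values, index=pd.Index(ks_table["site"], name="feature_id"), columns=samples
    )
    planted_pairs = {
        f"{k}::{s}" for k, s in zip(ks_table["kinase"], ks_table["site"])
        if k in planted_kinases
    }
    truth = GroundTruth(
        true_wgii=pd.Series(dtype=np.float64),
        true_group=groups,
        planted_pairs=planted_pairs,
        true_effects={
            p: (config.effect_size_kinase, config.effect_size_substrate) for p in planted_pairs
        },
    )
    return global_matrix, phospho_matrix, ks_table.drop(columns="site"), truth


@dataclass
class SimulatedCohort:
    """Everything one simulated cohort consists of."""

    config: SimulationConfig
    profiles: list[SegmentProfile]
    clinical: pd.DataFrame
    global_matrix: pd.DataFrame
    phospho_matrix: pd.DataFrame
    ks_table: pd.DataFrame
    truth: GroundTruth


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the three generators in sequence off one seeded stream."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles, true_wgii = gen_segments(config, rng)
    clinical = gen_survival(true_wgii, config, rng)
    groups = pd.Series(
        np.where(true_wgii > config.true_cutoff, "high", "low"), index=true_wgii.index
    )
    global_matrix, phospho_matrix, ks_table, truth = gen_omics(
        config, groups, purity=clinical["purity"], rng=rng
    )
    truth.true_wgii = true_wgii
    return SimulatedCohort(
        config=config,
        profiles=profiles,
        clinical=clinical,
        global_matrix=global_matrix,
        phospho_matrix=phospho_matrix,
        ks_table=ks_table,
        truth=truth,
    )
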