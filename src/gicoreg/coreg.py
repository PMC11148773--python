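"""Two-dimensional kinase-substrate co-regulation model.

Each kinase-substrate relation links a kinase protein (quantified in the
global proteome) to a phosphosite on a substrate protein (quantified at
site-level resolution in the phosphoproteome). For every retained pair a
two-dimensional statistic Z = (Zk, Zs) is formed from the purity-adjusted
moderated t-statistics of the kinase protein and of the substrate site
between the two sample groups (e.g. high vs. low wGII).

The observed Z cloud is modelled as a two-component mixture

    f(Z) = p0 * f0(Z) + p1 * f1(Z),        p0 + p1 = 1,

where f0 is the null density of non-co-regulated pairs, estimated
empirically by recomputing Z under random permutations of the group labels
(one shared permutation per iteration for both matrices, purity staying
attached to its sample, so the kinase-substrate dependence is preserved
under the null). Densities f and f0 are 2D kernel density estimates; the
null proportion is read off at the origin, p0 = f(0,0) / f0(0,0), because
a pair with no effect in either coordinate concentrates there. Per pair,

    fdr(Z) = p0 * f0(Z) / f(Z)      (local false discovery rate)
    p1(Z)  = 1 - fdr(Z)             (posterior probability of co-regulation)

Significant co-regulated pairs are those passing a local-fdr threshold
together with minimum absolute log2 fold changes on both coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import KernelDensity

from .diffexpr import DesignSpec, fit_linear_model, moderate
from .errors import EmptyResultError, ValidationError

#: Features with this many or more missing samples are excluded ("missing
#: data in fewer than 6 samples" retained).
DEFAULT_MAX_MISSING = 6

DENSITY_FLOOR = 1e-12


def site_id(substrate: str, residue: str, position: int) -> str:
    """Canonical phosphosite identifier: protein, residue letter, position."""
    return f"{substrate}_{residue}{int(position)}"


@dataclass
class PairedData:
    """Kinase-substrate pairs joined to their quantified feature vectors."""

    pairs: pd.DataFrame  # index pair_id; columns kinase, site, substrate, residue, position
    global_matrix: pd.DataFrame  # unique retained kinase proteins x samples
    phospho_matrix: pd.DataFrame  # unique retained substrate sites x samples
    filter_counts: dict[str, int] = field(default_factory=dict)

    @property
    def sample_ids(self) -> pd.Index:
        return self.global_matrix.columns

    def __len__(self) -> int:
        return len(self.pairs)


def build_pairs(
    ks_table: pd.DataFrame,
    global_matrix: pd.DataFrame,
    phospho_matrix: pd.DataFrame,
    max_missing: int = DEFAULT_MAX_MISSING,
) -> PairedData:
    """Join relation rows to quantified kinases and sites, filter missingness.

    A pair is retained when its kinase protein and its substrate site are
    both quantified with missing values in fewer than ``max_missing``
    samples. Per-filter counts are recorded; a non-empty relation table that
    reduces to zero retained pairs raises :class:`EmptyResultError`.
    """
    required = {"kinase", "substrate", "residue", "position"}
    if not required.issubset(ks_table.columns):
        raise ValidationError(f"kinase-substrate table needs columns {sorted(required)}")
    if set(global_matrix.columns) != set(phospho_matrix.columns):
        raise ValidationError("global and phospho matrices must share sample ids")
    phospho_matrix = phospho_matrix[global_matrix.columns]

    counts: dict[str, int] = {"input_rows": len(ks_table)}
    tab = ks_table.copy()
    if "modification" in tab.columns:
        tab = tab[tab["modification"].astype(str).str.lower() == "phosphorylation"]
    counts["phosphorylation_rows"] = len(tab)
    tab = tab.drop_duplicates(subset=["kinase", "substrate", "residue", "position"])
    counts["unique_relations"] = len(tab)

    empty = PairedData(
        pairs=pd.DataFrame(columns=["kinase", "site", "substrate", "residue", "position"]),
        global_matrix=global_matrix.iloc[:0],
        phospho_matrix=phospho_matrix.iloc[:0],
        filter_counts=counts,
    )
    if len(tab) == 0 and counts["input_rows"] == 0:
        return empty

    tab = tab.assign(
        site=[site_id(s, r, p) for s, r, p in zip(tab["substrate"], tab["residue"], tab["position"])]
    )
    tab = tab[tab["kinase"].isin(global_matrix.index)]
    counts["kinase_quantified"] = len(tab)
    tab = tab[tab["site"].isin(phospho_matrix.index)]
    counts["site_quantified"] = len(tab)

    n_missing_kin = global_matrix.isna().sum(axis=1)
    n_missing_site = phospho_matrix.isna().sum(axis=1)
    ok_kin = set(n_missing_kin.index[n_missing_kin < max_missing])
    ok_site = set(n_missing_site.index[n_missing_site < max_missing])
    tab = tab[tab["kinase"].isin(ok_kin)]
    counts["kinase_missingness_pass"] = len(tab)
    tab = tab[tab["site"].isin(ok_site)]
    counts["retained_pairs"] = len(tab)

    if len(tab) == 0:
        if counts["input_rows"] > 0:
            raise EmptyResultError("no kinase-substrate pair retained", counts)
        return empty

    tab = tab.reset_index(drop=True)
    tab.index = pd.Index(
        [f"{k}::{s}" for k, s in zip(tab["kinase"], tab["site"])], name="pair_id"
    )
    kinases = pd.Index(pd.unique(tab["kinase"]))
    sites = pd.Index(pd.unique(tab["site"]))
    return PairedData(
        pairs=tab[["kinase", "site", "substrate", "residue", "position"]],
        global_matrix=global_matrix.loc[kinases],
        phospho_matrix=phospho_matrix.loc[sites],
        filter_counts=counts,
    )


def moderation_priors(
    paired: PairedData, groups: pd.Series, purity: pd.Series
) -> dict[str, tuple[float, float]]:
    """Variance-prior hyperparameters (d0, s0^2) per matrix, from the
    observed labelling (where real effects are absorbed by the group term)."""
    design = DesignSpec(group=groups.loc[paired.sample_ids], purity=purity, mode="groups")
    res_k = moderate(fit_linear_model(paired.global_matrix, design, min_obs_per_level=2))
    res_s = moderate(fit_linear_model(paired.phospho_matrix, design, min_obs_per_level=2))
    return {
        "kinase": (res_k.df_prior, res_k.s2_prior),
        "site": (res_s.df_prior, res_s.s2_prior),
    }


def compute_z(
    paired: PairedData,
    groups: pd.Series,
    purity: pd.Series,
    priors: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-pair 2D statistics (Zk, Zs) with their log2 fold changes.

    The moderated fit runs once per unique kinase protein and once per
    unique substrate site (not per pair); the moderation pools variances
    within each matrix. ``priors`` fixes the (d0, s0^2) hyperparameters per
    matrix instead of re-estimating them (see :func:`moderation_priors`).
    Pairs whose kinase or site fails the fit are dropped. Returns a frame
    indexed by pair id with columns kinase, site, Zk, Zs, lfc_k, lfc_s.
    """
    if len(paired) == 0:
        return pd.DataFrame(columns=["kinase", "site", "Zk", "Zs", "lfc_k", "lfc_s"])
    design = DesignSpec(group=groups.loc[paired.sample_ids], purity=purity, mode="groups")
    pk = priors.get("kinase", (None, None)) if priors else (None, None)
    ps = priors.get("site", (None, None)) if priors else (None, None)
    res_k = moderate(
        fit_linear_model(paired.global_matrix, design, min_obs_per_level=2),
        prior_df=pk[0], prior_s2=pk[1],
    )
    res_s = moderate(
        fit_linear_model(paired.phospho_matrix, design, min_obs_per_level=2),
        prior_df=ps[0], prior_s2=ps[1],
    )
    zk = res_k.table[["t_mod", "log2fc"]].rename(columns={"t_mod": "Zk", "log2fc": "lfc_k"})
    zs = res_s.table[["t_mod", "log2fc"]].rename(columns={"t_mod": "Zs", "log2fc": "lfc_s"})
    out = paired.pairs[["kinase", "site"]].join(zk, on="kinase").join(zs, on="site")
    return out.dropna(subset=["Zk", "Zs"])


def permutation_null(
    paired: PairedData,
    groups: pd.Series,
    purity: pd.Series,
    n_perm: int = 200,
    seed: int | None = None,
) -> np.ndarray:
    """Pooled null sample of (Zk, Zs) from group-label permutations.

    Each iteration applies one shared random permutation of the group labels
    over samples (kinase and substrate matrices see the same permutation;
    purity is never permuted) and reruns the full moderated fit, including
    re-estimation of the variance-prior hyperparameters, exactly as on the
    observed labelling. A permutation that happens to reproduce the original
    labelling is kept. Returns an (n_perm * n_pairs, 2) array.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    samples = paired.sample_ids
    g = groups.loc[samples].to_numpy()
    pooled = []
    for _ in range(n_perm):
        perm = rng.permutation(len(samples))
        g_perm = pd.Series(g[perm], index=samples)
        z = compute_z(paired, g_perm, purity)
        pooled.append(z[["Zk", "Zs"]].to_numpy(dtype=np.float64))
    return np.concatenate(pooled, axis=0)


class ProductKDE:
    """Product-Gaussian kernel density estimate with per-dimension Scott bandwidth.

    Each dimension is scaled by its own bandwidth h_i = sd_i * n^(-1/(d+4))
    (optionally multiplied by ``factor``); evaluation divides out the
    Jacobian so densities are on the original scale.
    """

    def __init__(self, factor: float = 1.0):
        self.factor = float(factor)

    def fit(self, X: np.ndarray, bandwidths: np.ndarray | None = None) -> "ProductKDE":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or len(X) < 2:
            raise ValidationError("KDE needs a 2D array with at least 2 points")
        n, d = X.shape
        if bandwidths is None:
            sd = X.std(axis=0, ddof=1)
            if np.any(sd <= 0):
                raise ValidationError("degenerate (zero-variance) sample for density estimation")
            bandwidths = sd * n ** (-1.0 / (d + 4)) * self.factor
        self.bandwidths_ = np.asarray(bandwidths, dtype=np.float64)
        self._jacobian = float(np.prod(self.bandwidths_))
        self._kde = KernelDensity(kernel="gaussian", bandwidth=1.0, rtol=1e-8)
        self._kde.fit(X / self.bandwidths_)
        return self

    def evaluate(self, query: np.ndarray) -> np.ndarray:
        query = np.atleast_2d(np.asarray(query, dtype=np.float64))
        log_dens = self._kde.score_samples(query / self.bandwidths_)
        return np.exp(log_dens) / self._jacobian


@dataclass
class MixtureFit:
    """Fitted 2D null/alternative mixture with per-pair posteriors."""

    p0: float  # null proportion, clipped to (0, 1]
    p0_raw: float  # unclipped density ratio at the origin
    table: pd.DataFrame  # index pair_id; columns p1, fdr
    f: ProductKDE
    f0: ProductKDE
    n_null: int

    @property
    def p1(self) -> float:
        return 1.0 - self.p0


def fit_mixture(
    zpairs: pd.DataFrame,
    null_z: np.ndarray,
    bandwidth_factor: float = 1.0,
    max_null_points: int = 100_000,
    seed: int | None = None,
    min_pairs: int = 100,
    min_null: int = 1_000,
) -> MixtureFit:
    """Deconvolve observed Z pairs into null and co-regulated components.

    ``zpairs`` must carry columns Zk and Zs; ``null_z`` is the pooled
    permutation sample. The pooled null is subsampled (seeded) to at most
    ``max_null_points`` before density fitting. A density floor guards the
    division by f(Z); fdr is clipped to [0, 1] and p1 = 1 - fdr, so the two
    always sum to one.
    """
    Z = zpairs[["Zk", "Zs"]].to_numpy(dtype=np.float64)
    null_z = np.asarray(null_z, dtype=np.float64)
    if len(Z) < min_pairs:
        raise ValidationError(f"need at least {min_pairs} observed pairs, got {len(Z)}")
    if len(null_z) < min_null:
        raise ValidationError(f"need at least {min_null} null points, got {len(null_z)}")
    if len(null_z) > max_null_points:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(null_z), size=max_null_points, replace=False)
        null_z = null_z[np.sort(keep)]
    # One shared kernel for both densities: the mixture's alternative
    # component inflates the observed spread, so Scott bandwidths computed on
    # the observed sample would oversmooth f relative to f0 and bias the
    # density ratio at the origin. The per-dimension scale is taken from the
    # (cleaner, larger) null sample; the Scott factor uses the observed
    # sample size, since the variance of the ratio is dominated by f.
    sd0 = null_z.std(axis=0, ddof=1)
    if np.any(sd0 <= 0):
        raise ValidationError("degenerate (zero-variance) null sample for density estimation")
    shared_bw = sd0 * len(Z) ** (-1.0 / 6.0) * bandwidth_factor
    f0 = ProductKDE(bandwidth_factor).fit(null_z, bandwidths=shared_bw)
    f = ProductKDE(bandwidth_factor).fit(Z, bandwidths=shared_bw)
    origin = np.zeros((1, 2))
    f_00 = float(f.evaluate(origin)[0])
    f0_00 = float(f0.evaluate(origin)[0])
    p0_raw = f_00 / max(f0_00, DENSITY_FLOOR)
    p0 = float(min(max(p0_raw, DENSITY_FLOOR), 1.0))
    f_z = np.maximum(f.evaluate(Z), DENSITY_FLOOR)
    f0_z = f0.evaluate(Z)
    fdr = np.clip(p0 * f0_z / f_z, 0.0, 1.0)
    table = pd.DataFrame({"p1": 1.0 - fdr, "fdr": fdr}, index=zpairs.index)
    return MixtureFit(p0=p0, p0_raw=float(p0_raw), table=table, f=f, f0=f0, n_null=len(null_z))


def significant_pairs(
    fit: MixtureFit,
    zpairs: pd.DataFrame,
    fdr_max: float = 0.05,
    lfc_k_min: float = 0.05,
    lfc_s_min: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Filter to significantly co-regulated pairs and count substrates per kinase.

    Retains pairs with local fdr below ``fdr_max`` and absolute kinase /
    substrate-site log2 fold changes above ``lfc_k_min`` / ``lfc_s_min``.
    The table is sorted by fdr, then |Zk|+|Zs| descending; the companion
    Series counts significant phosphorylation events per kinase (node sizes
    for a co-regulation network rendering).
    """
    merged = zpairs.join(fit.table, how="inner")
    keep = (
        (merged["fdr"] < fdr_max)
        & (merged["lfc_k"].abs() > lfc_k_min)
        & (merged["lfc_s"].abs() > lfc_s_min)
    )
    out = merged[keep].copy()
    out["_zsum"] = out["Zk"].abs() + out["Zs"].abs()
    out = out.sort_values(["fdr", "_zsum"], ascending=[True, False]).drop(columns="_zsum")
    per_kinase = out.groupby("kinase").size().sort_values(ascending=False)
    per_kinase.name = "n_significant_substrates"
    return out, per_kinase
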