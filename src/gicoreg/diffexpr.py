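"""Purity-adjusted differential expression with empirical-Bayes moderation.

Per feature (protein, phosphosite, glycosite, transcript) an ordinary
least-squares model is fitted on the observed samples only:

* between-groups mode:  value ~ intercept + group + purity, where the group
  coefficient is the log2 fold change between the two groups;
* tumor-vs-normal mode: value ~ intercept + purity, exploiting that normal
  tissue has purity zero, so the purity coefficient captures the
  tumor-associated effect.

Residual variances are then shrunk toward a common prior estimated across
features by matching moments of log residual variances (a scaled inverse
chi-square prior with df d0 and scale s0^2; digamma/trigamma method of
moments). The moderated t-statistic divides each coefficient by its
posterior standard error and is referred to t with d + d0 degrees of
freedom. Multiple testing is controlled by Benjamini-Hochberg step-up.

The module also provides the PTM-on-protein residual normalization (each
site's intensities regressed on its parent protein's global abundance, with
the residuals taken as normalized PTM signal) and the metagene score
(per-gene z-standardization followed by a per-sample mean over a gene set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDesignError, EmptyInputError, ValidationError

MODES = ("groups", "tumor-normal")


@dataclass
class DesignSpec:
    """Sample-level design: two-level grouping, purity covariate, and mode.

    The group coefficient is test level minus reference. The test level is
    ``test_level`` if given, else 'high' or 'tumor' when present, else the
    second level in sorted order.
    """

    group: pd.Series
    purity: pd.Series
    mode: str = "groups"
    test_level: str | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        self.group = pd.Series(self.group).astype(str)
        self.purity = pd.Series(self.purity, dtype=np.float64).loc[self.group.index]
        levels = sorted(map(str, pd.unique(self.group)))
        if len(levels) != 2:
            raise DegenerateDesignError(f"design needs exactly 2 group levels, got {levels}")
        if self.purity.isna().any():
            raise ValidationError("purity must be present for all samples")
        if ((self.purity < 0) | (self.purity > 1)).any():
            raise ValidationError("purity must lie in [0, 1]")
        if self.test_level is None:
            preferred = [c for c in ("high", "tumor") if c in levels]
            self.test_level = preferred[0] if preferred else levels[1]
        elif self.test_level not in levels:
            raise ValidationError(f"test_level {self.test_level!r} not among levels {levels}")
        self.levels = tuple(levels)

    def design_matrix(self, sample_ids) -> tuple[np.ndarray, int]:
        """Return (X, index of the effect coefficient) for the given samples."""
        g = self.group.loc[sample_ids]
        purity = self.purity.loc[sample_ids].to_numpy()
        n = len(g)
        if self.mode == "groups":
            X = np.column_stack([np.ones(n), (g == self.test_level).to_numpy(float), purity])
            return X, 1
        X = np.column_stack([np.ones(n), purity])
        return X, 1


@dataclass
class LinearFitResult:
    """Per-feature OLS summaries feeding the empirical-Bayes moderation."""

    feature_ids: pd.Index
    coef: np.ndarray  # effect coefficient (log2 fold change)
    stdev_unscaled: np.ndarray  # sqrt of (X'X)^-1 diagonal for the effect
    sigma2: np.ndarray  # residual variance
    df_residual: np.ndarray
    n_obs: np.ndarray
    dropped: pd.DataFrame  # feature, reason


def fit_linear_model(
    matrix: pd.DataFrame, design: DesignSpec, min_obs_per_level: int = 3
) -> LinearFitResult:
    """Ordinary least squares per feature on observed samples only.

    ``matrix`` is features x samples on the log2 scale with NaN for missing.
    Features with fewer than ``min_obs_per_level`` observed samples per
    design level (or a singular observed design) are excluded and listed in
    ``dropped`` rather than failing the whole fit.
    """
    samples = matrix.columns
    X, effect_ix = design.design_matrix(samples)
    n, p = X.shape
    Y = matrix.to_numpy(dtype=np.float64)
    M = np.isfinite(Y)
    Y0 = np.where(M, Y, 0.0)

    # admissibility per feature
    n_obs = M.sum(axis=1)
    ok = n_obs >= p + 1
    reasons = np.where(ok, "", "too_few_observations")
    if design.mode == "groups":
        high = X[:, effect_ix] > 0.5
        n_high = (M & high).sum(axis=1)
        n_low = (M & ~high).sum(axis=1)
        bad_level = ok & ((n_high < min_obs_per_level) | (n_low < min_obs_per_level))
        reasons = np.where(bad_level, "level_underrepresented", reasons)
        ok &= ~bad_level

    Mf = M[ok].astype(np.float64)
    Xty = np.einsum("ip,fi->fp", X, Mf * Y0[ok])
    XtX = np.einsum("ip,fi,iq->fpq", X, Mf, X)
    # singular observed designs (e.g. constant purity among observed samples)
    dets = np.linalg.det(XtX)
    nonsing = np.abs(dets) > 1e-10
    if not nonsing.all():
        idx = np.flatnonzero(ok)
        reasons[idx[~nonsing]] = "singular_design"
        ok[idx[~nonsing]] = False
        Mf, Xty, XtX = Mf[nonsing], Xty[nonsing], XtX[nonsing]

    XtX_inv = np.linalg.inv(XtX)
    beta = np.einsum("fpq,fq->fp", XtX_inv, Xty)
    fitted = beta @ X.T  # f x n
    resid = (Y0[ok] - fitted) * Mf
    rss = np.einsum("fi,fi->f", resid, resid)
    df_resid = Mf.sum(axis=1) - p
    sigma2 = rss / df_resid

    return LinearFitResult(
        feature_ids=matrix.index[ok],
        coef=beta[:, effect_ix],
        stdev_unscaled=np.sqrt(XtX_inv[:, effect_ix, effect_ix]),
        sigma2=sigma2,
        df_residual=df_resid,
        n_obs=n_obs[ok],
        dropped=pd.DataFrame(
            {"feature": matrix.index[~ok], "reason": reasons[~ok]}
        ).reset_index(drop=True),
    )


def _trigamma_inverse(y: float, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the nearly-linear 1/trigamma)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(sigma2, df) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse chi-square variance prior.

    Models s^2 ~ s0^2 * F(df, d0) and matches the mean and variance of
    log s^2 using digamma/trigamma identities. Returns (d0, s0^2); d0 may be
    inf when the observed log-variances are no more dispersed than sampling
    alone explains (complete pooling).
    """
    s2 = np.asarray(sigma2, dtype=np.float64)
    d = np.asarray(df, dtype=np.float64)
    keep = (s2 > 0) & (d > 0)
    s2, d = s2[keep], d[keep]
    if len(s2) < 2:
        raise ValidationError("need at least 2 positive residual variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = np.sum((e - emean) ** 2) / (len(e) - 1) - np.mean(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s20 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s20 = float(np.exp(emean))
    return float(d0), s20


@dataclass
class ModeratedResult:
    """Moderated statistics per feature plus the shared variance prior."""

    table: pd.DataFrame  # log2fc, t_mod, p_mod, q_mod, df_residual
    df_prior: float
    s2_prior: float
    dropped: pd.DataFrame


def moderate(
    fit: LinearFitResult,
    prior_df: float | None = None,
    prior_s2: float | None = None,
) -> ModeratedResult:
    """Empirical-Bayes moderated t-statistics from per-feature OLS fits.

    ``prior_df`` overrides the estimated prior degrees of freedom d0:
    0 reproduces the ordinary per-feature t-test, inf pools all features to
    the common prior variance; ``prior_s2`` likewise fixes s0^2 (used to hold
    the hyperparameters constant across permutation refits). The posterior
    variance is the df-weighted blend (d0*s0^2 + d*s^2) / (d0 + d).
    """
    if len(fit.feature_ids) == 0:
        raise EmptyInputError("no features survived the linear fit")
    if prior_df is None and prior_s2 is None:
        d0, s20 = estimate_variance_prior(fit.sigma2, fit.df_residual)
    else:
        d0 = float(prior_df) if prior_df is not None else None
        s20 = float(prior_s2) if prior_s2 is not None else None
        if d0 is not None and d0 < 0:
            raise ValidationError("prior_df must be >= 0")
        if d0 is None or (s20 is None and d0 != 0):
            d0_est, s20_est = estimate_variance_prior(fit.sigma2, fit.df_residual)
            d0 = d0_est if d0 is None else d0
            s20 = s20_est if s20 is None else s20
        if s20 is None:
            s20 = float(np.nan)  # prior scale is irrelevant without shrinkage
    d = fit.df_residual
    if np.isinf(d0):
        s2_post = np.full_like(fit.sigma2, s20)
        df_total = np.full_like(d, np.inf)
    elif d0 == 0:
        s2_post = fit.sigma2.copy()
        df_total = d.astype(np.float64)
    else:
        s2_post = (d0 * s20 + d * fit.sigma2) / (d0 + d)
        df_total = d + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = fit.coef / (np.sqrt(s2_post) * fit.stdev_unscaled)
    p_mod = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_mod = np.clip(p_mod, np.finfo(float).tiny, 1.0)
    q_mod = adjust_bh(p_mod)
    table = pd.DataFrame(
        {
            "log2fc": fit.coef,
            "t_mod": t_mod,
            "p_mod": p_mod,
            "q_mod": q_mod,
            "df_residual": d,
        },
        index=fit.feature_ids,
    )
    return ModeratedResult(table=table, df_prior=float(d0), s2_prior=float(s20), dropped=fit.dropped)


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def normalize_ptm(
    ptm: pd.DataFrame,
    global_matrix: pd.DataFrame,
    site_to_protein: dict[str, str],
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residual normalization of PTM intensities on parent-protein abundance.

    Per site, the PTM log2 ratios are regressed (simple linear regression)
    on the parent protein's global log2 ratios across samples observed in
    both; the residuals replace the PTM values. Samples missing in either
    matrix stay missing. Sites without a quantified parent protein, or with
    fewer than ``min_pairs`` paired observations, are passed through
    unchanged and flagged.

    Returns (residual matrix, flags) where flags has columns site, status in
    {normalized, no_parent, too_few_pairs}.
    """
    samples = ptm.columns
    common = [s for s in samples if s in global_matrix.columns]
    out = ptm.copy().astype(np.float64)
    flags = []
    gindex = global_matrix.index
    for site in ptm.index:
        protein = site_to_protein.get(site)
        if protein is None or protein not in gindex:
            flags.append((site, "no_parent"))
            continue
        y = ptm.loc[site, common].to_numpy(dtype=np.float64)
        x = global_matrix.loc[protein, common].to_numpy(dtype=np.float64)
        both = np.isfinite(y) & np.isfinite(x)
        if both.sum() < min_pairs:
            flags.append((site, "too_few_pairs"))
            continue
        xb, yb = x[both], y[both]
        xc = xb - xb.mean()
        denom = np.dot(xc, xc)
        slope = np.dot(xc, yb) / denom if denom > 0 else 0.0
        intercept = yb.mean() - slope * xb.mean()
        row = np.full(len(samples), np.nan)
        pos = [samples.get_loc(s) for s in np.asarray(common)[both]]
        row[pos] = yb - (intercept + slope * xb)
        out.loc[site] = row
        flags.append((site, "normalized"))
    return out, pd.DataFrame(flags, columns=["site", "status"])


def metagene_score(matrix: pd.DataFrame, gene_set) -> pd.Series:
    """Average per-gene z-score of a gene set, per sample.

    Each present gene is standardized across samples (mean 0, sd 1,
    NaN-aware); the metagene score of a sample is the mean of these
    z-scores over the genes present in the matrix.
    """
    present = [g for g in gene_set if g in matrix.index]
    if not present:
        raise EmptyInputError("no gene of the set is present in the matrix")
    sub = matrix.loc[present].astype(np.float64)
    mu = sub.mean(axis=1, skipna=True)
    sd = sub.std(axis=1, ddof=1, skipna=True)
    z = sub.sub(mu, axis=0).div(sd, axis=0)
    return z.mean(axis=0, skipna=True).rename("metagene_score")
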