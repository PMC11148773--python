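"""Survival machinery and the wGII cutoff search.

The high/low genome-instability groups are defined by dichotomizing the
per-sample wGII at the cutoff that minimizes the p-value of a Cox
proportional-hazards model on the group indicator, scanning a grid of
candidate cutoffs. The log-rank test and the Cox fit (Efron tie handling)
are delegated to lifelines; the partial-likelihood score test at beta=0 is
implemented directly, since for a binary covariate without ties it equals
the log-rank statistic and serves as a cross-check between the two routes.

Minimizing a p-value over a grid is anti-conservative by construction; the
search result therefore carries the full p-curve so the multiplicity is
visible (in practice a cutoff chosen this way should be validated on an
independent cohort).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import ConvergenceError, DegenerateDesignError, SearchFailureError, ValidationError

#: Clinical covariates adjusted for in the multivariate Cox models.
DEFAULT_COVARIATES = ("age", "gender", "race", "stage", "purity")


def _as_arrays(times, events):
    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events, dtype=np.int64)
    if t.shape != e.shape:
        raise ValidationError("times and events must have equal length")
    if (t < 0).any():
        raise ValidationError("negative survival time")
    if not np.isin(e, (0, 1)).all():
        raise ValidationError("events must be 0/1")
    return t, e


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    t, e = _as_arrays(times, events)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise DegenerateDesignError(f"log-rank test needs exactly 2 groups, got {len(levels)}")
    if e.sum() == 0:
        raise DegenerateDesignError("log-rank test needs at least one event")
    a = g == levels[0]
    res = _ll_logrank(t[a], t[~a], event_observed_A=e[a], event_observed_B=e[~a])
    return float(res.test_statistic), float(res.p_value)


def cox_score_test(times, events, covariate) -> tuple[float, float]:
    """Cox partial-likelihood score test of beta=0 for a single covariate.

    Uses the hypergeometric variance with the (n-d)/(n-1) tie correction,
    so for a binary covariate it reproduces the log-rank statistic exactly
    (including tied event times). Returns (chi-square statistic, p-value).
    """
    from scipy.stats import chi2

    t, e = _as_arrays(times, events)
    x = np.asarray(covariate, dtype=np.float64)
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    u = 0.0
    v = 0.0
    for tt in np.unique(t[e == 1]):
        at_risk = t >= tt
        n = at_risk.sum()
        dead = (t == tt) & (e == 1)
        d = dead.sum()
        xbar = x[at_risk].mean()
        u += x[dead].sum() - d * xbar
        if n > 1:
            s2 = np.mean((x[at_risk] - xbar) ** 2)  # population variance over risk set
            v += d * (n - d) / (n - 1) * s2
    if v <= 0:
        raise DegenerateDesignError("score test variance is zero (constant covariate?)")
    stat = u * u / v
    return float(stat), float(chi2.sf(stat, df=1))


@dataclass
class CoxResult:
    """Coefficients of a fitted Cox proportional-hazards model."""

    coefficients: pd.Series
    standard_errors: pd.Series
    wald_p: pd.Series
    n: int
    n_events: int

    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)


def cox_fit(times, events, covariates: pd.DataFrame) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) via partial likelihood.

    ``covariates`` is a numeric samples x covariates frame; categorical
    columns must be dummy-encoded by the caller (see
    :func:`encode_clinical_covariates`).
    """
    t, e = _as_arrays(times, events)
    X = covariates.reset_index(drop=True).astype(np.float64)
    if e.sum() == 0:
        raise DegenerateDesignError("Cox fit needs at least one event")
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise DegenerateDesignError(f"covariate {col!r} is constant")
    df = X.copy()
    df["_time"] = t
    df["_event"] = e
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except _LLConvergenceError as exc:  # pragma: no cover - pathological designs
        raise ConvergenceError(f"Cox fit did not converge: {exc}") from exc
    return CoxResult(
        coefficients=cph.params_.rename(None),
        standard_errors=cph.standard_errors_.rename(None),
        wald_p=cph.summary["p"].rename(None),
        n=len(t),
        n_events=int(e.sum()),
    )


def encode_clinical_covariates(
    clinical: pd.DataFrame, covariates=DEFAULT_COVARIATES
) -> pd.DataFrame:
    """Dummy-encode the requested clinical covariates for a Cox model."""
    cols = [c for c in covariates if c in clinical.columns]
    X = pd.get_dummies(clinical[cols], drop_first=True, dtype=np.float64)
    return X.astype(np.float64)


def assign_groups(wgii, cutoff: float) -> pd.Series:
    """Label samples 'high' iff wGII strictly exceeds the cutoff, else 'low'."""
    w = pd.Series(wgii, dtype=np.float64)
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    return pd.Series(np.where(w > cutoff, "high", "low"), index=w.index, name="wgii_group")


@dataclass
class CutoffSearchResult:
    """Outcome of the p-value-minimizing wGII cutoff scan."""

    grid: np.ndarray
    p_curve: np.ndarray
    chosen_cutoff: float
    group_sizes: tuple[int, int]  # (n_high, n_low) at the chosen cutoff
    adjusted: bool = False

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff": self.grid, "p": self.p_curve})


def find_wgii_cutoff(
    wgii,
    clinical: pd.DataFrame,
    grid_step: float = 0.01,
    min_group_fraction: float = 0.1,
    adjust: list[str] | None = None,
) -> CutoffSearchResult:
    """Scan candidate cutoffs and pick the one minimizing the Cox p-value.

    Candidates run from just above the observed minimum to just below the
    maximum of wGII in steps of ``grid_step``; a candidate is admissible only
    if both induced groups contain at least ``min_group_fraction`` of the
    cohort. The recorded p-value is the Wald p of the high/low indicator in
    a Cox model (univariate by default; ``adjust`` names clinical covariates
    to include). Ties on the minimal p are broken toward the more balanced
    split. The full p-curve is returned alongside the argmin.
    """
    w = pd.Series(wgii, dtype=np.float64)
    clinical = clinical.loc[w.index]
    t = clinical["time"].to_numpy(dtype=np.float64)
    e = clinical["event"].to_numpy(dtype=np.int64)
    n = len(w)
    lo, hi = float(w.min()), float(w.max())
    first = np.ceil(lo / grid_step + 1e-9) * grid_step
    candidates = np.round(np.arange(first, hi, grid_step), 10)
    candidates = candidates[(candidates > lo) & (candidates < hi)]

    X_adjust = None
    if adjust:
        X_adjust = encode_clinical_covariates(clinical, adjust)

    grid, p_curve, balance = [], [], []
    for c in candidates:
        high = (w > c).to_numpy()
        n_high = int(high.sum())
        n_low = n - n_high
        if min(n_high, n_low) < min_group_fraction * n:
            continue
        X = pd.DataFrame({"high_wgii": high.astype(np.float64)})
        if X_adjust is not None:
            X = pd.concat([X, X_adjust.reset_index(drop=True)], axis=1)
        try:
            res = cox_fit(t, e, X)
            p = float(res.wald_p.iloc[0])
        except (ConvergenceError, DegenerateDesignError):
            continue
        grid.append(float(c))
        p_curve.append(p)
        balance.append(abs(n_high - n_low))
    if not grid:
        raise SearchFailureError(
            "no admissible cutoff candidate (grid too coarse or groups too small)"
        )
    grid_arr = np.asarray(grid)
    p_arr = np.asarray(p_curve)
    pmin = p_arr.min()
    tied = np.flatnonzero(p_arr <= pmin * (1 + 1e-12))
    best = tied[int(np.argmin(np.asarray(balance)[tied]))] if len(tied) > 1 else tied[0]
    chosen = float(grid_arr[best])
    n_high = int((w > chosen).sum())
    return CutoffSearchResult(
        grid=grid_arr,
        p_curve=p_arr,
        chosen_cutoff=chosen,
        group_sizes=(n_high, n - n_high),
        adjusted=bool(adjust),
    )


def kaplan_meier_table(times, events, groups=None) -> pd.DataFrame:
    """Kaplan-Meier survival step function(s) as a tidy table.

    Returns columns group, time, survival, n_at_risk. With ``groups=None``
    a single curve labelled 'all' is produced.
    """
    from lifelines import KaplanMeierFitter

    t, e = _as_arrays(times, events)
    g = np.asarray(["all"] * len(t)) if groups is None else np.asarray(groups)
    frames = []
    for level in pd.unique(g):
        m = g == level
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m])
        sf = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        frames.append(
            pd.DataFrame(
                {
                    "group": level,
                    "time": sf.index.to_numpy(dtype=np.float64),
                    "survival": sf.to_numpy(dtype=np.float64),
                    "n_at_risk": at_risk.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
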