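"""Discrimination and reclassification metrics for risk scores.

AUROC is computed by midrank (Mann-Whitney) concordance with a DeLong
confidence interval by default; cutoff tables target specificities on a
grid and report likelihood ratios; IDI and continuous NRI compare two
probability predictors; decile odds ratios contrast score deciles
against the lowest; and phenotype associations regress traits on the
score with optional log transformation and covariate adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association.logistic import Z975, fit_logit
from .errors import ConfigError, DataError

__all__ = [
    "RocResult",
    "ReclassResult",
    "auroc",
    "cutoff_table",
    "idi_nri",
    "decile_or",
    "phenotype_association",
]


@dataclass
class RocResult:
    points: pd.DataFrame  # cutoff, fpr, tpr
    auroc: float
    ci95: tuple[float, float]
    n_cases: int
    n_controls: int
    ci_method: str
    degenerate: bool = False


def _midrank_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    """P(case score > control score) with ties counted 1/2, via midranks."""
    combined = np.concatenate([cases, controls])
    ranks = stats.rankdata(combined)
    n1, n0 = len(cases), len(controls)
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_variance(cases: np.ndarray, controls: np.ndarray, auc: float) -> float:
    n1, n0 = len(cases), len(controls)
    all_scores = np.concatenate([cases, controls])
    rank_all = stats.rankdata(all_scores)
    rank_cases = stats.rankdata(cases)
    rank_controls = stats.rankdata(controls)
    # structural components
    v10 = (rank_all[:n1] - rank_cases) / n0
    v01 = 1.0 - (rank_all[n1:] - rank_controls) / n1
    s10 = np.var(v10, ddof=1) if n1 > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n0 > 1 else 0.0
    return s10 / n1 + s01 / n0


def auroc(
    scores: np.ndarray | pd.Series,
    status: np.ndarray | pd.Series,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """Area under the ROC curve with a 95% confidence interval.

    The AUROC equals the probability that a random case outscores a
    random control (ties counted half). Constant scores return 0.5 with a
    degenerate-CI flag rather than an error.
    """
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=int)
    cases = scores[status == 1]
    controls = scores[status == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise DataError("need at least one case and one control")
    points = _roc_points(scores, status)
    if np.ptp(scores) == 0:
        return RocResult(points, 0.5, (float("nan"), float("nan")),
                         len(cases), len(controls), ci_method, degenerate=True)
    auc = _midrank_auc(cases, controls)
    if ci_method == "delong":
        var = _delong_variance(cases, controls, auc)
        half = Z975 * np.sqrt(var)
        ci = (max(0.0, auc - half), min(1.0, auc + half))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for i in range(n_boot):
            bc = rng.choice(cases, size=len(cases), replace=True)
            bn = rng.choice(controls, size=len(controls), replace=True)
            reps[i] = _midrank_auc(bc, bn)
        ci = tuple(np.quantile(reps, [0.025, 0.975]))
    else:
        raise ConfigError(f"unknown ci_method {ci_method!r}")
    return RocResult(points, auc, (float(ci[0]), float(ci[1])),
                     len(cases), len(controls), ci_method)


def _roc_points(scores: np.ndarray, status: np.ndarray) -> pd.DataFrame:
    cutoffs = np.unique(scores)[::-1]
    n1 = status.sum()
    n0 = len(status) - n1
    rows = [{"cutoff": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for c in cutoffs:
        pred = scores >= c
        rows.append(
            {
                "cutoff": float(c),
                "fpr": float(np.sum(pred & (status == 0)) / n0),
                "tpr": float(np.sum(pred & (status == 1)) / n1),
            }
        )
    return pd.DataFrame(rows)


def cutoff_table(
    scores: np.ndarray | pd.Series,
    status: np.ndarray | pd.Series,
    specificity_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Cutoffs achieving each target specificity, with likelihood ratios.

    For every target the smallest cutoff whose specificity is >= the
    target is chosen; achieved sensitivity/specificity are reported along
    with LR+ = sens/(1-spec) and LR- = (1-sens)/spec. An unattainable
    combination yields a row with sensitivity 0.
    """
    if specificity_grid is None:
        specificity_grid = np.round(np.arange(0.95, 1.0001, 0.01), 10)
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=int)
    cases = scores[status == 1]
    controls = scores[status == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise DataError("need at least one case and one control")
    candidates = np.concatenate([np.unique(scores), [np.inf]])
    spec_at = np.array([np.mean(controls < c) for c in candidates])
    sens_at = np.array([np.mean(cases >= c) for c in candidates])
    rows = []
    for target in specificity_grid:
        ok = np.flatnonzero(spec_at >= target - 1e-12)
        idx = ok[0]  # smallest qualifying cutoff (candidates sorted ascending)
        sens, spec = float(sens_at[idx]), float(spec_at[idx])
        lr_pos = sens / (1.0 - spec) if spec < 1.0 else float("inf") if sens > 0 else float("nan")
        lr_neg = (1.0 - sens) / spec if spec > 0 else float("nan")
        rows.append(
            {
                "target_specificity": float(target),
                "cutoff": float(candidates[idx]),
                "sensitivity": sens,
                "specificity": spec,
                "lr_pos": lr_pos,
                "lr_neg": lr_neg,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ReclassResult:
    idi: float
    nri: float
    p_up_event: float
    p_down_event: float
    p_up_nonevent: float
    p_down_nonevent: float


def idi_nri(
    p_old: np.ndarray | pd.Series,
    p_new: np.ndarray | pd.Series,
    status: np.ndarray | pd.Series,
) -> ReclassResult:
    """Integrated discrimination improvement and continuous (category-free)
    net reclassification improvement of p_new over p_old."""
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    status = np.asarray(status, dtype=int)
    for name, p in (("p_old", p_old), ("p_new", p_new)):
        if np.any((p < 0) | (p > 1)):
            raise DataError(f"{name} outside [0,1]")
    events = status == 1
    if not events.any() or events.all():
        raise DataError("need both events and non-events")
    d = p_new - p_old
    idi = float(d[events].mean() - d[~events].mean())
    up_e = float(np.mean(d[events] > 0))
    down_e = float(np.mean(d[events] < 0))
    up_n = float(np.mean(d[~events] > 0))
    down_n = float(np.mean(d[~events] < 0))
    nri = (up_e - down_e) + (down_n - up_n)
    return ReclassResult(idi, float(nri), up_e, down_e, up_n, down_n)


def decile_or(
    scores: np.ndarray | pd.Series,
    status: np.ndarray | pd.Series,
    basis: str = "all",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Odds ratio per score decile against the lowest decile.

    Decile boundaries come from the full analyzed sample by default
    (``basis='all'``) or from controls only (``basis='controls'``); ORs
    and Wald CIs come from a logistic regression on decile indicator
    variables. A decile with no cases or no controls is flagged.
    """
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=int)
    if basis == "all":
        ref_scores = scores
    elif basis == "controls":
        ref_scores = scores[status == 0]
    else:
        raise ConfigError(f"unknown basis {basis!r}")
    edges = np.quantile(ref_scores, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    bins = np.clip(np.searchsorted(edges, scores, side="right") - 1, 0, n_bins - 1)
    counts = pd.crosstab(bins, status).reindex(range(n_bins), fill_value=0)
    flagged = (counts.get(0, 0) == 0) | (counts.get(1, 0) == 0)
    X = np.column_stack(
        [np.ones(len(scores))] + [(bins == k).astype(float) for k in range(1, n_bins)]
    )
    fit = fit_logit(X, status)
    rows = [{
        "decile": 1,
        "or_": 1.0,
        "ci_low": 1.0,
        "ci_high": 1.0,
        "n_cases": int(counts.loc[0].get(1, 0)),
        "n_controls": int(counts.loc[0].get(0, 0)),
        "flagged": bool(flagged.loc[0]),
    }]
    for k in range(1, n_bins):
        beta, se = float(fit.params[k]), float(fit.bse[k])
        bad = fit.separation or not np.isfinite(beta)
        rows.append(
            {
                "decile": k + 1,
                "or_": float("nan") if bad else float(np.exp(beta)),
                "ci_low": float("nan") if bad else float(np.exp(beta - Z975 * se)),
                "ci_high": float("nan") if bad else float(np.exp(beta + Z975 * se)),
                "n_cases": int(counts.loc[k].get(1, 0)),
                "n_controls": int(counts.loc[k].get(0, 0)),
                "flagged": bool(flagged.loc[k]) or bad,
            }
        )
    return pd.DataFrame(rows)


def phenotype_association(
    grs: np.ndarray | pd.Series,
    trait: np.ndarray | pd.Series,
    family: str = "linear",
    covariates: np.ndarray | pd.DataFrame | None = None,
    transform: str = "none",
) -> dict:
    """Effect of the score on a clinical trait.

    ``family='linear'`` regresses the (optionally log-transformed) trait
    on the score; ``family='logistic'`` treats the trait as binary and
    reports an OR. Natural-log transformation refuses non-positive
    values, naming the offending rows.
    """
    grs = np.asarray(grs, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if transform == "log":
        bad = np.flatnonzero(trait <= 0)
        if bad.size:
            raise DataError(
                f"non-positive trait values under log transform at rows {bad[:10].tolist()}"
            )
        trait = np.log(trait)
    elif transform != "none":
        raise ConfigError(f"unknown transform {transform!r}")
    n = len(grs)
    cols = [np.ones(n), grs]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
    X = np.column_stack(cols)
    if family == "linear":
        res = sm.OLS(trait, X).fit()
        beta, se, p = float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])
        return {"family": "linear", "slope": beta, "se": se, "p": p}
    if family == "logistic":
        fit = fit_logit(X, trait.astype(int))
        beta, se = float(fit.params[1]), float(fit.bse[1])
        p = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else float("nan")
        return {
            "family": "logistic",
            "beta": beta,
            "or_": float(np.exp(beta)),
            "se": se,
            "p": p,
            "separation": fit.separation,
        }
    raise ConfigError(f"unknown family {family!r}")
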