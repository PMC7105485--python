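"""Additive logistic association and stepwise conditional scans."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ..errors import DataError

logger = logging.getLogger(__name__)

Z975 = 1.959964  # Phi^-1(0.975)

# |beta| beyond this on the log-odds scale is treated as quasi-complete
# separation (OR > 3e6); plain logistic MLEs this large are never real.
_SEPARATION_BETA = 15.0


@dataclass
class LogitFit:
    """Raw maximum-likelihood fit of a logistic model."""

    params: np.ndarray
    bse: np.ndarray
    llf: float
    converged: bool
    separation: bool


def fit_logit(X: np.ndarray, y: np.ndarray, maxiter: int = 100) -> LogitFit:
    """Fit P(y=1) = expit(X @ beta), flagging separation instead of raising."""
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=maxiter, warn_convergence=False)
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        separation = (
            not res.mle_retvals.get("converged", True)
            and bool(np.any(np.abs(params) > _SEPARATION_BETA))
        ) or bool(np.any(np.abs(params) > _SEPARATION_BETA))
        return LogitFit(params, bse, float(res.llf), bool(res.mle_retvals.get("converged", False)), separation)
    except (np.linalg.LinAlgError, PerfectSeparationError):
        k = X.shape[1]
        return LogitFit(np.full(k, np.nan), np.full(k, np.nan), np.nan, False, True)


@dataclass
class AssocResult:
    """Single-variant additive association estimate."""

    variant_id: str
    beta: float
    se: float
    p_wald: float
    n_cases: int
    n_controls: int
    df: int = 1
    p_lrt: float | None = None
    separation: bool = False
    conditioned_on: tuple[str, ...] = ()
    effect_allele: str | None = None

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - Z975 * self.se)),
            float(np.exp(self.beta + Z975 * self.se)),
        )


def _design(
    dosage: np.ndarray,
    covariates: np.ndarray | None,
    conditioning: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """(full design with dosage in column 1, reduced design without it)."""
    n = len(dosage)
    cols = [np.ones(n), np.asarray(dosage, dtype=float)]
    reduced = [np.ones(n)]
    for block in (conditioning, covariates):
        if block is not None:
            block = np.atleast_2d(np.asarray(block, dtype=float))
            if block.shape[0] != n:
                block = block.T
            cols.extend(block.T)
            reduced.extend(block.T)
    return np.column_stack(cols), np.column_stack(reduced)


def fit_additive_logistic(
    dosage: np.ndarray | pd.Series,
    status: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
    conditioning: np.ndarray | pd.DataFrame | None = None,
    variant_id: str = "variant",
    conditioned_on: Sequence[str] = (),
    lrt: bool = False,
) -> AssocResult:
    """Additive-coding logistic association of one dosage column.

    The model is status ~ intercept + dosage + conditioning + covariates;
    Wald p comes from beta/se, and an LRT p against the dosage-free model
    is added when ``lrt=True``. Separation is detected and flagged on the
    result (beta/se set to NaN for complete separation), never silently
    returned as a finite estimate.
    """
    dosage = np.asarray(dosage, dtype=float)
    status = np.asarray(status, dtype=int)
    n_cases = int(status.sum())
    n_controls = int(len(status) - n_cases)
    if n_cases == 0 or n_controls == 0:
        raise DataError("need at least one case and one control")
    if np.var(dosage) == 0:
        raise DataError(f"{variant_id}: dosage has zero variance")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
    if conditioning is not None:
        conditioning = np.asarray(conditioning, dtype=float)
    X_full, X_red = _design(dosage, covariates, conditioning)
    fit = fit_logit(X_full, status)
    beta, se = float(fit.params[1]), float(fit.bse[1])
    if fit.separation or not np.isfinite(beta) or not np.isfinite(se) or se == 0:
        return AssocResult(
            variant_id, float("nan"), float("nan"), float("nan"),
            n_cases, n_controls, separation=True,
            conditioned_on=tuple(conditioned_on),
        )
    p_wald = float(2.0 * stats.norm.sf(abs(beta / se)))
    p_wald = max(p_wald, np.nextafter(0, 1))
    p_lrt = None
    if lrt:
        fit0 = fit_logit(X_red, status)
        dev = 2.0 * (fit.llf - fit0.llf)
        p_lrt = float(stats.chi2.sf(max(dev, 0.0), 1))
    return AssocResult(
        variant_id, beta, se, p_wald, n_cases, n_controls,
        p_lrt=p_lrt, conditioned_on=tuple(conditioned_on),
    )


@dataclass
class ConditionalStep:
    """One round of a greedy stepwise conditional scan."""

    selected: str
    scan: pd.DataFrame
    conditioned_on: tuple[str, ...] = ()


@dataclass
class ConditionalScanResult:
    steps: list[ConditionalStep] = field(default_factory=list)
    final_scan: pd.DataFrame | None = None

    @property
    def selected(self) -> list[str]:
        return [s.selected for s in self.steps]


def _scan_frame(results: Sequence[AssocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "p": [r.p_wald for r in results],
            "separation": [r.separation for r in results],
        }
    ).set_index("variant_id")


def conditional_scan(
    dosages: pd.DataFrame,
    status: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
    threshold: float = 5e-8,
    max_steps: int | None = None,
) -> ConditionalScanResult:
    """Greedy stepwise conditioning across the variants of one locus.

    Each round scans every unselected variant with the already-selected
    set entered as covariates; the smallest-p variant below ``threshold``
    joins the conditioning set. Stops when no variant qualifies. Variants
    perfectly collinear (r^2 = 1) with a selected variant are skipped.
    """
    if dosages.shape[1] < 1:
        raise DataError("conditional_scan needs at least one variant")
    status = np.asarray(status, dtype=int)
    selected: list[str] = []
    result = ConditionalScanResult()
    while max_steps is None or len(selected) < max_steps:
        cond = dosages[selected].to_numpy() if selected else None
        round_results: list[AssocResult] = []
        for vid in dosages.columns:
            if vid in selected:
                continue
            d = dosages[vid].to_numpy()
            if selected and _collinear(d, dosages[selected].to_numpy()):
                logger.info("skipping %s: collinear with conditioning set", vid)
                continue
            round_results.append(
                fit_additive_logistic(
                    d, status, covariates=covariates, conditioning=cond,
                    variant_id=vid, conditioned_on=tuple(selected),
                )
            )
        if not round_results:
            break
        scan = _scan_frame(round_results)
        best = scan["p"].idxmin()
        if not np.isfinite(scan.loc[best, "p"]) or scan.loc[best, "p"] >= threshold:
            result.final_scan = scan
            break
        result.steps.append(
            ConditionalStep(selected=str(best), scan=scan, conditioned_on=tuple(selected))
        )
        selected.append(str(best))
    else:
        result.final_scan = None
    if result.final_scan is None and (max_steps is None or len(selected) < dosages.shape[1]):
        # produce the fully conditioned scan when the loop broke by selection
        cond = dosages[selected].to_numpy() if selected else None
        leftovers = [
            fit_additive_logistic(
                dosages[vid].to_numpy(), status, covariates=covariates,
                conditioning=cond, variant_id=vid, conditioned_on=tuple(selected),
            )
            for vid in dosages.columns
            if vid not in selected
            and not (selected and _collinear(dosages[vid].to_numpy(), dosages[selected].to_numpy()))
        ]
        if leftovers:
            result.final_scan = _scan_frame(leftovers)
    return result


def _collinear(d: np.ndarray, selected: np.ndarray, tol: float = 1.0 - 1e-10) -> bool:
    sel = np.atleast_2d(selected.T)
    for col in sel:
        if np.std(col) == 0 or np.std(d) == 0:
            continue
        r = np.corrcoef(d, col)[0, 1]
        if r * r >= tol:
            return True
    return False
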