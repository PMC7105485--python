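"""Pairwise multiplicative interaction testing.

The screen enumerates the configured lead x HLA SNP pairs plus the
shared non-HLA pairs, applies a Bonferroni-corrected per-test threshold,
and tests each pair with a 1-df likelihood-ratio test of the product
term. Stratified genotype-combination grids report crude odds ratios per
dosage cell against a reference cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association.logistic import Z975, fit_logit
from .errors import DataError


@dataclass
class InteractionResult:
    variant_a: str
    variant_b: str
    beta_interaction: float
    se: float
    lrt_deviance: float
    p: float
    df: int = 1
    separation: bool = False

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta_interaction))


def interaction_lrt(
    dosage_a: np.ndarray | pd.Series,
    dosage_b: np.ndarray | pd.Series,
    status: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
    variant_a: str = "a",
    variant_b: str = "b",
) -> InteractionResult:
    """1-df LRT of the dosage-product term over the main-effects model."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    status = np.asarray(status, dtype=int)
    if np.var(a) == 0 or np.var(b) == 0:
        raise DataError("both dosages must have positive variance")
    n = len(status)
    base = [np.ones(n), a, b]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        base.extend(cov.T)
    X_red = np.column_stack(base)
    X_full = np.column_stack(base[:3] + [a * b] + base[3:])
    fit_full = fit_logit(X_full, status)
    fit_red = fit_logit(X_red, status)
    if fit_full.separation or fit_red.separation:
        return InteractionResult(
            variant_a, variant_b, float("nan"), float("nan"),
            float("nan"), float("nan"), separation=True,
        )
    deviance = max(0.0, 2.0 * (fit_full.llf - fit_red.llf))
    p = float(stats.chi2.sf(deviance, 1))
    return InteractionResult(
        variant_a, variant_b, float(fit_full.params[3]), float(fit_full.bse[3]),
        deviance, p,
    )


def enumerate_interaction_pairs(
    lead_snps: Sequence[str],
    hla_snps: Sequence[str],
    shared_pairs: Sequence[tuple[str, str]] = (),
) -> list[tuple[str, str]]:
    """Lead x HLA cross pairs plus explicit shared pairs, deduplicated."""
    pairs: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    for lead in lead_snps:
        for hla in hla_snps:
            key = frozenset((lead, hla))
            if key in seen:
                warnings.warn(f"duplicate interaction pair {lead}/{hla} dropped", stacklevel=2)
                continue
            seen.add(key)
            pairs.append((lead, hla))
    for a, b in shared_pairs:
        key = frozenset((a, b))
        if key in seen:
            warnings.warn(f"duplicate interaction pair {a}/{b} dropped", stacklevel=2)
            continue
        seen.add(key)
        pairs.append((a, b))
    return pairs


def interaction_screen(
    dosages: pd.DataFrame,
    status: np.ndarray | pd.Series,
    lead_snps: Sequence[str],
    hla_snps: Sequence[str],
    shared_pairs: Sequence[tuple[str, str]] = (),
    covariates: np.ndarray | pd.DataFrame | None = None,
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """Bonferroni-controlled multiplicative interaction screen.

    Returns a frame with one row per tested pair: pair, beta, se, p,
    threshold (= family_alpha / n_tests) and a significance flag.
    """
    pairs = enumerate_interaction_pairs(lead_snps, hla_snps, shared_pairs)
    missing = {v for pair in pairs for v in pair} - set(dosages.columns)
    if missing:
        raise DataError(f"dosages missing for: {sorted(missing)}")
    threshold = family_alpha / len(pairs)
    rows = []
    for a, b in pairs:
        res = interaction_lrt(
            dosages[a], dosages[b], status, covariates, variant_a=a, variant_b=b
        )
        rows.append(
            {
                "pair": f"{a}x{b}",
                "beta": res.beta_interaction,
                "se": res.se,
                "p": res.p,
                "threshold": threshold,
                "significant": bool(res.p < threshold) if np.isfinite(res.p) else False,
                "separation": res.separation,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GenotypeGrid:
    """3x3 case/control counts by hard-called dosage, with crude ORs."""

    cells: pd.DataFrame  # dosage_a, dosage_b, n_cases, n_controls, or_, ci_low, ci_high, flagged
    reference_cell: tuple[int, int]


def genotype_grid(
    dosage_a: np.ndarray | pd.Series,
    dosage_b: np.ndarray | pd.Series,
    status: np.ndarray | pd.Series,
    reference_cell: tuple[int, int] = (0, 0),
) -> GenotypeGrid:
    """Crude per-cell odds ratios against a reference genotype cell.

    Dosages are hard-called by rounding to 0/1/2. The crude OR for a cell
    is (cases_cell * controls_ref) / (controls_cell * cases_ref) with a
    Woolf 95% CI on the log scale; cells with a zero contrasted count are
    flagged with an undefined OR (no continuity correction).
    """
    a = np.clip(np.rint(np.asarray(dosage_a, dtype=float)), 0, 2).astype(int)
    b = np.clip(np.rint(np.asarray(dosage_b, dtype=float)), 0, 2).astype(int)
    status = np.asarray(status, dtype=int)
    ra, rb = reference_cell
    ref_cases = int(np.sum((a == ra) & (b == rb) & (status == 1)))
    ref_ctrls = int(np.sum((a == ra) & (b == rb) & (status == 0)))
    if ref_cases == 0 or ref_ctrls == 0:
        raise DataError(
            f"reference cell {reference_cell} empty in cases or controls"
        )
    rows = []
    for da in range(3):
        for db in range(3):
            n_cases = int(np.sum((a == da) & (b == db) & (status == 1)))
            n_ctrls = int(np.sum((a == da) & (b == db) & (status == 0)))
            if (da, db) == (ra, rb):
                or_, lo, hi, flagged = 1.0, 1.0, 1.0, False
            elif n_cases == 0 or n_ctrls == 0:
                or_, lo, hi, flagged = float("nan"), float("nan"), float("nan"), True
            else:
                or_ = (n_cases * ref_ctrls) / (n_ctrls * ref_cases)
                se = np.sqrt(1 / n_cases + 1 / n_ctrls + 1 / ref_cases + 1 / ref_ctrls)
                lo = float(np.exp(np.log(or_) - Z975 * se))
                hi = float(np.exp(np.log(or_) + Z975 * se))
                flagged = False
            rows.append(
                {
                    "dosage_a": da,
                    "dosage_b": db,
                    "n_cases": n_cases,
                    "n_controls": n_ctrls,
                    "or_": or_,
                    "ci_low": lo,
                    "ci_high": hi,
                    "flagged": flagged,
                }
            )
    return GenotypeGrid(cells=pd.DataFrame(rows), reference_cell=(ra, rb))
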