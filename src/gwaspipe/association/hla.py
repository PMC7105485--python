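"""Multi-allelic omnibus tests, QC filtering, and phased conditional
haplotype tests for amino-acid positions."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import DataError
from .logistic import fit_logit

__all__ = [
    "OmnibusResult",
    "hla_qc_filter",
    "omnibus_multiallelic",
    "conditional_haplotype_test",
    "stepwise_position_scan",
]


@dataclass
class OmnibusResult:
    """Likelihood-ratio test of a block of category terms.

    deviance = -2 x log likelihood ratio of the covariate-only (or
    conditioned) null against the full model; df counts the extra
    categories the full model introduces.
    """

    deviance: float
    df: int
    p: float
    reference: str
    collapsed: tuple[str, ...] = ()
    degenerate: bool = False


def hla_qc_filter(
    table: pd.DataFrame,
    maf_threshold: float = 0.01,
    r2_threshold: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain alleles with MAF strictly above ``maf_threshold`` and
    imputation R^2 strictly above ``r2_threshold``.

    ``table`` needs columns ``allele``, ``freq``, ``r2``. Returns
    (retained, dropped-with-reason). A missing R^2 is an error: an allele
    may never pass QC because its quality was simply not recorded.
    """
    for col in ("allele", "freq", "r2"):
        if col not in table.columns:
            raise DataError(f"QC table missing column {col!r}")
    if table["r2"].isna().any():
        bad = table.loc[table["r2"].isna(), "allele"].tolist()
        raise DataError(f"missing imputation R^2 for alleles: {bad}")
    maf = np.minimum(table["freq"], 1.0 - table["freq"])
    reasons = []
    for m, r2 in zip(maf, table["r2"]):
        why = []
        if not m > maf_threshold:
            why.append(f"MAF {m:.4g} <= {maf_threshold}")
        if not r2 > r2_threshold:
            why.append(f"R2 {r2:.4g} <= {r2_threshold}")
        reasons.append("; ".join(why))
    keep = np.array([not r for r in reasons])
    dropped = table.loc[~keep].copy()
    dropped["reason"] = [r for r in reasons if r]
    return table.loc[keep].copy(), dropped


def _block_lrt(
    full_block: pd.DataFrame,
    null_block: pd.DataFrame | None,
    status: np.ndarray,
    covariates: np.ndarray | None,
) -> float:
    """Deviance of (covariates + full_block) vs (covariates + null_block).

    The null block must lie in the span of the full block plus intercept
    (true for haplotype codings over nested position sets), so the models
    are nested even though the null columns are not physically reused.
    """
    n = len(status)
    base_cols = [np.ones(n)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        base_cols.extend(cov.T)
    null_cols = list(base_cols)
    if null_block is not None and null_block.shape[1] > 0:
        null_cols.extend(null_block.to_numpy().T)
    X_null = np.column_stack(null_cols)
    X_full = np.column_stack(base_cols + list(full_block.to_numpy().T))
    fit_full = fit_logit(X_full, status)
    fit_null = fit_logit(X_null, status)
    return max(0.0, 2.0 * (fit_full.llf - fit_null.llf))


def _category_dosages(dosages: pd.DataFrame) -> tuple[pd.DataFrame, str, tuple[str, ...]]:
    """Drop zero-variance categories and omit the most frequent as reference."""
    variances = dosages.var(axis=0)
    collapsed = tuple(str(c) for c in dosages.columns[variances == 0])
    if collapsed:
        warnings.warn(
            f"zero-variance categories collapsed into reference: {collapsed}",
            stacklevel=3,
        )
    usable = dosages.loc[:, variances > 0]
    if usable.shape[1] < 2:
        raise DataError("fewer than two variable categories; omnibus test undefined")
    reference = str(usable.mean(axis=0).idxmax())
    return usable.drop(columns=[reference]), reference, collapsed


def omnibus_multiallelic(
    allele_dosages: pd.DataFrame,
    status: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> OmnibusResult:
    """Joint LRT of all m-1 allele-dosage terms at a multi-allelic locus.

    The most frequent allele is omitted as the reference category (the
    choice is arbitrary and does not affect the deviance); the test
    compares the full model against covariates only, on m-1 degrees of
    freedom (reduced if zero-variance alleles had to be collapsed).
    """
    status = np.asarray(status, dtype=int)
    if allele_dosages.shape[1] < 2:
        raise DataError("omnibus test needs >=2 alleles")
    sums = allele_dosages.sum(axis=1)
    if (sums > 2.0 + 1e-6).any():
        raise DataError("per-individual allele dosages exceed 2")
    block, reference, collapsed = _category_dosages(allele_dosages)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
    deviance = _block_lrt(block, None, status, covariates)
    df = block.shape[1]
    p = float(stats.chi2.sf(deviance, df))
    return OmnibusResult(deviance, df, p, reference, collapsed)


def _haplotype_frame(
    residues: Mapping[int, np.ndarray], positions: Sequence[int]
) -> pd.DataFrame:
    """Per-individual counts (0-2) of each unique haplotype over positions."""
    if not positions:
        raise ValueError("positions must be non-empty")
    n = residues[positions[0]].shape[0]
    labels = np.empty((n, 2), dtype=object)
    for h in (0, 1):
        parts = [np.asarray(residues[p][:, h], dtype=object) for p in positions]
        combined = parts[0].astype(str)
        for part in parts[1:]:
            combined = np.char.add(np.char.add(combined.astype(str), "|"), part.astype(str))
        labels[:, h] = combined
    uniques = sorted(set(labels.ravel()))
    return pd.DataFrame(
        {u: (labels == u).sum(axis=1).astype(float) for u in uniques}
    )


def conditional_haplotype_test(
    residues: Mapping[int, np.ndarray],
    test_position: int,
    conditioned_positions: Sequence[int],
    status: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> OmnibusResult:
    """Test whether an amino-acid position adds information beyond the
    haplotypes already formed by the conditioned positions.

    Null model: unique phased haplotypes over ``conditioned_positions``
    (covariates only, if none). Full model: haplotypes over the
    conditioned positions plus ``test_position``. The LRT has
    k = (#unique full haplotypes) - (#unique null haplotypes) degrees of
    freedom; k = 0 (perfect LD with the conditioning set) yields a
    degenerate flagged result.
    """
    status = np.asarray(status, dtype=int)
    if test_position in conditioned_positions:
        raise DataError("test position already in the conditioning set")
    res = residues[test_position]
    if len(set(np.asarray(res, dtype=object).ravel())) < 2:
        raise DataError(f"position {test_position} is monomorphic")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)

    full_positions = sorted([*conditioned_positions, test_position])
    full = _haplotype_frame(residues, full_positions)
    if conditioned_positions:
        null = _haplotype_frame(residues, sorted(conditioned_positions))
        n_null = null.shape[1]
    else:
        null = None
        n_null = 1  # the empty haplotype: intercept only
    k = full.shape[1] - n_null
    if k <= 0:
        return OmnibusResult(0.0, 0, float("nan"), "", degenerate=True)

    # reference haplotype: most frequent in the full coding
    reference = str(full.mean(axis=0).idxmax())
    full_block = full.drop(columns=[reference])
    if null is not None:
        null_ref = str(null.mean(axis=0).idxmax())
        null_block = null.drop(columns=[null_ref])
    else:
        null_block = None
    deviance = _block_lrt(full_block, null_block, status, covariates)
    p = float(stats.chi2.sf(deviance, k))
    return OmnibusResult(deviance, k, p, reference)


def stepwise_position_scan(
    residues: Mapping[int, np.ndarray],
    status: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
    alpha: float = 5e-8,
    max_steps: int | None = None,
) -> list[tuple[int, OmnibusResult]]:
    """Greedy selection of independently associated amino-acid positions.

    Each round runs :func:`conditional_haplotype_test` for every
    unselected polymorphic position against the selected set and admits
    the smallest-p position if its p-value is below ``alpha``; stops at
    the first round where none qualifies.
    """
    status = np.asarray(status, dtype=int)
    polymorphic = [
        p
        for p in sorted(residues)
        if len(set(np.asarray(residues[p], dtype=object).ravel())) >= 2
    ]
    if not polymorphic:
        raise DataError("no polymorphic positions")
    selected: list[tuple[int, OmnibusResult]] = []
    chosen: list[int] = []
    while max_steps is None or len(chosen) < max_steps:
        best: tuple[int, OmnibusResult] | None = None
        for pos in polymorphic:
            if pos in chosen:
                continue
            result = conditional_haplotype_test(
                residues, pos, chosen, status, covariates
            )
            if result.degenerate:
                continue
            if best is None or result.p < best[1].p:
                best = (pos, result)
        if best is None or not np.isfinite(best[1].p) or best[1].p >= alpha:
            break
        selected.append(best)
        chosen.append(best[0])
    return selected
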