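"""Fixed-effects meta-analysis and genomic inflation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ..errors import DataError


@dataclass
class MetaResult:
    """Inverse-variance fixed-effects combination of k study estimates."""

    beta_fixed: float
    se_fixed: float
    p: float
    Q: float
    I2: float  # percent
    k_studies: int

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta_fixed))


def meta_fixed(
    betas: Sequence[float],
    ses: Sequence[float],
    effect_alleles: Sequence[str] | None = None,
) -> MetaResult:
    """Combine per-cohort estimates with inverse-variance weights.

    Heterogeneity is summarized by Cochran's Q (chi-square, k-1 df) and
    I^2 = max(0, (Q - (k-1)) / Q) * 100.

    ``effect_alleles``, if given, must be identical across cohorts:
    mismatched orientation is an input error, not something to fix
    silently here.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape or betas.ndim != 1:
        raise DataError("betas and ses must be 1-D and the same length")
    k = len(betas)
    if k < 2:
        raise DataError("meta-analysis needs at least two studies")
    if not np.all(np.isfinite(ses)) or np.any(ses <= 0):
        raise DataError("all standard errors must be finite and positive")
    if effect_alleles is not None and len(set(effect_alleles)) > 1:
        raise DataError(
            f"effect-allele orientation mismatch across cohorts "
            f"({sorted(set(effect_alleles))}); harmonize before meta-analysis"
        )
    w = ses**-2.0
    beta_fixed = float(np.sum(w * betas) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    z = beta_fixed / se_fixed
    p = float(2.0 * stats.norm.sf(abs(z)))
    Q = float(np.sum(w * (betas - beta_fixed) ** 2))
    I2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    return MetaResult(beta_fixed, se_fixed, p, Q, I2, k)


_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...


def genomic_lambda(
    p_values: Sequence[float],
    exclude: Sequence[bool] | None = None,
) -> float:
    """Genomic inflation factor: median association chi-square over the
    null chi-square median, after masking out excluded regions."""
    p = np.asarray(p_values, dtype=float)
    if exclude is not None:
        p = p[~np.asarray(exclude, dtype=bool)]
    if p.size == 0:
        raise DataError("no p-values left after exclusion")
    if p.size < 100:
        raise DataError(f"need >=100 p-values after exclusion, got {p.size}")
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)
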