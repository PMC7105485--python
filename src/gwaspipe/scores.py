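"""Published genetic and combined risk scores.

The genetic risk score (GRS) is a weighted sum of effect-allele dosages
plus weighted dosage-product interaction terms, Z-standardized against
an ethnically matched control distribution using fixed published
constants. The combined risk score (CRS) adds a weighted natural-log
antibody titer (with a +0.001 offset so zero titers remain defined) and
is likewise Z-standardized against controls.

Score definitions ship as versioned JSON (``data/score_definitions.json``)
and are stored at full published precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association.logistic import fit_logit
from .errors import ConfigError, DataError, NumericalError

__all__ = [
    "ScoreDefinition",
    "CrsCalibration",
    "LiabilityTransformSpec",
    "load_score_definition",
    "load_crs_calibration",
    "compute_grs",
    "derive_crs_weight",
    "compute_crs",
    "nagelkerke_r2",
    "liability_h2",
]


@dataclass(frozen=True)
class ScoreDefinition:
    """Weighted-dosage score with interaction terms and control standardization."""

    ethnicity: str
    terms: tuple[tuple[str, str, float], ...]  # (variant_id, effect_allele, weight)
    interactions: tuple[tuple[str, str, float], ...]  # (variant_a, variant_b, weight)
    control_mean: float
    control_sd: float

    def __post_init__(self) -> None:
        if not self.control_sd > 0:
            raise ConfigError("control_sd must be positive")
        for *_, w in [*self.terms, *self.interactions]:
            if not math.isfinite(w):
                raise ConfigError("score weights must be finite")

    @property
    def variant_ids(self) -> list[str]:
        return [vid for vid, _, _ in self.terms]


@dataclass(frozen=True)
class CrsCalibration:
    """Titer weight and control standardization for the combined score."""

    ethnicity: str
    weight: float  # beta2 / beta1 from the two-predictor logistic fit
    control_mean: float
    control_sd: float
    offset: float = 0.001
    beta1: float | None = None
    beta2: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.weight):
            raise ConfigError("CRS weight must be finite")
        if not self.control_sd > 0:
            raise ConfigError("CRS control_sd must be positive")


def _raw_definitions() -> dict:
    with resources.files("gwaspipe.data").joinpath("score_definitions.json").open() as fh:
        return json.load(fh)


def load_score_definition(ethnicity: str, path: str | None = None) -> ScoreDefinition:
    """Load a published score definition ('east_asian' or 'european')."""
    if path is None:
        raw = _raw_definitions()
    else:
        with open(path) as fh:
            raw = json.load(fh)
    if ethnicity not in raw:
        raise ConfigError(f"no score definition for ethnicity {ethnicity!r}")
    entry = raw[ethnicity]
    return ScoreDefinition(
        ethnicity=ethnicity,
        terms=tuple((v, a, float(w)) for v, a, w in entry["terms"]),
        interactions=tuple((a, b, float(w)) for a, b, w in entry["interactions"]),
        control_mean=float(entry["control_mean"]),
        control_sd=float(entry["control_sd"]),
    )


def load_crs_calibration(ethnicity: str, path: str | None = None) -> CrsCalibration:
    if path is None:
        raw = _raw_definitions()
    else:
        with open(path) as fh:
            raw = json.load(fh)
    if ethnicity not in raw or "crs" not in raw[ethnicity]:
        raise ConfigError(f"no CRS calibration for ethnicity {ethnicity!r}")
    crs = raw[ethnicity]["crs"]
    return CrsCalibration(
        ethnicity=ethnicity,
        weight=float(crs["weight"]),
        control_mean=float(crs["control_mean"]),
        control_sd=float(crs["control_sd"]),
        offset=float(crs.get("offset", 0.001)),
    )


def compute_grs(
    dosages: pd.DataFrame,
    definition: ScoreDefinition,
    standardize: bool = True,
) -> pd.DataFrame:
    """Score every individual: raw weighted sum and standardized GRS.

    Every term's variant must be present in the dosage frame; absent
    variants are a hard error (no silent zero-imputation). Dosages must
    lie in [0, 2]. Returns a frame with columns ``grs_raw`` and ``grs``.
    """
    needed = {vid for vid, _, _ in definition.terms}
    needed |= {v for a, b, _ in definition.interactions for v in (a, b)}
    missing = sorted(needed - set(dosages.columns))
    if missing:
        raise DataError(f"dosage matrix missing score variants: {missing}")
    sub = dosages[sorted(needed)].to_numpy(dtype=float)
    if np.any(sub < 0) or np.any(sub > 2):
        raise DataError("dosages outside [0, 2]")
    raw = np.zeros(len(dosages))
    for vid, _, w in definition.terms:
        raw += w * dosages[vid].to_numpy(dtype=float)
    for va, vb, w in definition.interactions:
        raw += w * dosages[va].to_numpy(dtype=float) * dosages[vb].to_numpy(dtype=float)
    out = pd.DataFrame({"grs_raw": raw}, index=dosages.index)
    if standardize:
        out["grs"] = (raw - definition.control_mean) / definition.control_sd
    return out


def derive_crs_weight(
    grs: np.ndarray | pd.Series,
    titers: np.ndarray | pd.Series,
    status: np.ndarray | pd.Series,
    ethnicity: str = "custom",
    offset: float = 0.001,
) -> CrsCalibration:
    """Calibrate the titer weight from a two-predictor logistic fit.

    Fits status ~ intercept + b1*GRS + b2*ln(titer + offset) and returns
    weight = b2 / b1, together with control-arm standardization constants
    of the implied crude combined score.
    """
    grs = np.asarray(grs, dtype=float)
    titers = np.asarray(titers, dtype=float)
    status = np.asarray(status, dtype=int)
    if np.any(titers < 0):
        raise DataError("titers must be non-negative")
    log_titer = np.log(titers + offset)
    for name, x in (("grs", grs), ("log titer", log_titer)):
        if np.var(x) == 0:
            raise DataError(f"{name} has zero variance")
    X = np.column_stack([np.ones(len(grs)), grs, log_titer])
    fit = fit_logit(X, status)
    if fit.separation:
        raise NumericalError("separation in the CRS calibration fit")
    beta1, beta2 = float(fit.params[1]), float(fit.params[2])
    if abs(beta1) < 1e-8:
        raise NumericalError("GRS coefficient is ~0; titer weight undefined")
    weight = beta2 / beta1
    crude = grs + weight * log_titer
    controls = crude[status == 0]
    sd = float(controls.std(ddof=1))
    if sd == 0:
        raise NumericalError("control crude-CRS standard deviation is zero")
    return CrsCalibration(
        ethnicity=ethnicity,
        weight=weight,
        control_mean=float(controls.mean()),
        control_sd=sd,
        offset=offset,
        beta1=beta1,
        beta2=beta2,
    )


def compute_crs(
    grs_standardized: np.ndarray | pd.Series,
    titer_u_ml: np.ndarray | pd.Series,
    calibration: CrsCalibration,
) -> pd.DataFrame:
    """Crude and standardized combined risk score.

    crude = GRS + weight * ln(titer + offset);
    crs = (crude - control_mean) / control_sd.
    """
    grs = np.asarray(grs_standardized, dtype=float)
    titer = np.asarray(titer_u_ml, dtype=float)
    if np.any(titer < 0):
        bad = np.flatnonzero(titer < 0)[:5].tolist()
        raise DataError(f"negative titers at rows {bad}")
    crude = grs + calibration.weight * np.log(titer + calibration.offset)
    crs = (crude - calibration.control_mean) / calibration.control_sd
    index = grs_standardized.index if isinstance(grs_standardized, pd.Series) else None
    return pd.DataFrame({"crs_crude": crude, "crs": crs}, index=index)


def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke's rescaled pseudo-R^2 from two nested log-likelihoods."""
    if ll_model < ll_null - 1e-9:
        raise DataError(
            f"model log-likelihood ({ll_model:.4f}) below null ({ll_null:.4f}); "
            "models are not nested or fits failed"
        )
    cox_snell = 1.0 - math.exp(2.0 * (ll_null - ll_model) / n)
    max_r2 = 1.0 - math.exp(2.0 * ll_null / n)
    return float(cox_snell / max_r2)


@dataclass(frozen=True)
class LiabilityTransformSpec:
    """Prevalence K, sample case fraction P, and the normal density z at
    the liability threshold Phi^-1(1-K)."""

    K: float
    P: float
    z: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.K < 1.0:
            raise ConfigError(f"K must be in (0,1), got {self.K}")
        if not 0.0 < self.P < 1.0:
            raise ConfigError(f"P must be in (0,1), got {self.P}")
        object.__setattr__(self, "z", float(stats.norm.pdf(stats.norm.isf(self.K))))


def liability_h2(h2_observed: float, spec: LiabilityTransformSpec) -> tuple[float, bool]:
    """Observed-scale heritability transformed to the liability scale.

    h2_liab = h2_obs * [K(1-K)]^2 / (z^2 * P(1-P)). Returns the estimate
    and a flag set when it exceeds 1 (retained, not truncated).
    """
    if h2_observed < 0:
        raise DataError("observed-scale heritability must be >= 0")
    K, P, z = spec.K, spec.P, spec.z
    h2 = h2_observed * (K * (1.0 - K)) ** 2 / (z**2 * P * (1.0 - P))
    return float(h2), bool(h2 > 1.0)
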