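"""Approximate-Bayes-factor fine-mapping under a single causal variant.

The evidence for association of each variant is the closed-form
approximate Bayes factor computed from its effect estimate, squared
standard error V, and a prior effect variance W (log-odds scale):

    ABF = sqrt(V / (V + W)) * exp(z^2 * W / (2 * (V + W)))

Posterior probabilities are the ABFs normalized over the region, and the
99% credible set is built by adding variants in decreasing posterior
probability until the cumulative probability strictly exceeds the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

DEFAULT_PRIOR_W = 0.04  # prior sd 0.2 on the log-odds scale


def wakefield_log_abf(
    beta: np.ndarray | float, se: np.ndarray | float, W: float = DEFAULT_PRIOR_W
) -> np.ndarray | float:
    """Natural log of the approximate Bayes factor (association-oriented)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if not np.all(np.isfinite(beta)) or not np.all(np.isfinite(se)):
        raise DataError("beta and se must be finite")
    if np.any(se <= 0):
        raise DataError("se must be positive")
    if not W > 0:
        raise DataError(f"prior variance W must be positive, got {W}")
    V = se**2
    z2 = (beta / se) ** 2
    log_abf = 0.5 * np.log(V / (V + W)) + z2 * W / (2.0 * (V + W))
    return log_abf if log_abf.ndim else float(log_abf)


def wakefield_abf(
    beta: np.ndarray | float, se: np.ndarray | float, W: float = DEFAULT_PRIOR_W
) -> np.ndarray | float:
    """Approximate Bayes factor; larger values mean stronger association."""
    with np.errstate(over="ignore"):  # huge z: ABF overflows to inf, PP math stays in logs
        out = np.exp(wakefield_log_abf(beta, se, W))
    return out if np.ndim(out) else float(out)


@dataclass
class CredibleSet:
    """Per-variant posterior probabilities and credible-set membership."""

    table: pd.DataFrame  # variant_id, beta, se, abf, pp, in_credible_set, cum_pp
    threshold: float

    @property
    def members(self) -> list[str]:
        t = self.table
        return t.loc[t["in_credible_set"] == 1, "variant_id"].tolist()

    @property
    def cumulative_pp(self) -> float:
        t = self.table
        return float(t.loc[t["in_credible_set"] == 1, "pp"].sum())


def credible_set(
    variant_ids: Sequence[str],
    betas: Sequence[float],
    ses: Sequence[float],
    W: float = DEFAULT_PRIOR_W,
    threshold: float = 0.99,
) -> CredibleSet:
    """Single-causal-variant credible set from summary statistics.

    Posterior probability of variant i is ABF_i / sum_j ABF_j (computed in
    log space for stability); variants are ranked by descending PP with a
    deterministic tie-break on variant_id, and added until the cumulative
    PP strictly exceeds ``threshold``.
    """
    variant_ids = [str(v) for v in variant_ids]
    if len(variant_ids) == 0:
        raise DataError("credible_set needs at least one variant")
    if len(set(variant_ids)) != len(variant_ids):
        raise DataError("duplicate variant ids")
    log_abf = np.atleast_1d(wakefield_log_abf(np.asarray(betas), np.asarray(ses), W))
    if not np.all(np.isfinite(log_abf)):
        raise DataError("non-finite ABF encountered")
    shifted = log_abf - log_abf.max()
    pp = np.exp(shifted)
    pp /= pp.sum()
    with np.errstate(over="ignore"):  # raw ABF may overflow; reported as inf
        abf = np.exp(log_abf)
    frame = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "beta": np.asarray(betas, dtype=float),
            "se": np.asarray(ses, dtype=float),
            "abf": abf,
            "pp": pp,
        }
    )
    frame = frame.sort_values(
        ["pp", "variant_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["cum_pp"] = frame["pp"].cumsum()
    n_members = int(np.searchsorted(frame["cum_pp"].to_numpy(), threshold, side="right")) + 1
    n_members = min(n_members, len(frame))
    frame["in_credible_set"] = (np.arange(len(frame)) < n_members).astype(int)
    return CredibleSet(table=frame, threshold=threshold)
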