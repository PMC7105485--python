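"""Seeded case-control cohort simulation.

Generates genotype dosage matrices, phased haplotype pairs with a target
level of linkage disequilibrium, disease status under a prospective
logistic model with a prevalence-calibrated intercept (sampled
retrospectively to case/control quotas, which preserves odds ratios),
serum antibody titers coupled to a genetic risk score, and phased
amino-acid residue haplotypes derived from classical allele calls.

Random-number streams: each public operation derives independent child
streams from the root seed via ``numpy.random.SeedSequence.spawn``. The
stream order inside :func:`simulate_case_control` is fixed and documented
there, so identical specs and seeds give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .errors import ConfigError, DataError, LdInfeasibleError, NumericalError

__all__ = [
    "VariantSpec",
    "InteractionSpec",
    "CohortSpec",
    "SerologySpec",
    "ResidueTable",
    "Cohort",
    "make_ld_haplotypes",
    "simulate_genotypes",
    "calibrate_intercept",
    "simulate_case_control",
    "simulate_antibody",
    "simulate_allele_haplotypes",
    "assign_residues",
    "east_asian_spec",
    "european_spec",
    "default_serology",
    "default_drb1_residues",
    "grs_model_variance",
    "calibrate_tag_frequency",
]


# ---------------------------------------------------------------------------
# Specifications


@dataclass(frozen=True)
class VariantSpec:
    """A biallelic variant: effect allele, control frequency, log-odds effect."""

    variant_id: str
    effect_allele: str
    control_allele_freq: float
    log_odds: float

    def __post_init__(self) -> None:
        if not 0.0 < self.control_allele_freq < 1.0:
            raise ConfigError(
                f"{self.variant_id}: control_allele_freq must be in (0,1), "
                f"got {self.control_allele_freq}"
            )
        if not math.isfinite(self.log_odds):
            raise ConfigError(f"{self.variant_id}: log_odds must be finite")


@dataclass(frozen=True)
class InteractionSpec:
    """Multiplicative interaction: coefficient on the dosage product."""

    variant_a: str
    variant_b: str
    log_odds: float

    def __post_init__(self) -> None:
        if self.variant_a == self.variant_b:
            raise ConfigError(f"interaction requires two distinct variants, got {self.variant_a} twice")
        if not math.isfinite(self.log_odds):
            raise ConfigError("interaction log_odds must be finite")


@dataclass(frozen=True)
class CohortSpec:
    """Full generative description of a case-control cohort."""

    ethnicity: str
    variants: tuple[VariantSpec, ...]
    interactions: tuple[InteractionSpec, ...] = ()
    ld_pairs: tuple[tuple[str, str, float], ...] = ()
    prevalence: float = 0.001
    n_cases: int = 1000
    n_controls: int = 1000
    n_pcs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ethnicity not in ("east_asian", "european"):
            raise ConfigError(f"unknown ethnicity {self.ethnicity!r}")
        if not 0.0 < self.prevalence < 0.5:
            raise ConfigError(f"prevalence must be in (0, 0.5), got {self.prevalence}")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigError("case and control counts must be positive")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate variant_id in spec")
        known = set(ids)
        for it in self.interactions:
            for v in (it.variant_a, it.variant_b):
                if v not in known:
                    raise ConfigError(f"interaction references unknown variant {v!r}")
        seen_in_ld: set[str] = set()
        for a, b, r2 in self.ld_pairs:
            for v in (a, b):
                if v not in known:
                    raise ConfigError(f"ld_pair references unknown variant {v!r}")
                if v in seen_in_ld:
                    raise ConfigError(f"variant {v!r} appears in more than one ld_pair")
                seen_in_ld.add(v)
            if not 0.0 <= r2 <= 1.0:
                raise ConfigError(f"ld_pair r2 must be in [0,1], got {r2}")

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def variant(self, variant_id: str) -> VariantSpec:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise KeyError(variant_id)


@dataclass(frozen=True)
class SerologySpec:
    """Parameters of the antibody-titer generator (units: U/mL).

    Seropositivity of cases is logistic in the standardized genetic risk
    score; seropositive titers are log-normal truncated to >= 20 U/mL, so
    the seropositive fraction equals the assay sensitivity at the 20 U/mL
    cutoff. Controls draw from a banded distribution whose exceedance
    rates over 20 and 2 U/mL are set exactly, with a point mass at 0 for
    a fraction of the bottom band and log-normal shapes within bands.
    Seronegative cases draw from their own truncated log-normal below
    20 U/mL, concentrated in the borderline band (2-20 U/mL), so that
    borderline titers are case-enriched.
    """

    seropos_intercept: float
    seropos_slope: float
    titer_meanlog: float = 5.0
    titer_sdlog: float = 1.0
    control_exceed_rate_20: float = 0.0
    control_exceed_rate_2: float = 0.13
    zero_fraction: float = 0.8
    control_meanlog: float = 0.5
    control_sdlog: float = 1.2
    case_neg_meanlog: float = 2.2
    case_neg_sdlog: float = 1.0
    case_neg_zero_fraction: float = 0.005

    def __post_init__(self) -> None:
        if not (0.0 <= self.control_exceed_rate_20 <= self.control_exceed_rate_2 <= 1.0):
            raise ConfigError(
                "need 0 <= control_exceed_rate_20 <= control_exceed_rate_2 <= 1"
            )
        for name in ("zero_fraction", "case_neg_zero_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0,1]")


class ResidueTable:
    """Mapping classical allele -> amino-acid residue at each polymorphic position.

    Every allele must map to exactly one residue per position; positions are
    shared across alleles.
    """

    def __init__(self, mapping: Mapping[str, Mapping[int, str]]):
        if not mapping:
            raise ConfigError("empty residue table")
        positions = None
        for allele, residues in mapping.items():
            pos = tuple(sorted(residues))
            if positions is None:
                positions = pos
            elif pos != positions:
                raise ConfigError(
                    f"allele {allele!r} does not cover the same positions as others"
                )
        self._mapping = {a: dict(r) for a, r in mapping.items()}
        self.positions: tuple[int, ...] = positions  # type: ignore[assignment]

    def residue(self, allele: str, position: int) -> str:
        try:
            return self._mapping[allele][position]
        except KeyError:
            raise DataError(f"allele {allele!r} not present in residue table") from None

    @property
    def alleles(self) -> list[str]:
        return sorted(self._mapping)


@dataclass
class Cohort:
    """Simulated (or loaded) case-control cohort.

    genotypes: samples x variants dosage matrix (float, entries in [0, 2]).
    phenotypes: per-sample table with at least ``status``; simulation adds
        ancestry PCs, and downstream stages may attach ``grs`` and
        ``titer_u_ml`` columns.
    haplotypes: phased 0/1 haplotype pairs, keyed by variant_id, for the
        variants simulated through LD pairs; shape (n, 2).
    effect_alleles: variant_id -> effect allele label.
    """

    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    effect_alleles: dict[str, str] = field(default_factory=dict)
    haplotypes: dict[str, np.ndarray] = field(default_factory=dict)
    classical_haplotypes: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def status(self) -> np.ndarray:
        return self.phenotypes["status"].to_numpy()

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.status).sum())

    def pc_columns(self) -> list[str]:
        return [c for c in self.phenotypes.columns if c.startswith("PC")]


# ---------------------------------------------------------------------------
# Haplotypes with target LD


def ld_r2_max(p: float, q: float) -> float:
    """Maximum attainable r^2 between two loci with positive association."""
    d_max = min(p * (1.0 - q), q * (1.0 - p))
    return d_max**2 / (p * (1.0 - p) * q * (1.0 - q))


def make_ld_haplotypes(
    p: float,
    q: float,
    r2_target: float,
    n_hap: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw phased binary haplotypes at two loci with target r^2.

    The haplotype-class frequencies are solved from the single correlation
    r = +sqrt(r2_target) (positive association of the two minor/effect
    alleles), i.e. freq(1,1) = p*q + r*sqrt(p(1-p)q(1-q)).

    Returns an integer array of shape (n_hap, 2); column 0 carries the
    allele at the first locus, column 1 at the second.

    Raises
    ------
    LdInfeasibleError
        If the implied freq(1,1) falls outside [max(0, p+q-1), min(p, q)].
    """
    for name, val in (("p", p), ("q", q)):
        if not 0.0 < val < 1.0:
            raise ConfigError(f"{name} must be in (0,1), got {val}")
    if not 0.0 <= r2_target <= 1.0:
        raise ConfigError(f"r2_target must be in [0,1], got {r2_target}")
    r = math.sqrt(r2_target)
    denom = math.sqrt(p * (1.0 - p) * q * (1.0 - q))
    p11 = p * q + r * denom
    lo, hi = max(0.0, p + q - 1.0), min(p, q)
    if p11 > hi + 1e-12 or p11 < lo - 1e-12:
        raise LdInfeasibleError(r2_target, ld_r2_max(p, q), p, q)
    p11 = min(max(p11, lo), hi)
    p10 = p - p11
    p01 = q - p11
    p00 = 1.0 - p11 - p10 - p01
    probs = np.array([p00, p01, p10, p11])
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = rng.choice(4, size=n_hap, p=probs)
    out = np.empty((n_hap, 2), dtype=np.int8)
    out[:, 0] = classes // 2
    out[:, 1] = classes % 2
    return out


# ---------------------------------------------------------------------------
# Genotypes


def _draw_genotypes(
    spec: CohortSpec, n: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    ld_members = {v: (a, b, r2) for (a, b, r2) in spec.ld_pairs for v in (a, b)}
    columns: dict[str, np.ndarray] = {}
    haplotypes: dict[str, np.ndarray] = {}
    done_pairs: set[tuple[str, str]] = set()
    for v in spec.variants:
        if v.variant_id in ld_members:
            a, b, r2 = ld_members[v.variant_id]
            if (a, b) in done_pairs:
                continue
            pa = spec.variant(a).control_allele_freq
            pb = spec.variant(b).control_allele_freq
            haps = make_ld_haplotypes(pa, pb, r2, 2 * n, rng)
            h1, h2 = haps[:n], haps[n:]
            for idx, vid in enumerate((a, b)):
                haplotypes[vid] = np.stack([h1[:, idx], h2[:, idx]], axis=1)
                columns[vid] = (h1[:, idx] + h2[:, idx]).astype(np.float64)
            done_pairs.add((a, b))
        else:
            columns[v.variant_id] = rng.binomial(
                2, v.control_allele_freq, size=n
            ).astype(np.float64)
    frame = pd.DataFrame({vid: columns[vid] for vid in spec.variant_ids})
    return frame, haplotypes


def simulate_genotypes(
    spec: CohortSpec, n: int, seed: int | np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Simulate a population genotype matrix at the spec's control frequencies.

    Non-LD variants are drawn as Binomial(2, freq) (Hardy-Weinberg);
    variants named in ``ld_pairs`` are built from phased haplotype pools
    with the target r^2. Returns (dosage frame, phased haplotypes for the
    LD-pair variants).
    """
    if seed is None:
        seed = spec.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _draw_genotypes(spec, n, rng)


def linear_predictor(
    genotypes: pd.DataFrame,
    variants: Sequence[VariantSpec],
    interactions: Sequence[InteractionSpec] = (),
) -> np.ndarray:
    """Sum of weighted dosages plus weighted dosage products (no intercept)."""
    lp = np.zeros(len(genotypes))
    for v in variants:
        lp += v.log_odds * genotypes[v.variant_id].to_numpy()
    for it in interactions:
        lp += it.log_odds * (
            genotypes[it.variant_a].to_numpy() * genotypes[it.variant_b].to_numpy()
        )
    return lp


# ---------------------------------------------------------------------------
# Disease model


def calibrate_intercept(
    K: float,
    variants: Sequence[VariantSpec],
    interactions: Sequence[InteractionSpec] = (),
    ld_pairs: Sequence[tuple[str, str, float]] = (),
    n_mc: int = 1_000_000,
    seed: int = 2024,
    tol: float = 1e-10,
) -> float:
    """Intercept of the prospective logistic model attaining prevalence K.

    Solves E[expit(c + lp)] = K by root-finding over a large simulated
    reference population (the Monte-Carlo population is drawn from a fixed
    internal stream so the intercept is a deterministic function of the
    arguments).
    """
    if not 0.0 < K < 1.0:
        raise ConfigError(f"prevalence must be in (0,1), got {K}")
    if not variants:
        return float(logit(K))
    probe = CohortSpec(
        ethnicity="east_asian",
        variants=tuple(variants),
        interactions=tuple(interactions),
        ld_pairs=tuple(ld_pairs),
        prevalence=min(K, 0.49),
        n_cases=1,
        n_controls=1,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    genotypes, _ = _draw_genotypes(probe, n_mc, rng)
    lp = linear_predictor(genotypes, variants, interactions)
    if np.allclose(lp, 0.0):
        return float(logit(K))

    def prevalence_gap(c: float) -> float:
        return float(np.mean(expit(c + lp))) - K

    span = float(lp.max() - lp.min()) + 1.0
    lo = float(logit(K)) - span
    hi = float(logit(K)) + span
    f_lo, f_hi = prevalence_gap(lo), prevalence_gap(hi)
    if f_lo * f_hi > 0:
        raise NumericalError(
            f"intercept root not bracketed: f({lo:.3f})={f_lo:.3e}, "
            f"f({hi:.3f})={f_hi:.3e}"
        )
    return float(brentq(prevalence_gap, lo, hi, xtol=tol))


def simulate_case_control(
    spec: CohortSpec,
    batch_size: int = 1_000_000,
    max_batches: int = 200,
) -> Cohort:
    """Simulate a case-control cohort by retrospective quota sampling.

    Population individuals are drawn in batches from the prospective
    logistic model (intercept calibrated to ``spec.prevalence``) and
    retained until the case and control quotas fill. Odds ratios are
    invariant to this ascertainment, so fitted logistic coefficients
    recover the generative log-odds.

    Stream order from the root seed: 0 = intercept-calibration population,
    1 = genotype/status batches, 2 = ancestry-PC noise.
    """
    root = np.random.SeedSequence(spec.seed)
    calib_seed, batch_seq, pc_seq = root.spawn(3)
    intercept = calibrate_intercept(
        spec.prevalence,
        spec.variants,
        spec.interactions,
        spec.ld_pairs,
        seed=int(calib_seed.generate_state(1)[0]),
    )
    rng = np.random.default_rng(batch_seq)

    case_geno: list[pd.DataFrame] = []
    ctrl_geno: list[pd.DataFrame] = []
    case_haps: dict[str, list[np.ndarray]] = {}
    ctrl_haps: dict[str, list[np.ndarray]] = {}
    n_case = n_ctrl = 0
    for _ in range(max_batches):
        if n_case >= spec.n_cases and n_ctrl >= spec.n_controls:
            break
        genotypes, haps = _draw_genotypes(spec, batch_size, rng)
        lp = linear_predictor(genotypes, spec.variants, spec.interactions)
        status = rng.random(batch_size) < expit(intercept + lp)
        if n_case < spec.n_cases:
            take = np.flatnonzero(status)[: spec.n_cases - n_case]
            case_geno.append(genotypes.iloc[take])
            for vid, h in haps.items():
                case_haps.setdefault(vid, []).append(h[take])
            n_case += len(take)
        if n_ctrl < spec.n_controls:
            take = np.flatnonzero(~status)[: spec.n_controls - n_ctrl]
            ctrl_geno.append(genotypes.iloc[take])
            for vid, h in haps.items():
                ctrl_haps.setdefault(vid, []).append(h[take])
            n_ctrl += len(take)
    if n_case < spec.n_cases or n_ctrl < spec.n_controls:
        raise NumericalError(
            f"quota unreachable within {max_batches} batches of {batch_size}: "
            f"got {n_case}/{spec.n_cases} cases, {n_ctrl}/{spec.n_controls} controls"
        )

    genotypes = pd.concat(case_geno + ctrl_geno, ignore_index=True)
    n = spec.n_cases + spec.n_controls
    genotypes.index = pd.Index([f"S{i:06d}" for i in range(n)], name="sample_id")
    status_col = np.zeros(n, dtype=np.int64)
    status_col[: spec.n_cases] = 1
    pheno = pd.DataFrame({"status": status_col}, index=genotypes.index)
    pc_rng = np.random.default_rng(pc_seq)
    for k in range(spec.n_pcs):
        pheno[f"PC{k + 1}"] = pc_rng.standard_normal(n)
    haplotypes = {
        vid: np.concatenate(case_haps.get(vid, []) + ctrl_haps.get(vid, []))
        for vid in set(case_haps) | set(ctrl_haps)
    }
    return Cohort(
        genotypes=genotypes,
        phenotypes=pheno,
        effect_alleles={v.variant_id: v.effect_allele for v in spec.variants},
        haplotypes=haplotypes,
    )


# ---------------------------------------------------------------------------
# Serology


def _truncated_lognormal(
    n: int,
    meanlog: float,
    sdlog: float,
    lower: float | None,
    rng: np.random.Generator,
    upper: float | None = None,
) -> np.ndarray:
    """Log-normal conditioned on [lower, upper), via inverse-CDF."""
    a = norm.cdf((math.log(lower) - meanlog) / sdlog) if lower else 0.0
    b = norm.cdf((math.log(upper) - meanlog) / sdlog) if upper else 1.0
    u = a + (b - a) * rng.random(n)
    return np.exp(meanlog + sdlog * norm.ppf(u))


def _control_titers(n: int, serology: SerologySpec, rng: np.random.Generator) -> np.ndarray:
    """Control titers: bands [0,2), [2,20), [20,inf) at exact rates.

    Within-band values follow the control log-normal shape restricted to
    the band (log-normal truncated at 20 for the top band), with a point
    mass at exactly 0 for ``zero_fraction`` of the bottom band.
    """
    p20 = serology.control_exceed_rate_20
    p2 = serology.control_exceed_rate_2
    ml, sd = serology.control_meanlog, serology.control_sdlog
    band = rng.random(n)
    titers = np.empty(n)
    low = band >= p2
    mid = (band >= p20) & ~low
    high = band < p20
    n_low = int(low.sum())
    low_vals = _truncated_lognormal(n_low, ml, sd, None, rng, upper=2.0)
    low_vals[rng.random(n_low) < serology.zero_fraction] = 0.0
    titers[low] = low_vals
    titers[mid] = _truncated_lognormal(int(mid.sum()), ml, sd, 2.0, rng, upper=20.0)
    titers[high] = _truncated_lognormal(
        int(high.sum()), serology.titer_meanlog, serology.titer_sdlog, 20.0, rng
    )
    return titers


def _seronegative_case_titers(
    n: int, serology: SerologySpec, rng: np.random.Generator
) -> np.ndarray:
    vals = _truncated_lognormal(
        n, serology.case_neg_meanlog, serology.case_neg_sdlog, None, rng, upper=20.0
    )
    vals[rng.random(n) < serology.case_neg_zero_fraction] = 0.0
    return vals


def simulate_antibody(
    cohort: Cohort, serology: SerologySpec, seed: int = 0
) -> np.ndarray:
    """Attach serum antibody titers (U/mL, >= 0) to a scored cohort.

    Case seropositivity is Bernoulli(expit(intercept + slope * GRS)) on the
    standardized GRS; seropositive titers are log-normal truncated at
    20 U/mL, so the case seropositive fraction equals the assay
    sensitivity at the 20 U/mL cutoff. Seronegative cases concentrate in
    the borderline band below 20 U/mL; controls follow the banded
    distribution of :class:`SerologySpec`.
    """
    if "grs" not in cohort.phenotypes.columns:
        raise DataError(
            "cohort has no 'grs' phenotype column; compute the genetic risk "
            "score first (scores.compute_grs) and attach it before simulating titers"
        )
    rng = np.random.default_rng(seed)
    status = cohort.status
    grs = cohort.phenotypes["grs"].to_numpy()
    n = len(status)
    titers = np.empty(n)
    is_case = status == 1
    p_pos = expit(serology.seropos_intercept + serology.seropos_slope * grs[is_case])
    seropos = rng.random(int(is_case.sum())) < p_pos
    pos_idx = np.flatnonzero(is_case)[seropos]
    neg_case_idx = np.flatnonzero(is_case)[~seropos]
    ctl_idx = np.flatnonzero(~is_case)
    titers[pos_idx] = _truncated_lognormal(
        len(pos_idx), serology.titer_meanlog, serology.titer_sdlog, 20.0, rng
    )
    titers[neg_case_idx] = _seronegative_case_titers(len(neg_case_idx), serology, rng)
    titers[ctl_idx] = _control_titers(len(ctl_idx), serology, rng)
    cohort.phenotypes["titer_u_ml"] = titers
    return titers


def calibrate_seropositivity_intercept(
    grs_cases: np.ndarray, slope: float, target_sensitivity: float
) -> float:
    """Intercept making mean case seropositivity equal the target."""
    grs_cases = np.asarray(grs_cases, dtype=float)

    def gap(a: float) -> float:
        return float(np.mean(expit(a + slope * grs_cases))) - target_sensitivity

    return float(brentq(gap, -30.0, 30.0, xtol=1e-10))


# ---------------------------------------------------------------------------
# Classical alleles and residues


def simulate_allele_haplotypes(
    freqs: Mapping[str, float], n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Phased classical-allele haplotypes: (n, 2) array of allele labels.

    Each of the two haplotypes per individual is drawn independently from
    the supplied allele-frequency distribution (frequencies must sum to 1).
    """
    alleles = list(freqs)
    p = np.array([freqs[a] for a in alleles], dtype=float)
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
        raise ConfigError(f"allele frequencies sum to {p.sum():.6f}, expected 1")
    p = p / p.sum()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.choice(len(alleles), size=(n, 2), p=p)
    return np.asarray(alleles, dtype=object)[draws]


def assign_residues(
    classical_haplotypes: np.ndarray, table: ResidueTable
) -> dict[int, np.ndarray]:
    """Translate phased classical alleles into phased residues per position.

    Returns {position: (n, 2) array of residue labels}; phase is preserved
    (column h of every position comes from haplotype h).
    """
    haps = np.asarray(classical_haplotypes, dtype=object)
    if haps.ndim != 2 or haps.shape[1] != 2:
        raise DataError("classical_haplotypes must have shape (n, 2)")
    observed = set(np.unique(haps))
    missing = observed - set(table.alleles)
    if missing:
        raise DataError(f"alleles missing from residue table: {sorted(missing)}")
    out: dict[int, np.ndarray] = {}
    for pos in table.positions:
        lookup = {a: table.residue(a, pos) for a in observed}
        res = np.vectorize(lookup.__getitem__, otypes=[object])(haps)
        out[pos] = res
    return out


def residue_dosages(residues_at_pos: np.ndarray) -> pd.DataFrame:
    """Count dosage (0-2) of each residue per individual at one position."""
    res = np.asarray(residues_at_pos, dtype=object)
    labels = sorted(set(res.ravel()))
    return pd.DataFrame(
        {lab: (res == lab).sum(axis=1).astype(float) for lab in labels}
    )


# ---------------------------------------------------------------------------
# Shipped default specifications
#
# Frequencies printed in the source tables are used as-is; the remaining
# tag-SNP frequencies are package defaults, with one frequency per
# ethnicity calibrated analytically so the control-arm raw-score standard
# deviation matches the published standardization constant (see
# calibrate_tag_frequency).

_EA_WEIGHTS = {
    "rs9269027": ("A", 0.69173),
    "rs1974461": ("T", 1.23685),
    "rs6707458": ("G", 0.36687),
    "rs230540": ("C", 0.25098),
    "rs9405192": ("G", 0.39127),
}
_EA_INTERACTION = ("rs9269027", "rs6707458", 0.48798)
_EA_CONTROL_SD = 1.0033
_EA_FREQS = {
    "rs9269027": 0.08,  # tags the East Asian DRB1*15:01 risk haplotype
    "rs6707458": 0.70,
    "rs230540": 0.35,
    "rs9405192": 0.42,
}
_EA_CALIBRATED = "rs1974461"

_EUR_WEIGHTS = {
    "rs9271541": ("C", 0.34945),
    "rs9265949": ("T", 0.67919),
    "rs2858309": ("C", 0.30707),
    "rs6707458": ("G", 0.34601),
    "rs230540": ("C", 0.17450),
    "rs9405192": ("G", 0.18343),
}
_EUR_INTERACTION = ("rs9271541", "rs6707458", 0.33782)
_EUR_CONTROL_SD = 0.8202
_EUR_FREQS = {
    "rs9271541": 0.30,  # tags the European DQA1*05:01 risk haplotype
    "rs2858309": 0.20,
    "rs6707458": 0.61,
    "rs230540": 0.32,
    "rs9405192": 0.69,
}
_EUR_CALIBRATED = "rs9265949"


def grs_model_variance(
    weights: Mapping[str, tuple[str, float]],
    interaction: tuple[str, str, float],
    freqs: Mapping[str, float],
) -> float:
    """Analytic variance of the raw weighted-dosage score under HWE.

    Assumes independent variants; the single interaction pair contributes
    Var(w_a A + w_b B + w_i A*B) computed from binomial moments.
    """
    a_id, b_id, w_i = interaction
    var = 0.0
    for vid, (_, w) in weights.items():
        if vid in (a_id, b_id):
            continue
        p = freqs[vid]
        var += w * w * 2.0 * p * (1.0 - p)
    pa, pb = freqs[a_id], freqs[b_id]
    wa, wb = weights[a_id][1], weights[b_id][1]
    mu_a, mu_b = 2 * pa, 2 * pb
    va, vb = 2 * pa * (1 - pa), 2 * pb * (1 - pb)
    ea2, eb2 = va + mu_a**2, vb + mu_b**2
    var_ab = ea2 * eb2 - mu_a**2 * mu_b**2
    cov_a_ab = mu_b * va
    cov_b_ab = mu_a * vb
    var += (
        wa**2 * va
        + wb**2 * vb
        + w_i**2 * var_ab
        + 2 * wa * w_i * cov_a_ab
        + 2 * wb * w_i * cov_b_ab
    )
    return var


def calibrate_tag_frequency(
    weights: Mapping[str, tuple[str, float]],
    interaction: tuple[str, str, float],
    fixed_freqs: Mapping[str, float],
    free_variant: str,
    target_sd: float,
) -> float:
    """Solve the free variant's frequency so the model SD hits target_sd.

    The free variant must not be part of the interaction pair; its
    contribution is w^2 * 2p(1-p), so the solution is the smaller root of
    a quadratic in p. Raises if the target variance is unattainable.
    """
    if free_variant in interaction[:2]:
        raise ConfigError("calibrated variant may not be in the interaction pair")
    w = weights[free_variant][1]
    base = grs_model_variance(
        weights, interaction, {**fixed_freqs, free_variant: 0.5}
    ) - w * w * 0.5
    residual = target_sd**2 - base
    if residual <= 0:
        raise NumericalError(
            f"target SD {target_sd} unattainable: fixed terms already "
            f"contribute variance {base:.4f}"
        )
    pq = residual / (2.0 * w * w)
    if pq > 0.25:
        raise NumericalError(
            f"target SD {target_sd} unattainable: needs p(1-p)={pq:.4f} > 0.25"
        )
    return 0.5 * (1.0 - math.sqrt(1.0 - 4.0 * pq))


def _build_spec(
    ethnicity: str,
    weights: Mapping[str, tuple[str, float]],
    interaction: tuple[str, str, float],
    fixed_freqs: Mapping[str, float],
    calibrated: str,
    target_sd: float,
    n_cases: int,
    n_controls: int,
    prevalence: float,
    seed: int,
) -> CohortSpec:
    freqs = dict(fixed_freqs)
    freqs[calibrated] = calibrate_tag_frequency(
        weights, interaction, fixed_freqs, calibrated, target_sd
    )
    variants = tuple(
        VariantSpec(vid, allele, freqs[vid], w) for vid, (allele, w) in weights.items()
    )
    return CohortSpec(
        ethnicity=ethnicity,
        variants=variants,
        interactions=(InteractionSpec(*interaction),),
        prevalence=prevalence,
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
    )


def east_asian_spec(
    n_cases: int = 1000, n_controls: int = 2000, prevalence: float = 0.001, seed: int = 0
) -> CohortSpec:
    """Default East Asian generative model (published weights; calibrated freqs)."""
    return _build_spec(
        "east_asian",
        _EA_WEIGHTS,
        _EA_INTERACTION,
        _EA_FREQS,
        _EA_CALIBRATED,
        _EA_CONTROL_SD,
        n_cases,
        n_controls,
        prevalence,
        seed,
    )


def european_spec(
    n_cases: int = 1000, n_controls: int = 2000, prevalence: float = 0.001, seed: int = 0
) -> CohortSpec:
    """Default European generative model (published weights; calibrated freqs)."""
    return _build_spec(
        "european",
        _EUR_WEIGHTS,
        _EUR_INTERACTION,
        _EUR_FREQS,
        _EUR_CALIBRATED,
        _EUR_CONTROL_SD,
        n_cases,
        n_controls,
        prevalence,
        seed,
    )


# Intercepts below were calibrated with calibrate_seropositivity_intercept
# against the case-arm standardized-GRS distribution of the matching default
# cohort spec at large n, targeting the published assay sensitivities at the
# 20 U/mL cutoff (0.60 East Asian, 0.54 European).
_SEROLOGY_DEFAULTS = {
    "east_asian": SerologySpec(
        seropos_intercept=-0.19729,
        seropos_slope=0.4,
        control_exceed_rate_20=0.0,
        control_exceed_rate_2=0.13,
    ),
    "european": SerologySpec(
        seropos_intercept=-0.37826,
        seropos_slope=0.4,
        control_exceed_rate_20=0.005,
        control_exceed_rate_2=0.13,
    ),
}


def default_serology(ethnicity: str) -> SerologySpec:
    try:
        return _SEROLOGY_DEFAULTS[ethnicity]
    except KeyError:
        raise ConfigError(f"no default serology for ethnicity {ethnicity!r}") from None


# Minimal synthetic residue table for the DR beta-1 chain: encodes only the
# published risk-allele/residue pairings at positions 13, 71 and 74 plus two
# common reference alleles; it is not an IMGT extract.
_DRB1_RESIDUES = {
    "DRB1*1501": {13: "Arg", 71: "Ala", 74: "Ala"},
    "DRB1*0301": {13: "Ser", 71: "Lys", 74: "Arg"},
    "DRB1*0901": {13: "Gly", 71: "Arg", 74: "Glu"},
    "DRB1*0405": {13: "His", 71: "Arg", 74: "Ala"},
    "DRB1*0701": {13: "Gly", 71: "Glu", 74: "Gln"},
}


def default_drb1_residues() -> ResidueTable:
    return ResidueTable(_DRB1_RESIDUES)
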