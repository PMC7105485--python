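"""Readers and writers for the plain-text interchange formats.

Canonical formats (all TSV, UTF-8, ``#``-prefixed metadata header lines):

- genotypes: rows = samples, columns = ``variant_id:effect_allele``,
  values = dosages in [0, 2] (fractional allowed);
- phenotypes: ``sample_id`` plus ``status`` and arbitrary covariate/score
  columns;
- phased haplotypes: long format ``sample_id  hap  locus  allele``;
- summary statistics: one row per variant with effect, SE, OR, CI, p and
  the conditioning set as a semicolon list.

VCF is supported read-only through cyvcf2 (requires a per-sample dosage
FORMAT field, default ``DS``); a minimal dosage VCF writer is provided
for round-trip testing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, DataError

SUMMARY_COLUMNS = [
    "variant_id", "effect_allele", "other_allele", "eaf_cases", "eaf_controls",
    "beta", "se", "or", "ci_low", "ci_high", "p", "n_cases", "n_controls",
    "conditioned_on",
]


def metadata_header(meta: Mapping[str, object] | None) -> list[str]:
    lines = [f"#gwaspipe_version={__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"#{key}={value}")
    return lines


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write_tsv(frame: pd.DataFrame, path: str | Path, meta: Mapping | None, index: bool) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in metadata_header(meta):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=index)


def write_dosage_tsv(
    dosages: pd.DataFrame,
    effect_alleles: Mapping[str, str],
    path: str | Path,
    meta: Mapping | None = None,
) -> None:
    out = dosages.copy()
    out.columns = [f"{vid}:{effect_alleles.get(vid, 'NA')}" for vid in dosages.columns]
    out.index.name = "sample_id"
    _write_tsv(out, path, meta, index=True)


def read_dosage_tsv(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    effect_alleles: dict[str, str] = {}
    new_cols = []
    for col in frame.columns:
        vid, _, allele = col.partition(":")
        effect_alleles[vid] = allele or "NA"
        new_cols.append(vid)
    frame.columns = new_cols
    _validate_dosages(frame)
    return frame, effect_alleles


def _validate_dosages(frame: pd.DataFrame) -> None:
    values = frame.to_numpy(dtype=float)
    bad = np.argwhere((values < 0) | (values > 2) | ~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise DataError(
            f"dosage out of [0,2] at sample {frame.index[r]!r}, "
            f"variant {frame.columns[c]!r}: {values[r, c]}"
        )


def write_phenotypes_tsv(
    phenotypes: pd.DataFrame, path: str | Path, meta: Mapping | None = None
) -> None:
    out = phenotypes.copy()
    out.index.name = "sample_id"
    _write_tsv(out, path, meta, index=True)


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    if "status" in frame.columns:
        bad = ~frame["status"].isin([0, 1])
        if bad.any():
            raise DataError(f"status not in {{0,1}} for samples {frame.index[bad].tolist()[:5]}")
    return frame


def write_haplotypes_tsv(
    haplotypes: Mapping[str, np.ndarray],
    sample_ids: Iterable[str],
    path: str | Path,
    meta: Mapping | None = None,
) -> None:
    sample_ids = list(sample_ids)
    rows = []
    for locus, haps in haplotypes.items():
        for i, sid in enumerate(sample_ids):
            for h in (0, 1):
                rows.append({"sample_id": sid, "hap": h + 1, "locus": locus,
                             "allele": haps[i, h]})
    _write_tsv(pd.DataFrame(rows), path, meta, index=False)


def read_haplotypes_tsv(path: str | Path) -> tuple[dict[str, np.ndarray], list[str]]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    sample_ids = list(dict.fromkeys(frame["sample_id"]))
    order = {s: i for i, s in enumerate(sample_ids)}
    out: dict[str, np.ndarray] = {}
    for locus, sub in frame.groupby("locus", sort=False):
        haps = np.empty((len(sample_ids), 2), dtype=object)
        for _, row in sub.iterrows():
            haps[order[row["sample_id"]], int(row["hap"]) - 1] = row["allele"]
        if (haps == None).any():  # noqa: E711
            raise DataError(f"incomplete haplotype pairs for locus {locus!r}")
        out[str(locus)] = haps
    return out, sample_ids


def write_summary_tsv(frame: pd.DataFrame, path: str | Path, meta: Mapping | None = None) -> None:
    missing = set(SUMMARY_COLUMNS) - set(frame.columns)
    if missing:
        raise DataError(f"summary frame missing columns: {sorted(missing)}")
    _write_tsv(frame[SUMMARY_COLUMNS], path, meta, index=False)


def read_summary_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SUMMARY_COLUMNS) - set(frame.columns)
    if missing:
        raise DataError(f"summary file {path} missing columns: {sorted(missing)}")
    return frame


# --- VCF ------------------------------------------------------------------


def read_dosage_vcf(path: str | Path, dosage_field: str = "DS") -> tuple[pd.DataFrame, dict[str, str]]:
    """Dosage matrix from a VCF carrying a per-sample dosage FORMAT field."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ConfigError("cyvcf2 is required to read VCF input") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    effect_alleles: dict[str, str] = {}
    for record in vcf:
        vid = record.ID or f"{record.CHROM}:{record.POS}"
        try:
            ds = record.format(dosage_field)
        except KeyError:
            ds = None
        if ds is None:
            raise DataError(f"variant {vid}: missing {dosage_field} FORMAT field")
        columns[vid] = np.asarray(ds, dtype=float).ravel()
        effect_alleles[vid] = record.ALT[0] if record.ALT else "NA"
    frame = pd.DataFrame(columns, index=pd.Index(samples, name="sample_id"))
    _validate_dosages(frame)
    return frame, effect_alleles


def write_dosage_vcf(
    dosages: pd.DataFrame,
    effect_alleles: Mapping[str, str],
    path: str | Path,
    dosage_field: str = "DS",
) -> None:
    """Minimal sites+dosage VCF (synthetic coordinates, ALT = effect allele)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=gwaspipe {__version__}\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        fh.write("##contig=<ID=0>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in dosages.index) + "\n")
        for pos, vid in enumerate(dosages.columns, start=1):
            alt = effect_alleles.get(vid, "A")
            ref = "T" if alt != "T" else "C"
            values = "\t".join(f"{v:.6g}" for v in dosages[vid])
            fh.write(f"0\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\t{dosage_field}\t{values}\n")


# --- configuration --------------------------------------------------------

KNOWN_CONFIG_KEYS = {
    "ethnicity", "n_cases", "n_controls", "prevalence", "seed",
    "genotypes", "phenotypes", "haplotypes", "score_definition",
    "stages", "out_dir", "threshold", "prior_w", "alpha",
    "specificity_grid", "lead_snps", "hla_snps", "shared_pairs",
    "family_alpha", "decile_basis", "serology",
}


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return config
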