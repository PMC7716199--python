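"""File formats and run configuration.

Reads/writes the PLINK text PED/MAP dialect (whitespace-delimited, missing
allele "0"), tab-delimited covariate tables, and the TSV/JSON association
reports. Holds the :class:`RunConfig` with the pipeline defaults.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .containers import (ANCESTRY_COLUMNS, PHENO_COLUMNS, VALID_BASES,
                         GenotypeMatrix, PhenotypeTable, SNPInfo)

logger = logging.getLogger("admixscan")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Analysis thresholds and resampling parameters.

    Defaults are the study conditions: SNPs with MAF < 1% or call rate
    < 90% excluded, samples with call rate < 90% excluded; 1000 randomized
    sub-samples of 100 cases + 108 controls, balance and test alpha 0.05,
    units kept when significant in more than 50% of sub-samples.
    """

    # QC
    maf_min: float = 0.01
    snp_call_min: float = 0.90
    sample_call_min: float = 0.90
    hwe_alpha: float = 0.05
    maf_scope: str = "pooled"       # or "controls"
    # RDM
    n_subsamples: int = 1000
    n_cases_sub: int = 100
    n_controls_sub: int = 108
    balance_alpha: float = 0.05
    test_alpha: float = 0.05
    keep_fraction: float = 0.5
    # haplotypes
    ld_alpha: float = 0.05
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    rare_hap_pool_freq: float = 0.01
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("maf_min", "snp_call_min", "sample_call_min", "hwe_alpha",
                     "balance_alpha", "test_alpha", "keep_fraction",
                     "ld_alpha", "rare_hap_pool_freq"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("n_subsamples", "n_cases_sub", "n_controls_sub",
                     "em_max_iter"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.maf_scope not in ("pooled", "controls"):
            raise ValueError("maf_scope must be 'pooled' or 'controls'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat-key YAML config; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def with_overrides(self, **overrides) -> "RunConfig":
        return replace(self, **{k: v for k, v in overrides.items()
                                if v is not None})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {f.name: getattr(self, f.name) for f in fields(self)},
            sort_keys=False))


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read PLINK text PED/MAP and recode to minor-allele dosages.

    The minor allele is the less frequent allele over all samples; ties
    at 0.5 break alphabetically. A pair with any "0" allele is treated as
    fully missing. Monomorphic SNPs keep the observed allele as major with
    the alphabetically-first unused base as placeholder minor.
    """
    snp_meta = []
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{map_path}: line {lineno}: expected 4 columns, "
                             f"got {len(parts)}")
        chrom, snp_id, _cm, pos = parts
        snp_meta.append((snp_id, chrom, int(pos)))
    m = len(snp_meta)

    samples: list[str] = []
    allele_rows: list[list[str]] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ValueError(
                f"{ped_path}: row {lineno} (sample {parts[1] if len(parts) > 1 else '?'}): "
                f"expected {6 + 2 * m} columns for {m} SNPs, got {len(parts)}")
        samples.append(parts[1])
        allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype="U1").reshape(len(samples), m, 2)

    snps: list[SNPInfo] = []
    dosages = np.full((len(samples), m), np.nan)
    for j, (snp_id, chrom, pos) in enumerate(snp_meta):
        pair = alleles[:, j, :]
        complete = (pair != "0").all(axis=1)   # half-missing pairs are missing
        observed = pair[complete].ravel()
        bad = set(observed) - set(VALID_BASES)
        if bad:
            raise ValueError(f"{snp_id}: invalid allele codes {sorted(bad)}")
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            raise ValueError(f"{snp_id}: more than two alleles observed")
        if len(uniq) == 0:
            raise ValueError(f"{snp_id}: all genotypes missing")
        if len(uniq) == 1:
            major = str(uniq[0])
            minor = next(b for b in VALID_BASES if b != major)
        else:
            a, b = str(uniq[0]), str(uniq[1])   # uniq is sorted alphabetically
            ca, cb = counts
            if ca < cb or (ca == cb):           # tie -> alphabetical
                minor, major = a, b
            else:
                minor, major = b, a
        snps.append(SNPInfo(snp_id, chrom, pos, minor, major))
        dosages[complete, j] = (pair[complete] == minor).sum(axis=1)
    return GenotypeMatrix(samples, snps, dosages)


def write_ped_map(matrix: GenotypeMatrix,
                  ped_path: str | Path, map_path: str | Path,
                  pheno: Optional[PhenotypeTable] = None) -> None:
    """Write PED/MAP; phenotype column uses PLINK coding (2=case, 1=control,
    -9 when no phenotype table is given)."""
    with open(map_path, "w") as fh:
        for s in matrix.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\n")
    status = None
    if pheno is not None:
        status = pheno.data["status"].reindex(matrix.samples)
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(matrix.samples):
            code = "-9"
            if status is not None and isinstance(status.iloc[i], str):
                code = "2" if status.iloc[i] == "case" else "1"
            row = [sid, sid, "0", "0", "0", code]
            for j, snp in enumerate(matrix.snps):
                d = matrix.dosages[i, j]
                if not np.isfinite(d):
                    row += ["0", "0"]
                else:
                    n_minor = int(d)
                    # alphabetical pair order keeps the file stable under
                    # minor/major role flips at MAF exactly 0.5
                    row += sorted([snp.allele_minor] * n_minor
                                  + [snp.allele_major] * (2 - n_minor))
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# Covariate table
# ---------------------------------------------------------------------------

def read_covariates(tsv_path: str | Path, *,
                    status_dialect: str = "labels") -> PhenotypeTable:
    """Read the tab-delimited covariate table.

    ``status_dialect``: "labels" accepts case/control or 1/0; "plink"
    accepts 2=case, 1=control (-9 = missing). Rows with missing status are
    rejected (dropped with a warning); rows with missing covariates are
    retained and can be flagged via ``PhenotypeTable.missing_covariates``.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{tsv_path}: missing required column sample_id")
    df = df.set_index("sample_id")

    if status_dialect == "labels":
        mapping = {"case": "case", "control": "control", "1": "case", "0": "control"}
    elif status_dialect == "plink":
        mapping = {"2": "case", "1": "control"}
    else:
        raise ValueError(f"unknown status dialect {status_dialect!r}")
    raw = df["status"].astype(str).str.strip().str.lower()
    missing_codes = {"", "nan", "-9", "na"}
    keep = ~raw.isin(missing_codes)
    if (~keep).any():
        logger.warning("dropping %d rows with missing status", (~keep).sum())
    df, raw = df.loc[keep], raw.loc[keep]
    unknown = ~raw.isin(mapping)
    if unknown.any():
        raise ValueError(
            f"unknown status code {raw[unknown].iloc[0]!r} "
            f"for sample {df.index[unknown][0]!r}")
    df["status"] = raw.map(mapping)
    for col in PHENO_COLUMNS[1:]:
        if col not in df.columns:
            raise ValueError(f"{tsv_path}: missing required column {col}")
        df[col] = pd.to_numeric(df[col], errors="coerce")

    anc = df[list(ANCESTRY_COLUMNS)].to_numpy(dtype=float)
    complete = np.isfinite(anc).all(axis=1)
    off = complete & (np.abs(anc.sum(axis=1) - 1.0) > 1e-6)
    if off.any():
        raise ValueError(
            f"ancestry proportions do not sum to 1 for sample "
            f"{df.index[off][0]!r}")
    return PhenotypeTable(df)


def write_covariates(pheno: PhenotypeTable, tsv_path: str | Path, *,
                     status_dialect: str = "labels") -> None:
    df = pheno.data.copy()
    if status_dialect == "plink":
        df["status"] = df["status"].map({"case": "2", "control": "1"})
    out = df.reset_index().rename(columns={"index": "sample_id"})
    if out.columns[0] != "sample_id":
        out = out.rename(columns={out.columns[0]: "sample_id"})
    out.to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _format_cell(v) -> str:
    if isinstance(v, (float, np.floating)):
        if not np.isfinite(v):
            return "NA"
        return format(v, ".6g")
    if v is None:
        return "NA"
    return str(v)


def write_report(results: pd.DataFrame, path: str | Path,
                 format: str = "both") -> None:
    """Write an association/RDM/haplotype report.

    TSV cells are printed at 6 significant digits; the JSON twin keeps full
    float precision. ``format`` is "tsv", "json" or "both" (the TSV path
    gets a ``.json`` sibling).
    """
    path = Path(path)
    if format in ("tsv", "both"):
        cells = results.map(_format_cell)
        with open(path, "w") as fh:
            fh.write("\t".join(map(str, results.columns)) + "\n")
            for _, row in cells.iterrows():
                fh.write("\t".join(row.tolist()) + "\n")
    if format in ("json", "both"):
        jpath = path.with_suffix(".json") if format == "both" else path
        records = []
        for _, row in results.iterrows():
            rec = {}
            for k, v in row.items():
                if isinstance(v, (float, np.floating)):
                    rec[k] = None if not np.isfinite(v) else float(v)
                elif isinstance(v, (int, np.integer)):
                    rec[k] = int(v)
                elif isinstance(v, (bool, np.bool_)):
                    rec[k] = bool(v)
                else:
                    rec[k] = v
            records.append(rec)
        with open(jpath, "w") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a report TSV back as strings (lossless for round-tripping)."""
    return pd.read_csv(path, sep="\t", dtype=str)
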