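"""Core data containers shared by every pipeline stage.

Genotypes are held as a samples x SNPs minor-allele dosage matrix
(float array; 0/1/2 copies of the minor allele, NaN for missing calls).
Phenotypes and covariates are held in a pandas DataFrame indexed by
sample id.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_BASES = ("A", "C", "G", "T")

#: Columns a phenotype table must carry, in canonical order.
PHENO_COLUMNS = (
    "status", "age", "bmi", "anc_eur", "anc_afr", "anc_nat", "ses", "education",
)

ANCESTRY_COLUMNS = ("anc_eur", "anc_afr", "anc_nat")


@dataclass(frozen=True)
class SNPInfo:
    """Identity and allele coding of one biallelic SNP.

    ``allele_minor`` is the allele counted by the dosage matrix; positions
    are 1-based; chromosome is a string so "X" is admissible.
    """

    snp_id: str
    chromosome: str
    position: int
    allele_minor: str
    allele_major: str

    def __post_init__(self) -> None:
        if self.allele_minor not in VALID_BASES:
            raise ValueError(f"{self.snp_id}: bad minor allele {self.allele_minor!r}")
        if self.allele_major not in VALID_BASES:
            raise ValueError(f"{self.snp_id}: bad major allele {self.allele_major!r}")
        if self.allele_minor == self.allele_major:
            raise ValueError(f"{self.snp_id}: minor and major alleles are equal")
        if self.position < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")

    def flipped(self) -> "SNPInfo":
        """Same SNP with the allele roles swapped (dosage d maps to 2-d)."""
        return SNPInfo(self.snp_id, self.chromosome, self.position,
                       self.allele_major, self.allele_minor)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix with SNP metadata."""

    samples: list[str]
    snps: list[SNPInfo]
    dosages: np.ndarray  # (n_samples, n_snps), float, NaN = missing

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.snps = list(self.snps)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs")
        vals = self.dosages[np.isfinite(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        return self.snp_ids.index(snp_id)

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def take_snps(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(self.samples,
                              [self.snps[i] for i in idx],
                              self.dosages[:, idx])

    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix([self.samples[i] for i in idx],
                              self.snps,
                              self.dosages[idx, :])

    def snp_call_rates(self) -> np.ndarray:
        return np.isfinite(self.dosages).mean(axis=0)

    def sample_call_rates(self) -> np.ndarray:
        return np.isfinite(self.dosages).mean(axis=1)


class PhenotypeTable:
    """Per-sample case/control status and covariates.

    Wraps a DataFrame indexed by sample id with the columns in
    :data:`PHENO_COLUMNS`. Status is stored as the strings ``case`` /
    ``control``; ancestry proportions must sum to 1 per sample.
    """

    def __init__(self, data: pd.DataFrame, *, validate: bool = True) -> None:
        missing = [c for c in PHENO_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        self.data = data.loc[:, list(PHENO_COLUMNS)].copy()
        if validate:
            self._validate()

    def _validate(self) -> None:
        bad = ~self.data["status"].isin(["case", "control"])
        if bad.any():
            raise ValueError(
                f"unknown status for samples {list(self.data.index[bad])}")
        anc = self.data[list(ANCESTRY_COLUMNS)].to_numpy(dtype=float)
        ok_rows = np.isfinite(anc).all(axis=1)
        sums = anc[ok_rows].sum(axis=1)
        off = np.abs(sums - 1.0) > 1e-6
        if off.any():
            culprit = self.data.index[ok_rows][off][0]
            raise ValueError(
                f"ancestry proportions do not sum to 1 for sample {culprit!r}")
        if ((anc[ok_rows] < -1e-12) | (anc[ok_rows] > 1 + 1e-12)).any():
            raise ValueError("ancestry proportions outside [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def status(self) -> pd.Series:
        return self.data["status"]

    @property
    def y(self) -> np.ndarray:
        """Binary outcome: 1 = case, 0 = control."""
        return (self.data["status"] == "case").to_numpy(dtype=float)

    @property
    def case_ids(self) -> list[str]:
        return list(self.data.index[self.data["status"] == "case"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.data.index[self.data["status"] == "control"])

    def missing_covariates(self) -> pd.Series:
        """Flag rows with any missing covariate (status is never missing)."""
        covs = self.data.drop(columns=["status"])
        return covs.isna().any(axis=1)

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        return self.data.loc[:, list(names)].to_numpy(dtype=float)

    def subset(self, sample_ids: Iterable[str]) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[list(sample_ids)], validate=False)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        return self.data.equals(other.data)
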