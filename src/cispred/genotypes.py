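"""Genotype dosage container used throughout the package.

A :class:`GenotypeMatrix` holds the n × p matrix of allele dosages for the
cis-SNPs of a single gene (or a whole chromosome before window extraction),
together with per-SNP metadata: base-pair position and minor-allele
frequency.  Dosages are allele counts in {0, 1, 2} or real-valued mean
dosages in [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


def empirical_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency of each column of a dosage matrix.

    The allele frequency is ``mean(dosage)/2``; the minor-allele frequency
    folds it onto (0, 0.5].
    """
    dosages = np.asarray(dosages, dtype=float)
    f = dosages.mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


@dataclass
class GenotypeMatrix:
    """n individuals × p cis-SNPs with per-SNP metadata.

    Parameters
    ----------
    dosages
        n × p array of allele dosages in [0, 2].
    positions
        Base-pair coordinate of each SNP (1-based), strictly increasing
        within the chromosome.
    maf
        Minor-allele frequency of each SNP; must match the dosage columns.
    sample_ids, snp_ids
        Identifiers; generated if omitted.
    chrom
        Chromosome label for all SNPs in this matrix.
    """

    dosages: np.ndarray
    positions: np.ndarray
    maf: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        n, p = self.dosages.shape
        if self.positions.shape != (p,) or self.maf.shape != (p,):
            raise ValueError("positions and maf must have one entry per SNP")
        if p > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not self.sample_ids:
            self.sample_ids = [f"ind{i}" for i in range(n)]
        if not self.snp_ids:
            self.snp_ids = [f"snp{j}" for j in range(p)]
        if len(self.sample_ids) != n or len(self.snp_ids) != p:
            raise ValueError("id lists do not match the dosage shape")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    def validate_maf(self, atol: float = 1e-12) -> None:
        """Check the stored MAF against the dosage columns."""
        if not np.allclose(self.maf, empirical_maf(self.dosages), atol=atol, rtol=0):
            raise ValueError("stored maf does not match dosages")

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return replace(
            self,
            dosages=self.dosages[:, idx],
            positions=self.positions[idx],
            maf=self.maf[idx],
            snp_ids=[self.snp_ids[j] for j in idx],
        )

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosages=self.dosages[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )


def standardize_columns(
    X: np.ndarray, means: np.ndarray | None = None, scales: np.ndarray | None = None
):
    """Center columns and scale them to unit variance (1/n convention).

    Zero-variance columns get scale 1 so they standardize to all-zero rather
    than dividing by zero.  Returns ``(X_std, means, scales)``; pass training
    ``means``/``scales`` to transform held-out data consistently.
    """
    X = np.asarray(X, dtype=float)
    if means is None:
        means = X.mean(axis=0)
    if scales is None:
        scales = X.std(axis=0)
        scales = np.where(scales > 0, scales, 1.0)
    return (X - means) / scales, means, scales
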