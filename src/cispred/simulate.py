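"""Synthetic data: LD-structured genotypes, architecture-specific expression
phenotypes, and gene landscapes for the enrichment stage.

The genotype generator emulates the cis-region of a single gene: a dosage
matrix with local linkage disequilibrium and a minor-allele-frequency floor,
standing in for real (already MAF-filtered) genotype data.  Haplotypes are
drawn by thresholding a latent first-order autoregressive Gaussian at the
per-SNP allele-frequency quantile and summing two haplotypes per individual,
so adjacent SNPs are correlated with strength controlled by ``ld_rho``.

Expression phenotypes follow three genetic architectures:

* **Scenario I** — a hybrid: every SNP carries a small (polygenic) effect and
  ``n_sparse`` randomly chosen SNPs carry additional large effects; the two
  parts are scaled so they contribute fixed shares (default 0.60/0.40) of the
  total proportion of expression variance explained (PVE).
* **Scenario II** — purely polygenic: all SNPs causal, Gaussian effects.
* **Scenario III** — purely sparse: only ``n_sparse`` SNPs causal.

Scaling is exact in-sample: the sparse genetic component is orthogonalized
against the polygenic one and the noise against the total genetic values, so
realized PVE and the polygenic/sparse split match their targets to machine
precision (see docs/methods.md).  Variances use the population (1/n)
convention throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from .genotypes import GenotypeMatrix, empirical_maf
from .records import GeneResult, GenomicRegion

__all__ = [
    "ArchitectureConfig",
    "SimulatedGene",
    "simulate_genotypes",
    "scale_to_pve",
    "simulate_gene",
    "simulate_gene_landscape",
    "replicate_rng",
]

_SCENARIOS = ("I", "II", "III")


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent, reproducible stream for one simulation replicate.

    Seeds derive from the (study seed, replicate index) pair via numpy's
    SeedSequence, so replicates are statistically independent yet fully
    determined by the pair.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate)]))


@dataclass
class ArchitectureConfig:
    """Genetic architecture of a simulated gene.

    ``polygenic_share`` is the fraction of the *total* PVE contributed by the
    polygenic part (the remainder comes from the sparse part).  Scenario II
    forces share 1 and no sparse SNPs; scenario III forces share 0.
    """

    scenario: str
    total_pve: float = 0.5
    n_sparse: int = 15
    polygenic_share: float | None = None
    n_replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"scenario must be one of {_SCENARIOS}")
        if not 0.0 < self.total_pve < 1.0:
            raise ValueError("total_pve must lie in (0, 1)")
        if self.polygenic_share is None:
            self.polygenic_share = {"I": 0.6, "II": 1.0, "III": 0.0}[self.scenario]
        if self.scenario == "II":
            if self.polygenic_share != 1.0:
                raise ValueError("scenario II is purely polygenic (share must be 1)")
            self.n_sparse = 0
        if self.scenario == "III" and self.polygenic_share != 0.0:
            raise ValueError("scenario III is purely sparse (share must be 0)")
        if self.scenario in ("I", "III") and self.n_sparse < 1:
            raise ValueError(f"scenario {self.scenario} needs n_sparse >= 1")
        if not 0.0 <= self.polygenic_share <= 1.0:
            raise ValueError("polygenic_share must lie in [0, 1]")


@dataclass
class SimulatedGene:
    """One simulated expression phenotype and its generating truth."""

    expression: np.ndarray
    beta_polygenic: np.ndarray
    beta_sparse: np.ndarray
    sparse_indices: np.ndarray
    residual_sd: float
    realized_pve: float
    scenario: str = ""
    part_pve: tuple[float, float] = (0.0, 0.0)  # (polygenic, sparse) shares of var(y)


def simulate_genotypes(
    n: int,
    p: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    ld_rho: float = 0.9,
    seed: int = 0,
    chrom: str = "1",
    start_position: int = 1_000_000,
    enforce_maf_floor: bool = True,
) -> GenotypeMatrix:
    """Draw an LD-structured dosage matrix for one cis-region.

    Each of the 2n haplotypes is a latent AR(1) Gaussian across SNPs with
    autocorrelation ``ld_rho``; the minor allele is called where the latent
    value falls below the allele-frequency quantile.  With
    ``enforce_maf_floor`` the realized minor-allele count of every SNP is
    floored at ``ceil(2n * maf_low)`` by shifting that SNP's threshold, so the
    matrix looks like post-MAF-filter data.
    """
    if n < 2 or p < 1:
        raise ValueError("need n >= 2 individuals and p >= 1 SNPs")
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    freqs = rng.uniform(maf_low, maf_high, size=p)
    innov = rng.standard_normal((2 * n, p))
    Z = np.empty((2 * n, p))
    Z[:, 0] = innov[:, 0]
    scale = math.sqrt(1.0 - ld_rho**2)
    for j in range(1, p):
        Z[:, j] = ld_rho * Z[:, j - 1] + scale * innov[:, j]

    thresholds = ndtri(freqs)
    alleles = Z < thresholds  # minor-allele indicator per haplotype
    if enforce_maf_floor:
        k_min = math.ceil(2 * n * maf_low)
        counts = alleles.sum(axis=0)
        for j in np.flatnonzero(counts < k_min):
            cutoff = np.partition(Z[:, j], k_min - 1)[k_min - 1]
            alleles[:, j] = Z[:, j] <= cutoff
    dosages = alleles[:n].astype(float) + alleles[n:].astype(float)

    gaps = rng.integers(1, 1000, size=p)
    positions = start_position + np.cumsum(gaps)
    return GenotypeMatrix(
        dosages=dosages,
        positions=positions,
        maf=empirical_maf(dosages),
        chrom=chrom,
    )


def scale_to_pve(genetic_values: np.ndarray, target_pve: float):
    """Residual standard deviation that sets the in-sample PVE.

    Returns ``(genetic_values, residual_sd)`` with
    ``var(g) / (var(g) + residual_sd**2) == target_pve`` exactly, where
    ``var`` is the population variance of the (unmodified) genetic values.
    """
    g = np.asarray(genetic_values, dtype=float)
    if not 0.0 < target_pve < 1.0:
        raise ValueError("target_pve must lie in (0, 1)")
    var_g = float(np.var(g))
    if var_g <= 0.0:
        raise ValueError("genetic values have zero variance; cannot set PVE")
    residual_sd = math.sqrt(var_g * (1.0 - target_pve) / target_pve)
    return g, residual_sd


def _center(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def _residualize(v: np.ndarray, onto: np.ndarray) -> tuple[np.ndarray, float]:
    """Remove the in-sample projection of ``v`` on ``onto`` (both centered)."""
    denom = float(onto @ onto)
    c = float(v @ onto) / denom if denom > 0 else 0.0
    return v - c * onto, c


def simulate_gene(
    genotypes: GenotypeMatrix,
    config: ArchitectureConfig,
    replicate_seed: int = 0,
) -> SimulatedGene:
    """Simulate one expression phenotype under the configured architecture.

    Effect sizes are standard normal.  Components are rescaled so the total
    genetic variance equals ``total_pve`` and the residual variance
    ``1 - total_pve`` (phenotypic variance 1), with the polygenic/sparse parts
    holding exactly ``polygenic_share``/``1 - polygenic_share`` of the genetic
    variance.  Expression is centered.
    """
    X = genotypes.dosages
    n, p = X.shape
    if config.n_sparse > p:
        raise ValueError(f"n_sparse={config.n_sparse} exceeds p={p}")
    rng = replicate_rng(config.seed, replicate_seed)
    Xc = X - X.mean(axis=0)

    pve = config.total_pve
    share = config.polygenic_share
    var_y = 1.0
    var_g = pve * var_y

    beta_poly = np.zeros(p)
    beta_sparse = np.zeros(p)
    sparse_idx = np.array([], dtype=int)
    g = np.zeros(n)

    if config.scenario in ("I", "II"):
        b_poly = rng.standard_normal(p)
        g_poly = Xc @ b_poly
        if np.var(g_poly) <= 0:
            raise ValueError("degenerate genotypes: polygenic values constant")
    if config.scenario in ("I", "III"):
        sparse_idx = np.sort(rng.choice(p, size=config.n_sparse, replace=False))
        b_sp = rng.standard_normal(config.n_sparse)
        g_sp = Xc[:, sparse_idx] @ b_sp
        if np.var(g_sp) <= 0:
            raise ValueError("degenerate genotypes: sparse values constant")

    if config.scenario == "II":
        a = math.sqrt(var_g / np.var(g_poly))
        g = a * g_poly
        beta_poly = a * b_poly
    elif config.scenario == "III":
        b = math.sqrt(var_g / np.var(g_sp))
        g = b * g_sp
        beta_sparse[sparse_idx] = b * b_sp
    else:  # scenario I: orthogonalize the sparse part so shares are exact
        g_sp_perp, c = _residualize(g_sp, g_poly)
        if np.var(g_sp_perp) <= 0:
            raise ValueError("sparse part collinear with polygenic part")
        a = math.sqrt(share * var_g / np.var(g_poly))
        b = math.sqrt((1.0 - share) * var_g / np.var(g_sp_perp))
        g = a * g_poly + b * g_sp_perp
        # g = Xc @ ((a - b*c) * b_poly) + Xc[:, idx] @ (b * b_sp)
        beta_poly = (a - b * c) * b_poly
        beta_sparse[sparse_idx] = b * b_sp

    _, residual_sd = scale_to_pve(g, pve)
    eps = rng.standard_normal(n)
    eps, _ = _residualize(_center(eps), g)  # exactly uncorrelated with g
    eps *= residual_sd / eps.std()
    y = _center(g + eps)

    realized = float(np.var(g) / np.var(y))
    if config.scenario == "I":
        part = (
            float(np.var(a * g_poly) / np.var(y)),
            float(np.var(b * g_sp_perp) / np.var(y)),
        )
    elif config.scenario == "II":
        part = (realized, 0.0)
    else:
        part = (0.0, realized)

    return SimulatedGene(
        expression=y,
        beta_polygenic=beta_poly,
        beta_sparse=beta_sparse,
        sparse_indices=sparse_idx,
        residual_sd=residual_sd,
        realized_pve=realized,
        scenario=config.scenario,
        part_pve=part,
    )


def simulate_gene_landscape(
    n_genes: int,
    chrom_lengths: dict[str, int],
    enriched_region: GenomicRegion | None = None,
    enrichment_factor: float = 1.0,
    base_rate: float = 0.05,
    seed: int = 0,
    method: str = "bslmm",
    gene_halfwidth: int = 1000,
) -> list[GeneResult]:
    """Scatter scored genes over a genome, enriching one region.

    Genes are placed uniformly (chromosomes weighted by length); each gene is
    predictive (R² >= 0.05) with probability ``base_rate`` outside the
    enriched region and ``base_rate * enrichment_factor`` inside.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    if base_rate * enrichment_factor > 1.0 or base_rate < 0:
        raise ValueError("base_rate * enrichment_factor must lie in [0, 1]")
    if enriched_region is not None:
        L = chrom_lengths.get(enriched_region.chrom)
        if L is None or enriched_region.end > L:
            raise ValueError("enriched region falls outside its chromosome")
    if n_genes == 0:
        return []

    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    chrom_draw = rng.choice(len(chroms), size=n_genes, p=lengths / lengths.sum())

    genes: list[GeneResult] = []
    for i in range(n_genes):
        chrom = chroms[chrom_draw[i]]
        mid = int(rng.integers(1, chrom_lengths[chrom] + 1))
        rate = base_rate
        if enriched_region is not None and enriched_region.contains(chrom, mid):
            rate = base_rate * enrichment_factor
        predictive = rng.random() < rate
        r2 = 0.05 + 0.55 * rng.random() if predictive else 0.05 * rng.random()
        genes.append(
            GeneResult(
                gene_id=f"gene{i}",
                chrom=chrom,
                start=max(1, mid - gene_halfwidth),
                end=min(chrom_lengths[chrom], mid + gene_halfwidth),
                r2={method: float(r2)},
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.midpoint))
    return genes
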