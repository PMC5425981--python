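"""Predictive-gene classification and regional enrichment statistics.

A gene is *predictive* when its held-out prediction R² reaches 0.05
(inclusive).  For a genomic region the enrichment-fold is

    fold = (n_predictive_in / n_predictive_total)
           / (region_length / reference_length)

i.e. the proportion of predictive genes whose midpoint falls in the region
divided by the region's share of the reference length.  By default the
reference is the region's own chromosome (its predictive genes and its
length); a genome-wide reference is available for whole-genome LD-block
scans.  Enrichment of one region against the folds of background regions is
tested with an approximate z-test:

    z = (fold_target − mean(background folds)) / sd(background folds)

with a one-sided upper-tail normal p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .records import GeneResult, GenomicRegion

__all__ = [
    "EnrichmentResult",
    "predictive_gene_set",
    "enrichment_fold",
    "fold_from_counts",
    "block_enrichment_scan",
    "z_test_enrichment",
]

PREDICTIVE_R2_THRESHOLD = 0.05


@dataclass
class EnrichmentResult:
    region: GenomicRegion
    n_predictive_in: int
    n_predictive_total: int
    region_length: float
    reference_length: float
    fold: float
    z: float = float("nan")
    p_value: float = float("nan")


def predictive_gene_set(
    results: list[GeneResult],
    threshold: float = PREDICTIVE_R2_THRESHOLD,
    method: str = "bslmm",
) -> list[GeneResult]:
    """Genes whose R² for ``method`` meets the threshold (inclusive)."""
    if not 0.0 <= threshold:
        raise ValueError("threshold must be non-negative")
    out = []
    for g in results:
        if method not in g.r2:
            raise KeyError(f"gene {g.gene_id} has no R² for method '{method}'")
        if g.r2[method] >= threshold:
            out.append(g)
    return out


def fold_from_counts(
    n_predictive_in: int,
    n_predictive_total: int,
    region_length: float,
    reference_length: float,
) -> float:
    """Enrichment-fold from raw counts and lengths (any consistent length unit)."""
    if n_predictive_total < 1:
        raise ValueError("no predictive genes in the reference set; fold undefined")
    if not 0 < region_length <= reference_length:
        raise ValueError("need 0 < region_length <= reference_length")
    return (n_predictive_in / n_predictive_total) / (region_length / reference_length)


def enrichment_fold(
    region: GenomicRegion,
    predictive: list[GeneResult],
    reference_length: float,
) -> EnrichmentResult:
    """Fold for one region; gene membership by gene midpoint.

    ``predictive`` is the reference set of predictive genes (e.g. those of
    the region's chromosome); ``reference_length`` the matching total length.
    """
    n_total = len(predictive)
    n_in = sum(1 for g in predictive if region.contains(g.chrom, g.midpoint))
    fold = fold_from_counts(n_in, n_total, region.length, reference_length)
    return EnrichmentResult(
        region=region,
        n_predictive_in=n_in,
        n_predictive_total=n_total,
        region_length=region.length,
        reference_length=reference_length,
        fold=fold,
    )


def _check_non_overlapping(blocks: list[GenomicRegion]) -> None:
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)
    offenders = []
    for chrom, bs in by_chrom.items():
        bs = sorted(bs, key=lambda b: b.start)
        for a, b in zip(bs, bs[1:]):
            if b.start <= a.end:
                offenders.append((a, b))
    if offenders:
        msg = "; ".join(
            f"{a.chrom}:{a.start}-{a.end} overlaps {b.chrom}:{b.start}-{b.end}"
            for a, b in offenders
        )
        raise ValueError(f"overlapping blocks: {msg}")


def block_enrichment_scan(
    blocks: list[GenomicRegion],
    predictive: list[GeneResult],
    all_results: list[GeneResult],
    chrom_lengths: dict[str, int],
    reference: str = "chromosome",
):
    """Per-block enrichment folds plus distribution summaries.

    With ``reference="chromosome"`` each block's fold is computed against the
    predictive genes and length of its own chromosome; with ``"genome"``
    against all predictive genes and the total genome length.  Blocks on
    chromosomes without predictive genes get a NaN fold and are excluded
    from the summaries.
    """
    if reference not in ("chromosome", "genome"):
        raise ValueError("reference must be 'chromosome' or 'genome'")
    _check_non_overlapping(blocks)
    genome_length = float(sum(chrom_lengths.values()))
    pred_by_chrom: dict[str, list[GeneResult]] = {}
    for g in predictive:
        pred_by_chrom.setdefault(g.chrom, []).append(g)

    results = []
    for block in blocks:
        if block.chrom not in chrom_lengths or block.end > chrom_lengths[block.chrom]:
            raise ValueError(f"block {block.chrom}:{block.start}-{block.end} exceeds chromosome")
        if reference == "chromosome":
            ref_genes = pred_by_chrom.get(block.chrom, [])
            ref_len = float(chrom_lengths[block.chrom])
        else:
            ref_genes = predictive
            ref_len = genome_length
        if not ref_genes:
            results.append(
                EnrichmentResult(block, 0, 0, block.length, ref_len, float("nan"))
            )
            continue
        results.append(enrichment_fold(block, ref_genes, ref_len))

    folds = np.array([r.fold for r in results])
    valid = folds[np.isfinite(folds)]
    summary = {
        "n_blocks": len(blocks),
        "median_fold": float(np.median(valid)) if valid.size else float("nan"),
        "max_fold": float(valid.max()) if valid.size else float("nan"),
        "n_fold_ge_4": int((valid >= 4).sum()),
        "n_fold_ge_10": int((valid >= 10).sum()),
        "n_fold_ge_20": int((valid >= 20).sum()),
    }
    return results, summary


def z_test_enrichment(target_fold: float, background_folds) -> tuple[float, float]:
    """Approximate z-test of one region's fold against background folds.

    One-sided in the enrichment direction: p = 1 − Φ(z).
    """
    bg = np.asarray(background_folds, dtype=float)
    bg = bg[np.isfinite(bg)]
    if bg.size < 3:
        raise ValueError("need at least 3 background folds")
    sd = bg.std(ddof=1)
    if sd <= 0:
        raise ValueError("background folds have zero dispersion")
    z = (target_fold - bg.mean()) / sd
    return float(z), float(norm.sf(z))


def write_enrichment_tsv(results: list[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tlabel\tn_predictive_in\tn_predictive_total\t"
            "region_length\treference_length\tfold\tz\tp_value\n"
        )
        for r in results:
            fh.write(
                f"{r.region.chrom}\t{r.region.start}\t{r.region.end}\t{r.region.label}\t"
                f"{r.n_predictive_in}\t{r.n_predictive_total}\t{r.region_length:.10g}\t"
                f"{r.reference_length:.10g}\t{r.fold:.6g}\t{r.z:.6g}\t{r.p_value:.6g}\n"
            )
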