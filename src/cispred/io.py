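"""Readers and writers for the plain-text formats the pipeline speaks.

Genotypes travel as BIMBAM mean-genotype files (one row per SNP: id, minor
allele, major allele, then one mean dosage per sample) with a companion SNP
location file, or as standard VCF (dosage from DS when present, otherwise
from GT).  Phenotypes are one value per line in the sample order of the
genotype file.  Regions arrive as BED (0-based half-open, converted to the
package's 1-based closed convention at this boundary) and chromosome lengths
as a two-column TSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, empirical_maf
from .records import GeneResult, GenomicRegion

__all__ = [
    "write_bimbam",
    "read_bimbam",
    "write_phenotype",
    "read_phenotype",
    "write_truth",
    "read_bed",
    "write_bed",
    "read_chrom_lengths",
    "read_gene_scores",
    "write_gene_scores",
    "read_vcf",
    "write_vcf",
]


def write_bimbam(genotypes: GenotypeMatrix, geno_path, snp_path=None) -> None:
    """BIMBAM mean-genotype file plus (optionally) a SNP location file."""
    with open(geno_path, "w") as fh:
        for j, sid in enumerate(genotypes.snp_ids):
            dosages = "\t".join(f"{d:g}" for d in genotypes.dosages[:, j])
            fh.write(f"{sid}\tA\tG\t{dosages}\n")
    if snp_path is not None:
        with open(snp_path, "w") as fh:
            for j, sid in enumerate(genotypes.snp_ids):
                fh.write(f"{sid}\t{genotypes.positions[j]}\t{genotypes.chrom}\n")


def read_bimbam(geno_path, snp_path=None, chrom: str = "1") -> GenotypeMatrix:
    snp_ids, rows = [], []
    with open(geno_path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError("BIMBAM rows need id, two alleles and dosages")
            snp_ids.append(parts[0])
            rows.append([float(x) for x in parts[3:]])
    dosages = np.array(rows).T
    if snp_path is not None:
        pos_of, chrom_of = {}, {}
        with open(snp_path) as fh:
            for line in fh:
                sid, pos, *rest = line.split()
                pos_of[sid] = int(pos)
                if rest:
                    chrom_of[sid] = rest[0]
        positions = np.array([pos_of[s] for s in snp_ids])
        chroms = {chrom_of.get(s, chrom) for s in snp_ids}
        if len(chroms) > 1:
            raise ValueError("a GenotypeMatrix holds a single chromosome")
        chrom = chroms.pop()
        order = np.argsort(positions, kind="stable")
        dosages = dosages[:, order]
        positions = positions[order]
        snp_ids = [snp_ids[j] for j in order]
    else:
        positions = np.arange(1, len(snp_ids) + 1)
    return GenotypeMatrix(
        dosages=dosages,
        positions=positions,
        maf=empirical_maf(dosages),
        snp_ids=snp_ids,
        chrom=chrom,
    )


def write_phenotype(values, path) -> None:
    with open(path, "w") as fh:
        for v in np.asarray(values, dtype=float):
            fh.write(f"{v:.10g}\n")


def read_phenotype(path) -> np.ndarray:
    return np.loadtxt(path, ndmin=1)


def write_truth(gene, snp_ids, path) -> None:
    """Effect sizes and realized quantities of a simulated gene."""
    with open(path, "w") as fh:
        fh.write(f"# scenario\t{gene.scenario}\n")
        fh.write(f"# realized_pve\t{gene.realized_pve:.10g}\n")
        fh.write(f"# residual_sd\t{gene.residual_sd:.10g}\n")
        fh.write("snp_id\tbeta_polygenic\tbeta_sparse\tis_sparse\n")
        sparse = set(int(i) for i in gene.sparse_indices)
        for j, sid in enumerate(snp_ids):
            fh.write(
                f"{sid}\t{gene.beta_polygenic[j]:.10g}\t{gene.beta_sparse[j]:.10g}\t"
                f"{int(j in sparse)}\n"
            )


def read_bed(path) -> list[GenomicRegion]:
    """BED (0-based half-open) to 1-based closed regions."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            regions.append(GenomicRegion(chrom=chrom, start=start + 1, end=end, label=label))
    return regions


def write_bed(regions: list[GenomicRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.label}\n")


def read_chrom_lengths(path) -> dict[str, int]:
    lengths = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, length = line.split()[:2]
            lengths[chrom] = int(length)
    return lengths


def write_gene_scores(results: list[GeneResult], path) -> None:
    methods = sorted({m for g in results for m in g.r2})
    with open(path, "w") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "chrom", "start", "end"] + [f"r2_{m}" for m in methods])
        for g in results:
            writer.writerow(
                [g.gene_id, g.chrom, g.start, g.end]
                + [f"{g.r2[m]:.6g}" if m in g.r2 else "NA" for m in methods]
            )


def read_gene_scores(path) -> list[GeneResult]:
    df = pd.read_csv(path, sep="\t")
    method_cols = [c for c in df.columns if c.startswith("r2_")]
    out = []
    for row in df.itertuples(index=False):
        r2 = {
            c[3:]: float(getattr(row, c))
            for c in method_cols
            if pd.notna(getattr(row, c))
        }
        out.append(
            GeneResult(
                gene_id=str(row.gene), chrom=str(row.chrom),
                start=int(row.start), end=int(row.end), r2=r2,
            )
        )
    return out


def read_vcf(path, chrom: str | None = None) -> GenotypeMatrix:
    """Load dosages from a VCF; uses the DS FORMAT field when present."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, positions, rows = [], [], []
    seen_chrom = chrom
    for var in vcf:
        if chrom is not None and var.CHROM != chrom:
            continue
        if seen_chrom is None:
            seen_chrom = var.CHROM
        elif var.CHROM != seen_chrom:
            raise ValueError("VCF spans multiple chromosomes; pass chrom=")
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).ravel()
        else:
            gts = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 3 hom-alt
            dos = np.where(gts == 3, 2.0, np.where(gts == 1, 1.0, 0.0))
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)
        rows.append(dos)
    vcf.close()
    if not rows:
        raise ValueError("no variants read from VCF")
    dosages = np.array(rows).T
    positions = np.array(positions)
    order = np.argsort(positions, kind="stable")
    dosages = dosages[:, order]
    return GenotypeMatrix(
        dosages=dosages,
        positions=positions[order],
        maf=empirical_maf(dosages),
        sample_ids=samples,
        snp_ids=[snp_ids[j] for j in order],
        chrom=seen_chrom or "1",
    )


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Export with dosages rounded to hard diploid genotypes."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(
        f"##contig=<ID={genotypes.chrom},length={int(genotypes.positions.max()) + 1}>"
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in genotypes.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, sid in enumerate(genotypes.snp_ids):
            rec = out.new_record(
                contig=genotypes.chrom,
                start=int(genotypes.positions[j]) - 1,
                stop=int(genotypes.positions[j]),
                alleles=("G", "A"),
                id=sid,
            )
            hard = np.clip(np.rint(genotypes.dosages[:, j]), 0, 2).astype(int)
            for s, d in zip(genotypes.sample_ids, hard):
                rec.samples[s]["GT"] = [(0, 0), (0, 1), (1, 1)][d]
            out.write(rec)


def _ensure_parent(path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
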