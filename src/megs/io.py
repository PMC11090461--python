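"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF (bi-allelic sites; read through cyvcf2) or as a TSV
dosage matrix with a marker-metadata sidecar; microbiome tables as TSV
(observations x ASVs) with a taxonomy TSV; designs and phenotypes as CSV;
generative ground truth as a JSON sidecar.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .microbiome import MicrobiomeTable
from .synthetic_data import SimulatedDataset, TruthBundle

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_microbiome_tsv",
    "write_microbiome_tsv",
    "read_design_csv",
    "write_design_csv",
    "write_truth_json",
    "read_truth_json",
    "write_dataset",
]


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load bi-allelic SNPs from a VCF; multi-allelic rows are skipped with a warning."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    marker_ids, chrom, pos, rows = [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        gt = np.asarray(var.genotype.array())[:, :2].astype(float)
        gt[gt < 0] = np.nan
        rows.append(np.nansum(gt, axis=1) + np.where(np.isnan(gt).all(axis=1), np.nan, 0.0))
    if n_skipped:
        logger.warning("skipped %d multi-allelic VCF records", n_skipped)
    dosages = np.column_stack(rows) if rows else np.empty((len(individual_ids), 0))
    return GenotypeMatrix(individual_ids=individual_ids, marker_ids=marker_ids,
                          chrom=np.array(chrom), pos_bp=np.array(pos, dtype=np.int64),
                          dosages=dosages)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as an uncompressed VCFv4.2 with synthetic REF/ALT alleles."""
    path = Path(path)
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=megs\n")
        for c in pd.unique(pd.Series(geno.chrom)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.individual_ids) + "\n")
        for j in range(geno.n_markers):
            calls = [gt_of.get(d, "./.") if not np.isnan(d) else "./."
                     for d in geno.dosages[:, j]]
            fh.write(f"{geno.chrom[j]}\t{geno.pos_bp[j]}\t{geno.marker_ids[j]}"
                     f"\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def write_genotypes_tsv(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Dosage matrix TSV (rows = individuals) plus a `<prefix>.markers.tsv` sidecar."""
    prefix = Path(prefix)
    pd.DataFrame(geno.dosages, index=pd.Index(geno.individual_ids, name="individual_id"),
                 columns=geno.marker_ids).to_csv(f"{prefix}.dosages.tsv", sep="\t")
    pd.DataFrame({"marker_id": geno.marker_ids, "chrom": geno.chrom,
                  "pos": geno.pos_bp}).to_csv(f"{prefix}.markers.tsv", sep="\t", index=False)


def read_genotypes_tsv(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    dosages = pd.read_csv(f"{prefix}.dosages.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(f"{prefix}.markers.tsv", sep="\t")
    if list(dosages.columns) != meta["marker_id"].astype(str).tolist():
        raise ValueError("marker sidecar does not match dosage columns")
    return GenotypeMatrix(individual_ids=dosages.index.astype(str).tolist(),
                          marker_ids=meta["marker_id"].astype(str).tolist(),
                          chrom=meta["chrom"].to_numpy(),
                          pos_bp=meta["pos"].to_numpy(dtype=np.int64),
                          dosages=dosages.to_numpy(dtype=float))


def write_microbiome_tsv(table: MicrobiomeTable, prefix: str | Path) -> None:
    prefix = Path(prefix)
    table.values.to_csv(f"{prefix}.abundance.tsv", sep="\t")
    if table.taxonomy is not None:
        table.taxonomy.rename(columns={"class_": "class"}).to_csv(
            f"{prefix}.taxonomy.tsv", sep="\t")
    if table.annotations is not None:
        table.annotations.to_csv(f"{prefix}.annotations.tsv", sep="\t")


def read_microbiome_tsv(prefix: str | Path) -> MicrobiomeTable:
    prefix = Path(prefix)
    values = pd.read_csv(f"{prefix}.abundance.tsv", sep="\t", index_col=0)
    taxonomy = None
    tax_path = Path(f"{prefix}.taxonomy.tsv")
    if tax_path.exists():
        taxonomy = pd.read_csv(tax_path, sep="\t", index_col=0).rename(
            columns={"class": "class_"})
    annotations = None
    ann_path = Path(f"{prefix}.annotations.tsv")
    if ann_path.exists():
        annotations = pd.read_csv(ann_path, sep="\t", index_col=0)
    return MicrobiomeTable(values=values, taxonomy=taxonomy, annotations=annotations)


def write_design_csv(design: pd.DataFrame, path: str | Path,
                     phenotype: pd.Series | None = None) -> None:
    out = design.copy()
    if phenotype is not None:
        out[phenotype.name or "phenotype"] = phenotype.loc[design.index]
    out.to_csv(path)


def read_design_csv(path: str | Path) -> tuple[pd.DataFrame, pd.Series | None]:
    df = pd.read_csv(path, index_col=0)
    y = None
    if "phenotype" in df.columns:
        y = df.pop("phenotype")
    return df, y


def write_truth_json(truth: TruthBundle, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_jsonable(), indent=1))


def read_truth_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, str]:
    """Write a simulated dataset to a directory; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotypes_tsv(ds.genotypes, out / "genotypes")
    write_microbiome_tsv(ds.microbiome, out / "microbiome")
    write_design_csv(ds.design, out / "design.csv", phenotype=ds.phenotype)
    write_truth_json(ds.truth, out / "truth.json")
    return {
        "genotypes": str(out / "genotypes.dosages.tsv"),
        "markers": str(out / "genotypes.markers.tsv"),
        "abundance": str(out / "microbiome.abundance.tsv"),
        "taxonomy": str(out / "microbiome.taxonomy.tsv"),
        "design": str(out / "design.csv"),
        "truth": str(out / "truth.json"),
    }
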