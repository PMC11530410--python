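"""Readers and writers for the pipeline's file formats.

VCFv4.2 is the genotype interchange format (read through :mod:`cyvcf2`,
written as plain text); everything else is tab-separated tables handled with
pandas: the variant-effect annotation table, the population map, chromosome
sizes, and gridded climate tables.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

ANNOTATION_COLUMNS = ("chrom", "pos", "effect", "aa_ref", "aa_alt")
POPMAP_COLUMNS = ("sample", "population", "lat", "lon")


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------
def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a multi-sample VCF of biallelic SNPs into a GenotypeMatrix.

    Multiallelic records raise; the GT field is converted to alt-allele
    dosage with ``-1`` for missing calls.
    """
    from cyvcf2 import VCF

    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"site {rec.CHROM}:{rec.POS} is not biallelic ({len(rec.ALT)} ALT alleles)"
            )
        chroms.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        # gts012=True: 0/1/2 dosage, 3 = missing
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        rows.append(g)
    vcf.close()
    if not rows:
        raise ValueError(f"VCF {path} contains no variant records")
    sites = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": ref, "alt": alt})
    return GenotypeMatrix(samples=samples, sites=sites, genotypes=np.stack(rows, axis=1))


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | os.PathLike,
    chrom_sizes: Mapping[str, int] | None = None,
) -> None:
    """Write a GenotypeMatrix as an uncompressed VCFv4.2 file.

    ``chrom_sizes`` (chromosome -> length in bp) populates ``##contig``
    header lines so the file round-trips with its companion sizes table.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##source=loadscape"]
    if chrom_sizes:
        for chrom, size in chrom_sizes.items():
            lines.append(f"##contig=<ID={chrom},length={int(size)}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(matrix.samples)
    lines.append("\t".join(header))
    sites = matrix.sites
    gt = matrix.genotypes
    for j in range(matrix.n_sites):
        row = [
            str(sites.at[j, "chrom"]),
            str(int(sites.at[j, "pos"])),
            ".",
            str(sites.at[j, "ref"]),
            str(sites.at[j, "alt"]),
            ".",
            "PASS",
            ".",
            "GT",
        ]
        row.extend(_GT_STRINGS[int(g)] for g in gt[:, j])
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Plain TSV tables
# ----------------------------------------------------------------------
def read_annotation_table(path: str | os.PathLike) -> pd.DataFrame:
    """Annotation TSV: chrom, pos, effect, aa_ref, aa_alt (amino acids may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "aa_ref": str, "aa_alt": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table {path} lacks columns {missing}")
    df["aa_ref"] = df["aa_ref"].fillna("")
    df["aa_alt"] = df["aa_alt"].fillna("")
    return df


def write_annotation_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_popmap(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str})
    missing = [c for c in POPMAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"population map {path} lacks columns {missing}")
    return df


def write_popmap(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={0: str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{int(size)}\n")


def read_climate_table(path: str | os.PathLike) -> pd.DataFrame:
    """Gridded climate TSV: cell, lat, lon, then one column per variable."""
    df = pd.read_csv(path, sep="\t")
    for col in ("cell", "lat", "lon"):
        if col not in df.columns:
            raise ValueError(f"climate table {path} lacks column {col!r}")
    return df


def write_climate_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
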