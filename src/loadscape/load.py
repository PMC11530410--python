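"""Polarization, mutation classification, and the three load statistics.

Sites are polarized against the cohort: the allele homozygous in more than
50% of genotyped individuals is taken as ancestral; sites with no such
majority, or whose inferred ancestral allele differs from the reference
genome (a reference-bias guard), are excluded.  Derived alleles at polarized
sites are then classed SYN (synonymous), TOL (missense, Grantham 5-150),
DEL (missense, Grantham > 150) or LOF (stop gain / splice acceptor / splice
donor), and counted per individual as heterozygous or homozygous-derived.

Load statistics per individual:

* homozygosity load (per class) = 2*n_hom / (2*n_hom + n_het) — the share of
  derived alleles sitting in homozygotes;
* masked load   = derived heterozygous DEL+LOF alleles / SYN derived alleles;
* realized load = 2 * derived homozygous DEL+LOF loci  / SYN derived alleles.

``count_mode="loci"`` switches the masked/realized normalization to SYN locus
counts (n_hom + n_het) with unit weight per homozygous locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .grantham import grantham_score

logger = logging.getLogger(__name__)

POLARIZED = "polarized"
EXCLUDED_NO_MAJORITY = "excluded_no_majority"
EXCLUDED_REF_MISMATCH = "excluded_ref_mismatch"

LOAD_CLASSES = ("SYN", "TOL", "DEL", "LOF")
LOF_EFFECTS = ("stop_gained", "splice_acceptor", "splice_donor")

TOL_MIN_GS = 5
DEL_MIN_GS = 150  # exclusive: GS > 150 is DEL, 5 <= GS <= 150 is TOL


@dataclass
class PolarizationResult:
    table: pd.DataFrame  # chrom, pos, ancestral, derived, status

    @property
    def polarized_mask(self) -> np.ndarray:
        return (self.table["status"] == POLARIZED).to_numpy()


def polarize(matrix: GenotypeMatrix, majority: float = 0.5) -> PolarizationResult:
    """Infer ancestral alleles from the cohort's homozygote majority.

    For each site, the allele that is homozygous in more than ``majority`` of
    genotyped individuals is ancestral.  Sites where no allele reaches the
    majority are ``excluded_no_majority``; sites whose ancestral allele is not
    the reference allele are ``excluded_ref_mismatch`` (the derived/ancestral
    orientation cannot be trusted against a reference that may itself carry
    the derived allele).
    """
    gt = matrix.genotypes
    called = gt != MISSING
    n_called = called.sum(axis=0)
    n_ref_hom = ((gt == 0) & called).sum(axis=0)
    n_alt_hom = (gt == 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_ref = np.where(n_called > 0, n_ref_hom / np.maximum(n_called, 1), 0.0)
        frac_alt = np.where(n_called > 0, n_alt_hom / np.maximum(n_called, 1), 0.0)
    status = np.full(matrix.n_sites, EXCLUDED_NO_MAJORITY, dtype=object)
    status[frac_ref > majority] = POLARIZED
    status[frac_alt > majority] = EXCLUDED_REF_MISMATCH
    ref = matrix.sites["ref"].to_numpy()
    alt = matrix.sites["alt"].to_numpy()
    ancestral = np.where(frac_alt > majority, alt, ref)
    derived = np.where(frac_alt > majority, ref, alt)
    table = matrix.sites[["chrom", "pos"]].copy()
    table["ancestral"] = ancestral
    table["derived"] = derived
    table["status"] = status
    return PolarizationResult(table)


def classify_sites(annotations: pd.DataFrame) -> pd.Series:
    """Mutation class per site from effect + amino-acid pair.

    Returns a Series of {SYN, TOL, DEL, LOF} with NaN for sites outside the
    load analysis (intergenic/other, or missense lacking a usable amino-acid
    pair).
    """
    classes = pd.Series(np.nan, index=annotations.index, dtype=object)
    effect = annotations["effect"]
    classes[effect == "synonymous"] = "SYN"
    classes[effect.isin(LOF_EFFECTS)] = "LOF"
    mis = effect == "missense"
    n_bad = 0
    for i in annotations.index[mis]:
        a, b = annotations.at[i, "aa_ref"], annotations.at[i, "aa_alt"]
        try:
            gs = grantham_score(a, b)
        except (ValueError, KeyError):
            n_bad += 1
            continue
        if gs == 0:  # identical residues: annotation error, not a missense change
            n_bad += 1
            continue
        classes.at[i] = "DEL" if gs > DEL_MIN_GS else "TOL"
    if n_bad:
        logger.info("%d missense records without a usable amino-acid pair excluded", n_bad)
    return classes


def count_derived(
    matrix: GenotypeMatrix,
    polarization: PolarizationResult,
    classes: pd.Series,
) -> pd.DataFrame:
    """Per-individual derived het/hom counts for each mutation class.

    Only polarized sites enter; at polarized sites ancestral == reference, so
    dosage codes 1 and 2 are derived-het and derived-hom directly.  Missing
    genotypes contribute to neither count.
    """
    keep = polarization.polarized_mask & classes.notna().to_numpy()
    gt = matrix.genotypes[:, keep]
    cls = classes.to_numpy()[keep]
    rows = []
    for i, sample in enumerate(matrix.samples):
        g = gt[i]
        for c in LOAD_CLASSES:
            sel = cls == c
            rows.append(
                {
                    "sample": sample,
                    "class": c,
                    "n_het": int(np.sum(g[sel] == 1)),
                    "n_hom": int(np.sum(g[sel] == 2)),
                }
            )
    return pd.DataFrame(rows)


def compute_load(
    matrix: GenotypeMatrix,
    polarization: PolarizationResult,
    classes: pd.Series,
    count_mode: str = "alleles",
) -> pd.DataFrame:
    """Per-individual LoadReport.

    Columns: per-class counts and homozygosity load, plus masked and realized
    load normalized by the individual's SYN derived alleles (``alleles`` mode)
    or SYN derived loci (``loci`` mode).  Undefined ratios are NaN.
    """
    if count_mode not in ("alleles", "loci"):
        raise ValueError("count_mode must be 'alleles' or 'loci'")
    counts = count_derived(matrix, polarization, classes)
    wide = counts.pivot(index="sample", columns="class", values=["n_het", "n_hom"])
    rows = []
    for sample in matrix.samples:
        row: dict[str, object] = {"sample": sample}
        het = {c: int(wide.loc[sample, ("n_het", c)]) for c in LOAD_CLASSES}
        hom = {c: int(wide.loc[sample, ("n_hom", c)]) for c in LOAD_CLASSES}
        for c in LOAD_CLASSES:
            row[f"n_het_{c}"] = het[c]
            row[f"n_hom_{c}"] = hom[c]
            alleles = 2 * hom[c] + het[c]
            row[f"hom_load_{c}"] = (2 * hom[c] / alleles) if alleles else np.nan
        if count_mode == "alleles":
            syn_denom = 2 * hom["SYN"] + het["SYN"]
            hom_weight = 2
        else:
            syn_denom = hom["SYN"] + het["SYN"]
            hom_weight = 1
        del_lof_het = het["DEL"] + het["LOF"]
        del_lof_hom = hom["DEL"] + hom["LOF"]
        if syn_denom:
            row["masked_load"] = del_lof_het / syn_denom
            row["realized_load"] = hom_weight * del_lof_hom / syn_denom
        else:
            row["masked_load"] = np.nan
            row["realized_load"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def population_load(load_report: pd.DataFrame, popmap: pd.DataFrame) -> pd.DataFrame:
    """Population means of the per-individual load statistics."""
    merged = load_report.merge(popmap[["sample", "population"]], on="sample")
    value_cols = [c for c in load_report.columns if c != "sample"]
    return merged.groupby("population")[value_cols].mean().reset_index()
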