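"""Site-level filtering and SNP-set construction.

Implements the standard post-calling cleanup for a biallelic SNP matrix:
missingness and minor-allele-frequency filters, plus sliding-window LD
pruning on genotype-dosage correlation (plink ``--indep-pairwise`` dialect).
Depth/quality filtering belongs to the variant caller upstream; when a VCF
carries FORMAT/DP and QUAL those can be screened while reading, otherwise the
matrix is taken as called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

EFFECT_CLASSES = (
    "synonymous",
    "missense",
    "stop_gained",
    "splice_acceptor",
    "splice_donor",
    "intergenic",
    "other",
)

# SnpEff ANN terms -> canonical effect class
_EFFECT_SYNONYMS = {
    "synonymous_variant": "synonymous",
    "synonymous": "synonymous",
    "missense_variant": "missense",
    "missense": "missense",
    "stop_gained": "stop_gained",
    "splice_acceptor_variant": "splice_acceptor",
    "splice_acceptor": "splice_acceptor",
    "splice_donor_variant": "splice_donor",
    "splice_donor": "splice_donor",
    "intergenic_region": "intergenic",
    "intergenic_variant": "intergenic",
    "intergenic": "intergenic",
}


@dataclass
class FilterThresholds:
    """Thresholds for site filtering and LD pruning.

    max_missing_rate: drop sites with a higher fraction of missing calls
    min_maf: drop sites with lower minor-allele frequency (on called alleles)
    ld_r2, ld_window, ld_step: plink-style indep-pairwise parameters
    """

    max_missing_rate: float = 0.20
    min_maf: float = 0.0
    ld_r2: float = 0.2
    ld_window: int = 50
    ld_step: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if not 0.0 <= self.ld_r2 <= 1.0:
            raise ValueError("ld_r2 must be in [0, 1]")
        if self.ld_window < 2:
            raise ValueError("ld_window must be at least 2")
        if self.ld_step < 1:
            raise ValueError("ld_step must be positive")


def site_filter_mask(matrix: GenotypeMatrix, thresholds: FilterThresholds) -> np.ndarray:
    """Boolean keep-mask applying the missingness, polymorphism and MAF rules."""
    miss = matrix.missing_rate()
    alt, tot = matrix.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)
    biallelic = (alt > 0) & (alt < tot)  # both alleles observed among called genotypes
    keep = (miss <= thresholds.max_missing_rate) & (tot > 0)
    if thresholds.min_maf > 0:
        keep &= biallelic & (maf >= thresholds.min_maf)
    return keep


def filter_sites(matrix: GenotypeMatrix, thresholds: FilterThresholds) -> GenotypeMatrix:
    """Retain sites passing the missingness/biallelic/MAF rules, order preserved."""
    keep = site_filter_mask(matrix, thresholds)
    if not keep.any():
        logger.warning("all %d sites removed by filters", matrix.n_sites)
    return matrix.take_sites(np.flatnonzero(keep))


def dosage_r2(gt: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage columns over shared calls."""
    a, b = gt[:, i], gt[:, j]
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return r * r


def _window_r2_matrix(gt: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """r^2 matrix for a window of dosage columns, missing-aware."""
    block = gt[:, cols]
    if (block == MISSING).any():
        k = len(cols)
        r2 = np.zeros((k, k))
        for a in range(k):
            for b in range(a + 1, k):
                r2[a, b] = r2[b, a] = dosage_r2(gt, int(cols[a]), int(cols[b]))
        return r2
    x = block.astype(float)
    sd = x.std(axis=0)
    const = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    r2 = r * r
    r2[const, :] = 0.0
    r2[:, const] = 0.0
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(matrix: GenotypeMatrix, thresholds: FilterThresholds) -> np.ndarray:
    """Indices of sites surviving sliding-window LD pruning, in original order.

    Windows of ``ld_window`` sites advance by ``ld_step``; while any retained
    pair within the window has dosage r^2 above ``ld_r2``, the member of the
    worst pair with lower MAF (tie: later coordinate) is dropped.  Pruning is
    per chromosome.
    """
    if thresholds.ld_window < 2:
        raise ValueError("ld_window must be at least 2")
    gt = matrix.genotypes
    maf = matrix.minor_allele_freq()
    keep = np.ones(matrix.n_sites, dtype=bool)
    chroms = matrix.sites["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        n = len(idx)
        start = 0
        while True:
            window = idx[start : start + thresholds.ld_window]
            live = [int(s) for s in window if keep[s]]
            if len(live) > 1:
                cols = np.asarray(live)
                r2 = _window_r2_matrix(gt, cols)
                alive = np.ones(len(live), dtype=bool)
                while True:
                    masked = np.where(np.outer(alive, alive), r2, 0.0)
                    a, b = np.unravel_index(int(np.argmax(masked)), masked.shape)
                    if masked[a, b] <= thresholds.ld_r2:
                        break
                    si, sj = int(cols[min(a, b)]), int(cols[max(a, b)])
                    # drop lower MAF; tie -> later coordinate
                    drop = si if (maf[si], -si) < (maf[sj], -sj) else sj
                    keep[drop] = False
                    alive[list(cols).index(drop)] = False
            if start + thresholds.ld_window >= n:
                break
            start += thresholds.ld_step
    return np.flatnonzero(keep)


# ----------------------------------------------------------------------
# Annotation parsing
# ----------------------------------------------------------------------
def canonical_effect(effect: str) -> str:
    eff = effect.strip().lower()
    if eff in _EFFECT_SYNONYMS:
        return _EFFECT_SYNONYMS[eff]
    # ANN fields may carry multiple &-joined terms; take the first recognised one
    for part in eff.split("&"):
        if part in _EFFECT_SYNONYMS:
            return _EFFECT_SYNONYMS[part]
    return "other"


def _parse_hgvs_p(hgvs: str) -> tuple[str, str]:
    """Extract (ref_aa, alt_aa) one-letter codes from e.g. ``p.Ala123Thr``."""
    from .grantham import AA3_TO_1

    s = hgvs.removeprefix("p.")
    if len(s) < 7:
        return "", ""
    a3, b3 = s[:3], s[-3:]
    return AA3_TO_1.get(a3, ""), AA3_TO_1.get(b3, "")


def parse_annotations(path: str, matrix: GenotypeMatrix, strict: bool = False) -> pd.DataFrame:
    """Per-site effect classes aligned to the matrix.

    Accepts either the plain annotation TSV (chrom, pos, effect, aa_ref,
    aa_alt) or a VCF whose INFO/ANN field carries SnpEff-style annotations.
    Returns one row per matrix site with columns ``chrom, pos, effect,
    aa_ref, aa_alt``; sites without an annotation record get class ``other``.
    Unknown effect strings map to ``other`` with a logged count.  Annotation
    records at coordinates absent from the matrix (e.g. sites removed by
    filtering) are dropped with a log line, or raise when ``strict``.
    """
    from . import io as _io

    if str(path).endswith((".vcf", ".vcf.gz")):
        ann = _annotations_from_vcf(path)
    else:
        ann = _io.read_annotation_table(path)
    ann = ann.copy()
    n_unknown = 0
    classes = []
    for eff in ann["effect"].astype(str):
        c = canonical_effect(eff)
        if c == "other" and eff.strip().lower() not in ("other", ""):
            n_unknown += 1
        classes.append(c)
    ann["effect"] = classes
    if n_unknown:
        logger.info("%d annotation records with unrecognised effect -> 'other'", n_unknown)

    key = pd.MultiIndex.from_frame(ann[["chrom", "pos"]])
    if key.has_duplicates:
        ann = ann[~key.duplicated()]
        key = key[~key.duplicated()]
    site_key = pd.MultiIndex.from_frame(matrix.sites[["chrom", "pos"]])
    extra = key.difference(site_key)
    if len(extra):
        if strict:
            raise ValueError(
                f"{len(extra)} annotation records do not match any matrix site, "
                f"first: {extra[0]}"
            )
        logger.info("%d annotation records at non-matrix coordinates dropped", len(extra))
    ann = ann.set_index(key)
    out = matrix.sites[["chrom", "pos"]].copy()
    aligned = ann.reindex(site_key)
    out["effect"] = aligned["effect"].fillna("other").to_numpy()
    out["aa_ref"] = aligned["aa_ref"].fillna("").to_numpy()
    out["aa_alt"] = aligned["aa_alt"].fillna("").to_numpy()
    return out


def _annotations_from_vcf(path: str) -> pd.DataFrame:
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(path))
    for rec in vcf:
        raw = rec.INFO.get("ANN")
        if raw is None:
            continue
        first = str(raw).split(",")[0].split("|")
        effect = first[1] if len(first) > 1 else ""
        hgvs_p = first[10] if len(first) > 10 else ""
        aa_ref, aa_alt = _parse_hgvs_p(hgvs_p) if hgvs_p else ("", "")
        rows.append((rec.CHROM, rec.POS, effect, aa_ref, aa_alt))
    vcf.close()
    return pd.DataFrame(rows, columns=["chrom", "pos", "effect", "aa_ref", "aa_alt"])
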