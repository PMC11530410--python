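"""Windowed diversity and divergence statistics with missing-data-aware
denominators.

Per-site allele counts are taken over called genotypes only, and window
statistics are ratios of window sums (the pixy convention), so sites that are
partially missing contribute exactly the information they carry:

* pi     = sum_sites(c_ref * c_alt) / sum_sites C(n_site, 2)
* d_xy   = sum_sites(cA_ref*cB_alt + cA_alt*cB_ref) / sum_sites(nA * nB)
* F_ST   = Hudson estimator, 1 - mean within-population pi / d_xy
           (ratio of window sums, never mean of per-site ratios)
* Tajima's D on complete-genotype segregating sites with the 1989 constants.

Undefined statistics are returned as NaN, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import MISSING, GenotypeMatrix

DEFAULT_WINDOW_SIZE = 100_000


# ----------------------------------------------------------------------
# per-site component sums
# ----------------------------------------------------------------------
def _allele_counts(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt count, total called alleles) per site for a genotype block."""
    called = gt != MISSING
    alt = np.where(called, gt, 0).sum(axis=0).astype(np.int64)
    tot = 2 * called.sum(axis=0).astype(np.int64)
    return alt, tot


def pi_components(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (numerator, denominator) of nucleotide diversity."""
    alt, tot = _allele_counts(gt)
    ref = tot - alt
    num = (ref * alt).astype(float)
    den = (tot * (tot - 1) / 2.0).astype(float)
    return num, den


def dxy_components(gt_a: np.ndarray, gt_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (numerator, denominator) of between-population diversity."""
    alt_a, tot_a = _allele_counts(gt_a)
    alt_b, tot_b = _allele_counts(gt_b)
    ref_a, ref_b = tot_a - alt_a, tot_b - alt_b
    num = (ref_a * alt_b + alt_a * ref_b).astype(float)
    den = (tot_a * tot_b).astype(float)
    return num, den


def window_pi(gt: np.ndarray) -> float:
    """Nucleotide diversity of one window (genotype block samples x sites)."""
    num, den = pi_components(gt)
    usable = den > 0
    if not usable.any():
        return float("nan")
    return float(num[usable].sum() / den[usable].sum())


def window_dxy(gt_a: np.ndarray, gt_b: np.ndarray) -> float:
    num, den = dxy_components(gt_a, gt_b)
    usable = den > 0
    if not usable.any():
        return float("nan")
    return float(num[usable].sum() / den[usable].sum())


def window_fst(gt_a: np.ndarray, gt_b: np.ndarray) -> float:
    """Hudson F_ST for one window: 1 - mean(pi_A, pi_B) / d_xy (window sums).

    May be slightly negative; NaN when the between-population denominator is
    empty or d_xy is zero.
    """
    dxy_num, dxy_den = dxy_components(gt_a, gt_b)
    usable = dxy_den > 0
    if not usable.any():
        return float("nan")
    dxy = dxy_num[usable].sum() / dxy_den[usable].sum()
    if dxy == 0.0:
        return float("nan")
    pis = []
    for gt in (gt_a, gt_b):
        num, den = pi_components(gt)
        ok = den > 0
        pis.append(num[ok].sum() / den[ok].sum() if ok.any() else np.nan)
    hw = np.nanmean(pis)
    return float(1.0 - hw / dxy)


# ----------------------------------------------------------------------
# Tajima's D
# ----------------------------------------------------------------------
def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalizing constants for n sampled haplotypes."""
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(gt: np.ndarray, min_segregating: int = 3) -> float:
    """Tajima's D for one window; sites with any missing genotype are excluded.

    ``n`` is the full haplotype count (2 x diploids).  Returns NaN when fewer
    than ``min_segregating`` complete segregating sites are available.
    """
    complete = ~(gt == MISSING).any(axis=0)
    g = gt[:, complete]
    if g.size == 0:
        return float("nan")
    n = 2 * g.shape[0]
    alt = g.sum(axis=0)
    seg = (alt > 0) & (alt < n)
    s = int(seg.sum())
    if s < min_segregating:
        return float("nan")
    k = alt[seg].astype(float)
    pi_hat = float(np.sum(2.0 * k * (n - k)) / (n * (n - 1)))
    c = tajima_constants(n)
    theta_w = s / c["a1"]
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    return float((pi_hat - theta_w) / np.sqrt(var))


# ----------------------------------------------------------------------
# scan cutoff and landscape correlation
# ----------------------------------------------------------------------
def normal_cutoff(confidence: float) -> float:
    """One-sided standard-normal quantile, rounded to 4 decimals for reporting.

    ``normal_cutoff(0.99) == 2.3263`` is the customary 99%-confidence
    selection-scan threshold.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    return round(float(sps.norm.ppf(confidence)), 4)


def landscape_correlation(stat_a, stat_b) -> tuple[float, float]:
    """Spearman rank correlation between two per-window statistics.

    Pairs where either value is undefined (NaN) are dropped; returns
    (R, two-sided p).  Constant input gives (nan, nan).
    """
    a = np.asarray(stat_a, dtype=float)
    b = np.asarray(stat_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need at least 3 paired windows")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan"), float("nan")
    res = sps.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------------------------------
# windowed scan over a cohort
# ----------------------------------------------------------------------
@dataclass
class WindowGrid:
    """Non-overlapping windows anchored at position 1 per chromosome."""

    window_size: int = DEFAULT_WINDOW_SIZE

    def windows(self, chrom_length: int):
        start = 1
        while start <= chrom_length:
            yield start, min(start + self.window_size - 1, chrom_length)
            start += self.window_size


def windowed_statistics(
    matrix: GenotypeMatrix,
    popmap: pd.DataFrame,
    chrom_sizes: dict[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
    pop_pair: tuple[str, str] | None = None,
    lineages: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-window pi (per population), and d_xy/F_ST/Tajima's D for one pair.

    ``pop_pair`` selects the two groups compared by d_xy/F_ST; with
    ``lineages`` (population -> lineage label) the comparison is between
    lineages instead and per-lineage pi and Tajima's D are added.  Returns a
    tidy frame with one row per (chrom, window).
    """
    pops = {
        p: matrix.sample_index(popmap.loc[popmap["population"] == p, "sample"])
        for p in popmap["population"].unique()
    }
    groups: dict[str, np.ndarray] = {}
    if lineages is not None:
        for lin in sorted(set(lineages.values())):
            members = [p for p, l in lineages.items() if l == lin and p in pops]
            groups[lin] = np.concatenate([pops[p] for p in members])
        pair = tuple(sorted(groups))
    elif pop_pair is not None:
        pair = pop_pair
        groups = {p: pops[p] for p in pair}
    else:
        pair = None

    gt = matrix.genotypes
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    grid = WindowGrid(window_size)
    rows = []
    for chrom, length in chrom_sizes.items():
        on_chrom = chroms == chrom
        cpos = pos[on_chrom]
        cidx = np.flatnonzero(on_chrom)
        for start, end in grid.windows(length):
            in_win = cidx[(cpos >= start) & (cpos <= end)]
            row: dict[str, object] = {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_sites_used": len(in_win),
            }
            for p, idx in pops.items():
                row[f"pi_{p}"] = window_pi(gt[np.ix_(idx, in_win)]) if len(in_win) else np.nan
            if pair is not None:
                ga = gt[np.ix_(groups[pair[0]], in_win)]
                gb = gt[np.ix_(groups[pair[1]], in_win)]
                if len(in_win):
                    row["dxy"] = window_dxy(ga, gb)
                    row["fst"] = window_fst(ga, gb)
                    for name, g in zip(pair, (ga, gb)):
                        row[f"pi_{name}"] = window_pi(g)
                        row[f"tajima_d_{name}"] = tajimas_d(g)
                else:
                    row["dxy"] = row["fst"] = np.nan
                    for name in pair:
                        row[f"pi_{name}"] = row[f"tajima_d_{name}"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
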