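"""Independent brute-force reference implementations used by the tests.

Everything here is written from first principles (explicit enumeration of
allele pairs, direct formula evaluation, linear scans) and deliberately
shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np

MISSING = -1


def alleles_at_site(column: np.ndarray) -> list[int]:
    """Pooled allele list for one site (two alleles per called diploid)."""
    out: list[int] = []
    for g in column:
        if g == MISSING:
            continue
        if g == 0:
            out.extend([0, 0])
        elif g == 1:
            out.extend([0, 1])
        else:
            out.extend([1, 1])
    return out


def brute_pi(gt: np.ndarray) -> float:
    """Average pairwise difference per site by enumerating all allele pairs."""
    num = 0
    den = 0
    for j in range(gt.shape[1]):
        alleles = alleles_at_site(gt[:, j])
        if len(alleles) < 2:
            continue
        for a, b in itertools.combinations(alleles, 2):
            num += int(a != b)
            den += 1
    return num / den if den else float("nan")


def brute_dxy(gt_a: np.ndarray, gt_b: np.ndarray) -> float:
    num = 0
    den = 0
    for j in range(gt_a.shape[1]):
        aa = alleles_at_site(gt_a[:, j])
        bb = alleles_at_site(gt_b[:, j])
        if not aa or not bb:
            continue
        for a in aa:
            for b in bb:
                num += int(a != b)
                den += 1
    return num / den if den else float("nan")


def brute_hudson_fst(gt_a: np.ndarray, gt_b: np.ndarray) -> float:
    """Textbook Hudson estimator: 1 - Hw / Hb with window-summed components."""
    dxy = brute_dxy(gt_a, gt_b)
    if not np.isfinite(dxy) or dxy == 0.0:
        return float("nan")
    hw = np.nanmean([brute_pi(gt_a), brute_pi(gt_b)])
    return 1.0 - hw / dxy


def brute_tajimas_d(gt: np.ndarray) -> float:
    """Tajima's D via direct evaluation of the 1989 formulas."""
    cols = [gt[:, j] for j in range(gt.shape[1]) if not np.any(gt[:, j] == MISSING)]
    if not cols:
        return float("nan")
    n = 2 * gt.shape[0]
    pi_sum = 0.0
    s = 0
    for col in cols:
        alleles = alleles_at_site(col)
        k = sum(alleles)
        if 0 < k < n:
            s += 1
            diffs = sum(
                int(a != b) for a, b in itertools.combinations(alleles, 2)
            )
            pi_sum += diffs / (n * (n - 1) / 2.0)
    if s < 3:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    theta_w = s / a1
    return (pi_sum - theta_w) / np.sqrt(e1 * s + e2 * s * (s - 1))


def brute_f_is(individual: np.ndarray, cohort_gt: np.ndarray) -> float:
    """Per-site evaluation of the plink-style method-of-moments coefficient."""
    o_hom = 0
    e_hom = 0.0
    n_used = 0
    for j in range(cohort_gt.shape[1]):
        if individual[j] == MISSING:
            continue
        alleles = alleles_at_site(cohort_gt[:, j])
        tot = len(alleles)
        if tot < 2:
            continue
        p = sum(alleles) / tot
        n_used += 1
        o_hom += int(individual[j] != 1)
        e_hom += 1.0 - 2.0 * p * (1.0 - p) * (tot / (tot - 1.0))
    if n_used == 0 or n_used == e_hom:
        return float("nan")
    return (o_hom - e_hom) / (n_used - e_hom)


def brute_roh_segments(
    genotypes: np.ndarray,
    positions: np.ndarray,
    min_length: int = 10_000,
    min_snps: int = 50,
    max_gap: int = 1_000_000,
) -> list[tuple[int, int, int]]:
    """Maximal het-free runs on one chromosome by linear scan.

    Missing genotypes are tolerated inside a run but do not count as support;
    returns (start, end, n_hom_snps) for runs passing the thresholds.
    """
    segments = []
    run: list[tuple[int, int]] = []  # (pos, genotype)
    last_called_pos = None

    def flush():
        if run:
            start, end = run[0][0], run[-1][0]
            n = len(run)
            if end - start + 1 >= min_length and n >= min_snps:
                segments.append((start, end, n))

    for pos, g in zip(positions, genotypes):
        if g == MISSING:
            continue
        if last_called_pos is not None and pos - last_called_pos > max_gap:
            flush()
            run = []
        last_called_pos = pos
        if g == 1:
            flush()
            run = []
        else:
            run.append((int(pos), int(g)))
    flush()
    return segments


def brute_spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman R via explicit mid-ranking and a Pearson formula."""

    def midrank(x: np.ndarray) -> np.ndarray:
        order = np.argsort(x, kind="mergesort")
        ranks = np.empty(len(x), dtype=float)
        i = 0
        while i < len(x):
            j = i
            while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    ra, rb = midrank(np.asarray(a, float)), midrank(np.asarray(b, float))
    ra -= ra.mean()
    rb -= rb.mean()
    return float(np.sum(ra * rb) / np.sqrt(np.sum(ra**2) * np.sum(rb**2)))


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of closed 1-based intervals."""
    if not intervals:
        return []
    merged = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def interval_overlap(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Total overlapping length between two closed-interval lists."""
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            lo, hi = max(s1, s2), min(e1, e2)
            if hi >= lo:
                total += hi - lo + 1
    return total
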