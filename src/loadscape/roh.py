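"""Runs of homozygosity and individual inbreeding coefficients.

An ROH is a maximal stretch of consecutive genotyped SNPs with no
heterozygous call, scanned with a 50-SNP window that tolerates zero
heterozygotes.  Missing genotypes inside a candidate run neither break it nor
count toward its SNP support; a gap between consecutive genotyped SNPs larger
than ``max_gap`` does break the run.  Segments are kept when they span at
least ``min_length`` (10 kb) and contain at least ``min_snps`` homozygous
SNPs, then classed short [10,100) kb, medium [100,200) kb, long >= 200 kb.

F_ROH is the summed ROH length over the genome length; F_IS is the plink
``--het`` method-of-moments coefficient from observed vs expected homozygous
site counts given cohort allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

SHORT_MAX = 100_000
MEDIUM_MAX = 200_000


@dataclass
class ROHParams:
    window_snps: int = 50        # scanning window (SNPs); 0 het allowed inside
    het_allowance: int = 0
    min_length: int = 10_000     # bp
    min_snps: int = 50           # homozygous SNPs supporting a segment
    max_gap: int = 1_000_000     # bp between consecutive genotyped SNPs


def classify_length(length: int) -> str:
    if length < 10_000:
        raise ValueError("segments below 10 kb are discarded before classification")
    if length < SHORT_MAX:
        return "short"
    if length < MEDIUM_MAX:
        return "medium"
    return "long"


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start: int   # 1-based inclusive
    end: int     # 1-based inclusive
    n_snps: int
    length: int = field(init=False)
    length_class: str = field(init=False)

    def __post_init__(self) -> None:
        self.length = self.end - self.start + 1
        self.length_class = classify_length(self.length)


def _runs_for_chromosome(
    genotypes: np.ndarray, positions: np.ndarray, params: ROHParams
) -> list[tuple[int, int, int]]:
    """(start, end, n_hom_snps) runs of het-free genotyped stretches."""
    called = genotypes != MISSING
    cpos = positions[called]
    cg = genotypes[called]
    if len(cpos) == 0:
        return []
    het = cg == 1
    gap_break = np.diff(cpos) > params.max_gap
    # boundaries: before any het, after any het, and at large gaps
    breaks = het[:-1] | het[1:] | gap_break
    run_id = np.concatenate([[0], np.cumsum(breaks)])
    runs = []
    for rid in np.unique(run_id):
        sel = run_id == rid
        if het[sel].any():
            continue
        p = cpos[sel]
        runs.append((int(p[0]), int(p[-1]), int(sel.sum())))
    return runs


def detect_roh(
    genotypes: np.ndarray,
    sites: pd.DataFrame,
    params: ROHParams | None = None,
    sample: str = "",
) -> list[ROHSegment]:
    """ROH segments for one individual (dosage vector aligned to ``sites``)."""
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        cpos = pos[mask]
        if np.any(np.diff(cpos) <= 0):
            raise ValueError(f"sites on {chrom} are not position-sorted")
        for start, end, n_snps in _runs_for_chromosome(genotypes[mask], cpos, params):
            length = end - start + 1
            if length >= params.min_length and n_snps >= params.min_snps:
                segments.append(ROHSegment(sample, str(chrom), start, end, n_snps))
    return segments


def detect_roh_cohort(
    matrix: GenotypeMatrix, params: ROHParams | None = None
) -> pd.DataFrame:
    """ROH table for every individual: sample, chrom, start, end, n_snps, length, class."""
    rows = []
    for i, sample in enumerate(matrix.samples):
        for seg in detect_roh(matrix.genotypes[i], matrix.sites, params, sample):
            rows.append(
                (seg.sample, seg.chrom, seg.start, seg.end, seg.n_snps, seg.length, seg.length_class)
            )
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_snps", "length", "length_class"]
    )


def f_roh(segments: pd.DataFrame | list[ROHSegment], genome_length: int) -> float:
    """Cumulative ROH length divided by total genome length."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    if isinstance(segments, pd.DataFrame):
        total = int(segments["length"].sum()) if len(segments) else 0
    else:
        total = sum(s.length for s in segments)
    return total / genome_length


def f_is(genotypes: np.ndarray, cohort: GenotypeMatrix) -> float:
    """Method-of-moments inbreeding coefficient for one individual.

    F = (O_hom - E_hom) / (N_used - E_hom) with E_hom summed over the
    individual's called sites using cohort allele frequencies and the
    small-sample correction 2n/(2n-1).
    """
    alt, tot = cohort.allele_counts()
    called = genotypes != MISSING
    usable = called & (tot > 1)
    if not usable.any():
        raise ValueError("no usable genotyped site")
    p = alt[usable] / tot[usable]
    corr = tot[usable] / (tot[usable] - 1.0)
    e_hom = float(np.sum(1.0 - 2.0 * p * (1.0 - p) * corr))
    n_used = int(usable.sum())
    o_hom = int(np.sum(genotypes[usable] != 1))
    denom = n_used - e_hom
    if denom == 0:
        return float("nan")
    return (o_hom - e_hom) / denom


def inbreeding_report(
    matrix: GenotypeMatrix,
    roh_table: pd.DataFrame,
    genome_length: int,
) -> pd.DataFrame:
    """Per-sample F_ROH, F_IS and total ROH length per length class."""
    rows = []
    by_sample = dict(tuple(roh_table.groupby("sample"))) if len(roh_table) else {}
    for i, sample in enumerate(matrix.samples):
        segs = by_sample.get(sample, roh_table.iloc[0:0])
        row = {
            "sample": sample,
            "f_roh": f_roh(segs, genome_length),
            "f_is": f_is(matrix.genotypes[i], matrix),
            "n_roh": len(segs),
        }
        for cls in ("short", "medium", "long"):
            row[f"roh_{cls}_bp"] = (
                int(segs.loc[segs["length_class"] == cls, "length"].sum()) if len(segs) else 0
            )
        rows.append(row)
    return pd.DataFrame(rows)
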