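"""Diploid genotype matrix shared by every analysis stage.

Genotypes are stored as derived/alt-allele dosage codes ``{0, 1, 2}`` with
``-1`` marking a missing call, in a dense ``int8`` array of shape
``(n_samples, n_sites)``.  Site metadata (chromosome, 1-based position,
ref/alt alleles) lives in a parallel :class:`pandas.DataFrame`.  Positions are
strictly increasing within each chromosome; every retained site is biallelic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    samples: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x sites)")
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"site table lacks columns {missing_cols}")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        self.sites = self.sites.reset_index(drop=True)
        self._check_sorted()

    def _check_sorted(self) -> None:
        pos = self.sites["pos"].to_numpy()
        chrom = self.sites["chrom"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        if np.any(same & (pos[1:] <= pos[:-1])):
            raise ValueError("positions must be strictly increasing within a chromosome")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, names: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def take_sites(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[:, idx].copy(),
        )

    def take_samples(self, names: Iterable[str]) -> "GenotypeMatrix":
        idx = self.sample_index(names)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=self.sites.copy(),
            genotypes=self.genotypes[idx].copy(),
        )

    # -- per-site summaries --------------------------------------------
    def missing_rate(self) -> np.ndarray:
        """Fraction of missing genotype calls per site."""
        return (self.genotypes == MISSING).mean(axis=0)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, total called allele count)."""
        called = self.genotypes != MISSING
        alt = np.where(called, self.genotypes, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def alt_freq(self) -> np.ndarray:
        """Per-site alt-allele frequency among called alleles (NaN if none)."""
        alt, tot = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    def minor_allele_freq(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.sites.reset_index(drop=True).equals(other.sites.reset_index(drop=True))
            and np.array_equal(self.genotypes, other.genotypes)
        )
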