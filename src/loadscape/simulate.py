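"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-lineage, 13-population relict-tree cohort of
154 diploid individuals: Balding-Nichols lineage divergence with extra
within-lineage and edge-population drift, per-individual autozygous tracts
overwritten as homozygous runs, an annotated site spectrum (synonymous /
missense / loss-of-function / intergenic) whose derived-allele frequencies
fall with deleteriousness, and environmental clines that drive allele
frequencies at designated adaptive loci.  Matching current and
future-scenario climate grids are produced from smooth deterministic fields
evaluated on a regular lat/lon lattice, so population profiles and grid
cells are mutually consistent by construction.

Every random draw flows from the single configured seed; a fixed seed yields
a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .genotypes import MISSING, GenotypeMatrix
from .grantham import GRANTHAM_MATRIX

SCENARIOS = ("ssp126", "ssp245", "ssp370", "ssp585")

#: population code -> (lineage, n individuals, lat, lon, edge population?)
DEFAULT_POPULATIONS: dict[str, tuple[str, int, float, float, bool]] = {
    "LQ":  ("west", 14, 24.5, 103.4, False),
    "LP":  ("west", 14, 25.2, 104.6, False),
    "MLP": ("west", 14, 23.8, 106.2, False),
    "ZJJ": ("west", 9, 29.1, 110.5, True),
    "ES":  ("west", 8, 30.2, 109.4, True),
    "WZS": ("west", 8, 18.8, 109.5, True),
    "NP":  ("east", 14, 27.7, 117.1, False),
    "DH":  ("east", 14, 24.9, 113.0, False),
    "SM":  ("east", 14, 26.3, 117.6, False),
    "YS":  ("east", 14, 24.2, 115.5, False),
    "LH":  ("east", 14, 28.4, 118.9, False),
    "TB":  ("east", 9, 23.5, 121.0, True),
    "PB":  ("east", 8, 25.5, 119.7, True),
}

DEFAULT_CLASS_MIX = {
    "SYN": 0.15,
    "TOL": 0.10,
    "DEL": 0.02,
    "LOF": 0.01,
    "intergenic": 0.60,
    "other": 0.12,
}

#: Beta-prior mean derived frequency per class (purifying-selection mimic)
CLASS_FREQ_MEANS = {"SYN": 0.10, "TOL": 0.05, "DEL": 0.02, "LOF": 0.02}

CLIMATE_VARIABLES = (
    "BIO1", "BIO2", "BIO5", "BIO6", "BIO7", "BIO12", "BIO13", "BIO15", "BIO17",
)


@dataclass
class AdaptiveSpec:
    n_loci: int = 60
    slope: float = 4.0
    noise_sd: float = 0.05
    variable: str = "BIO1"


@dataclass
class SimulationConfig:
    populations: dict[str, tuple[str, int, float, float, bool]] = field(
        default_factory=lambda: dict(DEFAULT_POPULATIONS)
    )
    n_sites: int = 50_000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 6_000_000 for i in range(1, 9)}
    )
    fst_target: float = 0.35
    lineage_drift: dict[str, float] = field(
        default_factory=lambda: {"west": 0.04, "east": 0.10}
    )
    edge_extra_drift: float = 0.12
    #: population -> list of (tract length bp, count) per individual
    roh_spec: dict[str, list[tuple[int, int]]] | None = None
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    adaptive_spec: AdaptiveSpec = field(default_factory=AdaptiveSpec)
    #: scenario -> warming severity (deg C on BIO1 at the range center)
    future_shift: dict[str, float] = field(
        default_factory=lambda: {"ssp126": 1.2, "ssp245": 2.0, "ssp370": 3.0, "ssp585": 4.2}
    )
    missing_rate: float = 0.0
    grid_cell_deg: float = 1.0 / 24.0  # ~4.6 km grid cells
    grid_margin_deg: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix proportions must sum to 1, got {total}")
        if not 0.0 < self.fst_target < 1.0:
            raise ValueError("fst_target must be in (0, 1)")
        if self.n_sites <= 0 or not self.populations:
            raise ValueError("n_sites and populations must be positive/non-empty")
        if self.roh_spec is None:
            self.roh_spec = {
                pop: (
                    [(100_000, 2), (200_000, 2), (300_000, 2)]
                    if edge
                    else [(150_000, 1), (250_000, 1)]
                )
                for pop, (_, _, _, _, edge) in self.populations.items()
            }

    # convenience views -------------------------------------------------
    @property
    def pop_names(self) -> list[str]:
        return list(self.populations)

    @property
    def lineage_assignment(self) -> dict[str, str]:
        return {p: v[0] for p, v in self.populations.items()}

    @property
    def pop_sizes(self) -> dict[str, int]:
        return {p: v[1] for p, v in self.populations.items()}

    @property
    def edge_populations(self) -> list[str]:
        return [p for p, v in self.populations.items() if v[4]]

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass
class SyntheticTruth:
    ancestral: np.ndarray            # per-site true ancestral allele
    class_labels: np.ndarray         # per-site true class (SYN/TOL/DEL/LOF/intergenic/other)
    adaptive: np.ndarray             # per-site bool
    tracts: pd.DataFrame             # sample, chrom, start, end (true autozygous tracts)
    pop_freqs: pd.DataFrame          # populations x sites true derived frequencies
    driving_variable: str


@dataclass
class Cohort:
    matrix: GenotypeMatrix
    annotations: pd.DataFrame
    popmap: pd.DataFrame
    chrom_sizes: dict[str, int]
    env_pop: pd.DataFrame                    # populations x climate variables (current)
    climate: dict[str, pd.DataFrame]         # "current" + one table per scenario
    truth: SyntheticTruth
    config: SimulationConfig


# ----------------------------------------------------------------------
# allele-frequency machinery
# ----------------------------------------------------------------------
def simulate_allele_frequencies(
    p_anc: np.ndarray | float,
    fst: float,
    n_pops: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Balding-Nichols population frequencies.

    Each population's frequency is an independent Beta draw with mean
    ``p_anc`` and variance ``fst * p_anc * (1 - p_anc)``, i.e.
    ``Beta(p (1-F)/F, (1-p)(1-F)/F)``.  Shape: (n_pops, n_loci).
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be strictly inside (0, 1)")
    p = np.atleast_1d(np.asarray(p_anc, dtype=float))
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("ancestral frequencies must be strictly inside (0, 1)")
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale, size=(n_pops, len(p)))


def genotypes_from_freqs(
    freqs: np.ndarray, pop_sizes: Sequence[int], rng: np.random.Generator
) -> np.ndarray:
    """Binomial diploid genotypes from per-population frequencies.

    ``freqs`` is (n_pops, n_loci); returns (sum(pop_sizes), n_loci) dosages.
    """
    blocks = [
        rng.binomial(2, freqs[k], size=(int(n), freqs.shape[1]))
        for k, n in enumerate(pop_sizes)
    ]
    return np.concatenate(blocks, axis=0).astype(np.int8)


def simulate_neutral_sfs_genotypes(
    n_diploids: int,
    n_sites: int,
    rng: np.random.Generator,
    min_freq: float | None = None,
) -> np.ndarray:
    """Single-population genotypes with a neutral (1/p) frequency spectrum.

    Site frequencies are drawn with density proportional to 1/p on
    [min_freq, 1] — the equilibrium neutral spectrum — and genotypes
    binomially; used for Tajima's D calibration.
    """
    if min_freq is None:
        min_freq = 1.0 / (20.0 * n_diploids)
    u = rng.random(n_sites)
    p = np.exp(np.log(min_freq) * (1.0 - u))  # log-uniform on [min_freq, 1]
    return rng.binomial(2, p, size=(n_diploids, n_sites)).astype(np.int8)


# ----------------------------------------------------------------------
# climate fields
# ----------------------------------------------------------------------
def _climate_fields(lat: np.ndarray, lon: np.ndarray) -> pd.DataFrame:
    """Smooth deterministic bioclim-style fields over (lat, lon)."""
    la = np.asarray(lat, dtype=float)
    lo = np.asarray(lon, dtype=float)
    bio1 = 26.0 - 0.55 * (la - 18.0) + 0.06 * (lo - 102.0) + 0.4 * np.sin(0.7 * lo)
    bio2 = 8.0 + 0.18 * (la - 18.0) + 0.3 * np.cos(0.5 * la + 0.2 * lo)
    bio5 = bio1 + 8.5 + 0.10 * (lo - 110.0) + 0.3 * np.sin(0.9 * la)
    bio6 = bio1 - 12.0 - 0.08 * (la - 18.0)
    bio7 = bio5 - bio6
    bio12 = 1200.0 + 45.0 * (lo - 102.0) - 25.0 * (la - 18.0) + 60.0 * np.sin(0.4 * lo)
    bio13 = 0.18 * bio12 + 15.0 * np.cos(0.3 * la)
    bio15 = 55.0 + 1.2 * (la - 18.0) - 0.5 * (lo - 102.0) + 2.0 * np.sin(0.8 * lo)
    bio17 = 0.08 * bio12 + 10.0 * np.sin(0.5 * la + 0.3 * lo)
    return pd.DataFrame(
        {
            "BIO1": bio1, "BIO2": bio2, "BIO5": bio5, "BIO6": bio6, "BIO7": bio7,
            "BIO12": bio12, "BIO13": bio13, "BIO15": bio15, "BIO17": bio17,
        }
    )


def _displacement_factor(lat, lon, config: SimulationConfig) -> np.ndarray:
    """Climate-displacement multiplier: ~1 in the range core, rising to ~3
    around the designated edge populations (Gaussian bumps, sd 1.5 deg)."""
    la = np.atleast_1d(np.asarray(lat, dtype=float))
    lo = np.atleast_1d(np.asarray(lon, dtype=float))
    factor = np.ones_like(la)
    sigma2 = 1.5**2
    for pop in config.edge_populations:
        _, _, p_lat, p_lon, _ = config.populations[pop]
        d2 = (la - p_lat) ** 2 + (lo - p_lon) ** 2
        factor = np.maximum(factor, 1.0 + 3.0 * np.exp(-d2 / (2.0 * sigma2)))
    return factor


def _apply_future_shift(
    table: pd.DataFrame, severity: float, config: SimulationConfig
) -> pd.DataFrame:
    """Additive climate displacement for one scenario."""
    out = table.copy()
    f = _displacement_factor(table["lat"].to_numpy(), table["lon"].to_numpy(), config)
    warm = severity * f
    out["BIO1"] += warm
    out["BIO5"] += 1.1 * warm
    out["BIO6"] += 0.8 * warm
    out["BIO7"] += 0.3 * warm
    out["BIO2"] += 0.1 * warm
    out["BIO12"] -= 18.0 * warm
    out["BIO13"] -= 2.5 * warm
    out["BIO17"] -= 1.5 * warm
    out["BIO15"] += 1.2 * warm
    return out


def climate_grid(config: SimulationConfig) -> pd.DataFrame:
    """Regular lat/lon grid of current climate covering the populations."""
    lats = [v[2] for v in config.populations.values()]
    lons = [v[3] for v in config.populations.values()]
    m = config.grid_margin_deg
    step = config.grid_cell_deg
    lat_axis = np.arange(min(lats) - m, max(lats) + m + step / 2, step)
    lon_axis = np.arange(min(lons) - m, max(lons) + m + step / 2, step)
    gg = np.meshgrid(lat_axis, lon_axis, indexing="ij")
    lat, lon = gg[0].ravel(), gg[1].ravel()
    grid = pd.DataFrame({"cell": np.arange(len(lat)), "lat": lat, "lon": lon})
    return pd.concat([grid, _climate_fields(lat, lon)], axis=1)


# ----------------------------------------------------------------------
# amino-acid pairs by Grantham range (for missense annotations)
# ----------------------------------------------------------------------
def _aa_pairs_by_class() -> dict[str, list[tuple[str, str]]]:
    tol, dele = [], []
    for pair, score in GRANTHAM_MATRIX.items():
        a, b = sorted(pair)
        (dele if score > 150 else tol).append((a, b))
    return {"TOL": sorted(tol), "DEL": sorted(dele)}


_AA_PAIRS = _aa_pairs_by_class()
_LOF_EFFECTS = ("stop_gained", "splice_acceptor", "splice_donor")


# ----------------------------------------------------------------------
# cohort generation
# ----------------------------------------------------------------------
def _site_positions(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    lengths = np.array(list(config.chrom_lengths.values()), dtype=float)
    n_per = np.floor(config.n_sites * lengths / lengths.sum()).astype(int)
    n_per[0] += config.n_sites - n_per.sum()
    frames = []
    for (chrom, length), n in zip(config.chrom_lengths.items(), n_per):
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n, replace=False))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    sites = pd.concat(frames, ignore_index=True)
    nt = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=len(sites))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(sites))) % 4
    sites["ref"] = nt[ref_idx]
    sites["alt"] = nt[alt_idx]
    return sites


def _assign_classes(n_sites: int, mix: Mapping[str, float], rng: np.random.Generator) -> np.ndarray:
    labels = list(mix)
    counts = np.floor(np.array([mix[c] for c in labels]) * n_sites).astype(int)
    counts[0] += n_sites - counts.sum()
    arr = np.repeat(labels, counts)
    rng.shuffle(arr)
    return arr


def _ancestral_freqs(classes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Derived-allele ancestral frequencies with frequency-deleteriousness coupling."""
    p = rng.uniform(0.05, 0.95, size=len(classes))
    kappa = 2.0
    for cls, mean in CLASS_FREQ_MEANS.items():
        sel = classes == cls
        draws = rng.beta(mean * kappa, (1.0 - mean) * kappa, size=int(sel.sum()))
        p[sel] = np.clip(draws, 1e-4, 1.0 - 1e-4)
    return p


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def simulate_cohort(config: SimulationConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort (genotypes, annotations, climate, truth)."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    pops = config.pop_names
    n_pops = len(pops)

    sites = _site_positions(config, rng)
    n_sites = len(sites)
    classes = _assign_classes(n_sites, config.class_mix, rng)
    p_anc = _ancestral_freqs(classes, rng)

    # hierarchical Balding-Nichols: lineages then populations
    lineages = sorted(set(config.lineage_assignment.values()))
    lin_freqs = {}
    for lin in lineages:
        lin_freqs[lin] = simulate_allele_frequencies(p_anc, config.fst_target, 1, rng)[0]
    pop_freqs = np.empty((n_pops, n_sites))
    for k, pop in enumerate(pops):
        lin, _, _, _, edge = config.populations[pop]
        drift = config.lineage_drift[lin] + (config.edge_extra_drift if edge else 0.0)
        base = np.clip(lin_freqs[lin], 1e-4, 1.0 - 1e-4)
        pop_freqs[k] = simulate_allele_frequencies(base, drift, 1, rng)[0]

    # adaptive loci: logistic cline on the driving variable, shared by all pops
    spec = config.adaptive_spec
    if spec.n_loci > n_sites:
        raise ValueError("adaptive loci exceed the number of sites")
    other_sites = np.flatnonzero(classes == "other")
    if spec.n_loci > len(other_sites):
        raise ValueError("not enough 'other'-class sites to host the adaptive loci")
    adaptive_idx = np.sort(rng.choice(other_sites, size=spec.n_loci, replace=False))
    env_pop_current = _climate_fields(
        np.array([v[2] for v in config.populations.values()]),
        np.array([v[3] for v in config.populations.values()]),
    )
    env_pop_current.index = pd.Index(pops, name="population")
    driver = env_pop_current[spec.variable].to_numpy()
    z = (driver - driver.mean()) / driver.std()
    intercepts = rng.normal(0.0, 1.0, size=spec.n_loci)
    signs = rng.choice([-1.0, 1.0], size=spec.n_loci)
    cline = _logistic(intercepts[None, :] + signs[None, :] * spec.slope * z[:, None])
    cline = cline + rng.normal(0.0, spec.noise_sd, size=cline.shape)
    pop_freqs[:, adaptive_idx] = np.clip(cline, 0.01, 0.99)

    # genotypes
    sizes = [config.pop_sizes[p] for p in pops]
    genotypes = genotypes_from_freqs(pop_freqs, sizes, rng)
    samples = [
        f"{pop}_{i + 1:02d}" for pop, n in zip(pops, sizes) for i in range(n)
    ]
    sample_pop = np.repeat(pops, sizes)

    # autozygous tracts overwritten as homozygous runs
    chrom_names = list(config.chrom_lengths)
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    tract_rows = []
    for i, (sample, pop) in enumerate(zip(samples, sample_pop)):
        k = pops.index(pop)
        for length, count in config.roh_spec[pop]:
            for _ in range(count):
                chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
                clen = config.chrom_lengths[chrom]
                if length > clen:
                    raise ValueError(f"tract of {length} bp exceeds {chrom} ({clen} bp)")
                start = int(rng.integers(1, clen - length + 2))
                end = start + length - 1
                in_tract = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr <= end)
                alleles = rng.random(int(in_tract.sum())) < pop_freqs[k, in_tract]
                genotypes[i, in_tract] = 2 * alleles.astype(np.int8)
                tract_rows.append((sample, chrom, start, end))
    tracts = pd.DataFrame(tract_rows, columns=["sample", "chrom", "start", "end"])

    # missingness injection
    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = MISSING

    matrix = GenotypeMatrix(samples=samples, sites=sites, genotypes=genotypes)

    # annotations
    effects = np.empty(n_sites, dtype=object)
    aa_ref = np.full(n_sites, "", dtype=object)
    aa_alt = np.full(n_sites, "", dtype=object)
    effects[classes == "SYN"] = "synonymous"
    effects[classes == "intergenic"] = "intergenic"
    effects[classes == "other"] = "other"
    lof_idx = np.flatnonzero(classes == "LOF")
    effects[lof_idx] = rng.choice(_LOF_EFFECTS, size=len(lof_idx))
    for cls in ("TOL", "DEL"):
        idx = np.flatnonzero(classes == cls)
        pool = _AA_PAIRS[cls]
        choice = rng.integers(0, len(pool), size=len(idx))
        for j, c in zip(idx, choice):
            a, b = pool[c]
            effects[j] = "missense"
            aa_ref[j], aa_alt[j] = a, b
    annotations = sites[["chrom", "pos"]].copy()
    annotations["effect"] = effects
    annotations["aa_ref"] = aa_ref
    annotations["aa_alt"] = aa_alt

    popmap = pd.DataFrame(
        {
            "sample": samples,
            "population": sample_pop,
            "lat": [config.populations[p][2] for p in sample_pop],
            "lon": [config.populations[p][3] for p in sample_pop],
        }
    )

    # climate tables
    grid = climate_grid(config)
    climate = {"current": grid}
    for scen, severity in config.future_shift.items():
        climate[scen] = _apply_future_shift(grid, severity, config)

    truth = SyntheticTruth(
        ancestral=sites["ref"].to_numpy().copy(),
        class_labels=classes,
        adaptive=np.isin(np.arange(n_sites), adaptive_idx),
        tracts=tracts,
        pop_freqs=pd.DataFrame(
            pop_freqs,
            index=pd.Index(pops, name="population"),
            columns=[f"{c}:{p}" for c, p in zip(sites["chrom"], sites["pos"])],
        ),
        driving_variable=spec.variable,
    )
    return Cohort(
        matrix=matrix,
        annotations=annotations,
        popmap=popmap,
        chrom_sizes=dict(config.chrom_lengths),
        env_pop=env_pop_current,
        climate=climate,
        truth=truth,
        config=config,
    )


# ----------------------------------------------------------------------
# writing
# ----------------------------------------------------------------------
def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as VCF + TSV tables; returns the emitted paths."""
    if cohort.matrix.n_sites == 0 or cohort.matrix.n_samples == 0:
        raise ValueError("refusing to write an empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "annotations": out / "annotations.tsv",
        "popmap": out / "popmap.tsv",
        "chrom_sizes": out / "chrom_sizes.tsv",
    }
    _io.write_vcf(cohort.matrix, paths["vcf"], cohort.chrom_sizes)
    _io.write_annotation_table(cohort.annotations, paths["annotations"])
    _io.write_popmap(cohort.popmap, paths["popmap"])
    _io.write_chrom_sizes(cohort.chrom_sizes, paths["chrom_sizes"])
    for name, table in cohort.climate.items():
        p = out / f"climate_{name}.tsv"
        _io.write_climate_table(table, p)
        paths[f"climate_{name}"] = p
    env = cohort.env_pop.reset_index()
    env.to_csv(out / "env_populations.tsv", sep="\t", index=False)
    paths["env_populations"] = out / "env_populations.tsv"
    return paths
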