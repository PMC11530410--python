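"""End-to-end orchestration: filtering -> load -> ROH -> windowed stats -> offset.

``run_pipeline`` reads the cohort files, runs the enabled stages in order,
writes one TSV per stage plus a JSON run manifest (parameters, seeds, input
checksums), and finishes with a per-population summary joining nucleotide
diversity, inbreeding, mutation load and genomic offsets together with their
pairwise Spearman correlations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import filtering, io as _io, load as _load, offset as _offset, popgen, roh as _roh
from .gf import fit_gradient_forest

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    annotations: str
    popmap: str
    chrom_sizes: str
    climate_current: str
    climate_future: dict[str, str] = field(default_factory=dict)  # scenario -> path
    lineages: str | None = None          # TSV population<TAB>lineage
    out_dir: str = "loadscape_run"
    seed: int = 0

    # stage toggles
    run_filter: bool = True
    run_stats: bool = True
    run_load: bool = True
    run_roh: bool = True
    run_offset: bool = True

    # stage parameters
    max_missing_rate: float = 0.20
    min_maf: float = 0.01
    ld_window: int = 50
    ld_step: int = 10
    ld_r2: float = 0.2
    window_size: int = 100_000
    count_mode: str = "alleles"
    roh_window: int = 50
    roh_min_kb: float = 10.0
    roh_min_snps: int = 50
    roh_max_gap: int = 1_000_000
    n_trees: int = 500
    r_threshold: float = 0.7
    n_axes: int = 3
    n_perm: int = 999
    alpha: float = 0.05
    radius_km: float = 20.0
    gf_max_loci: int = 150     # cap per SNP set fed to the gradient forest
    gf_screen_loci: int = 200  # loci subsampled for the variable-screening forest

    def validate(self) -> None:
        paths = [self.vcf, self.annotations, self.popmap, self.chrom_sizes]
        if self.run_offset:
            paths.append(self.climate_current)
            paths.extend(self.climate_future.values())
        if self.lineages:
            paths.append(self.lineages)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _genomewide_pi(matrix, popmap: pd.DataFrame) -> pd.Series:
    values = {}
    for pop in popmap["population"].unique():
        idx = matrix.sample_index(popmap.loc[popmap["population"] == pop, "sample"])
        values[pop] = popgen.window_pi(matrix.genotypes[idx])
    return pd.Series(values, name="pi")


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute the enabled stages; returns the stage tables keyed by name."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}
    manifest: dict[str, object] = {
        "loadscape_version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "inputs": {},
    }
    for name in ("vcf", "annotations", "popmap", "chrom_sizes", "climate_current"):
        path = getattr(config, name)
        if path and Path(path).exists():
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}
    for scen, path in config.climate_future.items():
        manifest["inputs"][f"climate_{scen}"] = {"path": str(path), "sha256": _sha256(path)}

    matrix = _io.read_vcf(config.vcf)
    popmap = _io.read_popmap(config.popmap)
    chrom_sizes = _io.read_chrom_sizes(config.chrom_sizes)
    lineages = None
    if config.lineages:
        lin = pd.read_csv(config.lineages, sep="\t")
        lineages = dict(zip(lin["population"], lin["lineage"]))

    def _fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---------------- filter ----------------
    if config.run_filter:
        try:
            thresholds = filtering.FilterThresholds(
                max_missing_rate=config.max_missing_rate,
                min_maf=config.min_maf,
                ld_r2=config.ld_r2,
                ld_window=config.ld_window,
                ld_step=config.ld_step,
            )
            matrix = filtering.filter_sites(matrix, thresholds)
            logger.info("filter: %d sites retained", matrix.n_sites)
        except Exception as exc:  # noqa: BLE001
            _fail("filter", exc)

    annotations = filtering.parse_annotations(config.annotations, matrix)

    # ---------------- load ----------------
    if config.run_load:
        try:
            polarization = _load.polarize(matrix)
            classes = _load.classify_sites(annotations)
            load_report = _load.compute_load(
                matrix, polarization, classes, count_mode=config.count_mode
            )
            pop_load = _load.population_load(load_report, popmap)
            load_report.to_csv(out / "load_individual.tsv", sep="\t", index=False)
            pop_load.to_csv(out / "load_population.tsv", sep="\t", index=False)
            results["load_individual"] = load_report
            results["load_population"] = pop_load
        except Exception as exc:  # noqa: BLE001
            _fail("load", exc)

    # ---------------- roh ----------------
    if config.run_roh:
        try:
            params = _roh.ROHParams(
                window_snps=config.roh_window,
                min_length=int(config.roh_min_kb * 1000),
                min_snps=config.roh_min_snps,
                max_gap=config.roh_max_gap,
            )
            roh_table = _roh.detect_roh_cohort(matrix, params)
            genome_length = sum(chrom_sizes.values())
            inbreeding = _roh.inbreeding_report(matrix, roh_table, genome_length)
            roh_table.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
            inbreeding.to_csv(out / "inbreeding.tsv", sep="\t", index=False)
            results["roh_segments"] = roh_table
            results["inbreeding"] = inbreeding
        except Exception as exc:  # noqa: BLE001
            _fail("roh", exc)

    # ---------------- windowed stats ----------------
    if config.run_stats:
        try:
            stats = popgen.windowed_statistics(
                matrix, popmap, chrom_sizes,
                window_size=config.window_size, lineages=lineages,
            )
            stats.to_csv(out / "window_stats.tsv", sep="\t", index=False)
            results["window_stats"] = stats
        except Exception as exc:  # noqa: BLE001
            _fail("stats", exc)

    # ---------------- offset ----------------
    if config.run_offset:
        try:
            results.update(_offset_stage(config, matrix, annotations, popmap, out))
        except Exception as exc:  # noqa: BLE001
            _fail("offset", exc)

    # ---------------- summary ----------------
    summary = _summarize(config, matrix, popmap, results)
    summary.to_csv(out / "summary_population.tsv", sep="\t", index=False)
    results["summary"] = summary
    numeric = summary.drop(columns=["population"]).dropna(axis=1, how="all")
    if numeric.shape[1] >= 2:
        corr = numeric.corr(method="spearman")
        corr.to_csv(out / "summary_correlations.tsv", sep="\t")
        results["summary_correlations"] = corr

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results


def _offset_stage(config, matrix, annotations, popmap, out: Path) -> dict[str, pd.DataFrame]:
    rng = np.random.default_rng(config.seed)
    thresholds = filtering.FilterThresholds(
        max_missing_rate=0.0, min_maf=max(config.min_maf, 1e-9),
        ld_r2=config.ld_r2, ld_window=config.ld_window, ld_step=config.ld_step,
    )
    complete = filtering.filter_sites(matrix, thresholds)
    pruned_idx = filtering.ld_prune(complete, thresholds)
    pruned = complete.take_sites(pruned_idx)
    freqs = _offset.population_allele_freqs(pruned, popmap)
    logger.info("offset: %d no-missing LD-pruned loci", pruned.n_sites)

    grid_current = _io.read_climate_table(config.climate_current)
    future = {s: _io.read_climate_table(p) for s, p in config.climate_future.items()}
    env_pop = _env_at_populations(grid_current, popmap)
    env_pop = env_pop.loc[list(freqs.index)]

    # variable screening: preliminary forest on the most variable loci
    # (high across-population variance carries the differentiation signal)
    n_screen = min(config.gf_screen_loci, freqs.shape[1])
    variance = freqs.var(axis=0)
    screen_cols = variance.nlargest(n_screen).index
    screen_model = fit_gradient_forest(
        freqs[screen_cols], env_pop, n_trees=config.n_trees, seed=config.seed,
    )
    variables = _offset.select_climate_variables(
        env_pop, screen_model.importance, config.r_threshold
    )
    logger.info("offset: retained climate variables %s", variables)
    env_sel = env_pop[variables]

    rda = _offset.rda_adaptive_snps(
        freqs, env_sel, n_axes=config.n_axes, n_perm=config.n_perm,
        alpha=config.alpha, seed=config.seed,
    )
    adaptive_loci = rda.loc[rda["adaptive"], "locus"].tolist()
    if len(adaptive_loci) > config.gf_max_loci:
        pick = np.sort(rng.choice(len(adaptive_loci), size=config.gf_max_loci, replace=False))
        adaptive_loci = [adaptive_loci[i] for i in pick]
    site_ids = annotations["chrom"].astype(str) + ":" + annotations["pos"].astype(str)
    pruned_ids = set(freqs.columns)
    intergenic_pool = annotations[
        (annotations["effect"] == "intergenic") & site_ids.isin(pruned_ids)
    ]
    n_neutral = min(len(adaptive_loci), len(intergenic_pool))
    neutral_rows = _offset.sample_neutral_snps(
        intergenic_pool, n_neutral, seed=config.seed
    )
    neutral_loci = site_ids.loc[neutral_rows].tolist()

    tables: dict[str, pd.DataFrame] = {"rda": rda}
    rda.to_csv(out / "rda_loci.tsv", sep="\t", index=False)
    pop_offsets = {}
    for label, loci in (("adaptive", adaptive_loci), ("neutral", neutral_loci)):
        if not loci:
            logger.warning("offset: empty %s locus set, skipping", label)
            continue
        model = fit_gradient_forest(
            freqs[loci], env_sel, n_trees=config.n_trees, seed=config.seed,
        )
        offset_map = _offset.genomic_offset(
            model, grid_current[["cell", "lat", "lon"] + variables],
            {s: f[["cell", "lat", "lon"] + variables] for s, f in future.items()},
        )
        per_pop = _offset.population_offset(offset_map, popmap, config.radius_km)
        offset_map.to_csv(out / f"offset_grid_{label}.tsv", sep="\t", index=False)
        tables[f"offset_grid_{label}"] = offset_map
        pop_offsets[label] = per_pop
    if pop_offsets:
        pop_table = pd.DataFrame(pop_offsets).rename_axis("population").reset_index()
        pop_table.to_csv(out / "offset_population.tsv", sep="\t", index=False)
        tables["offset_population"] = pop_table
    return tables


def _env_at_populations(grid: pd.DataFrame, popmap: pd.DataFrame) -> pd.DataFrame:
    """Climate at each population = nearest grid-cell values."""
    variables = [c for c in grid.columns if c not in ("cell", "lat", "lon")]
    rows = {}
    pops = popmap.drop_duplicates("population")
    for _, row in pops.iterrows():
        d = _offset.haversine_km(
            row["lat"], row["lon"], grid["lat"].to_numpy(), grid["lon"].to_numpy()
        )
        rows[row["population"]] = grid.iloc[int(np.argmin(d))][variables]
    env = pd.DataFrame.from_dict(rows, orient="index")[variables].astype(float)
    env.index.name = "population"
    return env


def _summarize(config, matrix, popmap, results) -> pd.DataFrame:
    summary = pd.DataFrame({"population": popmap["population"].unique()})
    pi = _genomewide_pi(matrix, popmap)
    summary["pi"] = summary["population"].map(pi)
    if "inbreeding" in results:
        merged = results["inbreeding"].merge(
            popmap[["sample", "population"]], on="sample"
        )
        agg = merged.groupby("population")[["f_roh", "f_is"]].mean()
        summary["f_roh"] = summary["population"].map(agg["f_roh"])
        summary["f_is"] = summary["population"].map(agg["f_is"])
    if "load_population" in results:
        lp = results["load_population"].set_index("population")
        for col in ("masked_load", "realized_load"):
            summary[col] = summary["population"].map(lp[col])
    if "offset_population" in results:
        op = results["offset_population"].set_index("population")
        for col in op.columns:
            summary[f"offset_{col}"] = summary["population"].map(op[col])
    return summary
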