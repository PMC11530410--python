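"""Genomic offset under future climate, and adaptive/neutral SNP sets.

The genomic offset of a grid cell is the Euclidean distance between its
current and future climate after both are mapped through the turnover
functions of a fitted :class:`~loadscape.gf.TurnoverModel`; offsets are
computed per future scenario and then averaged across scenarios.  Population
offsets are means over the grid cells whose centers fall within a fixed
radius (default 20 km, haversine) of the population coordinate.

Adaptive loci are flagged by redundancy analysis (RDA): the population
frequency matrix is regressed on standardized climate variables, the fitted
values are eigen-decomposed, and each locus is scored by its squared loading
norm on the first constrained axes; significance comes from row permutation
of the climate table.  Neutral loci are drawn uniformly from intergenic
annotations.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .gf import TurnoverModel

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


# ----------------------------------------------------------------------
# population allele frequencies
# ----------------------------------------------------------------------
def population_allele_freqs(matrix, popmap: pd.DataFrame) -> pd.DataFrame:
    """Populations x loci derived-allele frequencies (requires no missing calls)."""
    from .genotypes import MISSING

    if (matrix.genotypes == MISSING).any():
        raise ValueError(
            "input contains missing genotypes; build the frequency table from "
            "the no-missing SNP set (filter with max_missing_rate=0)"
        )
    loci = [f"{c}:{p}" for c, p in zip(matrix.sites["chrom"], matrix.sites["pos"])]
    rows = {}
    for pop in popmap["population"].unique():
        idx = matrix.sample_index(popmap.loc[popmap["population"] == pop, "sample"])
        rows[pop] = matrix.genotypes[idx].sum(axis=0) / (2.0 * len(idx))
    return pd.DataFrame.from_dict(rows, orient="index", columns=loci)


# ----------------------------------------------------------------------
# climate variable selection
# ----------------------------------------------------------------------
def select_climate_variables(
    env: pd.DataFrame,
    importances: Mapping[str, float],
    r_threshold: float = 0.7,
) -> list[str]:
    """Drop redundant climate variables by Spearman correlation.

    Among any pair with |Spearman R| > ``r_threshold`` the lower-importance
    variable is removed, repeating until no pair exceeds the threshold.
    Constant variables are dropped up front with a warning.
    """
    variables = [v for v in env.columns]
    for v in list(variables):
        if env[v].nunique() <= 1:
            logger.warning("dropping constant climate variable %s", v)
            variables.remove(v)
    if len(variables) < 2:
        return variables
    while True:
        corr = env[variables].corr(method="spearman").abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(int(np.argmax(corr)), corr.shape)
        if corr[i, j] <= r_threshold:
            break
        a, b = variables[i], variables[j]
        drop = a if importances.get(a, 0.0) <= importances.get(b, 0.0) else b
        variables.remove(drop)
        if len(variables) < 2:
            break
    return variables


# ----------------------------------------------------------------------
# offsets
# ----------------------------------------------------------------------
def genomic_offset(
    model: TurnoverModel,
    current: pd.DataFrame,
    future: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per-cell offsets for each scenario plus their mean.

    ``current`` and every scenario table must share the ``cell`` ids (and
    carry lat/lon, which are passed through).
    """
    if not future:
        raise ValueError("at least one future scenario is required")
    cur = current.set_index("cell")
    out = current[["cell", "lat", "lon"]].copy()
    t_cur = model.transform(cur)
    names = []
    for name, table in future.items():
        fut = table.set_index("cell")
        if not fut.index.equals(cur.index):
            raise ValueError(f"scenario {name!r} grid cells do not match the current grid")
        t_fut = model.transform(fut)
        out[f"offset_{name}"] = np.sqrt(
            ((t_fut.to_numpy() - t_cur.to_numpy()) ** 2).sum(axis=1)
        )
        names.append(f"offset_{name}")
    out["offset_mean"] = out[names].mean(axis=1)
    return out


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (inputs in decimal degrees)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def population_offset(
    offset_map: pd.DataFrame,
    popmap: pd.DataFrame,
    radius_km: float = 20.0,
    column: str = "offset_mean",
) -> pd.Series:
    """Mean offset over grid cells within ``radius_km`` of each population."""
    pops = popmap.drop_duplicates("population")
    values = {}
    for _, row in pops.iterrows():
        d = haversine_km(
            row["lat"], row["lon"], offset_map["lat"].to_numpy(), offset_map["lon"].to_numpy()
        )
        inside = d <= radius_km
        if not inside.any():
            logger.warning(
                "no grid cell within %.0f km of population %s", radius_km, row["population"]
            )
            values[row["population"]] = np.nan
        else:
            values[row["population"]] = float(offset_map.loc[inside, column].mean())
    return pd.Series(values, name=column)


# ----------------------------------------------------------------------
# RDA adaptive loci
# ----------------------------------------------------------------------
def _rda_statistic(y_centered: np.ndarray, x_std: np.ndarray, n_axes: int) -> np.ndarray:
    """Squared loading norm per locus on the first constrained RDA axes."""
    q, _ = np.linalg.qr(x_std)
    y_hat = q @ (q.T @ y_centered)
    _, s, vt = np.linalg.svd(y_hat, full_matrices=False)
    k = min(n_axes, np.sum(s > 1e-12 * max(s[0], 1e-300)))
    if k == 0:
        return np.zeros(y_centered.shape[1])
    loadings = s[:k, None] * vt[:k]  # axes x loci
    return np.sum(loadings**2, axis=0)


def rda_adaptive_snps(
    freqs: pd.DataFrame,
    env: pd.DataFrame,
    n_axes: int = 3,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Flag climate-associated loci by permutation RDA.

    Returns a per-locus frame with the observed statistic, the empirical
    p-value ``(1 + #{perm >= obs}) / (n_perm + 1)`` and an ``adaptive`` flag
    at ``p <= alpha``.
    """
    if len(freqs) != len(env):
        raise ValueError("frequency and climate tables must have the same populations")
    n_pops, n_vars = env.shape
    if n_pops < n_vars + 2:
        raise ValueError(f"need at least {n_vars + 2} populations for {n_vars} variables")
    x = env.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [env.columns[k] for k in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant climate variables {bad} make the design rank-deficient")
    x_std = (x - x.mean(axis=0)) / sd
    if np.linalg.matrix_rank(x_std) < n_vars:
        corr = pd.DataFrame(x_std, columns=env.columns).corr().abs()
        np.fill_diagonal(corr.values, 0)
        i, j = np.unravel_index(int(np.argmax(corr.to_numpy())), corr.shape)
        raise ValueError(
            f"collinear climate variables (e.g. {corr.index[i]} ~ {corr.columns[j]})"
        )
    y = freqs.to_numpy(dtype=float)
    y_c = y - y.mean(axis=0)
    observed = _rda_statistic(y_c, x_std, n_axes)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(y.shape[1], dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n_pops)
        stat = _rda_statistic(y_c, x_std[perm], n_axes)
        exceed += stat >= observed
    pval = (1.0 + exceed) / (n_perm + 1.0)
    return pd.DataFrame(
        {
            "locus": freqs.columns,
            "statistic": observed,
            "p_value": pval,
            "adaptive": pval <= alpha,
        }
    )


def sample_neutral_snps(
    annotations: pd.DataFrame,
    n: int,
    seed: int | None = None,
) -> pd.Index:
    """Uniform sample of ``n`` intergenic loci (annotation row index), no replacement."""
    intergenic = annotations.index[annotations["effect"] == "intergenic"]
    if n > len(intergenic):
        raise ValueError(f"requested {n} neutral loci but only {len(intergenic)} intergenic sites")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(intergenic), size=n, replace=False)
    return intergenic[np.sort(chosen)]
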