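"""Gradient-forest-style genotype-environment turnover model.

For every locus a bagged ensemble of regression trees predicts its
population allele frequencies from climate.  Each split's impurity reduction
is accrued to the split variable at the split threshold; per locus the
accrued mass is normalized to 1 and weighted by the locus' out-of-bag R^2
(negative R^2 truncates to zero, so unpredictable loci contribute nothing).
Summing over loci gives, per climate variable, a distribution of importance
mass along the variable's observed range.  Its cumulative curve — anchored at
0 at the range minimum, rising to the variable's total importance at the
maximum — is the "allelic turnover" function used to map climates into a
common genetic space.  Importance is impurity-reduction based rather than the
conditional-permutation importance of the reference R implementation; with
R^2 weighting it preserves the ranking and turnover geometry the offset
computation needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

DEFAULT_N_TREES = 500
DEFAULT_N_BINS = 101


@dataclass
class TurnoverModel:
    """Monotone cumulative-importance functions per climate variable."""

    variables: list[str]
    bin_edges: dict[str, np.ndarray]          # length n_bins + 1 per variable
    cumulative: dict[str, np.ndarray]         # same length; starts at 0
    importance: dict[str, float]              # total accrued importance
    locus_r2: pd.Series                        # OOB R^2 per locus (truncated at 0)
    n_trees: int = DEFAULT_N_TREES
    seed: int | None = None
    n_bins: int = field(default=DEFAULT_N_BINS)

    def turnover(self, variable: str, values) -> np.ndarray:
        """Evaluate one turnover function; out-of-range values are clamped."""
        if variable not in self.cumulative:
            raise KeyError(f"unknown variable {variable!r}")
        edges = self.bin_edges[variable]
        x = np.clip(np.asarray(values, dtype=float), edges[0], edges[-1])
        return np.interp(x, edges, self.cumulative[variable])

    def transform(self, climate: pd.DataFrame) -> pd.DataFrame:
        """Map climate vectors into turnover (genetic composition) space."""
        missing = [v for v in self.variables if v not in climate.columns]
        if missing:
            raise KeyError(f"climate table lacks model variables {missing}")
        out = pd.DataFrame(index=climate.index)
        for v in self.variables:
            out[v] = self.turnover(v, climate[v].to_numpy())
        return out


def _split_importances(forest: RandomForestRegressor) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(feature, threshold, impurity decrease) for every split in a forest."""
    feats, thrs, decs = [], [], []
    for est in forest.estimators_:
        t = est.tree_
        internal = t.children_left != -1
        idx = np.flatnonzero(internal)
        if len(idx) == 0:
            continue
        w = t.weighted_n_node_samples
        imp = t.impurity
        left, right = t.children_left[idx], t.children_right[idx]
        dec = w[idx] * imp[idx] - w[left] * imp[left] - w[right] * imp[right]
        feats.append(t.feature[idx])
        thrs.append(t.threshold[idx])
        decs.append(np.maximum(dec, 0.0))
    if not feats:
        return np.array([], dtype=int), np.array([]), np.array([])
    return np.concatenate(feats), np.concatenate(thrs), np.concatenate(decs)


def fit_gradient_forest(
    freqs: pd.DataFrame,
    env: pd.DataFrame,
    n_trees: int = DEFAULT_N_TREES,
    seed: int | None = None,
    n_bins: int = DEFAULT_N_BINS,
    min_samples_leaf: int = 2,
    max_features: float = 1 / 3,
) -> TurnoverModel:
    """Fit the turnover model.

    ``freqs``: populations x loci allele-frequency table; ``env``:
    populations x climate-variables table (same row order).  At least 4
    populations are required — below that the per-locus forests cannot be
    fit, let alone validated out-of-bag.
    """
    if len(freqs) != len(env):
        raise ValueError("frequency and climate tables must have the same populations")
    if len(freqs) < 4:
        raise ValueError(f"need at least 4 populations, got {len(freqs)}")
    if freqs.shape[1] < 1:
        raise ValueError("need at least one locus")
    variables = list(env.columns)
    x = env.to_numpy(dtype=float)
    edges = {
        v: np.linspace(x[:, k].min(), x[:, k].max(), n_bins + 1)
        for k, v in enumerate(variables)
    }
    # degenerate (constant) variables get a token width so interp is defined
    for v in variables:
        if edges[v][0] == edges[v][-1]:
            edges[v] = edges[v] + np.linspace(0.0, 1e-9, n_bins + 1)

    mass = {v: np.zeros(n_bins) for v in variables}
    r2_list = []
    seeds = np.random.SeedSequence(seed).generate_state(freqs.shape[1])
    for j, locus in enumerate(freqs.columns):
        y = freqs[locus].to_numpy(dtype=float)
        if np.all(y == y[0]):
            r2_list.append(0.0)
            continue
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            bootstrap=True,
            oob_score=True,
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
            random_state=int(seeds[j] % (2**31)),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            forest.fit(x, y)
            r2 = float(forest.oob_score_)
        r2 = 0.0 if not np.isfinite(r2) else max(r2, 0.0)
        r2_list.append(r2)
        if r2 == 0.0:
            continue
        feats, thrs, decs = _split_importances(forest)
        total = decs.sum()
        if total <= 0:
            continue
        # locus-normalized, R^2-weighted, averaged over loci so the total
        # turnover scale is the mean per-locus predictability
        weight = r2 / total / freqs.shape[1]
        for k, v in enumerate(variables):
            sel = feats == k
            if not sel.any():
                continue
            bins = np.clip(
                np.searchsorted(edges[v], thrs[sel], side="right") - 1, 0, n_bins - 1
            )
            np.add.at(mass[v], bins, decs[sel] * weight)

    cumulative = {v: np.concatenate([[0.0], np.cumsum(mass[v])]) for v in variables}
    importance = {v: float(cumulative[v][-1]) for v in variables}
    return TurnoverModel(
        variables=variables,
        bin_edges=edges,
        cumulative=cumulative,
        importance=importance,
        locus_r2=pd.Series(r2_list, index=freqs.columns, name="oob_r2"),
        n_trees=n_trees,
        seed=seed,
        n_bins=n_bins,
    )
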