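"""Turnover model, genomic offset, variable selection and RDA outliers."""

import numpy as np
import pandas as pd
import pytest

from loadscape import offset as off
from loadscape.gf import TurnoverModel, fit_gradient_forest

from conftest import make_matrix


def _toy_model(variables=("A", "B"), total=(1.0, 0.5)):
    """Hand-built 3-bin step-ish turnover model on [0, 3] per variable."""
    edges = {v: np.array([0.0, 1.0, 2.0, 3.0]) for v in variables}
    cumulative = {
        v: np.array([0.0, 0.2, 0.2, 1.0]) * t for v, t in zip(variables, total)
    }
    return TurnoverModel(
        variables=list(variables),
        bin_edges=edges,
        cumulative=cumulative,
        importance={v: float(c[-1]) for v, c in cumulative.items()},
        locus_r2=pd.Series(dtype=float),
        n_bins=3,
    )


def _cline_data(seed=5, n_pops=13, n_causal=25, n_noise=25):
    rng = np.random.default_rng(seed)
    env = pd.DataFrame(
        {
            "BIO1": np.linspace(14, 26, n_pops) + rng.normal(0, 0.4, n_pops),
            "BIO12": rng.uniform(900, 2100, n_pops),
            "BIO15": rng.uniform(40, 80, n_pops),
        }
    )
    z = (env["BIO1"] - env["BIO1"].mean()) / env["BIO1"].std()
    cols = {}
    for j in range(n_causal):
        cline = 1 / (1 + np.exp(-(rng.normal(0, 1) + 4.0 * z * rng.choice([-1, 1]))))
        cols[f"causal{j}"] = np.clip(cline + rng.normal(0, 0.03, n_pops), 0.01, 0.99)
    for j in range(n_noise):
        cols[f"noise{j}"] = rng.uniform(0.1, 0.9, n_pops)
    return pd.DataFrame(cols), env


class TestPopulationFreqs:
    def test_counting(self):
        g = np.array([[0], [1], [2]], dtype=np.int8)
        m = make_matrix(g)
        popmap = pd.DataFrame(
            {"sample": ["s0", "s1", "s2"], "population": "P", "lat": 25.0, "lon": 110.0}
        )
        freqs = off.population_allele_freqs(m, popmap)
        assert freqs.loc["P"].iloc[0] == pytest.approx(0.5)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(61)
        g = rng.binomial(2, 0.4, (10, 30)).astype(np.int8)
        m = make_matrix(g)
        popmap = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(10)],
                "population": ["P1"] * 6 + ["P2"] * 4,
                "lat": 25.0,
                "lon": 110.0,
            }
        )
        freqs = off.population_allele_freqs(m, popmap)
        for j in range(30):
            assert freqs.loc["P1"].iloc[j] == g[:6, j].sum() / 12
            assert freqs.loc["P2"].iloc[j] == g[6:, j].sum() / 8

    def test_missing_genotypes_rejected(self):
        g = np.array([[0], [-1]], dtype=np.int8)
        m = make_matrix(g)
        popmap = pd.DataFrame(
            {"sample": ["s0", "s1"], "population": "P", "lat": 25.0, "lon": 110.0}
        )
        with pytest.raises(ValueError, match="no-missing"):
            off.population_allele_freqs(m, popmap)


class TestVariableSelection:
    def test_duplicate_variable_keeps_higher_importance(self):
        rng = np.random.default_rng(62)
        x = rng.normal(size=20)
        env = pd.DataFrame({"A": x, "B": x.copy(), "C": rng.normal(size=20)})
        kept = off.select_climate_variables(env, {"A": 2.0, "B": 1.0, "C": 0.5})
        assert "A" in kept and "B" not in kept and "C" in kept

    def test_independent_variables_all_kept(self):
        rng = np.random.default_rng(63)
        env = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("ABCDE"))
        kept = off.select_climate_variables(env, {v: 1.0 for v in "ABCDE"})
        assert kept == list("ABCDE")

    def test_retained_set_passes_exhaustive_pair_check(self):
        rng = np.random.default_rng(64)
        base = rng.normal(size=50)
        env = pd.DataFrame(
            {
                "A": base,
                "B": base + rng.normal(0, 0.1, 50),
                "C": base + rng.normal(0, 0.1, 50),
                "D": rng.normal(size=50),
                "E": rng.normal(size=50),
            }
        )
        imp = {"A": 5.0, "B": 4.0, "C": 3.0, "D": 2.0, "E": 1.0}
        kept = off.select_climate_variables(env, imp, r_threshold=0.7)
        corr = env[kept].corr(method="spearman").abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.7

    def test_constant_variable_dropped(self):
        env = pd.DataFrame({"A": np.arange(10.0), "B": np.ones(10)})
        kept = off.select_climate_variables(env, {"A": 1.0, "B": 9.0})
        assert kept == ["A"]


class TestTurnoverModel:
    def test_zero_at_training_minimum_and_clamped(self):
        model = _toy_model()
        grid = pd.DataFrame({"A": [0.0, -5.0, 99.0], "B": [0.0, -5.0, 99.0]})
        tr = model.transform(grid)
        assert tr.iloc[0].tolist() == [0.0, 0.0]
        assert tr.iloc[1].tolist() == [0.0, 0.0]          # clamp below
        assert tr.iloc[2].tolist() == [1.0, 0.5]          # clamp above

    def test_piecewise_lookup(self):
        model = _toy_model(variables=("A",), total=(1.0,))
        # linear interpolation inside each bin of the cumulative curve
        assert float(model.turnover("A", 0.5)) == pytest.approx(0.1)
        assert float(model.turnover("A", 1.5)) == pytest.approx(0.2)
        assert float(model.turnover("A", 2.5)) == pytest.approx(0.6)

    def test_unknown_variable_rejected(self):
        with pytest.raises(KeyError):
            _toy_model().turnover("Z", 1.0)


class TestFitGradientForest:
    def test_constant_loci_give_flat_functions(self):
        env = pd.DataFrame({"A": np.arange(8.0), "B": np.arange(8.0)[::-1]})
        freqs = pd.DataFrame({"L1": np.full(8, 0.5), "L2": np.full(8, 0.2)})
        model = fit_gradient_forest(freqs, env, n_trees=50, seed=0)
        assert all(v == 0.0 for v in model.importance.values())
        assert np.all(model.cumulative["A"] == 0.0)

    def test_causal_variable_ranks_first(self):
        freqs, env = _cline_data(n_causal=20, n_noise=10)
        model = fit_gradient_forest(freqs, env, n_trees=300, seed=1)
        assert max(model.importance, key=model.importance.get) == "BIO1"

    def test_turnover_functions_monotone(self):
        freqs, env = _cline_data(seed=8, n_causal=10, n_noise=10)
        model = fit_gradient_forest(freqs, env, n_trees=100, seed=2)
        for v in model.variables:
            assert np.all(np.diff(model.cumulative[v]) >= 0)
            assert model.cumulative[v][0] == 0.0

    def test_deterministic_for_fixed_seed(self):
        freqs, env = _cline_data(seed=9, n_causal=5, n_noise=5)
        m1 = fit_gradient_forest(freqs, env, n_trees=60, seed=3)
        m2 = fit_gradient_forest(freqs, env, n_trees=60, seed=3)
        for v in m1.variables:
            assert np.array_equal(m1.cumulative[v], m2.cumulative[v])
        assert m1.importance == m2.importance

    def test_too_few_populations_rejected(self):
        env = pd.DataFrame({"A": [1.0, 2.0, 3.0]})
        freqs = pd.DataFrame({"L1": [0.1, 0.5, 0.9]})
        with pytest.raises(ValueError, match="4 populations"):
            fit_gradient_forest(freqs, env, n_trees=10)


class TestGenomicOffset:
    def _grids(self):
        current = pd.DataFrame(
            {"cell": [0, 1, 2], "lat": [24.0, 24.1, 24.2], "lon": 110.0,
             "A": [0.5, 1.5, 2.5], "B": [0.5, 1.5, 2.5]}
        )
        return current

    def test_future_equals_current_is_zero(self):
        model = _toy_model()
        cur = self._grids()
        out = off.genomic_offset(model, cur, {"s1": cur.copy(), "s2": cur.copy()})
        assert np.allclose(out["offset_mean"], 0.0)

    def test_single_variable_absolute_difference(self):
        model = _toy_model(variables=("A",), total=(1.0,))
        cur = self._grids()[["cell", "lat", "lon", "A"]]
        fut = cur.copy()
        fut["A"] = [1.5, 2.5, 3.0]
        out = off.genomic_offset(model, cur, {"s": fut})
        expected = np.abs(
            model.turnover("A", fut["A"]) - model.turnover("A", cur["A"])
        )
        assert np.allclose(out["offset_s"], expected)

    def test_hand_computed_two_variable_norms(self):
        model = _toy_model()
        cur = self._grids()
        fut = cur.copy()
        fut["A"] = [1.5, 2.5, 3.0]
        fut["B"] = [0.0, 0.5, 2.0]
        out = off.genomic_offset(model, cur, {"s": fut})
        ta_c, ta_f = model.turnover("A", cur["A"]), model.turnover("A", fut["A"])
        tb_c, tb_f = model.turnover("B", cur["B"]), model.turnover("B", fut["B"])
        expected = np.sqrt((ta_f - ta_c) ** 2 + (tb_f - tb_c) ** 2)
        assert np.allclose(out["offset_s"], expected, atol=1e-12)

    def test_metric_axioms_on_random_triples(self):
        model = _toy_model()
        rng = np.random.default_rng(65)
        pts = pd.DataFrame(rng.uniform(0, 3, size=(30, 2)), columns=["A", "B"])
        tr = model.transform(pts).to_numpy()

        def d(i, j):
            return float(np.linalg.norm(tr[i] - tr[j]))

        for _ in range(100):
            i, j, k = rng.integers(0, 30, 3)
            assert d(i, j) >= 0
            assert d(i, j) == pytest.approx(d(j, i))
            assert d(i, k) <= d(i, j) + d(j, k) + 1e-12
            if np.allclose(tr[i], tr[j]):
                assert d(i, j) == 0.0

    def test_cell_mismatch_rejected(self):
        model = _toy_model()
        cur = self._grids()
        fut = cur.copy()
        fut["cell"] = [5, 6, 7]
        with pytest.raises(ValueError, match="cells"):
            off.genomic_offset(model, cur, {"s": fut})


class TestPopulationOffset:
    def _map(self):
        lat = np.repeat(np.arange(24.0, 25.0, 0.1), 10)
        lon = np.tile(np.arange(110.0, 111.0, 0.1), 10)
        return pd.DataFrame(
            {"cell": np.arange(100), "lat": lat, "lon": lon,
             "offset_mean": np.linspace(0, 1, 100)}
        )

    def test_uniform_field(self):
        omap = self._map()
        omap["offset_mean"] = 0.42
        popmap = pd.DataFrame(
            {"sample": ["x"], "population": ["P"], "lat": [24.5], "lon": [110.5]}
        )
        assert off.population_offset(omap, popmap).loc["P"] == pytest.approx(0.42)

    def test_matches_bruteforce_distance_filter(self):
        omap = self._map()
        popmap = pd.DataFrame(
            {"sample": ["x"], "population": ["P"], "lat": [24.45], "lon": [110.55]}
        )
        got = off.population_offset(omap, popmap, radius_km=20.0).loc["P"]
        inside = [
            v
            for la, lo, v in zip(omap["lat"], omap["lon"], omap["offset_mean"])
            if off.haversine_km(24.45, 110.55, la, lo) <= 20.0
        ]
        assert got == pytest.approx(np.mean(inside))

    def test_no_cell_in_radius_undefined(self):
        omap = self._map()
        popmap = pd.DataFrame(
            {"sample": ["x"], "population": ["FAR"], "lat": [50.0], "lon": [60.0]}
        )
        assert np.isnan(off.population_offset(omap, popmap).loc["FAR"])


class TestRda:
    def test_null_false_positive_rate_calibrated(self):
        rng = np.random.default_rng(66)
        _, env = _cline_data(seed=10, n_causal=1, n_noise=1)
        n_loci = 400
        freqs = pd.DataFrame(
            rng.uniform(0.1, 0.9, (13, n_loci)),
            columns=[f"N{j}" for j in range(n_loci)],
        )
        res = off.rda_adaptive_snps(freqs, env, n_perm=999, alpha=0.05, seed=1)
        fpr = res["adaptive"].mean()
        se = np.sqrt(0.05 * 0.95 / n_loci)
        assert abs(fpr - 0.05) <= 2 * se

    def test_power_on_strong_clines(self):
        freqs, env = _cline_data(seed=11, n_causal=40, n_noise=100)
        res = off.rda_adaptive_snps(freqs, env, n_perm=999, alpha=0.05, seed=2)
        flagged = res.set_index("locus")["adaptive"]
        power = flagged[[f"causal{j}" for j in range(40)]].mean()
        assert power >= 0.8

    def test_joint_relabeling_invariance(self):
        freqs, env = _cline_data(seed=12, n_causal=5, n_noise=20)
        res1 = off.rda_adaptive_snps(freqs, env, n_perm=199, seed=3)
        perm = np.random.default_rng(4).permutation(len(freqs))
        res2 = off.rda_adaptive_snps(
            freqs.iloc[perm].reset_index(drop=True),
            env.iloc[perm].reset_index(drop=True),
            n_perm=199,
            seed=3,
        )
        assert np.allclose(res1["statistic"], res2["statistic"])

    def test_collinear_climate_rejected(self):
        rng = np.random.default_rng(67)
        x = rng.normal(size=13)
        env = pd.DataFrame({"A": x, "B": 2 * x, "C": rng.normal(size=13)})
        freqs = pd.DataFrame(rng.uniform(0.2, 0.8, (13, 5)))
        with pytest.raises(ValueError, match="collinear|constant"):
            off.rda_adaptive_snps(freqs, env)

    def test_too_few_populations_rejected(self):
        rng = np.random.default_rng(68)
        env = pd.DataFrame(rng.normal(size=(4, 3)), columns=list("ABC"))
        freqs = pd.DataFrame(rng.uniform(0.2, 0.8, (4, 5)))
        with pytest.raises(ValueError, match="populations"):
            off.rda_adaptive_snps(freqs, env)


class TestNeutralSampling:
    def _annotations(self, n=50):
        rng = np.random.default_rng(69)
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, n + 1) * 100,
                "effect": rng.choice(["intergenic", "synonymous"], size=n, p=[0.6, 0.4]),
                "aa_ref": "",
                "aa_alt": "",
            }
        )

    def test_all_draws_are_intergenic(self):
        ann = self._annotations()
        idx = off.sample_neutral_snps(ann, 10, seed=1)
        assert (ann.loc[idx, "effect"] == "intergenic").all()

    def test_deterministic_per_seed(self):
        ann = self._annotations()
        assert off.sample_neutral_snps(ann, 10, seed=7).equals(
            off.sample_neutral_snps(ann, 10, seed=7)
        )

    def test_full_pool_returned_when_n_matches(self):
        ann = self._annotations()
        pool = ann.index[ann["effect"] == "intergenic"]
        idx = off.sample_neutral_snps(ann, len(pool), seed=1)
        assert set(idx) == set(pool)

    def test_insufficient_pool_rejected(self):
        ann = self._annotations()
        with pytest.raises(ValueError, match="intergenic"):
            off.sample_neutral_snps(ann, 10_000, seed=1)
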