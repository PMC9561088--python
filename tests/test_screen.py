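import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enmecotype.screen import (CorrelationReport, mvs_select, normality_check,
                               pca_summary, prune_correlated, spearman_matrix,
                               strength_label)


class TestNormality:
    def test_normal_quantiles_score_high_w(self):
        q = stats.norm.ppf((np.arange(50) + 0.5) / 50)
        out = normality_check(pd.DataFrame({"x": q}))
        assert out.loc[0, "W"] > 0.99
        assert not out.loc[0, "degenerate"]

    def test_constant_vector_flagged_not_fatal(self):
        out = normality_check(pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)}))
        assert out.set_index("variable").loc["x", "degenerate"]
        assert not out.set_index("variable").loc["y", "degenerate"]

    def test_w_never_exceeds_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({f"v{i}": rng.exponential(size=30) for i in range(5)})
        out = normality_check(df)
        assert (out["W"] <= 1.0).all()


class TestSpearman:
    def test_monotone_transform_gives_unit_correlation(self):
        x = np.linspace(-2, 2, 20)
        rep = spearman_matrix(pd.DataFrame({"x": x, "y": np.exp(x)}))
        assert rep.r.loc["x", "y"] == pytest.approx(1.0)

    def test_reversed_order_gives_minus_one(self):
        x = np.arange(10.0)
        rep = spearman_matrix(pd.DataFrame({"x": x, "y": -x}))
        assert rep.r.loc["x", "y"] == pytest.approx(-1.0)

    def test_midrank_ties_match_pearson_on_ranks_oracle(self):
        a = np.array([1.0, 1.0, 2.0, 3.0])
        b = np.array([4.0, 3.0, 2.0, 1.0])
        rep = spearman_matrix(pd.DataFrame({"a": a, "b": b}))
        ra, rb = stats.rankdata(a), stats.rankdata(b)  # midranks
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert rep.r.loc["a", "b"] == pytest.approx(oracle, abs=1e-12)

    def test_strength_bands(self):
        assert strength_label(0.85) == "very strong"
        assert strength_label(-0.65) == "strong"
        assert strength_label(0.45) == "moderate"
        assert strength_label(0.25) == "weak"
        assert strength_label(0.1) == "very weak"


def _report(names, r):
    n = len(names)
    m = np.eye(n)
    for (i, j), v in r.items():
        m[i, j] = m[j, i] = v
    dm = pd.DataFrame(m, index=names, columns=names)
    return CorrelationReport(r=dm, p=dm * 0)


class TestPrune:
    def test_priority_member_survives_pair(self):
        rep = _report(["A", "B"], {(0, 1): 0.9})
        kept, _ = prune_correlated(rep, threshold=0.6, priority=["A"])
        assert kept == ["A"]

    def test_uncorrelated_set_kept_whole(self):
        rep = _report(["A", "B", "C"], {(0, 1): 0.2, (1, 2): 0.1, (0, 2): 0.3})
        kept, _ = prune_correlated(rep, threshold=0.6)
        assert kept == ["A", "B", "C"]

    def test_chain_matches_exhaustive_oracle(self):
        # A~B 0.9, B~C 0.9, A~C 0.1; priority B
        rep = _report(["A", "B", "C"], {(0, 1): 0.9, (1, 2): 0.9, (0, 2): 0.1})
        kept, _ = prune_correlated(rep, threshold=0.6, priority=["B"])
        # exhaustive search over all subsets: feasible sets with pairwise
        # |r|<0.6 that contain the top-priority feasible variable B
        from itertools import combinations

        names = ["A", "B", "C"]
        feasible = []
        for r in range(1, 4):
            for sub in combinations(range(3), r):
                ok = all(
                    abs(rep.r.iloc[i, j]) < 0.6
                    for i in sub for j in sub if i < j
                )
                if ok and 1 in sub:
                    feasible.append({names[i] for i in sub})
        assert set(kept) in feasible
        assert set(kept) == {"B"}  # nothing uncorrelated with B remains

    def test_result_invariant_to_input_order(self):
        rng = np.random.default_rng(5)
        names = list("ABCDEF")
        m = np.eye(6)
        for i in range(6):
            for j in range(i + 1, 6):
                m[i, j] = m[j, i] = rng.uniform(-1, 1)
        priority = ["C", "F"]
        base = None
        for perm_seed in range(4):
            order = list(rng.permutation(names))
            dm = pd.DataFrame(m, index=names, columns=names).loc[order, order]
            kept, _ = prune_correlated(
                CorrelationReport(r=dm, p=dm * 0), threshold=0.6, priority=priority
            )
            if base is None:
                base = set(kept)
            assert set(kept) == base

    def test_empty_report_raises(self):
        empty = CorrelationReport(r=pd.DataFrame(), p=pd.DataFrame())
        with pytest.raises(ValueError):
            prune_correlated(empty)


class TestPCA:
    def test_perfectly_correlated_pair_loads_on_one_component(self):
        x = np.linspace(0, 1, 30)
        _, var = pca_summary(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        assert var.iloc[0] == pytest.approx(100.0, abs=1e-8)

    def test_independent_variables_split_evenly(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((4000, 2)), columns=["a", "b"])
        _, var = pca_summary(df)
        assert var.iloc[0] == pytest.approx(50.0, abs=5.0)

    def test_variance_explained_sums_to_hundred_and_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((50, 4)), columns=list("abcd"))
        loadings, var = pca_summary(df)
        assert var.sum() == pytest.approx(100.0, abs=1e-8)
        assert np.all(np.diff(var.to_numpy()) <= 1e-9)
        gram = loadings.to_numpy().T @ loadings.to_numpy()
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)


class TestIterativeSelection:
    DRIVERS = {"temp_max", "temp_wet", "precip_wet"}
    NOISE = {"soil_noise", "veg_noise"}

    def test_planted_drivers_kept_noise_dropped(self, default_scenario):
        res = mvs_select(
            default_scenario.stack, default_scenario.occurrences,
            bm_list=[1.0], fc_set=("H",), n_knots=10,
        )
        sel = set(res.selected)
        assert self.DRIVERS <= sel
        assert not (self.NOISE & sel)
        dropped = {t["variable"] for t in res.trace if t["action"] == "drop"}
        assert self.NOISE <= dropped

    def test_duplicate_driver_layer_collapses_to_one(self, default_scenario):
        from enmecotype.raster import EnvStack, RasterGrid

        stack = default_scenario.stack
        layers = dict(stack.layers)
        layers["temp_max_copy"] = RasterGrid(
            stack.layers["temp_max"].values.copy(), stack.transform
        )
        dup = EnvStack(
            layers=layers,
            groups={**stack.groups, "temp_max_copy": "climatic"},
            kind={**stack.kind, "temp_max_copy": "continuous"},
        )
        res = mvs_select(dup, default_scenario.occurrences, bm_list=[1.0],
                         fc_set=("H",), n_knots=10)
        assert ("temp_max" in res.selected) != ("temp_max_copy" in res.selected)

    def test_selected_set_pairwise_below_threshold(self, default_scenario):
        res = mvs_select(default_scenario.stack, default_scenario.occurrences,
                         bm_list=[1.0], fc_set=("H",), n_knots=10)
        stack = default_scenario.stack
        cont = [v for v in res.selected if stack.kind[v] == "continuous"]
        bg = stack.background_table().drop(columns=["row", "col"])
        if len(cont) >= 2:
            rep = spearman_matrix(bg[cont])
            off = rep.r.to_numpy()[~np.eye(len(cont), dtype=bool)]
            assert np.all(np.abs(off) < 0.6)

    def test_too_few_occurrences_rejected(self, tiny_scenario):
        from enmecotype.occurrences import OccurrenceSet

        occ = tiny_scenario["occ"]
        small = OccurrenceSet(points=occ.points.iloc[:5], seed=occ.seed)
        with pytest.raises(ValueError, match="minimum"):
            mvs_select(tiny_scenario["stack"], small)
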