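"""AICc, Akaike weights, RVI rotation and full model averaging."""

import numpy as np
import pandas as pd
import pytest

from sparrowmhc.modelsel import (
    CandidateModel,
    aggregate_by_clutch,
    aicc,
    all_subsets_fit,
    iterative_rvi_selection,
    model_average,
    report_table,
    significance_marker,
    weights_and_rvi,
)


def make_model(variables, aicc_value, coefs=None, variances=None, n=100, k=3):
    return CandidateModel(variables=tuple(variables), n=n, k=k,
                          loglik=0.0, aicc=aicc_value,
                          coefs=coefs or {}, variances=variances or {})


class TestAicc:
    def test_formula_arithmetic(self):
        assert aicc(-10.0, 2, 10) == pytest.approx(24 + 12 / 7)

    def test_large_n_limit_is_aic(self):
        assert aicc(-10.0, 2, 10 ** 9) == pytest.approx(24.0, abs=1e-6)

    def test_double_entry_oracle(self, rng):
        """Independent re-computation on 100 random (loglik, k, n) triples."""
        for _ in range(100):
            ll = float(rng.normal(-50, 20))
            k = int(rng.integers(1, 10))
            n = int(rng.integers(k + 2, 500))
            expected = -2 * ll + 2 * k + (2 * k * (k + 1)) / (n - k - 1)
            assert aicc(ll, k, n) == pytest.approx(expected)

    def test_undefined_below_minimum_n(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestWeightsAndRvi:
    def test_two_model_closed_form(self):
        models = [make_model(["x"], 100.0), make_model([], 102.0)]
        models, _ = weights_and_rvi(models)
        assert models[0].weight == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-4)
        assert models[1].weight == pytest.approx(np.exp(-1) / (1 + np.exp(-1)), abs=1e-4)

    def test_rvi_additivity(self):
        # engineer AICc values whose weights are 0.5, 0.3, 0.2
        target = np.array([0.5, 0.3, 0.2])
        aiccs = -2 * np.log(target)
        models = [make_model(["x"], aiccs[0]), make_model(["y"], aiccs[1]),
                  make_model(["x", "y"], aiccs[2])]
        _, rvi = weights_and_rvi(models)
        assert rvi["x"] == pytest.approx(0.7)
        assert rvi["y"] == pytest.approx(0.5)

    def test_variable_in_every_model_has_rvi_one(self):
        models = [make_model(["x"], 10.0), make_model(["x", "y"], 12.0)]
        _, rvi = weights_and_rvi(models)
        assert rvi["x"] == pytest.approx(1.0)

    def test_weights_sum_to_one_and_shift_invariance(self):
        models = [make_model(["x"], 10.0), make_model(["y"], 13.0),
                  make_model([], 17.0)]
        _, rvi1 = weights_and_rvi(models)
        assert sum(m.weight for m in models) == pytest.approx(1.0, abs=1e-12)
        shifted = [make_model(m.variables, m.aicc + 1234.5) for m in models]
        _, rvi2 = weights_and_rvi(shifted)
        pd.testing.assert_series_equal(rvi1, rvi2)

    def test_nonfinite_models_excluded(self):
        models = [make_model(["x"], 10.0), make_model(["y"], np.inf)]
        models, rvi = weights_and_rvi(models)
        assert models[1].weight == 0.0
        assert "y" not in rvi.index


class TestAllSubsets:
    def _table(self, rng, n=200, beta=1.0, sigma=0.5):
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = beta * x + sigma * rng.standard_normal(n)
        return pd.DataFrame({"y": y, "x": x, "z": z})

    def test_pool_of_two_gives_four_models(self, rng):
        models = all_subsets_fit(self._table(rng), "y", ["x", "z"])
        assert len(models) == 4
        assert any(m.variables == () for m in models)

    def test_pool_of_ten_gives_1024(self, rng):
        tab = self._table(rng)
        for i in range(8):
            tab[f"n{i}"] = rng.standard_normal(len(tab))
        models = all_subsets_fit(tab, "y", ["x", "z"] + [f"n{i}" for i in range(8)])
        assert len(models) == 1024

    def test_pool_cap_enforced(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            all_subsets_fit(self._table(rng), "y", ["x"] * 11)

    def test_true_predictor_wins_aicc(self, rng):
        """With beta = 1, sigma = 0.5 and n = 200, the best-AICc model
        contains the causal predictor in at least 95 of 100 replicates."""
        hits = 0
        for _ in range(100):
            models = all_subsets_fit(self._table(rng), "y", ["x", "z"])
            best = min(models, key=lambda m: m.aicc)
            hits += "x" in best.variables
        assert hits >= 95


class TestModelAverage:
    def test_single_model_degenerate(self):
        m = make_model(["x"], 10.0, coefs={"(Intercept)": 0.5, "x": 1.2},
                       variances={"(Intercept)": 0.01, "x": 0.04})
        m.weight = 1.0
        tab = model_average([m])
        row = tab[tab["variable"] == "x"].iloc[0]
        assert row["estimate"] == pytest.approx(1.2)
        assert row["adjusted_se"] == pytest.approx(0.2)

    def test_two_model_formula_arithmetic(self):
        """w = (0.5, 0.5), beta = (1, absent), var = (0.04, -):
        estimate 0.5, adjusted SE sqrt(0.27)."""
        m1 = make_model(["x"], 0.0, coefs={"x": 1.0}, variances={"x": 0.04})
        m2 = make_model([], 0.0, coefs={}, variances={})
        m1.weight = m2.weight = 0.5
        tab = model_average([m1, m2])
        row = tab[tab["variable"] == "x"].iloc[0]
        assert row["estimate"] == pytest.approx(0.5)
        assert row["adjusted_se"] == pytest.approx(np.sqrt(0.27), abs=1e-6)

    def test_order_invariance(self):
        m1 = make_model(["x"], 0.0, coefs={"x": 1.0}, variances={"x": 0.04})
        m2 = make_model([], 0.0, coefs={}, variances={})
        m1.weight, m2.weight = 0.7, 0.3
        a = model_average([m1, m2]).set_index("variable")
        b = model_average([m2, m1]).set_index("variable")
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


class TestAggregation:
    def _table(self):
        return pd.DataFrame({
            "clutch_id": ["c1"] * 4 + ["c2"] * 2,
            "aviary": ["A"] * 6,
            "mother": ["f1"] * 6,
            "survival_day6": [1, 1, 0, 1, 1, 1],
            "sex": [1, 0, 1, 1, 1, 0],
            "mass_day6": [10.0, 12.0, np.nan, 11.0, 9.0, 13.0],
        })

    def test_survival_mean_and_sex_ratio(self):
        agg = aggregate_by_clutch(self._table())
        c1 = agg[agg["clutch_id"] == "c1"].iloc[0]
        assert c1["survival_day6"] == pytest.approx(0.75)
        assert c1["sex"] == pytest.approx(0.75)
        c2 = agg[agg["clutch_id"] == "c2"].iloc[0]
        assert c2["sex"] == pytest.approx(0.5)

    def test_row_accounting(self):
        tab = self._table()
        agg = aggregate_by_clutch(tab)
        assert agg["n_in_clutch"].sum() == len(tab)

    def test_grouping_columns_carried(self):
        agg = aggregate_by_clutch(self._table())
        assert set(agg["aviary"]) == {"A"}
        assert set(agg["mother"]) == {"f1"}


class TestIterativeSelection:
    def _planted_table(self, rng, n=250, n_noise=14):
        x = rng.standard_normal(n)
        y = 1.0 * x + 1.0 * rng.standard_normal(n)
        tab = pd.DataFrame({"y": y, "x": x})
        for i in range(n_noise):
            tab[f"n{i:02d}"] = rng.standard_normal(n)
        return tab

    def test_single_round_when_pool_fits(self, rng):
        tab = self._planted_table(rng, n_noise=5)
        variables = ["x"] + [f"n{i:02d}" for i in range(5)]
        res = iterative_rvi_selection(tab, "y", variables)
        assert len(res.rounds) == 1
        assert "x" in res.kept

    def test_fifteen_variables_two_rounds_and_trace(self, rng):
        """15 variables: round 1 sees 10, survivors carry into round 2 with
        the remaining 5; the causal variable placed last still surfaces."""
        tab = self._planted_table(rng, n_noise=14)
        variables = [f"n{i:02d}" for i in range(14)] + ["x"]
        res = iterative_rvi_selection(tab, "y", variables)
        assert len(res.rounds) == 2
        assert set(res.rounds[0]["pool"]) == set(variables[:10])
        assert set(res.rounds[1]["pool"]) >= set(variables[10:])
        assert "x" in res.relevant
        assert res.final_rvi["x"] > 0.7

    def test_continuous_recovery_rate_at_study_n(self, rng):
        """A 1-residual-SD planted effect at n = 188 rows: sign correct and
        RVI > 0.7 in at least 90% of 50 replicates."""
        hits = 0
        for _ in range(50):
            tab = self._planted_table(rng, n=188, n_noise=8)
            res = iterative_rvi_selection(
                tab, "y", ["x"] + [f"n{i:02d}" for i in range(8)])
            row = res.table[res.table["variable"] == "x"]
            ok = (res.final_rvi.get("x", 0.0) > 0.7
                  and not row.empty and row.iloc[0]["estimate"] > 0)
            hits += ok
        assert hits >= 45

    def test_empty_keepset_continues_rotation(self, rng):
        """Pure-noise round 1 may keep nothing; rotation must continue and
        terminate with every variable having entered a pool."""
        tab = self._planted_table(rng, n=120, n_noise=14)
        tab["y"] = rng.standard_normal(len(tab))   # break the signal
        variables = [f"n{i:02d}" for i in range(14)] + ["x"]
        res = iterative_rvi_selection(tab, "y", variables)
        seen = set().union(*(set(r["pool"]) for r in res.rounds))
        assert seen == set(variables)


class TestReporting:
    @pytest.mark.parametrize("p,marker", [
        (0.0005, "***"), (0.005, "**"), (0.049, "*"), (0.051, "."),
        (0.099, "."), (0.11, ""),
    ])
    def test_significance_markers(self, p, marker):
        assert significance_marker(p) == marker

    def test_report_keeps_only_selected_and_flags_relevant(self, rng):
        x = rng.standard_normal(300)
        y = 1.5 * x + rng.standard_normal(300)
        tab = pd.DataFrame({"y": y, "x": x, "noise": rng.standard_normal(300)})
        res = iterative_rvi_selection(tab, "y", ["x", "noise"])
        rep = report_table(res)
        assert "(Intercept)" in set(rep["variable"])
        xrow = rep[rep["variable"] == "x"].iloc[0]
        assert xrow["relevant"]
        assert xrow["marker"] in {"*", "**", "***"}

    def test_report_roundtrips_tsv(self, tmp_path, rng):
        tab = pd.DataFrame({"y": rng.standard_normal(60),
                            "x": rng.standard_normal(60)})
        res = iterative_rvi_selection(tab, "y", ["x"])
        rep = report_table(res)
        path = tmp_path / "rep.tsv"
        rep.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == list(rep.columns)
        assert len(back) == len(rep)


def test_mixed_backend_satisfies_contract(rng):
    """The nested random-intercept backend returns a finite ML fit that the
    AICc machinery can consume."""
    n = 120
    groups = pd.DataFrame({
        "aviary": np.repeat([f"A{i}" for i in range(6)], 20),
        "mother": np.repeat([f"f{i}" for i in range(24)], 5),
    })
    u = rng.standard_normal(24)[np.repeat(np.arange(24), 5)]
    x = rng.standard_normal(n)
    y = 1.0 * x + u + 0.5 * rng.standard_normal(n)
    tab = pd.DataFrame({"y": y, "x": x}).join(groups)
    models = all_subsets_fit(tab, "y", ["x"], backend="mixed_gaussian",
                             group_cols=["aviary", "mother"])
    ok = [m for m in models if m.converged and np.isfinite(m.aicc)]
    assert ok, "mixed fits failed"
    best = min(ok, key=lambda m: m.aicc)
    assert "x" in best.variables
    assert abs(best.coefs["x"] - 1.0) < 0.3
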