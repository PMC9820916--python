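"""The genetic-programming engine, importance and sensitivity."""

import numpy as np
import pandas as pd
import pytest

from airwaymorph.symreg import (ExpressionModel, SRConfig, crossover,
                                eval_tree, evaluate, evolve, mutate,
                                run_experiments, sensitivity,
                                sensitivity_table, tree_size, tree_variables,
                                variable_importance)


def model(tree, names, a=1.0, b=0.0, val_mae=0.0):
    return ExpressionModel(tree=tree, feature_names=tuple(names), scale_a=a,
                           scale_b=b, train_mae=val_mae, val_mae=val_mae)


def interpret(tree, row):
    """Independent scalar recursive interpreter (oracle for eval_tree)."""
    kind = tree[0]
    if kind == "var":
        return row[tree[1]]
    if kind == "const":
        return tree[1]
    if kind == "u":
        import math
        v = interpret(tree[2], row)
        try:
            return {"exp": math.exp, "ln": math.log,
                    "sqrt": math.sqrt}[tree[1]](v)
        except ValueError:
            return float("nan")
    if kind == "pow":
        return interpret(tree[1], row) ** tree[2]
    l, r = interpret(tree[2], row), interpret(tree[3], row)
    if tree[1] == "add":
        return l + r
    if tree[1] == "sub":
        return l - r
    if tree[1] == "mul":
        return l * r
    return l / r if r != 0 else float("inf")


class TestEvaluate:
    def test_exact_model_zero_mae(self):
        df = pd.DataFrame({"x1": [3.0, -1.0, 7.0]})
        m = model(("b", "add", ("var", 0), ("const", 2.0)), ["x1"])
        assert evaluate(m, df, np.array([5.0, 1.0, 9.0])) == 0.0

    def test_log_of_nonpositive_is_infeasible(self):
        df = pd.DataFrame({"x1": [1.0, -2.0, 3.0]})
        m = model(("u", "ln", ("var", 0)), ["x1"])
        assert evaluate(m, df, df["x1"].to_numpy()) == np.inf

    def test_division_by_zero_is_infeasible(self):
        df = pd.DataFrame({"x1": [1.0, 0.0]})
        m = model(("b", "div", ("const", 1.0), ("var", 0)), ["x1"])
        assert np.isinf(evaluate(m, df, df["x1"].to_numpy()))

    def test_matches_recursive_interpreter(self, rng):
        """Vectorized evaluation equals an independent scalar interpreter."""
        from airwaymorph.symreg import _random_tree
        X = rng.normal(size=(30, 4))
        for _ in range(40):
            t = _random_tree(rng, 4, 5.0, depth=int(rng.integers(1, 5)))
            vec = eval_tree(t, X)
            scal = np.array([interpret(t, X[i]) for i in range(30)])
            both = np.isfinite(vec) & np.isfinite(scal)
            assert np.allclose(vec[both], scal[both], rtol=1e-10, atol=1e-12)

    def test_unknown_variable_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        m = model(("var", 0), ["zz"])
        with pytest.raises(KeyError):
            evaluate(m, df, df["a"].to_numpy())


class TestTreeOperations:
    def test_size_and_variables(self):
        t = ("b", "add", ("var", 0), ("u", "sqrt", ("var", 2)))
        assert tree_size(t) == 4
        assert tree_variables(t) == {0, 2}
        assert tree_size(("pow", ("var", 1), 2.0)) == 3

    def test_infix_rendering(self):
        m = model(("b", "mul", ("const", 2.0), ("var", 0)), ["HSP"])
        assert "HSP" in m.infix and "2" in m.infix

    def test_mutation_respects_size_cap(self, rng):
        from airwaymorph.symreg import _random_tree
        for _ in range(50):
            t = _random_tree(rng, 3, 5.0, depth=4)
            t2 = mutate(rng, t, 3, 5.0, max_nodes=25)
            # mutation never grows a tree past the cap (shrinking oversized
            # inputs is not its job: point mutation preserves size)
            assert tree_size(t2) <= max(25, tree_size(t))

    def test_crossover_respects_size_cap(self, rng):
        from airwaymorph.symreg import _random_tree
        for _ in range(50):
            t1 = _random_tree(rng, 3, 5.0, depth=4)
            t2 = _random_tree(rng, 3, 5.0, depth=4)
            child = crossover(rng, t1, t2, max_nodes=25)
            assert tree_size(child) <= max(25, tree_size(t1))

    def test_model_json_round_trip(self):
        m = model(("b", "sub", ("var", 1), ("pow", ("var", 0), 2.0)),
                  ["a", "b"], a=1.5, b=-2.0, val_mae=0.25)
        m2 = ExpressionModel.from_dict(m.to_dict())
        assert m2.tree == m.tree
        assert m2.scale_a == m.scale_a
        assert m2.val_mae == m.val_mae


def _tiny_table(rng, n=60):
    X = rng.normal(size=(n, 3))
    df = pd.DataFrame(X, columns=["x1", "x2", "x3"])
    df["y"] = 1.5 * df.x1 - 2.0 * df.x2
    return df


class TestEvolve:
    CFG = dict(population_size=120, generations=25, max_evaluations=50_000)

    def test_determinism_under_seed(self, rng):
        df = _tiny_table(rng)
        cfg = SRConfig(target="y", **self.CFG)
        r1 = evolve(df, "y", cfg, seed=3)
        r2 = evolve(df, "y", cfg, seed=3)
        assert [m.tree for m in r1.front] == [m.tree for m in r2.front]
        assert r1.best.val_mae == r2.best.val_mae

    def test_front_strictly_improves(self, rng):
        df = _tiny_table(rng)
        r = evolve(df, "y", SRConfig(target="y", **self.CFG), seed=4)
        cx = [m.complexity for m in r.front]
        mae = [m.train_mae for m in r.front]
        assert cx == sorted(cx)
        assert all(b < a for a, b in zip(mae, mae[1:]))

    def test_constant_target_rejected(self, rng):
        df = _tiny_table(rng)
        df["y"] = 7.0
        with pytest.raises(ValueError, match="zero variance"):
            evolve(df, "y", SRConfig(target="y", **self.CFG), seed=0)

    def test_near_constant_structure_recovered(self, rng):
        """A planted linear model is matched to high accuracy quickly."""
        df = _tiny_table(rng, n=80)
        r = evolve(df, "y", SRConfig(target="y", **self.CFG), seed=1)
        assert r.best.val_mae < 1e-6 * df.y.std()
        assert set(r.best.variables) >= {"x1", "x2"}

    def test_too_few_rows_rejected(self, rng):
        df = _tiny_table(rng, n=8)
        with pytest.raises(ValueError, match="10 rows"):
            evolve(df, "y", SRConfig(target="y", **self.CFG), seed=0)


class TestImportance:
    NAMES = ["x1", "x2"]

    def test_single_model(self):
        m = model(("var", 0), self.NAMES, val_mae=0.5)
        imp = variable_importance([m])
        assert imp["x1"] == pytest.approx(1.0)

    def test_two_equal_models_split_evenly(self):
        m1 = model(("var", 0), self.NAMES, val_mae=1.0)
        m2 = model(("var", 1), self.NAMES, val_mae=1.0)
        imp = variable_importance([m1, m2])
        assert imp["x1"] == pytest.approx(0.5)
        assert imp["x2"] == pytest.approx(0.5)

    def test_fit_weighting_ratio(self):
        """MAEs (1, 1, 9): the two good models' variable outweighs 20:1."""
        ms = [model(("var", 0), self.NAMES, val_mae=1.0),
              model(("var", 0), self.NAMES, val_mae=1.0),
              model(("var", 1), self.NAMES, val_mae=9.0)]
        imp = variable_importance(ms)
        assert imp["x1"] / imp["x2"] == pytest.approx(18.0, rel=1e-9)

    def test_duplication_invariance(self):
        ms = [model(("var", 0), self.NAMES, val_mae=1.0),
              model(("var", 1), self.NAMES, val_mae=3.0)]
        imp1 = variable_importance(ms)
        imp2 = variable_importance(ms + ms)
        assert np.allclose(imp1.sort_index(), imp2.sort_index())

    def test_normalization(self):
        ms = [model(("b", "add", ("var", 0), ("var", 1)), self.NAMES,
                    val_mae=0.5),
              model(("var", 0), self.NAMES, val_mae=2.0)]
        imp = variable_importance(ms)
        assert imp.sum() == pytest.approx(1.0)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            variable_importance([])


class TestSensitivity:
    def test_linear_scaling_gives_unit_magnitude(self, rng):
        df = pd.DataFrame({"x": rng.normal(2.0, 3.0, 50)})
        up = model(("b", "mul", ("const", 2.0), ("var", 0)), ["x"])
        dn = model(("b", "mul", ("const", -3.0), ("var", 0)), ["x"])
        s_up = sensitivity(up, df, "x")
        s_dn = sensitivity(dn, df, "x")
        assert s_up.loc["x", "signed_magnitude"] == pytest.approx(1.0, abs=1e-6)
        assert s_dn.loc["x", "signed_magnitude"] == pytest.approx(-1.0, abs=1e-6)

    def test_product_model_matches_numeric_oracle(self, rng):
        """d(x1*x2)/dx1 averaged over a Gaussian table, standardized."""
        X = rng.normal(size=(500, 2)) * [1.0, 2.0] + [3.0, 1.0]
        df = pd.DataFrame(X, columns=["x1", "x2"])
        m = model(("b", "mul", ("var", 0), ("var", 1)), ["x1", "x2"])
        s = sensitivity(m, df, "x1")
        f = X[:, 0] * X[:, 1]
        # oracle: mean d f / d x1 = mean(x2); standardized by sd(x1)/sd(f)
        expect = X[:, 1].mean() * X[:, 0].std() / f.std()
        assert s.loc["x1", "signed_magnitude"] == pytest.approx(expect, abs=1e-6)

    def test_undefined_rows_flagged(self, rng):
        x = np.concatenate([rng.uniform(0.5, 2.0, 10), -rng.uniform(1, 2, 10)])
        df = pd.DataFrame({"x": x})
        m = model(("u", "ln", ("var", 0)), ["x"])
        with pytest.raises(ValueError, match="infeasible"):
            sensitivity(m, df, "x")


class TestRunExperiments:
    def test_single_run_reduces_to_evolve(self, rng):
        df = _tiny_table(rng)
        cfg = SRConfig(target="y", runs=1, seed=9, population_size=100,
                       generations=15, max_evaluations=20_000)
        exp = run_experiments(df, "y", cfg)
        assert len(exp.runs) == 1
        assert exp.importance.sum() == pytest.approx(1.0)
        assert set(exp.sensitivity.index) <= {"x1", "x2", "x3"}

    def test_front_models_not_dominated(self, rng):
        df = _tiny_table(rng)
        cfg = SRConfig(target="y", runs=2, seed=2, population_size=100,
                       generations=15, max_evaluations=20_000)
        exp = run_experiments(df, "y", cfg)
        for r in exp.runs:
            for m in r.front:
                for other in r.front:
                    dominates = (other.complexity <= m.complexity
                                 and other.train_mae < m.train_mae) or \
                                (other.complexity < m.complexity
                                 and other.train_mae <= m.train_mae)
                    assert not dominates
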