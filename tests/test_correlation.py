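import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import naive_spearman
from promoscreen.correlation import (
    ConstantVectorError,
    SelectionPolicy,
    pairwise_gene_correlation,
    select_correlated_set,
    spearman_screen,
)


def _expr(rows: dict, samples=None) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    if samples:
        df.columns = samples
    return df


class TestSpearmanScreen:
    def test_identical_gene_has_rho_one(self, rng):
        seed = rng.normal(size=20)
        expr = _expr({"seed": seed, "twin": seed.copy(), "noise": rng.normal(size=20)})
        res = spearman_screen(expr, "seed")
        assert res.loc["twin", "rho"] == pytest.approx(1.0)
        assert res.loc["twin", "p_value"] == 0.0

    def test_rank_reversal_has_rho_minus_one(self, rng):
        seed = rng.normal(size=15)
        expr = _expr({"seed": seed, "anti": -seed})
        assert spearman_screen(expr, "seed").loc["anti", "rho"] == pytest.approx(-1.0)

    def test_textbook_example(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 = 4, n = 5 -> 0.8
        expr = _expr({"seed": [1, 2, 3, 4, 5], "g": [1, 3, 2, 5, 4]})
        assert spearman_screen(expr, "seed").loc["g", "rho"] == pytest.approx(0.8)

    def test_matches_bruteforce_oracle(self, rng):
        mat = rng.normal(size=(10, 20))
        mat[2] = np.round(mat[2], 1)  # force ties
        expr = pd.DataFrame(mat, index=[f"g{i}" for i in range(10)])
        res = spearman_screen(expr, "g0")
        for gid in res.index:
            expected = naive_spearman(expr.loc["g0"], expr.loc[gid])
            assert res.loc[gid, "rho"] == pytest.approx(expected, abs=1e-12)

    def test_constant_seed_raises(self):
        expr = _expr({"seed": [1.0] * 10, "g": list(range(10))})
        with pytest.raises(ConstantVectorError):
            spearman_screen(expr, "seed")

    def test_invariant_under_monotone_transform(self, rng):
        seed = rng.normal(size=25)
        g = rng.normal(size=25)
        base = spearman_screen(_expr({"seed": seed, "g": g}), "seed")
        warped = spearman_screen(
            _expr({"seed": np.exp(seed), "g": g**3}), "seed"
        )
        assert warped.loc["g", "rho"] == pytest.approx(base.loc["g", "rho"], abs=1e-12)

    def test_exact_permutation_p_small_n(self):
        expr = _expr({"seed": [1, 2, 3, 4, 5, 6], "g": [1, 2, 4, 3, 6, 5]})
        res = spearman_screen(expr, "seed", exact_p=True)
        # p is a permutation tail probability: in (0, 1], multiple of 1/6!
        p = res.loc["g", "p_value"]
        assert 0 < p <= 1
        assert (p * 720) == pytest.approx(round(p * 720), abs=1e-9)

    def test_fdr_family_excludes_seed(self, rng):
        expr = pd.DataFrame(rng.normal(size=(6, 30)), index=list("abcdef"))
        res = spearman_screen(expr, "a")
        assert "a" not in res.index
        assert len(res) == 5


class TestSelectCorrelatedSet:
    def _results(self, rhos: dict) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rho": list(rhos.values()),
                "p_value": 0.001,
                "fdr": 0.001,
                "n_samples": 50,
            },
            index=pd.Index(rhos.keys(), name="gene_id"),
        )

    def test_rho_min_threshold(self):
        res = self._results({"a": 0.9, "b": 0.5, "c": -0.2})
        gs = select_correlated_set(res, "seed", SelectionPolicy(rho_min=0.6, fdr_max=None))
        assert gs.member_gene_ids == ["a"]

    def test_top_n_ordering(self):
        res = self._results({"a": 0.5, "b": 0.9, "c": -0.2})
        gs = select_correlated_set(
            res, "seed", SelectionPolicy(rho_min=None, fdr_max=None, top_n=2)
        )
        assert gs.member_gene_ids == ["b", "a"]

    def test_rho_min_zero_keeps_only_positive(self):
        res = self._results({"a": 0.9, "b": 0.5, "c": -0.2})
        gs = select_correlated_set(res, "seed", SelectionPolicy(rho_min=0.0, fdr_max=None))
        assert gs.member_gene_ids == ["a", "b"]

    def test_top_n_returns_min_of_k_and_tested(self):
        res = self._results({"a": 0.9, "b": 0.5})
        gs = select_correlated_set(
            res, "seed", SelectionPolicy(rho_min=None, fdr_max=None, top_n=10)
        )
        assert len(gs.member_gene_ids) == 2

    def test_ties_break_lexicographically(self):
        res = self._results({"z": 0.7, "a": 0.7, "m": 0.7})
        gs = select_correlated_set(res, "seed", SelectionPolicy(rho_min=0.5, fdr_max=None))
        assert gs.member_gene_ids == ["a", "m", "z"]

    def test_empty_selection_warns(self):
        res = self._results({"a": 0.1})
        with pytest.warns(UserWarning):
            gs = select_correlated_set(
                res, "seed", SelectionPolicy(rho_min=0.99, fdr_max=None)
            )
        assert gs.member_gene_ids == []

    def test_selection_rule_recorded(self):
        res = self._results({"a": 0.9})
        gs = select_correlated_set(res, "seed")
        assert "rho_min=0.5" in gs.selection_rule
        assert "fdr_max=0.05" in gs.selection_rule

    def test_negative_sign_policy(self):
        res = self._results({"a": 0.9, "b": -0.8})
        gs = select_correlated_set(
            res, "seed", SelectionPolicy(rho_min=0.5, fdr_max=None, sign="negative")
        )
        assert gs.member_gene_ids == ["b"]


class TestPairwise:
    @pytest.mark.parametrize(
        "a,b,method,expected",
        [
            ([1, 2, 3], [2, 4, 6], "pearson", 1.0),
            ([1, 2, 3], [3, 2, 1], "pearson", -1.0),
            ([0, 1, 2, 3], [0, 1, 2, 100], "spearman", 1.0),
        ],
    )
    def test_known_values(self, a, b, method, expected):
        expr = _expr({"x": a, "y": b})
        r, p, n = pairwise_gene_correlation(expr, "x", "y", method)
        assert r == pytest.approx(expected)
        assert n == len(a)

    def test_constant_vector_raises(self):
        expr = _expr({"x": [1, 1, 1, 1], "y": [1, 2, 3, 4]})
        with pytest.raises(ConstantVectorError):
            pairwise_gene_correlation(expr, "x", "y")


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.integers(-50, 50), st.integers(-50, 50)),
        min_size=6,
        max_size=20,
    )
)
def test_spearman_matches_oracle_property(data):
    """Screen rho equals explicit rank-then-Pearson on arbitrary integer data."""
    x = np.array([d[0] for d in data], dtype=float)
    y = np.array([d[1] for d in data], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return
    expr = pd.DataFrame([x, y], index=["seed", "g"])
    res = spearman_screen(expr, "seed")
    assert res.loc["g", "rho"] == pytest.approx(naive_spearman(x, y), abs=1e-12)
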