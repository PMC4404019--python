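"""Codon-pair counting, independence expectations and adjusted residuals."""

import math

import numpy as np
import pytest
from scipy.stats.contingency import expected_freq

from codonscope.context import (AVOIDED, NO_BIAS, PREFERRED, PairContextTable,
                                adjusted_residuals, bias_calls,
                                bonferroni_threshold, differential_map,
                                expected_counts, pair_counts, top_pairs)
from codonscope.genetic_code import CODON_INDEX
from codonscope.sequences import OrfRecord, OrfSet
from conftest import make_cds


def brute_force_adjusted(observed):
    """Definition-level oracle: loops, no vectorisation shared with the
    implementation."""
    obs = [[float(x) for x in row] for row in observed]
    n = sum(map(sum, obs))
    rows = [sum(r) for r in obs]
    cols = [sum(c) for c in zip(*obs)]
    out = []
    for i, row in enumerate(obs):
        line = []
        for j, o in enumerate(row):
            e = rows[i] * cols[j] / n
            if e == 0:
                line.append(float("nan"))
                continue
            denom = math.sqrt(e * (1 - rows[i] / n) * (1 - cols[j] / n))
            line.append((o - e) / denom if denom > 0 else float("nan"))
        out.append(line)
    return np.array(out)


class TestPairCounts:
    def test_direct_enumeration(self):
        orfs = OrfSet([OrfRecord("a", make_cds("AUG", "GCU", "GCU", "UAA",
                                               pad_to=100))])
        obs = pair_counts(orfs)
        assert obs[CODON_INDEX["AUG"], CODON_INDEX["GCU"]] == 1
        assert obs[CODON_INDEX["GCU"], CODON_INDEX["GCU"]] == 97
        assert obs[CODON_INDEX["GCU"], CODON_INDEX["UAA"]] == 1

    def test_total_pairs_telescopes(self, tiny_orfs):
        obs = pair_counts(tiny_orfs)
        total_codons = sum(rec.length_nt // 3 for rec in tiny_orfs)
        assert obs.sum() == total_codons - len(tiny_orfs)

    def test_pairs_never_span_orfs(self, tiny_orfs):
        # orfA ends UAA, orfB starts AUG: the (UAA, AUG) cell must stay 0
        obs = pair_counts(tiny_orfs)
        assert obs[CODON_INDEX["UAA"], CODON_INDEX["AUG"]] == 0

    def test_exclude_stop_drops_terminal_pairs(self, tiny_orfs):
        with_stop = pair_counts(tiny_orfs, include_stop=True)
        without = pair_counts(tiny_orfs, include_stop=False)
        assert with_stop.sum() - without.sum() == len(tiny_orfs)

    def test_empty_member_set_raises(self, tiny_orfs):
        with pytest.raises(ValueError):
            pair_counts(tiny_orfs, [])


class TestExpectedCounts:
    def test_toy_diagonal_table(self):
        e = expected_counts(np.array([[10, 0], [0, 10]]))
        assert np.allclose(e, 5.0)

    def test_independence_case_fixed_point(self):
        obs = np.outer([1, 2, 3], [4, 5, 6]).astype(float)
        assert np.allclose(expected_counts(obs), obs)

    def test_marginal_conservation(self, tiny_orfs):
        obs = pair_counts(tiny_orfs)
        e = expected_counts(obs)
        assert e.sum() == pytest.approx(obs.sum())
        diff = obs - e
        assert np.allclose(diff.sum(axis=0), 0.0, atol=1e-8)
        assert np.allclose(diff.sum(axis=1), 0.0, atol=1e-8)

    def test_matches_scipy_independence_model(self):
        rng = np.random.default_rng(11)
        obs = rng.integers(1, 50, size=(6, 6))
        assert np.allclose(expected_counts(obs), expected_freq(obs))


class TestAdjustedResiduals:
    def test_toy_table_hand_value(self):
        r = adjusted_residuals(np.array([[10, 0], [0, 10]]))
        assert r[0, 0] == pytest.approx(5 / math.sqrt(5 * 0.5 * 0.5), abs=1e-9)
        assert r[0, 0] == pytest.approx(4.4721, abs=1e-4)

    def test_zero_when_observed_equals_expected(self):
        obs = np.outer([2, 3], [4, 6]).astype(float)
        assert np.allclose(adjusted_residuals(obs), 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            obs = rng.integers(0, 40, size=(6, 6))
            obs[obs.sum(axis=1) == 0, 0] += 1  # avoid empty table corner
            got = adjusted_residuals(obs)
            want = brute_force_adjusted(obs)
            mask = ~np.isnan(want)
            assert np.array_equal(np.isnan(got), np.isnan(want))
            assert np.allclose(got[mask], want[mask], rtol=1e-10, atol=0)

    def test_magnitudes_invariant_under_row_permutation(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            obs = rng.integers(1, 30, size=(4, 4))
            perm = rng.permutation(4)
            r = adjusted_residuals(obs)
            r_perm = adjusted_residuals(obs[perm])
            assert np.allclose(np.abs(r_perm), np.abs(r[perm]))

    def test_pearson_mode(self):
        obs = np.array([[10, 0], [0, 10]])
        r = adjusted_residuals(obs, mode="pearson")
        assert r[0, 0] == pytest.approx(5 / math.sqrt(5))

    def test_zero_expected_cells_undefined(self):
        obs = np.array([[5, 5], [0, 0]])
        r = adjusted_residuals(obs)
        assert np.isnan(r[1, 0]) and np.isnan(r[1, 1])


class TestBiasCalls:
    def _table(self):
        obs = np.zeros((64, 64), dtype=int)
        obs[:4, :4] = [[100, 10, 10, 10], [10, 100, 10, 10],
                       [10, 10, 100, 10], [10, 10, 10, 100]]
        exp = expected_counts(obs)
        res = adjusted_residuals(obs, exp)
        return PairContextTable("toy", obs, exp, res)

    def test_threshold_rule(self):
        table = self._table()
        calls = bias_calls(table)
        by_res = dict(zip(calls["residual"].round(2), calls["call"]))
        assert all(c == PREFERRED for r, c in by_res.items() if r > 3)
        assert all(c == AVOIDED for r, c in by_res.items() if r < -3)

    def test_band_is_no_bias_inclusive(self):
        obs = np.zeros((64, 64), dtype=int)
        obs[:2, :2] = [[12, 8], [8, 12]]
        table = PairContextTable("t", obs, expected_counts(obs),
                                 adjusted_residuals(obs))
        calls = bias_calls(table)
        assert set(calls["call"]) == {NO_BIAS}  # residuals ~ +/-1.26

    def test_top_pairs_directions(self):
        table = self._table()
        best = top_pairs(table, k=1, direction=PREFERRED)
        worst = top_pairs(table, k=1, direction=AVOIDED)
        assert best.loc[0, "residual"] > 3
        assert worst.loc[0, "residual"] < -3
        assert best.loc[0, "codon5"] == best.loc[0, "codon3"]  # a diagonal cell

    def test_top_pairs_tie_break_lexicographic(self):
        table = self._table()
        top = top_pairs(table, k=4, direction=PREFERRED)
        assert top["residual"].nunique() == 1  # four-way tie by symmetry
        assert list(top["codon5"]) == sorted(top["codon5"])

    def test_k_exceeding_cells_returns_all(self):
        table = self._table()
        out = top_pairs(table, k=10_000)
        assert len(out) == int((~np.isnan(table.residual)).sum())


class TestDifferentialMap:
    def _table(self, seed):
        rng = np.random.default_rng(seed)
        obs = np.zeros((64, 64), dtype=int)
        obs[:8, :8] = rng.integers(5, 50, size=(8, 8))
        return PairContextTable("g%d" % seed, obs, expected_counts(obs),
                                adjusted_residuals(obs))

    def test_self_comparison_all_similar(self):
        t = self._table(1)
        dm = differential_map(t, t)
        defined = ~np.isnan(dm.delta)
        assert np.allclose(dm.delta[defined], 0.0)
        assert dm.similar[defined].all()

    def test_antisymmetry(self):
        a, b = self._table(1), self._table(2)
        ab = differential_map(a, b)
        ba = differential_map(b, a)
        mask = ~np.isnan(ab.delta)
        assert np.allclose(ab.delta[mask], -ba.delta[mask])

    def test_large_difference_not_similar(self):
        obs_a = np.zeros((64, 64), dtype=int)
        obs_a[:2, :2] = [[90, 10], [10, 90]]
        obs_b = np.zeros((64, 64), dtype=int)
        obs_b[:2, :2] = [[50, 50], [50, 50]]
        a = PairContextTable("a", obs_a, expected_counts(obs_a),
                             adjusted_residuals(obs_a))
        b = PairContextTable("b", obs_b, expected_counts(obs_b),
                             adjusted_residuals(obs_b))
        dm = differential_map(a, b)
        assert not dm.similar[0, 0]

    def test_undefined_cells_propagate(self):
        a, b = self._table(1), self._table(2)
        dm = differential_map(a, b)
        assert np.isnan(dm.delta[60, 60])
        assert not dm.similar[60, 60]


def test_bonferroni_threshold_above_plain_band():
    assert bonferroni_threshold() > 3.0
    assert bonferroni_threshold(alpha=0.05, n_cells=1) == pytest.approx(1.96, abs=0.01)
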