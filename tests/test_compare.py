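"""Sliding-window alignment, UDF/Bonferroni corrections and ranking."""

import math

import numpy as np
import pytest

import oracles
from conftest import one_hot
from pssmcompare import (
    PSSM,
    ConfigError,
    all_vs_all_matrix,
    build_background,
    compare_pssm_set,
    compare_pssms,
    compare_windows,
    normalise,
    random_pssm,
    udf_correct,
)


@pytest.fixture
def pool_dist(rng):
    qs = [normalise(random_pssm(8, seed=s)) for s in range(6)]
    cs = [normalise(random_pssm(8, seed=s + 50)) for s in range(6)]
    return build_background(qs, cs, size=2000, seed=11)


def planted_pssm(core: PSSM, total_length: int, offset: int, rng) -> PSSM:
    """Random-column PSSM with `core` embedded at `offset`."""
    w = rng.random((20, total_length))
    w[:, offset : offset + core.length] = core.weights
    return PSSM(name=f"{core.name}_planted", weights=w)


def strong_core(rng, name="core", residues="PLW") -> PSSM:
    cols = [one_hot(aa) for aa in residues]
    return PSSM(name=name, weights=np.stack(cols, axis=1))


class TestUDF:
    def test_single_uniform_identity(self):
        for p in [1e-12, 0.001, 0.37, 1.0]:
            assert udf_correct(p, 1) == p

    def test_full_support(self):
        for n in [1, 2, 5, 50]:
            assert udf_correct(1.0, n) == 1.0

    def test_two_uniform_closed_form(self):
        assert udf_correct(0.01, 2) == pytest.approx(0.01 * (1 - math.log(0.01)))

    def test_matches_series_oracle(self):
        for p in [1e-8, 1e-4, 0.05, 0.5, 0.99]:
            for n in [1, 2, 3, 5, 8]:
                assert udf_correct(p, n) == pytest.approx(
                    oracles.udf_naive(p, n), rel=1e-10
                )

    def test_monotone_in_p(self):
        ps = np.logspace(-10, 0, 60)
        vals = [udf_correct(float(p), 4) for p in ps]
        assert all(a <= b + 1e-15 for a, b in zip(vals, vals[1:]))

    def test_stable_for_tiny_p(self):
        out = udf_correct(1e-280, 10)
        assert 0.0 < out < 1e-200

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ConfigError):
            udf_correct(0.0, 2)
        with pytest.raises(ConfigError):
            udf_correct(1.5, 2)
        with pytest.raises(ConfigError):
            udf_correct(0.5, 0)


class TestWindows:
    def test_equal_lengths_give_single_window(self, pool_dist):
        a = normalise(random_pssm(6, seed=1))
        b = normalise(random_pssm(6, seed=2))
        windows = compare_windows(a, b, pool_dist)
        assert len(windows) == 1 and windows[0].offset == 0

    def test_window_count_arithmetic(self, pool_dist):
        q = normalise(random_pssm(4, seed=1))
        c = normalise(random_pssm(10, seed=2))
        windows = compare_windows(q, c, pool_dist)
        assert [w.offset for w in windows] == list(range(7))
        assert all(w.window_length == 4 for w in windows)

    def test_window_invariants(self, pool_dist):
        q = normalise(random_pssm(5, seed=3))
        c = normalise(random_pssm(9, seed=4))
        for w in compare_windows(q, c, pool_dist):
            probs = [c_.iws_p for c_ in w.per_column]
            assert w.iws_p_win == pytest.approx(np.prod(probs), rel=1e-12)
            assert 0 < w.iws_sig_win <= 1
            assert w.max_iwd == pytest.approx(max(c_.iwd for c_ in w.per_column))

    def test_unnormalised_input_rejected(self, pool_dist):
        raw = random_pssm(5, seed=0)
        with pytest.raises(ConfigError, match="normalise"):
            compare_windows(raw, normalise(raw), pool_dist)

    def test_iwd_direction_follows_query_even_when_query_larger(self, pool_dist, rng):
        # query has a one-hot column; comparison is flat there -> iwd driven
        # by query importance regardless of which PSSM slides
        core = strong_core(rng)
        query = normalise(planted_pssm(core, 9, 3, rng))
        flat = PSSM(name="flat", weights=np.full((20, 3), 0.05))
        comparison = normalise(PSSM(name="c", weights=np.tile(flat.weights, (1, 1))))
        windows = compare_windows(query, comparison, pool_dist)
        w = windows[3]  # aligned with the planted core
        assert w.max_iwd > 0.0


class TestBestWindow:
    def test_self_comparison(self, pool_dist):
        p = normalise(random_pssm(7, seed=9))
        res = compare_pssms(p, p, pool_dist)
        assert res.n_windows == 1
        assert res.best_window.offset == 0
        assert res.corrected_p == pytest.approx(res.best_window.iws_sig_win)
        assert res.dissimilarity == pytest.approx(0.0, abs=1e-12)

    def test_planted_motif_recovered_at_true_offset(self, pool_dist, rng):
        core = strong_core(rng)
        query = normalise(core)
        comparison = normalise(planted_pssm(core, 10, 3, rng))
        res = compare_pssms(query, comparison, pool_dist)
        assert res.best_window.offset == 3

    def test_bonferroni_over_windows(self, pool_dist):
        q = normalise(random_pssm(4, seed=21))
        c = normalise(random_pssm(12, seed=22))
        res = compare_pssms(q, c, pool_dist)
        assert res.n_windows == 9
        assert res.corrected_p == pytest.approx(
            min(1.0, res.best_window.iws_sig_win * 9)
        )
        assert 0 < res.corrected_p <= 1

    def test_matches_enumeration_oracle(self, pool_dist, rng):
        for trial in range(10):
            lq = int(rng.integers(3, 13))
            lc = int(rng.integers(3, 13))
            q = normalise(random_pssm(lq, seed=1000 + trial))
            c = normalise(random_pssm(lc, seed=2000 + trial))
            windows, best = oracles.enumerate_best_window(
                q.weights.tolist(), c.weights.tolist(), pool_dist.samples.tolist()
            )
            res = compare_pssms(q, c, pool_dist)
            assert res.best_window.offset == windows[best]["offset"]
            assert res.best_window.iws_sig_win == pytest.approx(
                windows[best]["sig"], abs=1e-10
            )
            assert res.corrected_p == pytest.approx(
                min(1.0, windows[best]["sig"] * len(windows)), abs=1e-10
            )

    def test_wildcard_flanks_do_not_change_best_window(self, pool_dist, rng):
        core = strong_core(rng)
        query = normalise(planted_pssm(core, 6, 1, rng))
        comparison = normalise(planted_pssm(core, 10, 1, rng))
        base = compare_pssms(query, comparison, pool_dist)

        def pad(p, k=2):
            flank = np.full((20, k), 1 / 20)
            return PSSM(name=p.name, weights=np.hstack([flank, p.weights, flank]))

        padded = compare_pssms(
            normalise(pad(query)), normalise(pad(comparison)), pool_dist
        )
        assert padded.best_window.offset == base.best_window.offset


class TestSetRanking:
    def test_query_itself_ranks_first(self, pool_dist, rng):
        query = normalise(planted_pssm(strong_core(rng), 8, 2, rng))
        decoys = [normalise(random_pssm(8, seed=300 + i, name=f"decoy{i}"))
                  for i in range(10)]
        results = compare_pssm_set(query, decoys + [query], pool_dist)
        assert results[0].comparison_name == query.name
        assert results[0].rank == 1
        assert [r.rank for r in results] == list(range(1, 12))

    def test_flags_and_full_ranking_without_significance(self, pool_dist):
        query = normalise(random_pssm(8, seed=77))
        decoys = [normalise(random_pssm(8, seed=400 + i, name=f"d{i}"))
                  for i in range(5)]
        results = compare_pssm_set(query, decoys, pool_dist, p_cutoff=1e-12)
        assert all(not r.significant for r in results)
        assert sorted(r.rank for r in results) == [1, 2, 3, 4, 5]

    def test_deterministic_tie_break_by_name(self, pool_dist):
        query = normalise(random_pssm(6, seed=5))
        twin = normalise(random_pssm(6, seed=6))
        a = PSSM(name="aaa", weights=twin.weights, normalised=True)
        b = PSSM(name="bbb", weights=twin.weights, normalised=True)
        results = compare_pssm_set(query, [b, a], pool_dist)
        assert [r.comparison_name for r in results] == ["aaa", "bbb"]

    def test_empty_set_rejected(self, pool_dist):
        with pytest.raises(ConfigError):
            compare_pssm_set(normalise(random_pssm(6, seed=0)), [], pool_dist)


class TestMatrix:
    def test_duplicate_pssms_hit_background_floor(self, rng):
        core = strong_core(rng, residues="PLWY")
        p1 = normalise(PSSM(name="a", weights=core.weights))
        p2 = normalise(PSSM(name="b", weights=core.weights))
        fillers = [normalise(random_pssm(4, seed=i, name=f"f{i}")) for i in range(4)]
        pssms = [p1, p2] + fillers
        dist = build_background(pssms, pssms, size=2000, seed=1)
        df = all_vs_all_matrix(pssms, dist)
        # minimal attainable p: every column pair scores IWS = 1 exactly,
        # whose tail probability (ties included) is iws_p(1.0)
        from pssmcompare import iws_p

        floor = udf_correct(iws_p(1.0, dist) ** 4, 4)
        assert df.loc["a", "b"] == pytest.approx(floor)
        assert df.loc["a", "b"] == df.loc["b", "a"]
        off_diag = df.values[~np.eye(len(pssms), dtype=bool)]
        assert df.loc["a", "b"] == pytest.approx(off_diag.min())

    def test_symmetric_for_equal_length_sets(self, rng):
        pssms = [normalise(random_pssm(6, seed=i, name=f"p{i}")) for i in range(4)]
        dist = build_background(pssms, pssms, size=2000, seed=2)
        df = all_vs_all_matrix(pssms, dist)
        np.testing.assert_allclose(df.values, df.values.T, rtol=1e-12)

    def test_unrelated_pssms_not_significant(self, rng):
        pssms = [normalise(random_pssm(8, seed=500 + i, name=f"r{i}"))
                 for i in range(3)]
        dist = build_background(pssms, pssms, size=5000, seed=3)
        df = all_vs_all_matrix(pssms, dist)
        off_diag = df.values[~np.eye(3, dtype=bool)]
        assert np.all(off_diag > 0.001)
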