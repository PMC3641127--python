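import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tdscreen import (
    KnownFactorSet,
    TFCatalog,
    dominance_count,
    fold_enrichment,
    group_mean_dz,
    ks_one_sided,
    min_tie_ranks,
    rank_single_feature,
    recovered_at_top,
    recovery_curve,
    run_screen,
    select_signature_box,
    smooth_ties,
)
from tdscreen.screen import RecoveryCurve, ranked_list


def dominance_oracle(e, m):
    """Literal O(n^2) definition with strict inequalities."""
    n = len(e)
    return [
        sum(1 for j in range(n) if j != i and e[j] > e[i] and m[j] < m[i])
        for i in range(n)
    ]


class TestDominance:
    def test_single_tf_has_count_zero(self):
        out = dominance_count(pd.Series({"a": 1.0}), pd.Series({"a": -1.0}))
        assert out["a"] == 0

    def test_worked_three_point_example(self):
        e = pd.Series({"A": 2.0, "B": 1.0, "C": 0.0})
        m = pd.Series({"A": -3.0, "B": -1.0, "C": 0.0})
        out = dominance_count(e, m)
        assert out.to_dict() == {"A": 0, "B": 1, "C": 2}

    def test_identical_points_do_not_dominate(self):
        e = pd.Series({"a": 1.0, "b": 1.0})
        m = pd.Series({"a": -1.0, "b": -1.0})
        assert (dominance_count(e, m) == 0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_literal_definition_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        e = rng.normal(size=n)
        m = rng.normal(size=n)
        # duplicate some points to exercise tie semantics
        if n > 10:
            e[:5] = e[5:10]
            m[:5] = m[5:10]
        idx = [f"g{i}" for i in range(n)]
        fast = dominance_count(pd.Series(e, index=idx), pd.Series(m, index=idx))
        assert list(fast) == dominance_oracle(e, m)

    def test_missing_values_excluded_with_log(self, caplog):
        e = pd.Series({"a": 1.0, "b": np.nan, "c": 0.0})
        m = pd.Series({"a": -1.0, "b": 0.0, "c": 0.0})
        with caplog.at_level("INFO", logger="tdscreen"):
            out = dominance_count(e, m)
        assert "b" not in out.index and "excluded 1" in caplog.text


class TestSingleFeatureRanking:
    def test_expression_descending(self):
        dz = pd.Series({"a": 2.0, "b": 0.0, "c": -1.0})
        assert ranked_list(dz, "descending") == ["a", "b", "c"]
        assert list(rank_single_feature(dz, "descending").sort_values().index) == [
            "a", "b", "c"
        ]

    def test_modification_ascending(self):
        dz = pd.Series({"a": -3.0, "b": 0.0, "c": 1.0})
        assert ranked_list(dz, "ascending") == ["a", "b", "c"]

    def test_reversing_direction_reverses_tie_free_order(self, rng):
        dz = pd.Series(rng.normal(size=20), index=[f"g{i}" for i in range(20)])
        assert ranked_list(dz, "descending") == ranked_list(dz, "ascending")[::-1]

    def test_ties_share_smallest_rank(self):
        dz = pd.Series({"a": 5.0, "b": 5.0, "c": 1.0})
        ranks = rank_single_feature(dz, "descending")
        assert ranks["a"] == ranks["b"] == 1 and ranks["c"] == 3


class TestRecoveryCurve:
    def test_worked_four_tf_example(self):
        curve = recovery_curve(["A", "B", "C", "D"], {"A", "C"})
        assert list(curve.points["position"]) == [1, 2, 3, 4]
        assert list(curve.points["fraction"]) == [0.5, 0.5, 1.0, 1.0]

    def test_full_recovery_at_known_size_when_known_lead(self):
        curve = recovery_curve(["A", "B", "C"], {"A", "B", "C"})
        at = curve.points.set_index("position")["fraction"]
        assert at[3] == 1.0

    def test_known_at_bottom_recovered_last(self):
        curve = recovery_curve(["A", "B", "C", "D"], {"D"})
        fr = curve.points.set_index("position")["fraction"]
        assert fr[3] == 0.0 and fr[4] == 1.0

    def test_curve_is_monotone_and_terminates_at_one(self, rng):
        ids = [f"g{i}" for i in range(100)]
        counts = pd.Series(rng.integers(0, 20, 100), index=ids)
        known = set(rng.choice(ids, 10, replace=False))
        curve = recovery_curve(counts, known)
        fr = curve.points["fraction"].to_numpy()
        assert (np.diff(fr) >= 0).all() and fr[-1] == 1.0

    def test_tied_scores_collapse_to_one_position(self):
        counts = pd.Series({"a": 0, "b": 0, "c": 1})
        curve = recovery_curve(counts, {"a"})
        assert list(curve.points["position"]) == [2, 3]

    def test_absent_known_excluded_from_denominator(self, caplog):
        with caplog.at_level("WARNING", logger="tdscreen"):
            curve = recovery_curve(["A", "B"], {"A", "ZZ"})
        assert curve.n_known == 1
        assert curve.points["fraction"].iloc[0] == 1.0

    def test_empty_known_set_rejected(self):
        with pytest.raises(ValueError):
            recovery_curve(["A"], set())


class TestSmoothTies:
    def test_worked_example(self):
        curve = RecoveryCurve(
            pd.DataFrame({"position": [1, 2, 3, 4],
                          "fraction": [0.5, 0.5, 1.0, 1.0]}),
            n_known=2, n_universe=4,
        )
        out = smooth_ties(curve)
        assert list(out.points.itertuples(index=False, name=None)) == [
            (1, 0.5), (3, 1.0)
        ]
        assert out.smoothed

    def test_idempotent_and_fraction_preserving(self, rng):
        ids = [f"g{i}" for i in range(50)]
        counts = pd.Series(rng.integers(0, 8, 50), index=ids)
        curve = recovery_curve(counts, set(rng.choice(ids, 6, replace=False)))
        once = smooth_ties(curve)
        twice = smooth_ties(once)
        assert once.points.equals(twice.points)
        assert set(once.points["fraction"]) == set(curve.points["fraction"])

    def test_strictly_increasing_input_unchanged(self):
        curve = RecoveryCurve(
            pd.DataFrame({"position": [1, 2], "fraction": [0.5, 1.0]}),
            n_known=2, n_universe=2,
        )
        assert smooth_ties(curve).points.equals(curve.points)

    def test_constant_curve_keeps_first_point(self):
        curve = RecoveryCurve(
            pd.DataFrame({"position": [1, 2], "fraction": [1.0, 1.0]}),
            n_known=1, n_universe=2,
        )
        assert list(smooth_ties(curve).points["position"]) == [1]


class TestSignatureBox:
    def test_worked_example(self):
        e = pd.Series({"anchor": 2.0, "x": 3.0, "y": 1.0, "z": 3.0})
        m = pd.Series({"anchor": -3.0, "x": -4.0, "y": -4.0, "z": -2.0})
        selected, (e_min, m_max) = select_signature_box(e, m, {"anchor"})
        assert set(selected) == {"anchor", "x"}
        assert (e_min, m_max) == (2.0, -3.0)

    def test_anchors_alone_select_themselves(self):
        e = pd.Series({"a": 1.0, "b": 2.0})
        m = pd.Series({"a": -1.0, "b": -2.0})
        selected, _ = select_signature_box(e, m, {"a", "b"})
        assert set(selected) == {"a", "b"}

    def test_boundary_is_inclusive(self):
        e = pd.Series({"anchor": 2.0, "edge": 2.0})
        m = pd.Series({"anchor": -3.0, "edge": -3.0})
        selected, _ = select_signature_box(e, m, {"anchor"})
        assert "edge" in selected

    def test_single_feature_variants(self):
        e = pd.Series({"anchor": 2.0, "x": 3.0, "y": 1.0})
        m = pd.Series({"anchor": -3.0, "x": 0.0, "y": -4.0})
        by_e, _ = select_signature_box(e, m, {"anchor"}, feature="expression")
        by_m, _ = select_signature_box(e, m, {"anchor"}, feature="modification")
        assert set(by_e) == {"anchor", "x"} and set(by_m) == {"anchor", "y"}

    def test_enlarging_the_box_never_removes_a_selection(self, rng):
        ids = [f"g{i}" for i in range(60)]
        e = pd.Series(rng.normal(size=60), index=ids)
        m = pd.Series(rng.normal(size=60), index=ids)
        small, _ = select_signature_box(e, m, {ids[0]})
        large, _ = select_signature_box(e, m, {ids[0], ids[1], ids[2]})
        assert set(small) <= set(large)

    def test_empty_anchor_set_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            select_signature_box(pd.Series(dtype=float), pd.Series(dtype=float), set())


class TestFoldEnrichment:
    @pytest.mark.parametrize("n_known,n_other,n_total,expected", [
        (3, 9, 1447, 120),   # two-feature box, neurospheres
        (3, 18, 1447, 69),   # expression alone, neurospheres
        (3, 36, 1447, 37),   # H3K27me3 alone, neurospheres
        (3, 12, 1447, 96),   # two-feature box, neural progenitors
        (3, 54, 1447, 25),   # H3K27me3 alone, neural progenitors
    ])
    def test_reproduces_reported_values(self, n_known, n_other, n_total, expected):
        assert round(fold_enrichment(n_known, n_other, n_total)) == expected

    def test_selecting_only_the_known_set(self):
        assert fold_enrichment(3, 0, 1447) == pytest.approx(481.333, abs=1e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(0, 5, 100)
        with pytest.raises(ValueError):
            fold_enrichment(3, 97, 100)


class TestKsOneSided:
    def test_identical_samples(self):
        d, p = ks_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "greater")
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports_give_d_one(self):
        d, p = ks_one_sided([10, 11, 12], [0, 1, 2], "greater")
        assert d == 1.0
        d2, _ = ks_one_sided([0, 1, 2], [10, 11, 12], "less")
        assert d2 == 1.0

    def test_wrong_direction_sees_nothing(self):
        d, p = ks_one_sided([10, 11, 12], [0, 1, 2], "less")
        assert d == 0.0 and p == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_p_value_agrees_with_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.6, 1, 8)
        b = rng.normal(0, 1, 12)
        d_obs, p_scipy = ks_one_sided(a, b, "greater")

        def one_sided_d(x, y):
            allv = np.sort(np.concatenate([x, y]))
            fx = np.searchsorted(np.sort(x), allv, "right") / len(x)
            fy = np.searchsorted(np.sort(y), allv, "right") / len(y)
            return (fy - fx).max()  # a stochastically larger => F_a below F_b

        assert one_sided_d(a, b) == pytest.approx(d_obs, abs=1e-12)
        pooled = np.concatenate([a, b])
        n_perm = 10_000
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            hits += one_sided_d(perm[:8], perm[8:]) >= d_obs - 1e-12
        p_perm = hits / n_perm
        assert p_scipy == pytest.approx(p_perm, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ks_one_sided([], [1.0], "greater")


class TestGroupMean:
    def test_singleton_group(self):
        vals = pd.Series({"a": 1.5, "b": 0.0})
        assert group_mean_dz(vals, ["a"]) == 1.5

    def test_simple_mean(self):
        assert group_mean_dz(pd.Series({"a": 1.0, "b": 2.0, "c": 3.0}), "abc") == 2.0

    def test_group_and_complement_reconstruct_global_mean(self, rng):
        vals = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        group = [f"g{i}" for i in range(30)]
        rest = [f"g{i}" for i in range(30, 100)]
        recombined = 0.3 * group_mean_dz(vals, group) + 0.7 * group_mean_dz(vals, rest)
        assert recombined == pytest.approx(vals.mean())

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            group_mean_dz(pd.Series({"a": 1.0}), ["zz"])


class TestRunScreen:
    def test_ranks_are_min_tie_permutation(self, rng):
        ids = [f"g{i}" for i in range(50)]
        e = pd.Series(rng.normal(size=50), index=ids)
        m = pd.Series(rng.normal(size=50), index=ids)
        catalog = TFCatalog(frozenset(ids))
        known = KnownFactorSet("s", "t", frozenset(ids[:5]))
        res = run_screen(e, m, catalog, known)
        ranks = res.rows["rank"]
        counts = res.rows["dominance_count"]
        expected = min_tie_ranks(counts)
        assert (ranks == expected).all()
        assert ranks.min() == 1 and (counts < len(res.rows)).all()

    def test_known_factors_always_selected(self, rng):
        ids = [f"g{i}" for i in range(50)]
        e = pd.Series(rng.normal(size=50), index=ids)
        m = pd.Series(rng.normal(size=50), index=ids)
        res = run_screen(
            e, m, TFCatalog(frozenset(ids)),
            KnownFactorSet("s", "t", frozenset(ids[:4])),
        )
        assert res.rows.loc[res.rows["known"], "selected"].all()

    def test_recovered_at_top_counts_min_tie_ranks(self):
        ranks = pd.Series({"a": 1, "b": 1, "c": 3, "d": 4})
        assert recovered_at_top(ranks, ["a", "b"], 0.5) == 1.0
        assert recovered_at_top(ranks, ["d"], 0.5) == 0.0
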