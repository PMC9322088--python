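"""Enrichment oracles: hypergeometric enumeration, running-sum ES, permutation."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from lipomir import enrich
from lipomir.containers import ExpressionMatrix


def enumeration_hypergeom(overlap, universe, pathway_size, targets) -> Fraction:
    """Exhaustive oracle: exact P(X >= overlap) over all target-set draws."""
    genes = range(universe)
    pathway = set(range(pathway_size))
    hits = 0
    total = 0
    for draw in itertools.combinations(genes, targets):
        total += 1
        hits += len(pathway & set(draw)) >= overlap
    return Fraction(hits, total)


class TestPathwayTargeting:
    def test_example_enumeration(self):
        # universe 10, pathway 4, miRNA targets 5, overlap 3 -> 66/252
        oracle = enumeration_hypergeom(3, 10, 4, 5)
        assert oracle == Fraction(66, 252)
        assert enrich.hypergeometric_p(3, 10, 4, 5) == pytest.approx(float(oracle), abs=1e-12)

    def test_matches_enumeration_for_small_universes(self, rng):
        for _ in range(15):
            universe = int(rng.integers(5, 13))
            pathway = int(rng.integers(1, universe + 1))
            targets = int(rng.integers(1, universe + 1))
            overlap = int(rng.integers(0, min(pathway, targets) + 1))
            oracle = float(enumeration_hypergeom(overlap, universe, pathway, targets))
            got = enrich.hypergeometric_p(overlap, universe, pathway, targets)
            assert got == pytest.approx(oracle, abs=1e-10)

    def test_zero_overlap_gives_p_one_weight_zero(self):
        tm = {"mir-1": {"g1", "g2"}, "mir-2": {"g3", "g4"}}
        pw = {"p1": {"g3", "g4"}}
        prof = enrich.pathway_targeting(tm, pw, ["mir-1", "mir-2"])
        assert prof.pvalues.loc["p1", "mir-1"] == 1.0
        assert prof.weights.loc["p1", "mir-1"] == 0.0
        assert not prof.hits.loc["p1", "mir-1"]

    def test_pathway_equal_to_universe_gives_p_one(self):
        tm = {"mir-1": {"g1", "g2"}, "mir-2": {"g2", "g3"}}
        universe = {"g1", "g2", "g3"}
        prof = enrich.pathway_targeting(tm, {"all": universe}, ["mir-1", "mir-2"])
        assert (prof.pvalues.loc["all"] == 1.0).all()


class TestFilterPathways:
    @staticmethod
    def profile_with(counts, fracs):
        idx = pd.Index([f"p{i}" for i in range(len(counts))], name="pathway")
        dummy = pd.DataFrame(0.0, index=idx, columns=["mir-1"])
        return enrich.TargetingProfile(
            weights=dummy,
            hits=dummy.astype(bool),
            pvalues=dummy + 1.0,
            summary=pd.DataFrame({"n_targeting": counts, "measured_fraction": fracs}, index=idx),
            universe_size=100,
        )

    def test_lower_boundary(self):
        prof = self.profile_with([9, 10], [1.0, 1.0])
        assert list(enrich.filter_pathways(prof).summary.index) == ["p1"]

    def test_upper_boundary(self):
        prof = self.profile_with([200, 201], [1.0, 1.0])
        assert list(enrich.filter_pathways(prof).summary.index) == ["p0"]

    def test_measured_fraction_boundary(self):
        prof = self.profile_with([10, 10, 10], [0.4, 0.5, 1.0])
        assert list(enrich.filter_pathways(prof).summary.index) == ["p1", "p2"]


def ranked_series(values, ids=None):
    ids = ids or [f"mir-{i}" for i in range(len(values))]
    s = pd.Series(values, index=ids)
    return s.loc[sorted(s.index, key=lambda m: (-s[m], m))]


class TestComputeEs:
    def test_single_hit_ranked_first(self):
        ranked = ranked_series([3.0, 2.0, 1.0, 0.5, 0.2, -0.1, -0.5, -1, -2, -3])
        w = pd.Series(1.0, index=ranked.index)
        es, leading = enrich.compute_es(ranked, {ranked.index[0]}, w)
        assert es == pytest.approx(1.0)
        assert leading == [ranked.index[0]]

    def test_all_hits_give_one(self):
        ranked = ranked_series([2.0, 1.0, -1.0])
        w = pd.Series(1.0, index=ranked.index)
        es, _ = enrich.compute_es(ranked, set(ranked.index), w)
        assert es == pytest.approx(1.0)

    def test_zero_weights_give_zero_es(self):
        ranked = ranked_series([0.0, 0.0, 0.0])
        w = pd.Series(1.0, index=ranked.index)
        es, leading = enrich.compute_es(ranked, {ranked.index[1]}, w)
        assert es == 0.0 and leading == []

    def test_empty_hit_set_rejected(self):
        ranked = ranked_series([1.0, -1.0])
        with pytest.raises(ValueError, match="empty hit set"):
            enrich.compute_es(ranked, set(), pd.Series(1.0, index=ranked.index))

    @staticmethod
    def oracle_es(ranked, hit_set, weights):
        """Naive running-sum re-implementation."""
        ids = list(ranked.index)
        n = len(ids)
        hits = [m in hit_set for m in ids]
        w = [abs(ranked[m]) * weights.get(m, 0.0) if h else 0.0 for m, h in zip(ids, hits)]
        total = sum(w)
        if total == 0:
            return 0.0, []
        n_miss = n - sum(hits)
        running = 0.0
        path = []
        for h, wi in zip(hits, w):
            running += wi / total if h else -1.0 / n_miss
            path.append(running)
        i_pos = max(range(n), key=lambda i: (path[i], -i))
        i_neg = min(range(n), key=lambda i: (path[i], i))
        if path[i_pos] >= -path[i_neg]:  # ties resolve to the positive side
            best, best_i = path[i_pos], i_pos
        else:
            best, best_i = path[i_neg], i_neg
        if best >= 0:
            leading = [m for i, m in enumerate(ids) if hits[i] and i <= best_i]
        else:
            leading = [m for i, m in enumerate(ids) if hits[i] and i > best_i]
        return best, leading

    def test_stated_small_instance_vs_oracle(self):
        ranked = ranked_series([2.0, 1.5, 0.7, -0.3, -1.1], ids=list("abcde"))
        hit_set = {ranked.index[1], ranked.index[3]}
        w = pd.Series([0.2, 1.3, 0.4, 2.0, 0.6], index=ranked.index)
        es, leading = enrich.compute_es(ranked, hit_set, w)
        es_o, leading_o = self.oracle_es(ranked, hit_set, w)
        assert es == pytest.approx(es_o, abs=1e-12)
        assert leading == leading_o

    def test_random_instances_vs_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 12))
            vals = rng.normal(size=n)
            ranked = ranked_series(vals, ids=[f"m{i:02d}" for i in range(n)])
            n_hits = int(rng.integers(1, n + 1))
            hit_set = set(rng.choice(ranked.index, size=n_hits, replace=False))
            w = pd.Series(rng.uniform(0, 2, size=n), index=ranked.index)
            es, leading = enrich.compute_es(ranked, hit_set, w)
            es_o, leading_o = self.oracle_es(ranked, hit_set, w)
            if abs(abs(es) - abs(es_o)) < 1e-12 and abs(es - es_o) > 1e-12:
                # positive and negative extrema tie to rounding; either side
                # is a valid extremum, magnitude must still agree
                continue
            assert es == pytest.approx(es_o, abs=1e-12)
            assert leading == leading_o


def small_expression(rng, n_per_class=3, n_mirnas=8):
    ids = [f"mir-{i}" for i in range(n_mirnas)]
    samples = [f"s{i}" for i in range(2 * n_per_class)]
    vals = pd.DataFrame(rng.normal(size=(2 * n_per_class, n_mirnas)), index=samples, columns=ids)
    labels = pd.Series(["A"] * n_per_class + ["B"] * n_per_class, index=samples)
    expr = ExpressionMatrix(values=vals, detected=vals.notna(), labels=labels)
    return expr, labels


class TestRankMirnas:
    def test_equal_means_give_zero_weights(self):
        vals = pd.DataFrame({"m1": [1.0, 2.0, 1.0, 2.0], "m2": [3.0, 3.0, 3.0, 3.0]})
        labels = pd.Series(["A", "A", "B", "B"], index=vals.index)
        ranked = enrich.rank_mirnas(vals, labels, "B")
        assert np.allclose(ranked.to_numpy(), 0.0)

    def test_label_swap_reverses_order(self, rng):
        expr, labels = small_expression(rng)
        fwd = enrich.rank_mirnas(expr, labels, "B")
        rev = enrich.rank_mirnas(expr, labels, "A")
        assert list(fwd.index) == list(rev.index[::-1])

    def test_planted_markers_at_extremes(self, two_class_expression):
        expr, labels, truth = two_class_expression
        ranked = enrich.rank_mirnas(expr, labels, "B")
        up = [m for m in truth.marker_ids if truth.marker_directions[m] == 1]
        down = [m for m in truth.marker_ids if truth.marker_directions[m] == -1]
        assert set(ranked.index[: len(up)]) == set(up)
        assert set(ranked.index[-len(down):]) == set(down)


class TestPermutationTest:
    @staticmethod
    def profile_for(ids, hit_ids):
        idx = pd.Index(["p1"], name="pathway")
        hits = pd.DataFrame([[m in hit_ids for m in ids]], index=idx, columns=ids)
        weights = pd.DataFrame([[1.0 if m in hit_ids else 0.0 for m in ids]], index=idx, columns=ids)
        return enrich.TargetingProfile(
            weights=weights,
            hits=hits,
            pvalues=1.0 - weights,
            summary=pd.DataFrame({"n_targeting": [len(hit_ids)], "measured_fraction": [1.0]}, index=idx),
            universe_size=100,
        )

    def test_seed_determinism(self, rng):
        expr, labels = small_expression(rng, n_per_class=4)
        prof = self.profile_for(list(expr.mirnas), set(list(expr.mirnas)[:3]))
        _, p1, _ = enrich.permutation_test(expr, labels, "B", prof, n_perm=200, seed=3)
        _, p2, _ = enrich.permutation_test(expr, labels, "B", prof, n_perm=200, seed=3)
        pd.testing.assert_series_equal(p1, p2)

    def test_monte_carlo_matches_exhaustive_three_vs_three(self, rng):
        """3-vs-3 labels admit C(6,3)=20 assignments; the Monte-Carlo p must
        land within 2 MC standard deviations of the exhaustive value."""
        import itertools as it

        expr, labels = small_expression(rng, n_per_class=3, n_mirnas=10)
        ids = list(expr.mirnas)
        hit_ids = set(ids[:4])
        prof = self.profile_for(ids, hit_ids)
        obs, p_mc, _ = enrich.permutation_test(expr, labels, "B", prof, n_perm=4000, seed=9)

        X = expr.values.to_numpy()
        w = prof.weights.loc["p1"]
        exceed = 0
        combos = list(it.combinations(range(6), 3))
        for pos in combos:
            mask = np.zeros(6, dtype=bool)
            mask[list(pos)] = True
            fc = pd.Series(X[mask].mean(axis=0) - X[~mask].mean(axis=0), index=ids)
            ranked = fc.loc[sorted(fc.index, key=lambda m: (-fc[m], m))]
            es, _ = enrich.compute_es(ranked, hit_ids, w)
            exceed += abs(es) >= abs(obs["p1"])
        p_exact = exceed / len(combos)
        mc_sd = np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(p_mc["p1"] - p_exact) <= 2 * mc_sd + 1 / 4001

    def test_observed_es_matches_compute_es(self, rng):
        expr, labels = small_expression(rng, n_per_class=5, n_mirnas=12)
        ids = list(expr.mirnas)
        prof = self.profile_for(ids, set(ids[2:7]))
        obs, _, _ = enrich.permutation_test(expr, labels, "B", prof, n_perm=10, seed=0)
        ranked = enrich.rank_mirnas(expr, labels, "B")
        es, _ = enrich.compute_es(ranked, set(ids[2:7]), prof.weights.loc["p1"])
        assert obs["p1"] == pytest.approx(es, abs=1e-12)


class TestFdrCorrect:
    def test_strongest_pathway_beats_all_null(self):
        obs = pd.Series({"p1": 0.9})
        null = np.array([[0.1, 0.2, 0.3, -0.4]])
        q = enrich.fdr_correct(obs, null)
        assert q["p1"] == 0.0

    def test_identical_scores_identical_q(self):
        obs = pd.Series({"p1": 0.5, "p2": -0.5, "p3": 0.5})
        null = np.array([[0.2, 0.6], [0.1, -0.7], [0.4, 0.3]])
        q = enrich.fdr_correct(obs, null)
        assert q["p1"] == q["p2"] == q["p3"]

    def test_hand_worked_three_pathways(self):
        obs = pd.Series({"p1": 0.8, "p2": 0.5, "p3": 0.2})
        null = np.array([[0.9, 0.1], [0.4, 0.6], [0.3, 0.1]])
        q = enrich.fdr_correct(obs, null)
        # |null| pooled = {0.9, 0.1, 0.4, 0.6, 0.3, 0.1}
        # p1: null >= 0.8 -> 1/6; obs >= 0.8 -> 1/3; q = 0.5
        # p2: null >= 0.5 -> 2/6; obs >= 0.5 -> 2/3; q = 0.5
        # p3: null >= 0.2 -> 4/6; obs >= 0.2 -> 3/3; q = 2/3
        assert q["p1"] == pytest.approx(0.5)
        assert q["p2"] == pytest.approx(0.5)
        assert q["p3"] == pytest.approx(2 / 3)

    def test_monotone_in_abs_es(self, rng):
        obs = pd.Series(rng.normal(size=12), index=[f"p{i}" for i in range(12)])
        null = rng.normal(size=(12, 40))
        q = enrich.fdr_correct(obs, null)
        order = obs.abs().sort_values(ascending=False).index
        assert (q.loc[order].diff().dropna() >= -1e-12).all()


class TestSignificantPathways:
    def test_boundaries(self):
        res = pd.DataFrame(
            {"p": [0.009, 0.011, 0.010], "q": [0.049, 0.010, 0.050], "es": [0.9, 0.8, 0.7]},
            index=["keep", "fails_p", "fails_both"],
        )
        out = enrich.significant_pathways(res)
        assert list(out.index) == ["keep"]

    def test_empty_input(self):
        out = enrich.significant_pathways(pd.DataFrame(columns=["p", "q", "es"]))
        assert out.empty
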