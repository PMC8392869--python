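import numpy as np
import pandas as pd
import pytest

from polyptile import rulebase as rb
from polyptile.features import ANTECEDENT_NAMES
from polyptile.rulebase import (ExtendedMF, TriangularMF, build_histogram,
                                extend_support, fit_triangle, load_rulebase,
                                prune_narrow, save_rulebase, train_rulebase)


def make_feature_table(rng, n=120, shift=0.5):
    """Synthetic labelled table: polyp columns shifted from no_polyp."""
    labels = np.array(["polyp", "no_polyp"])[rng.integers(0, 2, size=n)]
    data = {"label": labels}
    for k, name in enumerate(ANTECEDENT_NAMES):
        base = rng.normal(0.0, 1.0, size=n)
        base[labels == "polyp"] += shift * (1 + k % 3)
        data[name] = base
    return pd.DataFrame(data)


class TestHistogram:
    def test_degenerate_constant_sample(self):
        h = build_histogram([0.0] * 10, bins=5)
        assert h.degenerate
        assert list(h.normalized) == [1.0]

    def test_uniform_sample_has_flat_bins(self, rng):
        h = build_histogram(rng.uniform(0, 1, size=20000), bins=10)
        assert h.normalized.min() > 0.8

    def test_matches_manual_binning(self):
        values = [0.1, 0.3, 0.32, 0.5, 0.51, 0.52, 0.7, 0.72, 0.9, 1.3,
                  1.31, 1.5, 1.7, 1.71, 1.72, 1.73, 1.9, 2.0, 2.05, 2.1]
        h = build_histogram(values, bins=5)
        edges = np.linspace(0.1, 2.1, 6)
        manual = np.zeros(5, dtype=int)
        for v in values:
            idx = min(int((v - 0.1) / (2.0 / 5)), 4)
            manual[idx] += 1
        assert np.array_equal(h.counts, manual)
        assert h.normalized.max() == 1.0
        assert np.allclose(h.bin_edges, edges)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([])


class TestFitTriangle:
    def test_histogram_mode_support_rule(self):
        # bin heights normalised: [0.005, 0.2, 1.0, 0.3, 0.008]; supports
        # are the centres of the first bins above 0.01 from each side
        values = ([0.1] * 1 + [0.3] * 40 + [0.5] * 200 + [0.7] * 60
                  + [0.9] * 2)
        tri = fit_triangle(values, mode="histogram", bins=5)
        centers = np.linspace(0.1, 0.9, 5)  # bin width 0.16, centres
        edges = np.linspace(0.1, 0.9, 6)
        centers = 0.5 * (edges[:-1] + edges[1:])
        assert tri.left == pytest.approx(centers[1])
        assert tri.core == pytest.approx(centers[2])
        assert tri.right == pytest.approx(centers[3])

    def test_mean_mode_symmetric_data(self):
        vals = [0.0, 0.25, 0.5, 0.75, 1.0]
        tri = fit_triangle(vals, mode="mean")
        assert (tri.left, tri.core, tri.right) == (0.0, 0.5, 1.0)
        assert tri.core == pytest.approx((tri.left + tri.right) / 2)

    def test_median_mode(self):
        tri = fit_triangle([0, 1, 1, 1, 10], mode="median")
        assert (tri.left, tri.core, tri.right) == (0.0, 1.0, 10.0)

    def test_degenerate_sample(self):
        tri = fit_triangle([0.4] * 7, mode="histogram")
        assert tri.degenerate and tri.left == tri.core == tri.right == 0.4

    def test_ordering_always_holds(self, rng):
        for _ in range(50):
            vals = rng.normal(size=rng.integers(5, 200)) ** 3
            for mode in ("mean", "median", "histogram"):
                tri = fit_triangle(vals, mode=mode, bins=20)
                assert tri.left <= tri.core <= tri.right

    def test_crossing_rule_brute_force(self, rng):
        vals = rng.lognormal(size=500)
        tri = fit_triangle(vals, mode="histogram", bins=40)
        h = build_histogram(vals, bins=40)
        above = [i for i, v in enumerate(h.normalized) if v > 0.01]
        assert tri.left == pytest.approx(h.centers[above[0]])
        assert tri.right == pytest.approx(h.centers[above[-1]])


class TestExtendSupport:
    def test_symmetric_triangle_half_gaussian_width(self):
        ext = extend_support(TriangularMF(0, 1, 2), "half_gaussian")
        sigma = 1 / np.sqrt(2 * np.log(100))
        assert ext.sigma_left == pytest.approx(sigma, abs=1e-12)
        assert ext.sigma_right == pytest.approx(sigma, abs=1e-12)
        assert ext(0) == pytest.approx(0.01, abs=1e-12)
        assert ext(2) == pytest.approx(0.01, abs=1e-12)
        assert ext(1) == 1.0

    def test_triangle_kind_is_identity(self, rng):
        tri = TriangularMF(0.2, 0.5, 0.9)
        ext = extend_support(tri, "triangle")
        for x in rng.uniform(-0.5, 1.5, size=20):
            assert ext(x) == tri(x)

    def test_asymmetric_boundary_conditions(self):
        ext = extend_support(TriangularMF(0, 1, 4), "half_gaussian")
        assert ext.sigma_right == pytest.approx(3 * ext.sigma_left)
        assert ext(0) == pytest.approx(0.01, abs=1e-9)
        assert ext(4) == pytest.approx(0.01, abs=1e-9)
        gauss = extend_support(TriangularMF(0, 1, 4), "gaussian")
        assert gauss.sigma_left == gauss.sigma_right
        # least-squares compromise: boundary memberships bracket 0.01
        assert gauss(0) < 0.5 and gauss(4) < 0.5

    def test_strictly_positive_everywhere(self):
        ext = extend_support(TriangularMF(0, 1, 2), "half_gaussian")
        assert ext(-10) > 0 and ext(10) > 0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            extend_support(TriangularMF(1, 1, 1, degenerate=True),
                           "gaussian")


class TestTrainRulebase:
    def test_rule_count_and_structure(self, rng):
        table = make_feature_table(rng)
        base = train_rulebase(table)
        assert len(base.rules) == 198
        assert len(base.active_antecedents) == 99
        for i in base.active_antecedents:
            assert base.rule(i, "polyp").consequent == "polyp"
            assert base.rule(i, "no_polyp").consequent == "no_polyp"

    def test_separated_classes_give_disjoint_supports(self, rng):
        table = make_feature_table(rng, shift=0.0)
        name = ANTECEDENT_NAMES[0]
        polyp = table["label"] == "polyp"
        table.loc[polyp, name] = rng.uniform(0.0, 0.4, polyp.sum())
        table.loc[~polyp, name] = rng.uniform(0.6, 1.0, (~polyp).sum())
        base = train_rulebase(table, mode="histogram", bins=20)
        tp = base.rule(1, "polyp").mf.base
        tn = base.rule(1, "no_polyp").mf.base
        assert tp.right < tn.left

    def test_identical_distributions_give_coincident_triangles(self, rng):
        table = make_feature_table(rng, shift=0.0, n=4000)
        base = train_rulebase(table, bins=10)
        tp = base.rule(5, "polyp").mf.base
        tn = base.rule(5, "no_polyp").mf.base
        lo, hi = base.normalization[5]
        span = hi - lo
        assert abs(tp.core - tn.core) / span < 0.25
        assert abs(tp.left - tn.left) / span < 0.25

    def test_missing_class_rejected(self, rng):
        table = make_feature_table(rng)
        table["label"] = "polyp"
        with pytest.raises(ValueError, match="no_polyp"):
            train_rulebase(table)

    def test_deterministic(self, rng):
        table = make_feature_table(rng)
        a = train_rulebase(table)
        b = train_rulebase(table.copy())
        for key in a.rules:
            assert a.rules[key].mf.base == b.rules[key].mf.base
        assert a.normalization == b.normalization


class TestDistancesAndPruning:
    def _toy_rulebase(self, tri_p, tri_n, norm=(0.0, 1.0)):
        base = rb.Rulebase()
        base.normalization[1] = norm
        base.rules[(1, "polyp")] = rb.Rule(1, "polyp",
                                           ExtendedMF(base=tri_p))
        base.rules[(1, "no_polyp")] = rb.Rule(1, "no_polyp",
                                              ExtendedMF(base=tri_n))
        base.active_antecedents = (1,)
        return base

    def test_identical_triangles_zero_distance(self):
        tri = TriangularMF(0.1, 0.4, 0.8)
        base = self._toy_rulebase(tri, tri)
        assert rb.antecedent_total_distance(base, 1) == 0.0
        assert rb.antecedent_center_distance(base, 1) == 0.0

    def test_hand_computed_distances(self):
        base = self._toy_rulebase(TriangularMF(0.0, 0.1, 0.2),
                                  TriangularMF(0.3, 0.5, 0.7))
        assert rb.antecedent_total_distance(base, 1) == pytest.approx(1.2)
        assert rb.antecedent_center_distance(base, 1) == pytest.approx(0.4)

    def test_center_distance_simple(self):
        base = self._toy_rulebase(TriangularMF(0.1, 0.2, 0.3),
                                  TriangularMF(0.6, 0.7, 0.8))
        assert rb.antecedent_center_distance(base, 1) == pytest.approx(0.5)

    def test_distance_invariant_under_affine_rescaling(self, rng):
        tri_p = TriangularMF(1.0, 4.0, 8.0)
        tri_n = TriangularMF(3.0, 5.0, 9.0)
        base = self._toy_rulebase(tri_p, tri_n, norm=(1.0, 9.0))
        d0 = rb.antecedent_total_distance(base, 1)
        # same shapes shifted/scaled by x -> 10x + 3
        f = lambda x: 10 * x + 3
        base2 = self._toy_rulebase(
            TriangularMF(f(1.0), f(4.0), f(8.0)),
            TriangularMF(f(3.0), f(5.0), f(9.0)), norm=(f(1.0), f(9.0)))
        assert rb.antecedent_total_distance(base2, 1) == pytest.approx(
            d0, abs=1e-12)

    def test_threshold_sweep_matches_brute_force(self, rng):
        table = make_feature_table(rng)
        base = train_rulebase(table)
        for threshold in (0.2, 0.35):
            kept = rb.select_by_distance(base, threshold).active_antecedents
            expected = [i for i in range(1, 100)
                        if rb.antecedent_total_distance(base, i) > threshold]
            assert sorted(kept) == sorted(expected)
        ranking = sorted(range(1, 100),
                         key=lambda i: -rb.antecedent_center_distance(base, i))
        kept = rb.select_by_distance(base, 0.0, metric="center")
        assert list(kept.active_antecedents) == [
            i for i in ranking
            if rb.antecedent_center_distance(base, i) > 0.0]

    def test_prune_narrow_by_width(self):
        base = rb.Rulebase()
        widths = {1: 0.01, 2: 0.10, 3: 0.50}
        for i, w in widths.items():
            base.normalization[i] = (0.0, 1.0)
            tri = TriangularMF(0.2, 0.2 + w / 2, 0.2 + w)
            for c in ("polyp", "no_polyp"):
                base.rules[(i, c)] = rb.Rule(i, c, ExtendedMF(base=tri))
        base.active_antecedents = (1, 2, 3)
        pruned = prune_narrow(base, 0.05)
        assert pruned.active_antecedents == (2, 3)
        assert base.active_antecedents == (1, 2, 3)  # original untouched
        nearly_all = prune_narrow(base, 0.0001)
        assert nearly_all.active_antecedents == (1, 2, 3)

    def test_degenerate_triangle_always_pruned(self, rng):
        table = make_feature_table(rng)
        name = ANTECEDENT_NAMES[7 - 1]
        table[name] = np.where(table["label"] == "polyp", 0.0,
                               table[name])
        base = train_rulebase(table)
        pruned = prune_narrow(base, 0.05)
        assert 7 not in pruned.active_antecedents


class TestSerialization:
    def test_round_trip_lossless(self, rng, tmp_path):
        table = make_feature_table(rng)
        base = train_rulebase(table, mode="histogram",
                              extension_kind="half_gaussian")
        path = tmp_path / "rulebase.json"
        save_rulebase(base, path)
        back = load_rulebase(path)
        assert back.active_antecedents == base.active_antecedents
        assert back.normalization == base.normalization
        assert back.fit_mode == base.fit_mode
        for key, rule in base.rules.items():
            other = back.rules[key]
            assert other.mf.base == rule.mf.base
            assert other.mf.kind == rule.mf.kind
            assert other.mf.sigma_left == rule.mf.sigma_left

    def test_unknown_schema_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"schema_version": 999}')
        with pytest.raises(ValueError, match="schema"):
            load_rulebase(path)
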