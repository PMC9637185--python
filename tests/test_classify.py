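"""Cutoff computation and the three classification rules."""

import numpy as np
import pytest
from scipy.stats import norm

from g3mix import Component, MixtureModel
from g3mix.classify import (
    build_cutoffs,
    classify_cutoff,
    classify_proba,
    classify_scutoff,
    cutoff_interval,
    pairwise_cutoff,
    summarize,
    heatmap_matrix,
)
from g3mix.synth import SyntheticSpec, generate


def comp(mean, sd, weight=0.5, label=1, frozen=False):
    return Component(label=label, mean=mean, sd=sd, weight=weight, frozen=frozen)


def grid_crossing(left, right, n=2_000_001):
    """Dense-grid oracle: density-equality point between the means."""
    x = np.linspace(left.mean, right.mean, n)
    diff = norm.pdf(x, left.mean, left.sd) - norm.pdf(x, right.mean, right.sd)
    sign = np.sign(diff)
    idx = np.flatnonzero(np.diff(sign) != 0)
    assert idx.size >= 1
    return 0.5 * (x[idx[0]] + x[idx[0] + 1])


class TestPairwiseCutoff:
    def test_equal_sigma_midpoint(self):
        assert pairwise_cutoff(comp(0, 1), comp(4, 1)) == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "left, right, published",
        [
            ((88.7, 48.9), (403.0, 189.0), 186.6),  # 4-class model, classes 1|2
            ((74.8, 37.9), (287.0, 155.0), 147.0),  # 5-class model, classes 1|2
            ((77.2, 21.8), (168.0, 57.6), 113.9),   # 8-class model, classes 1|2
        ],
    )
    def test_published_diagnostic_cutoffs(self, left, right, published):
        c = pairwise_cutoff(comp(*left), comp(*right))
        assert c == pytest.approx(published, abs=0.5)

    @pytest.mark.parametrize(
        "left, right",
        [((0, 1), (6, 2)), ((88.7, 48.9), (403, 189)), ((-3, 0.5), (0, 4)), ((0, 2), (1.2, 1.9))],
    )
    def test_matches_dense_grid_oracle(self, left, right):
        l, r = comp(*left), comp(*right)
        grid = grid_crossing(l, r)
        step = (r.mean - l.mean) / 2_000_000
        assert pairwise_cutoff(l, r) == pytest.approx(grid, abs=step + 1e-6)

    def test_wrong_order_rejected(self):
        with pytest.raises(ValueError):
            pairwise_cutoff(comp(4, 1), comp(0, 1))

    def test_fallback_weighted_midpoint_when_no_root_between_means(self, caplog):
        # tiny-sd component engulfed by a wide one can push both quadratic
        # roots outside (mu_L, mu_R); the SD-weighted midpoint is returned
        l, r = comp(0.0, 10.0), comp(0.5, 0.01)
        c = pairwise_cutoff(l, r)
        assert 0.0 < c < 0.5


class TestCutoffInterval:
    def test_rtol_zero_collapses(self):
        l, r = comp(0, 1), comp(4, 1)
        assert cutoff_interval(l, r, 0.0) == (2.0, 2.0)

    def test_symmetric_pair_symmetric_interval(self):
        lo, hi = cutoff_interval(comp(0, 1), comp(4, 1), 0.1)
        assert hi - 2.0 == pytest.approx(2.0 - lo, abs=1e-9)

    def test_endpoints_hit_inflated_error_exactly(self):
        l, r = comp(0, 1), comp(6, 2)
        cstar = pairwise_cutoff(l, r)
        err = lambda c: norm.sf(c, l.mean, l.sd) + norm.cdf(c, r.mean, r.sd)
        target = 1.1 * err(cstar)
        lo, hi = cutoff_interval(l, r, 0.1)
        assert err(lo) == pytest.approx(target, abs=1e-9)
        assert err(hi) == pytest.approx(target, abs=1e-9)
        assert lo <= cstar <= hi

    def test_heavy_overlap_clamped_at_means(self):
        l, r = comp(0, 1), comp(0.2, 1.0001)
        lo, hi = cutoff_interval(l, r, 5.0)
        assert lo >= l.mean and hi <= r.mean


class TestBuildCutoffs:
    def test_four_class_boundary_names(self, erbb2_4class):
        cs = build_cutoffs(erbb2_4class)
        assert [b.name for b in cs.boundaries] == ["up-1", "up-2", "up-3"]

    def test_five_class_with_negative_class_names(self, esr1_5class):
        cs = build_cutoffs(esr1_5class)
        assert [b.name for b in cs.boundaries] == ["down-1", "up-1", "up-2", "up-3"]

    def test_two_component_single_boundary(self):
        m = MixtureModel([comp(0, 1, 0.5, 0, frozen=True), comp(6, 1, 0.5, 1)])
        assert len(build_cutoffs(m).boundaries) == 1

    def test_single_class_empty_set(self):
        m = MixtureModel([comp(0, 1, 1.0, 0, frozen=True)])
        assert build_cutoffs(m).boundaries == ()

    def test_up2_matches_published_value(self, erbb2_4class):
        cs = build_cutoffs(erbb2_4class)
        assert cs.by_name("up-2").cstar == pytest.approx(186.6, abs=0.5)


class TestClassifyProba:
    def test_reference_mean_goes_to_class0(self, erbb2_4class):
        assert classify_proba([40.4], erbb2_4class)[0] == 0

    def test_high_value_goes_to_class2_not_3(self, erbb2_4class):
        # at 500 the wide class 2 still dominates the narrow class 3
        assert classify_proba([500.0], erbb2_4class)[0] == 2

    def test_posterior_tie_resolves_toward_class0(self):
        m = MixtureModel([comp(0, 1, 0.5, 0, frozen=True), comp(4, 1, 0.5, 1)])
        assert classify_proba([2.0], m)[0] == 0  # exact 0.5/0.5 tie

    def test_labels_come_from_model_label_set(self, erbb2_8class, rng):
        x = rng.uniform(0, 1000, 200)
        assert set(classify_proba(x, erbb2_8class)) <= set(erbb2_8class.labels)


class TestClassifyCutoff:
    def test_epsilon_around_published_cutoff(self, erbb2_4class):
        cs = build_cutoffs(erbb2_4class)
        up2 = cs.by_name("up-2").cstar
        lab = classify_cutoff([up2 - 1e-6, up2 + 1e-6], cs)
        assert lab.tolist() == [1, 2]

    def test_all_below_first_cutoff(self, erbb2_4class):
        cs = build_cutoffs(erbb2_4class)
        lab = classify_cutoff([0.0, 1.0, 10.0], cs)
        assert set(lab) == {0}

    def test_boundary_value_goes_to_side_nearer_class0(self, esr1_5class):
        cs = build_cutoffs(esr1_5class)
        down1 = cs.by_name("down-1").cstar
        up1 = cs.by_name("up-1").cstar
        lab = classify_cutoff([down1, up1], cs)
        assert lab.tolist() == [0, 0]

    def test_grid_agrees_with_interval_lookup(self, erbb2_8class):
        cs = build_cutoffs(erbb2_8class)
        x = np.linspace(-50, 1000, 10_000)
        lab = classify_cutoff(x, cs)
        # brute-force oracle: count boundaries strictly below x
        cuts = [b.cstar for b in cs.boundaries]
        labels = np.asarray(erbb2_8class.labels)
        oracle = labels[np.sum(np.asarray(cuts)[None, :] < x[:, None], axis=1)]
        mismatch = lab != oracle
        # only exact boundary hits may differ (tie rule); none on this grid
        assert not mismatch.any()

    def test_monotone_in_x(self, erbb2_5class, rng):
        cs = build_cutoffs(erbb2_5class)
        x = np.sort(rng.uniform(-100, 1200, 500))
        lab = classify_cutoff(x, cs)
        assert (np.diff(lab) >= 0).all()


class TestClassifyScutoff:
    def test_rtol_zero_equals_cutoff(self, erbb2_4class, rng):
        cs = build_cutoffs(erbb2_4class, r_tol=0.0)
        x = rng.uniform(0, 1000, 300)
        np.testing.assert_array_equal(classify_scutoff(x, cs), classify_cutoff(x, cs))

    def test_class0_count_never_shrinks(self, esr1_5class, rng):
        cs = build_cutoffs(esr1_5class, r_tol=0.1)
        x = rng.uniform(-1, 150, 500)
        c = classify_cutoff(x, cs)
        s = classify_scutoff(x, cs)
        assert np.sum(s == 0) >= np.sum(c == 0)

    def test_only_class0_adjacent_boundaries_move(self, esr1_5class, rng):
        cs = build_cutoffs(esr1_5class, r_tol=0.1)
        x = rng.uniform(-1, 400, 2000)
        c = classify_cutoff(x, cs)
        s = classify_scutoff(x, cs)
        for lab in (-1, 2, 3):
            if abs(lab) >= 2:
                assert np.sum(s == lab) == np.sum(c == lab)
        # class -1 may only lose values to class 0
        assert np.sum(s == -1) <= np.sum(c == -1)

    def test_requires_class0(self):
        m = MixtureModel([comp(0, 1, 0.5, 1), comp(6, 1, 0.5, 2)])
        cs = build_cutoffs(m)
        with pytest.raises(ValueError):
            classify_scutoff([1.0], cs)


class TestProbaCutoffAgreement:
    def test_well_separated_components_agree(self):
        # all adjacent pairs >= 6 pooled SDs apart, comparable weights
        spec = SyntheticSpec(
            components=((0.0, 1.0, 0.35), (10.0, 1.0, 0.35), (20.0, 1.0, 0.30)),
            n_test=3000, n_ref=100, n_query=10, seed=17,
        )
        d, _ = generate(spec)
        m = MixtureModel(
            [comp(0, 1, 0.35, 0, frozen=True), comp(10, 1, 0.35, 1), comp(20, 1, 0.30, 2)]
        )
        cs = build_cutoffs(m)
        p = classify_proba(d.test, m)
        c = classify_cutoff(d.test, cs)
        assert np.mean(p == c) >= 0.99


class TestSummaries:
    def test_fractions_sum_to_100_per_cohort_rule(self, erbb2_4class, rng):
        x = rng.uniform(0, 1000, 144)
        cs = build_cutoffs(erbb2_4class)
        labeled = {"test": {"cutoff": classify_cutoff(x, cs), "proba": classify_proba(x, erbb2_4class)}}
        df = summarize(labeled, {"test": x})
        for (_, _), grp in df.groupby(["cohort", "rule"]):
            assert grp["fraction_pct"].sum() == pytest.approx(100.0)

    def test_single_cohort_single_class(self):
        x = np.array([1.0, 2.0, 3.0])
        labeled = {"ref": {"cutoff": np.zeros(3, dtype=int)}}
        df = summarize(labeled, {"ref": x})
        row = df.iloc[0]
        assert row["fraction_pct"] == pytest.approx(100.0)
        assert (row["n"], row["mean"], row["median"], row["sd"]) == (3, 2.0, 2.0, 1.0)

    def test_singleton_class_blank_sd(self):
        labeled = {"t": {"cutoff": np.array([0, 1])}}
        df = summarize(labeled, {"t": np.array([5.0, 9.0])})
        single = df[df["class"] == 1].iloc[0]
        assert single["mean"] == single["median"] == 9.0
        assert np.isnan(single["sd"])


class TestHeatmapMatrix:
    def test_shape_and_label_membership(self, rng):
        labs = {g: rng.integers(-1, 4, size=5) for g in ("ESR1", "PGR", "ERBB2")}
        mat, scale = heatmap_matrix(labs)
        assert mat.shape == (5, 3)
        assert scale >= np.abs(mat.to_numpy()).max()

    def test_missing_analyte_column_is_nan(self):
        mat, _ = heatmap_matrix({"A": np.array([0, 1, 2]), "B": None})
        assert mat["B"].isna().all()

    def test_annotation_row_prepended(self):
        mat, _ = heatmap_matrix({"A": np.array([0, 1])}, annotation=np.array([1, 0]))
        assert list(mat.columns)[0] == "annotation"
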