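"""Discriminability index and split-half population correlation."""

import numpy as np
import pytest

from popcongruence import popmetrics, synth
from popcongruence.data_model import (
    ConditionLabel,
    SpikeCountTensor,
    condition_labels,
    make_bin_edges,
)


def di_oracle(a, b):
    """Independent re-implementation of the standardized difference."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    sa = np.sqrt(((a - a.mean()) ** 2).mean())
    sb = np.sqrt(((b - b.mean()) ** 2).mean())
    return (a.mean() - b.mean()) / np.sqrt((sa ** 2 + sb ** 2) / 2.0)


class TestDiFormula:
    def test_closed_form_value(self):
        # means 10 and 6, both SD 2 -> DI = 2
        a = np.array([8.0, 12.0, 8.0, 12.0])
        b = np.array([4.0, 8.0, 4.0, 8.0])
        assert popmetrics.di_formula(a, b) == pytest.approx(2.0)

    def test_identical_vectors_give_zero(self):
        a = np.array([3.0, 5.0, 7.0])
        assert popmetrics.di_formula(a, a.copy()) == 0.0

    def test_constant_equal_vectors_zero_but_unequal_raise(self):
        assert popmetrics.di_formula(np.ones(4), np.ones(4)) == 0.0
        with pytest.raises(ValueError, match="undefined"):
            popmetrics.di_formula(np.ones(4), np.zeros(4))

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(10, 3, 50)
            b = rng.normal(6, 2, 50)
            assert popmetrics.di_formula(a, b) == pytest.approx(
                di_oracle(a, b), abs=1e-12)

    def test_invariant_to_unit_reordering(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(5, 1, 30), rng.normal(3, 1, 30)
        perm = rng.permutation(30)
        assert popmetrics.di_formula(a[perm], b[perm]) == pytest.approx(
            popmetrics.di_formula(a, b), abs=1e-12)


def test_di_positive_for_driven_population(msmt_small):
    t = msmt_small.sessions[0]
    cond = condition_labels("MSMT")[0]
    di = popmetrics.discriminability_index(t, cond)
    assert np.isfinite(di) and di > 0


def test_crossval_mahalanobis_positive_for_driven(msmt_small):
    t = msmt_small.sessions[0]
    cond = condition_labels("MSMT")[0]
    assert popmetrics.crossval_mahalanobis_di(t, cond) > 0


def _pattern_tensor(patterns, n_trials=6, noise=0.0, seed=0):
    """Tensor whose condition-mean rates follow given unit x condition patterns."""
    rng = np.random.default_rng(seed)
    conds = condition_labels("BSMT")
    n_units = patterns.shape[0]
    edges = make_bin_edges((-1.5, 4.0))
    labels, cols = [], []
    for j, c in enumerate(conds):
        for _ in range(n_trials):
            labels.append(c)
            cols.append(j)
    n_bins = len(edges) - 1
    lam = np.maximum(patterns[:, cols, None] +
                     rng.normal(0, noise, (n_units, len(labels), 1)), 0) * 0.01
    counts = rng.poisson(lam * np.ones(n_bins)) if noise >= 0 else None
    return SpikeCountTensor(counts, edges, labels)


class TestSplithalfCorrelation:
    def test_noiseless_within_condition_r_is_one(self):
        conds = condition_labels("BSMT")
        edges = make_bin_edges((-1.5, 4.0))
        rng = np.random.default_rng(3)
        pattern = rng.uniform(1, 20, size=(8, 4))
        labels = [c for c in conds for _ in range(6)]
        cols = [conds.index(l) for l in labels]
        # identical trials within condition: deterministic counts per bin
        per_bin = np.round(pattern[:, cols] * 0.01 * 100) / 100
        counts = np.tile(np.round(pattern[:, cols])[:, :, None] // 10,
                         (1, 1, len(edges) - 1)).astype(int)
        t = SpikeCountTensor(counts, edges, labels)
        cm = popmetrics.splithalf_correlation(t, n_resamples=5, seed=0)
        assert np.allclose(np.diag(cm.r), 1.0)

    def test_same_mean_pattern_between_equals_within(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(5, 30, size=12)
        patterns = np.tile(base[:, None], (1, 4))  # all conditions identical
        t = _pattern_tensor(patterns, n_trials=10, seed=5)
        cm = popmetrics.splithalf_correlation(t, n_resamples=100, seed=1)
        within = np.diag(cm.r).mean()
        between = cm.r[~np.eye(4, dtype=bool)].mean()
        assert abs(within - between) < 0.1

    def test_orthogonal_patterns_between_near_zero(self):
        rng = np.random.default_rng(6)
        n_units = 40
        # independent condition patterns -> expected between-correlation 0
        patterns = 15.0 + rng.normal(0, 5, size=(n_units, 4))
        patterns = np.clip(patterns, 0.5, None)
        t = _pattern_tensor(patterns, n_trials=10, seed=7)
        cm = popmetrics.splithalf_correlation(t, n_resamples=100, seed=2)
        assert np.diag(cm.r).mean() > 0.5
        assert np.abs(cm.r[~np.eye(4, dtype=bool)]).mean() < 0.25

    def test_symmetric_and_reproducible(self, msmt_small):
        t = msmt_small.sessions[0]
        a = popmetrics.splithalf_correlation(t, n_resamples=20, seed=9)
        b = popmetrics.splithalf_correlation(t, n_resamples=20, seed=9)
        np.testing.assert_array_equal(a.r, b.r)
        np.testing.assert_allclose(a.r, a.r.T, atol=1e-12)

    def test_condition_with_single_trial_raises(self):
        conds = condition_labels("BSMT")
        edges = make_bin_edges((-1.5, 4.0))
        labels = list(conds)  # one trial each
        counts = np.zeros((3, 4, len(edges) - 1), dtype=int)
        t = SpikeCountTensor(counts, edges, labels)
        with pytest.raises(ValueError, match="fewer than 2"):
            popmetrics.splithalf_correlation(t)


class TestWithinBetween:
    def test_identical_sets_not_significant(self):
        vals = np.array([0.5, 0.52, 0.48, 0.51])
        t, p = popmetrics.within_between_test(vals, vals.copy())
        assert t == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_matched_pairs_layout(self):
        conds = condition_labels("BSMT")
        matched, mismatched = popmetrics.matched_mismatched_pairs(conds)
        assert len(matched) == 2 and len(mismatched) == 2
        for i, j in matched:
            assert conds[i].body_part == conds[j].body_part
            assert {conds[i].person, conds[j].person} == {"actual", "observed"}

    def test_congruent_population_matched_exceeds_mismatched(self):
        """Body-part-congruent units: same-body-part correlations win."""
        rng = np.random.default_rng(8)
        matched_vals, mismatched_vals = [], []
        for s in range(4):
            n_units = 30
            patterns = np.full((n_units, 4), 8.0)
            cheek_units = rng.random(n_units) < 0.5
            # conditions: Ac, As, Oc, Os (canonical) -> cheek cols 0, 2
            patterns[cheek_units][:, [0, 2]] += 0
            patterns[np.ix_(cheek_units, [0, 2])] += 20
            patterns[np.ix_(~cheek_units, [1, 3])] += 20
            t = _pattern_tensor(patterns, n_trials=10, seed=100 + s)
            cm = popmetrics.splithalf_correlation(t, n_resamples=50, seed=s)
            conds = condition_labels("BSMT")
            m, mm = popmetrics.matched_mismatched_pairs(conds)
            matched_vals.append(np.mean([cm.r[i, j] for i, j in m]))
            mismatched_vals.append(np.mean([cm.r[i, j] for i, j in mm]))
        t_stat, p = popmetrics.within_between_test(matched_vals, mismatched_vals)
        assert t_stat > 0 and p < 0.05

    def test_degenerate_variance_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            popmetrics.within_between_test([1.0, 1.0], [0.0, 0.0])
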