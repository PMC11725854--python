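"""Congruency-model enumeration, design matrices, selection, categories."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popcongruence import synth
from popcongruence.data_model import condition_labels, window_rate
from popcongruence.models import (
    BSMT_CATEGORIES,
    CongruencyModel,
    canonicalize,
    categorize,
    design_matrix,
    enumerate_models,
    fit_and_select,
    population_model_histogram,
    select_best_population,
)


def brute_force_count(n_fields, mode):
    """Enumerate all field labelings, canonicalize, dedup."""
    max_class = 1 if mode == "binary" else n_fields
    seen = set()
    for lab in itertools.product(range(max_class + 1), repeat=n_fields):
        canon = canonicalize(lab)
        if mode == "sp_sharing" and set(canon) == {0}:
            continue
        seen.add(canon)
    return len(seen)


class TestEnumeration:
    @pytest.mark.parametrize("n,mode,expect", [
        (4, "binary", 16),       # all 0/1 weighting patterns
        (4, "sp_sharing", 51),   # all SP-sharing partitions, no all-empty
        (2, "sp_sharing", 4),
        (3, "sp_sharing", 14),
    ])
    def test_published_counts(self, n, mode, expect):
        assert len(enumerate_models(n, mode)) == expect

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=5),
           st.sampled_from(["binary", "sp_sharing"]))
    def test_matches_brute_force(self, n, mode):
        got = enumerate_models(n, mode)
        assert len(got) == brute_force_count(n, mode)
        assert len({m.assignment for m in got}) == len(got)  # duplicate-free
        assert all(canonicalize(m.assignment) == m.assignment for m in got)

    def test_binary_count_is_power_of_two(self):
        for n in range(1, 6):
            assert len(enumerate_models(n, "binary")) == 2 ** n


class TestCategorize:
    @pytest.mark.parametrize("assignment,expect", [
        ((1, 2, 1, 2), "body_part_specific"),   # {Ac,Oc} / {As,Os}: mirror-like
        ((1, 1, 1, 1), "invariant"),
        ((1, 1, 2, 2), "person_specific"),
        ((1, 0, 0, 0), "single_field"),
        ((1, 1, 1, 0), "three_field_one_class"),
        ((1, 1, 2, 0), "two_class_other"),
        ((1, 2, 3, 0), "idiosyncratic"),
        ((1, 0, 1, 0), "body_part_specific"),   # responsive cheek only
    ])
    def test_msmt_structural_rules(self, assignment, expect):
        assert categorize(CongruencyModel(assignment, "sp_sharing")) == expect

    def test_bsmt_four_way(self):
        assert categorize(CongruencyModel((1, 1, 1, 1), "binary")) == "invariant"
        assert categorize(CongruencyModel((1, 0, 1, 0), "binary")) == \
            "body_part_specific"
        assert categorize(CongruencyModel((1, 1, 0, 0), "binary")) == \
            "person_specific"
        assert categorize(CongruencyModel((1, 0, 0, 0), "binary")) == \
            "idiosyncratic"
        assert categorize(CongruencyModel((0, 0, 0, 0), "binary")) == \
            "idiosyncratic"

    def test_every_model_maps_to_one_category(self):
        for m in enumerate_models(4, "binary"):
            assert categorize(m) in BSMT_CATEGORIES
        from popcongruence.models import MSMT_CATEGORIES
        for m in enumerate_models(4, "sp_sharing"):
            assert categorize(m) in MSMT_CATEGORIES


class TestDesignMatrix:
    def test_all_fields_one_class_msmt(self):
        labels = [c for c in condition_labels("MSMT") for _ in range(2)]
        X, names = design_matrix(CongruencyModel((1, 1, 1, 1), "sp_sharing"),
                                 labels)
        assert X.shape == (32, 4)
        assert all(":" in n for n in names)
        np.testing.assert_array_equal(X.sum(axis=1), 1.0)  # every trial covered

    def test_single_field_model_rows(self):
        labels = [c for c in condition_labels("MSMT") for _ in range(1)]
        X, _ = design_matrix(CongruencyModel((1, 0, 0, 0), "sp_sharing"), labels)
        active = X.sum(axis=1) > 0
        assert all(l.sensory_field == "Ac" for l, a in zip(labels, active) if a)
        assert active.sum() == 4  # 4 Ac conditions

    def test_full_column_rank_for_all_51_models(self):
        labels = [c for c in condition_labels("MSMT") for _ in range(2)]
        for m in enumerate_models(4, "sp_sharing"):
            X, _ = design_matrix(m, labels)
            assert np.linalg.matrix_rank(X) == X.shape[1]


class TestFitAndSelect:
    def _rates_from_model(self, model, sp_per_class, baseline, labels,
                          noise=0.0, rng=None):
        spec = synth.NeuronGenSpec(baseline=baseline, model=model,
                                   sp_per_class=sp_per_class, noise="none")
        y = np.array([spec.expected_rate(l) - baseline for l in labels])
        if noise and rng is not None:
            y = y + rng.normal(0, noise, len(y))
        return y

    def test_noiseless_recovery_with_cvr2_one(self):
        labels = [c for c in condition_labels("MSMT") for _ in range(10)]
        model = CongruencyModel((1, 2, 1, 2), "sp_sharing")
        sps = {1: np.array([8.0, 2, 5, 1]), 2: np.array([1.0, 9, 3, 6])}
        y = self._rates_from_model(model, sps, 3.0, labels)
        res = fit_and_select(y, labels, enumerate_models(4, "sp_sharing"),
                             seed=0)
        assert res.best_by_bic == model.model_id
        j = [m.model_id for m in res.models].index(model.model_id)
        assert res.cvr2[j] == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_prefers_parsimony(self):
        rng = np.random.default_rng(10)
        labels = [c for c in condition_labels("MSMT") for _ in range(4)]
        catalog = enumerate_models(4, "sp_sharing")
        min_k = min(m.n_params() for m in catalog)
        wins_small, neg_cv = 0, 0
        n_reps = 100
        for _ in range(n_reps):
            y = rng.normal(0, 1.0, len(labels))
            res = fit_and_select(y, labels, catalog, seed=0)
            best = res.best_model("bic")
            wins_small += best.n_params() == min_k
            j = [m.model_id for m in res.models].index(res.best_by_cvr2)
            neg_cv += res.cvr2[j] <= 0.2
        assert wins_small / n_reps > 0.8
        # no candidate explains held-out noise well
        assert neg_cv / n_reps > 0.9

    def test_zero_variance_neuron_flagged(self):
        labels = [c for c in condition_labels("MSMT") for _ in range(2)]
        res = fit_and_select(np.zeros(len(labels)), labels,
                             enumerate_models(4, "sp_sharing"))
        assert res.zero_variance and res.best_by_bic is None

    def test_selection_invariant_to_trial_order(self):
        rng = np.random.default_rng(11)
        labels = [c for c in condition_labels("MSMT") for _ in range(3)]
        model = CongruencyModel((1, 1, 0, 0), "sp_sharing")
        y = self._rates_from_model(model, {1: np.array([9.0, 1, 4, 2])}, 2.0,
                                   labels, noise=0.5, rng=rng)
        perm = rng.permutation(len(labels))
        res1 = fit_and_select(y, labels, enumerate_models(4, "sp_sharing"),
                              seed=3)
        res2 = fit_and_select(y[perm], [labels[i] for i in perm],
                              enumerate_models(4, "sp_sharing"), seed=3)
        assert res1.best_by_bic == res2.best_by_bic

    def test_bic_prefers_nested_truth_at_large_n(self):
        """Generative model nested in larger candidates: BIC picks smaller."""
        rng = np.random.default_rng(12)
        labels = [c for c in condition_labels("MSMT") for _ in range(100 // 16 + 6)]
        truth = CongruencyModel((1, 1, 1, 1), "sp_sharing")
        catalog = enumerate_models(4, "sp_sharing")
        wins = 0
        for _ in range(30):
            y = self._rates_from_model(truth, {1: np.array([7.0, 3, 5, 1])},
                                       2.0, labels, noise=1.0, rng=rng)
            res = fit_and_select(y, labels, catalog, seed=0)
            wins += res.best_by_bic == truth.model_id
        assert wins / 30 >= 0.9


def test_recovery_from_generated_population():
    """Best-by-BIC matches the generative model for most units."""
    spec = synth.PopulationGenSpec(n_units=60, n_sessions=1, seed=20)
    exp = synth.generate_population(spec, "MSMT")
    t = exp.sessions[0]
    resp = window_rate(t, t.timeline.analysis_window)
    base = window_rate(t, t.timeline.baseline_window)
    Y = resp - base.mean(axis=1, keepdims=True)
    catalog = enumerate_models(4, "sp_sharing")
    best = select_best_population(Y, t.trial_labels, catalog, seed=0)
    truth = exp.truth.drop_duplicates("unit").set_index("unit")
    match = np.mean([best.loc[u, "best_by_bic"] == truth.loc[u, "model_id"]
                     for u in range(t.n_units)])
    assert match >= 0.85


def test_histogram_concentrates_on_generative_model():
    mix = {"s1212": 1.0}
    spec = synth.PopulationGenSpec(n_units=40, n_sessions=1, seed=21,
                                   model_mixture=mix, sp_range=(6.0, 15.0))
    exp = synth.generate_population(spec, "MSMT")
    t = exp.sessions[0]
    resp = window_rate(t, t.timeline.analysis_window)
    base = window_rate(t, t.timeline.baseline_window)
    best = select_best_population(resp - base.mean(axis=1, keepdims=True),
                                  t.trial_labels,
                                  enumerate_models(4, "sp_sharing"), seed=0)
    hists = population_model_histogram(best)
    hist = hists["model_bic"].set_index("model_id")["percent"]
    assert hist.get("s1212", 0.0) >= 85.0
    cat = hists["category_bic"].set_index("category")["percent"]
    assert cat.get("body_part_specific", 0.0) >= 85.0
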