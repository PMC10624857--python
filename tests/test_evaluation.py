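"""Selection differential and the five index-evaluation criteria."""

import numpy as np
import pytest
from scipy import integrate, stats

from selindex import (IndexScores, TraitPanel, aggregate_gain,
                      base_coefficients, evaluate_index, index_cv,
                      optimum_coefficients, per_trait_gain,
                      relative_efficiency, response_correlation,
                      score_genotypes, selection_differential)
from selindex.indices import SelectionIndexModel

from conftest import random_spd


class TestSelectionDifferential:
    def test_ten_percent_matches_truncated_normal_mean(self):
        """k(0.10) ~ 1.755, the value breeders round to 1.76."""
        assert selection_differential(0.10) == pytest.approx(1.7550, abs=5e-4)

    @pytest.mark.parametrize("p", [0.05, 0.10, 0.25, 0.5, 0.9])
    def test_matches_numerical_integration(self, p):
        """k = E[Z | Z > z_p] by direct integration of the normal tail."""
        z = stats.norm.isf(p)
        num, _ = integrate.quad(lambda x: x * stats.norm.pdf(x), z, 12)
        assert selection_differential(p) == pytest.approx(num / p, rel=1e-8)

    def test_vanishes_as_everything_is_kept(self):
        assert selection_differential(0.999999) < 1e-4

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_domain(self, p):
        with pytest.raises(ValueError):
            selection_differential(p)


class TestResponseCorrelation:
    def test_hand_fixture(self, fixture2):
        _, P, G, a = fixture2
        model = optimum_coefficients(P, G, a)
        r, sH = response_correlation(model, P, G, a)
        assert r == pytest.approx(np.sqrt(0.5), abs=1e-10)
        assert sH == pytest.approx(2.0)

    def test_single_trait_accuracy_is_h(self):
        """m=1 optimum index: R_HI = h = sqrt(h2)."""
        sg2, se2 = 3.0, 5.0
        P, G = np.array([[sg2 + se2]]), np.array([[sg2]])
        model = optimum_coefficients(P, G, [1.0])
        r, _ = response_correlation(model, P, G, [1.0])
        assert r == pytest.approx(np.sqrt(sg2 / (sg2 + se2)), rel=1e-12)

    def test_indefinite_forms_rejected(self):
        model = SelectionIndexModel("base", [1.0, -1.0])
        P = np.eye(2)
        G = np.array([[1.0, 2.0], [2.0, 1.0]])     # indefinite
        with pytest.raises(ValueError, match="quadratic form"):
            response_correlation(model, P, G, [1.0, -1.0])


class TestGains:
    def test_aggregate_gain_hand_value(self, fixture2):
        _, P, G, a = fixture2
        model = optimum_coefficients(P, G, a)
        r, sH = response_correlation(model, P, G, a)
        assert aggregate_gain(1.76, r, sH) == pytest.approx(2.4890, abs=1e-4)
        assert aggregate_gain(0.0, r, sH) == 0.0

    def test_per_trait_gain_hand_value(self, fixture2):
        _, P, G, a = fixture2
        model = optimum_coefficients(P, G, a)
        np.testing.assert_allclose(per_trait_gain(1.76, G, model, P),
                                   [1.55563, 0.93338], atol=1e-5)

    def test_zero_index_rejected(self):
        model = SelectionIndexModel("base", [0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            per_trait_gain(1.76, np.eye(2), model, np.eye(2))

    def test_single_trait_classic_response(self):
        """m=1 optimum: delta = k h sigma_g, the breeder's equation."""
        sg2, se2, k = 2.5, 1.5, 1.755
        P, G = np.array([[sg2 + se2]]), np.array([[sg2]])
        model = optimum_coefficients(P, G, [1.0])
        h = np.sqrt(sg2 / (sg2 + se2))
        assert per_trait_gain(k, G, model, P)[0] == pytest.approx(
            k * h * np.sqrt(sg2), rel=1e-12)


class TestRelativeEfficiency:
    def test_hand_fixture(self, fixture2):
        _, P, G, a = fixture2
        model = optimum_coefficients(P, G, a)
        RE, r_GAI, h_A = relative_efficiency(model, P, G, 0)
        assert r_GAI == pytest.approx(0.625, abs=1e-10)
        assert h_A == pytest.approx(np.sqrt(0.5))
        assert RE == pytest.approx(0.88388, abs=1e-5)

    def test_self_selection_has_unit_efficiency(self):
        sg2, se2 = 3.0, 2.0
        P, G = np.array([[sg2 + se2]]), np.array([[sg2]])
        model = optimum_coefficients(P, G, [1.0])
        RE, _, _ = relative_efficiency(model, P, G, 0)
        assert RE == pytest.approx(1.0, rel=1e-12)

    def test_zero_target_variance_rejected(self):
        model = SelectionIndexModel("base", [1.0, 1.0])
        G = np.diag([0.0, 1.0])
        with pytest.raises(ValueError, match="nonpositive genotypic"):
            relative_efficiency(model, np.eye(2), G, 0)


class TestIndexCV:
    def test_hand_values_and_scale_invariance(self):
        ids = ["a", "b"]
        s = IndexScores(np.array([8.0, 12.0]), np.array([2, 1]), ids,
                        10.0, float(np.std([8.0, 12.0], ddof=1)))
        assert index_cv(s) == pytest.approx(28.2843, abs=1e-3)
        doubled = IndexScores(np.array([16.0, 24.0]), np.array([2, 1]), ids,
                              20.0, float(np.std([16.0, 24.0], ddof=1)))
        assert index_cv(doubled) == pytest.approx(index_cv(s), rel=1e-12)

    def test_constant_scores_give_zero(self):
        s = IndexScores(np.full(3, 5.0), np.array([1, 2, 3]), list("abc"), 5.0, 0.0)
        assert index_cv(s) == 0.0

    def test_zero_mean_flagged(self):
        s = IndexScores(np.array([-1.0, 1.0]), np.array([2, 1]), ["a", "b"],
                        0.0, np.sqrt(2.0))
        with pytest.raises(ValueError, match="undefined"):
            index_cv(s)


class TestEvaluateIndex:
    def test_composition_matches_component_oracles(self, fixture2):
        panel, P, G, a = fixture2
        model = optimum_coefficients(P, G, a, panel.trait_names)
        c = evaluate_index(model, P, G, a, panel=panel, target=0, k=1.76)
        assert c.R_HI == pytest.approx(np.sqrt(0.5), abs=1e-10)
        assert c.delta_H == pytest.approx(2.4890, abs=1e-4)
        np.testing.assert_allclose(c.delta, [1.55563, 0.93338], atol=1e-5)
        assert c.RE == pytest.approx(0.88388, abs=1e-5)
        scores = score_genotypes(panel, model)
        assert c.CV_I == pytest.approx(100 * scores.sd_score / scores.mean_score)

    def test_invariant_under_trait_permutation(self):
        rng = np.random.default_rng(11)
        m = 4
        P, G = random_spd(rng, m), random_spd(rng, m)
        a = rng.normal(size=m)
        X = rng.normal(loc=20.0, size=(12, m))
        perm = np.array([2, 0, 3, 1])
        panel = TraitPanel(X)
        panel_p = TraitPanel(X[:, perm])
        c = evaluate_index(optimum_coefficients(P, G, a), P, G, a,
                           panel=panel, target=3, k=1.755)
        c_p = evaluate_index(
            optimum_coefficients(P[np.ix_(perm, perm)], G[np.ix_(perm, perm)],
                                 a[perm]),
            P[np.ix_(perm, perm)], G[np.ix_(perm, perm)], a[perm],
            panel=panel_p, target=int(np.where(perm == 3)[0][0]), k=1.755)
        assert c_p.R_HI == pytest.approx(c.R_HI, rel=1e-10)
        assert c_p.delta_H == pytest.approx(c.delta_H, rel=1e-10)
        assert c_p.RE == pytest.approx(c.RE, rel=1e-10)
        assert c_p.CV_I == pytest.approx(c.CV_I, rel=1e-10)
        np.testing.assert_allclose(c_p.delta, c.delta[perm], rtol=1e-10)


class TestAlgebraicIdentities:
    def test_optimum_simplified_forms_coincide(self):
        """For b = P^-1 G a: sigma_I^2 = sigma_HI, so R_HI = sigma_I/sigma_H."""
        rng = np.random.default_rng(12)
        for _ in range(25):
            m = rng.integers(2, 6)
            # P = G + E so (P, G) is a realisable phenotypic/genotypic pair,
            # which is what bounds the optimum accuracy by 1
            G = random_spd(rng, m)
            P = G + random_spd(rng, m)
            a = rng.normal(size=m)
            model = optimum_coefficients(P, G, a)
            b = model.b
            var_I, cov_HI = b @ P @ b, b @ G @ a
            assert var_I == pytest.approx(cov_HI, rel=1e-9)
            r, sH = response_correlation(model, P, G, a)
            assert r == pytest.approx(np.sqrt(var_I) / sH, rel=1e-9)
            assert 0.0 <= r <= 1.0 + 1e-12

    def test_target_gain_links_delta_and_rgai(self):
        """delta[A] = k * r_GAI * sigma_G(A) ties the gain and efficiency paths."""
        rng = np.random.default_rng(13)
        for _ in range(25):
            m = rng.integers(2, 6)
            P, G = random_spd(rng, m), random_spd(rng, m)
            b = rng.normal(size=m)
            model = SelectionIndexModel("base", b)
            k = 1.755
            A = int(rng.integers(m))
            delta = per_trait_gain(k, G, model, P)
            _, r_GAI, _ = relative_efficiency(model, P, G, A)
            assert delta[A] == pytest.approx(k * r_GAI * np.sqrt(G[A, A]),
                                             rel=1e-10)

    def test_weight_scaling_behaviour(self):
        """Scaling w by c > 0: R_HI, RE unchanged; base-index dH scales by c."""
        rng = np.random.default_rng(14)
        m, c = 3, 4.2
        P, G = random_spd(rng, m), random_spd(rng, m)
        a = rng.normal(size=m)
        base1, basec = base_coefficients(a), base_coefficients(c * a)
        r1, sH1 = response_correlation(base1, P, G, a)
        rc, sHc = response_correlation(basec, P, G, c * a)
        assert rc == pytest.approx(r1, rel=1e-12)
        assert aggregate_gain(1.76, rc, sHc) == pytest.approx(
            c * aggregate_gain(1.76, r1, sH1), rel=1e-12)
        RE1 = relative_efficiency(base1, P, G, 0)[0]
        REc = relative_efficiency(basec, P, G, 0)[0]
        assert REc == pytest.approx(RE1, rel=1e-12)
        # optimum index: same invariances for R_HI and RE
        o1 = optimum_coefficients(P, G, a)
        oc = optimum_coefficients(P, G, c * a)
        assert response_correlation(oc, P, G, c * a)[0] == pytest.approx(
            response_correlation(o1, P, G, a)[0], rel=1e-12)
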