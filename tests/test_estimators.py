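"""Estimators invert the forward model and are exactly unbiased."""

import numpy as np
import pytest

from kinquartet import (
    COEFFICIENT_NAMES,
    JacquardVector,
    RelatednessParameters,
    allele_weights,
    class_spectrum,
    estimate_all_eight,
    estimate_G,
    estimate_H_F_R,
    estimate_H_Fab,
    estimate_R,
    jacquard_to_coefficients,
    weir_identity_disequilibrium,
)
from kinquartet.estimators import joint_forward_2x2, joint_forward_3x3
from kinquartet.components import component_system

from conftest import afv, random_admissible


class TestEstimateR:
    def test_null_inversion(self, afv631):
        spec = class_spectrum(afv631, RelatednessParameters(), 2)
        assert estimate_R(spec).estimates["R"] == pytest.approx(0.0, abs=1e-12)

    def test_full_identity(self, afv631):
        spec = class_spectrum(afv631, RelatednessParameters(R=1.0), 2)
        assert estimate_R(spec).estimates["R"] == pytest.approx(1.0)

    def test_forward_inversion(self):
        v = afv(0.6, 0.3, 0.1)
        spec = class_spectrum(v, RelatednessParameters(R=0.25), 2)
        res = estimate_R(spec)
        assert res.estimates["R"] == pytest.approx(0.25, abs=1e-12)
        assert sum(res.weights.values()) == pytest.approx(1.0, abs=1e-12)


class TestEstimateG:
    def test_forward_inversion(self, afv4321):
        truth = RelatednessParameters(F_A=0.4, R=0.35, G_A=0.3)
        spec = class_spectrum(afv4321, truth, 3)
        res = estimate_G(spec, truth.F_A, truth.R)
        assert res.estimates["G"] == pytest.approx(0.3, abs=1e-10)

    def test_null(self, afv631):
        spec = class_spectrum(afv631, RelatednessParameters(), 3)
        assert estimate_G(spec, 0.0, 0.0).estimates["G"] == pytest.approx(0.0, abs=1e-12)

    def test_half_frequency_component_flagged(self, afv532):
        spec = class_spectrum(afv532, RelatednessParameters(), 3)
        res = estimate_G(spec, 0.0, 0.0)
        assert any("A1" in f and "non-estimable" in f for f in res.flags)
        assert "A1" not in res.components["G"]


class TestJointSolvers:
    def test_2x2_inversion(self):
        p, q = 0.4, 0.3
        rhs = joint_forward_2x2(p, q) @ np.array([0.1, 0.05])
        res = estimate_H_Fab(rhs[0] + p**4, rhs[1] + 2 * p**2 * q**2, p, q)
        assert res.estimates["H"] == pytest.approx(0.1, abs=1e-10)
        assert res.estimates["F_ab"] == pytest.approx(0.05, abs=1e-10)

    def test_2x2_null(self):
        res = estimate_H_Fab(0.4**4, 2 * 0.4**2 * 0.3**2, 0.4, 0.3)
        assert res.estimates["H"] == pytest.approx(0.0, abs=1e-12)
        assert res.estimates["F_ab"] == pytest.approx(0.0, abs=1e-12)

    def test_2x2_singular_at_half(self):
        res = estimate_H_Fab(0.1, 0.05, 0.5, 0.3)
        assert np.isnan(res.estimates["H"])
        assert any("singular" in f for f in res.flags)

    def test_2x2_needs_third_allele(self):
        res = estimate_H_Fab(0.1, 0.05, 0.4, 0.6)
        assert any("third allele" in f for f in res.flags)

    def test_3x3_inversion(self):
        p, q = 0.4, 0.3
        rhs = joint_forward_3x3(p, q) @ np.array([0.05, 0.2, 0.1])
        res = estimate_H_F_R(
            rhs[0] + p**4, rhs[1] + 4 * p**2 * q**2, rhs[2] + 2 * p**2 * q**2, p, q
        )
        assert res.estimates["H"] == pytest.approx(0.05, abs=1e-10)
        assert res.estimates["F_ab"] == pytest.approx(0.2, abs=1e-10)
        assert res.estimates["R_abab"] == pytest.approx(0.1, abs=1e-10)

    def test_3x3_zero_parameters(self):
        p, q = 0.4, 0.3
        res = estimate_H_F_R(p**4, 4 * p**2 * q**2, 2 * p**2 * q**2, p, q)
        for v in res.estimates.values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_3x3_singular_at_third(self):
        res = estimate_H_F_R(0.1, 0.1, 0.1, 1 / 3, 0.3)
        assert np.isnan(res.estimates["H"])
        assert any("1/3" in f for f in res.flags)


class TestWeir:
    def test_printed_coefficients(self):
        res = weir_identity_disequilibrium(0.0, 0.0, 0.2, 0.3)
        assert res.extras["a"] == pytest.approx(2.16)
        assert res.extras["b"] == pytest.approx(0.64)
        assert res.extras["c"] == pytest.approx(0.072)
        assert res.estimates["R_AB"] == 0.0

    def test_singular_at_third(self):
        res = weir_identity_disequilibrium(0.1, 0.1, 1 / 3, 0.3)
        assert np.isnan(res.estimates["R_AB"])

    def test_sign_of_denominator_reported(self):
        res = weir_identity_disequilibrium(0.0, 0.0, 0.5, 0.2)
        assert res.extras["sign_c"] == -1


class TestAllEight:
    def test_forward_inversion(self, afv4321):
        d = JacquardVector(np.array([0.05, 0.1, 0.05, 0.1, 0.05, 0.1, 0.2, 0.15, 0.2]))
        c = jacquard_to_coefficients(d)
        spec = class_spectrum(afv4321, c, 4)
        res = estimate_all_eight(spec, (0, 1, 2))
        for n in COEFFICIENT_NAMES:
            assert res.estimates[n] == pytest.approx(getattr(c, n), abs=1e-10)

    def test_null_expectations_give_zeros(self, afv631):
        spec = class_spectrum(afv631, RelatednessParameters(), 4)
        res = estimate_all_eight(spec)
        for v in res.estimates.values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_singular_design_flagged(self):
        v = afv(0.3, 0.3, 0.4)
        spec = class_spectrum(v, RelatednessParameters(), 4)
        res = estimate_all_eight(spec, (0, 1, 2))
        assert any("singular" in f for f in res.flags)
        assert all(np.isnan(x) for x in res.estimates.values())

    def test_condition_number_reported(self, afv4321):
        spec = class_spectrum(afv4321, RelatednessParameters(), 4)
        res = estimate_all_eight(spec)
        assert res.extras["condition_number"] > 1


class TestAlleleWeights:
    def test_two_gene_zero_prior_closed_form(self):
        res = allele_weights(afv(0.6, 0.3, 0.1), target="R")
        assert res.weights["A1"] == pytest.approx(0.2, abs=1e-10)
        assert res.weights["A2"] == pytest.approx(0.35, abs=1e-10)
        assert res.weights["A3"] == pytest.approx(0.45, abs=1e-10)

    def test_biallelic_swaps_frequencies(self):
        res = allele_weights(afv(0.7, 0.3), target="R")
        assert res.weights["A1"] == pytest.approx(0.3, abs=1e-10)
        assert res.weights["A2"] == pytest.approx(0.7, abs=1e-10)

    @pytest.mark.parametrize("target", ["R", "F", "G_A", "H"])
    def test_weights_sum_to_one(self, target, afv4321):
        res = allele_weights(afv4321, target=target)
        assert sum(res.weights.values()) == pytest.approx(1.0, abs=1e-10)

    def test_half_frequency_component_excluded(self, afv532):
        res = allele_weights(afv532, target="G_A")
        assert res.weights["A1"] == 0.0
        assert any("A1" in f for f in res.flags)


class TestUnbiasedness:
    """Mean estimate over the full enumeration, weighted by model
    probabilities, equals the true parameter."""

    def test_components_unbiased_at_random_truths(self, rng, afv4321):
        for _ in range(20):
            _, c = random_admissible(rng)
            for target, attr in [
                ("R", "R"), ("F", "F_A"), ("G_A", "G_A"), ("H", "H"),
            ]:
                sys = component_system(target, afv4321, c)
                mean, _ = sys.moments()
                for a in np.nonzero(sys.estimable)[0]:
                    assert mean[a] == pytest.approx(getattr(c, attr), abs=1e-10)

    def test_linear_solve_unbiased_at_random_truths(self, rng, afv4321):
        from kinquartet.genoprob import design_matrix, genotype_pair_spectrum

        dm = design_matrix(afv4321, (0, 1, 2))
        Minv = np.linalg.inv(dm.matrix)
        for _ in range(20):
            _, c = random_admissible(rng)
            spec = genotype_pair_spectrum(afv4321, c)
            # expectation of the per-observation indicator solve is linear,
            # hence equals the solve of the expected indicators
            obs = np.array([spec.get(k, 0.0) for k in dm.class_keys])
            est = Minv @ (obs - dm.null)
            for n, v in zip(COEFFICIENT_NAMES, est):
                assert v == pytest.approx(getattr(c, n), abs=1e-10)
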