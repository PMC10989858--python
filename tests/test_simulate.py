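"""Simulator: determinism, agreement with the probability model, mixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kinquartet import (
    JacquardVector,
    MixtureSpec,
    SimulationDesign,
    empirical_identity_disequilibrium,
    jacquard_to_coefficients,
    mixture_moments,
    MixtureModel,
    sample_pair,
    simulate_dataset,
    simulate_mixture,
    validate_frequencies,
)
from kinquartet.genoprob import genotype_pair_spectrum

from conftest import afv


def empirical_spectrum(table, v):
    idx = {lab: i for i, lab in enumerate(v.alleles)}
    out = {}
    for a1, a2, b1, b2 in table[["a1", "a2", "b1", "b2"]].itertuples(index=False):
        key = (tuple(sorted((idx[a1], idx[a2]))), tuple(sorted((idx[b1], idx[b2]))))
        out[key] = out.get(key, 0) + 1
    return out, len(table)


class TestSamplePair:
    def test_total_identity_gives_quadruple_homozygote(self, rng, afv532):
        for _ in range(50):
            gp = sample_pair(JacquardVector.pure(1), afv532, rng)
            assert len({*gp.gA, *gp.gB}) == 1

    def test_unrelated_pairs_match_hardy_weinberg(self, afv532):
        design = SimulationDesign(
            delta=JacquardVector.pure(9), freqs=(afv532,), n_pairs=50_000, seed=17
        )
        table, _ = simulate_dataset(design)
        obs, n = empirical_spectrum(table, afv532)
        spec = genotype_pair_spectrum(
            afv532, jacquard_to_coefficients(JacquardVector.pure(9))
        )
        keys = sorted(spec)
        chi = stats.chisquare(
            [obs.get(k, 0) for k in keys], [spec[k] * n for k in keys]
        )
        assert chi.pvalue > 0.001

    def test_double_cross_pair_class_frequency(self, afv532):
        design = SimulationDesign(
            delta=JacquardVector.pure(7), freqs=(afv532,), n_pairs=100_000, seed=23
        )
        table, _ = simulate_dataset(design)
        obs, n = empirical_spectrum(table, afv532)
        f = obs.get(((0, 1), (0, 1)), 0) / n
        se = np.sqrt(0.30 * 0.70 / n)
        assert abs(f - 0.30) < 4 * se


class TestSimulateDataset:
    def test_seed_determinism(self, afv532, afv4321):
        design = SimulationDesign(
            delta=JacquardVector.pure(9), freqs=(afv532, afv4321), n_pairs=500, seed=7
        )
        t1, m1 = simulate_dataset(design)
        t2, m2 = simulate_dataset(design)
        assert t1.equals(t2)
        assert m1 == m2

    def test_empirical_matches_model_for_every_pure_mode(self, afv532, afv4321):
        arrays = [afv532, afv4321, afv(0.7, 0.3)]
        n = 100_000
        for m in range(1, 10):
            v = arrays[m % 3]
            design = SimulationDesign(
                delta=JacquardVector.pure(m), freqs=(v,), n_pairs=n, seed=100 + m
            )
            table, _ = simulate_dataset(design)
            obs, _ = empirical_spectrum(table, v)
            spec = genotype_pair_spectrum(
                v, jacquard_to_coefficients(JacquardVector.pure(m))
            )
            for key, pth in spec.items():
                pth = max(pth, 0.0)  # clip −1e-17 roundoff in exact zeros
                se = max(np.sqrt(pth * (1 - pth) / n), 1e-12)
                assert abs(obs.get(key, 0) / n - pth) <= 4 * se + 1e-12, (m, key)

    def test_zero_loci_rejected(self, afv532):
        with pytest.raises(ValueError):
            SimulationDesign(
                delta=JacquardVector.pure(9), freqs=(), n_pairs=10, seed=1
            )

    def test_latent_mode_labels_retained(self, afv532):
        design = SimulationDesign(
            delta=JacquardVector.pure(4), freqs=(afv532,), n_pairs=10, seed=1,
            keep_latent=True,
        )
        table, _ = simulate_dataset(design)
        assert (table["mode"] == 4).all()


class TestSimulateMixture:
    @staticmethod
    def _two_pop_spec(p, a, n_loci=2):
        d9 = JacquardVector.pure(9)
        hi = validate_frequencies([("A", p + a), ("a", 1 - p - a)]) if a else None
        if a == 0:
            f = validate_frequencies([("A", p), ("a", 1 - p)])
            comps = ((f,) * n_loci, (f,) * n_loci)
        else:
            lo = validate_frequencies([("A", p - a), ("a", 1 - p + a)])
            comps = ((hi,) * n_loci, (lo,) * n_loci)
        return MixtureSpec((0.5, 0.5), (d9, d9), comps)

    def test_mixture_induces_positive_homozygosity_covariance(self):
        p, a, n = 0.3, 0.1, 100_000
        mix = self._two_pop_spec(p, a)
        design = SimulationDesign(
            delta=JacquardVector.pure(9),
            freqs=mix.freqs_by_component[0],
            n_pairs=n,
            seed=31,
            mixture=mix,
        )
        table, _ = simulate_mixture(design)
        idq = empirical_identity_disequilibrium(table)
        excess = idq.loc[0, "excess"]
        # brute-force oracle for the across-locus covariance of homozygosity
        expected = mixture_moments(MixtureModel.two_population(p, a))[
            "var_component_total_homozygosity"
        ]
        se = np.sqrt(0.25 / n)
        assert excess > 3 * se  # strictly positive
        assert abs(excess - expected) < 4 * se

    def test_no_divergence_no_covariance(self):
        mix = self._two_pop_spec(0.3, 0.0)
        design = SimulationDesign(
            delta=JacquardVector.pure(9),
            freqs=mix.freqs_by_component[0],
            n_pairs=100_000,
            seed=37,
            mixture=mix,
        )
        table, _ = simulate_mixture(design)
        idq = empirical_identity_disequilibrium(table)
        assert abs(idq.loc[0, "excess"]) < 4 * np.sqrt(0.25 / 100_000)

    def test_single_component_matches_plain_simulation_in_distribution(
        self, afv532
    ):
        d = JacquardVector(np.array([0.05, 0.1, 0.05, 0.1, 0.05, 0.1, 0.2, 0.15, 0.2]))
        mix = MixtureSpec((1.0,), (d,), ((afv532,),))
        design = SimulationDesign(
            delta=d, freqs=(afv532,), n_pairs=50_000, seed=41, mixture=mix
        )
        table, _ = simulate_mixture(design)
        obs, n = empirical_spectrum(table, afv532)
        spec = genotype_pair_spectrum(afv532, jacquard_to_coefficients(d))
        keys = sorted(spec)
        chi = stats.chisquare(
            [obs.get(k, 0) for k in keys], [spec[k] * n for k in keys]
        )
        assert chi.pvalue > 0.001


class TestIdentityDisequilibrium:
    def test_independent_loci_show_no_excess(self, afv532):
        design = SimulationDesign(
            delta=JacquardVector.pure(9), freqs=(afv532,) * 2, n_pairs=50_000, seed=43
        )
        table, _ = simulate_dataset(design)
        idq = empirical_identity_disequilibrium(table)
        assert abs(idq.loc[0, "excess"]) < 4 * np.sqrt(0.25 / 50_000)

    def test_duplicated_locus_excess_is_bernoulli_variance(self, afv532):
        design = SimulationDesign(
            delta=JacquardVector.pure(9), freqs=(afv532,), n_pairs=20_000, seed=47
        )
        table, _ = simulate_dataset(design)
        dup = table.copy()
        dup["locus"] = "L1"
        both = pd.concat([table, dup], ignore_index=True)
        idq = empirical_identity_disequilibrium(both)
        hom = (table["a1"] == table["a2"]).mean()
        assert idq.loc[0, "excess"] == pytest.approx(hom * (1 - hom), abs=1e-12)

    def test_needs_two_loci(self, afv532):
        design = SimulationDesign(
            delta=JacquardVector.pure(9), freqs=(afv532,), n_pairs=100, seed=1
        )
        table, _ = simulate_dataset(design)
        idq = empirical_identity_disequilibrium(table)
        assert len(idq) == 0
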