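"""Per-allele component estimators and their exact moments by enumeration.

Each single-locus coefficient estimator is a weighted combination of
per-allele components, one component per allele, each a linear function of
indicator statistics of the observation unit:

* ``F``   — unit: one unordered genotype; component (1{g=ii} − p_i²)/(p_i q_i)
* ``R``   — unit: one unordered cross-individual gene pair (a gene of A with
  a gene of B); component (1{pair = ii} − p_i²)/(p_i q_i)
* ``G_A`` — unit: a gene triplet (A's genotype plus one gene of B); indicator
  of the iii class inverted through the three-gene class formula; the
  denominator p_i q_i (1 − 2p_i) vanishes at p_i = 1/2 (non-estimable)
* ``G_B`` — as G_A with individuals exchanged
* ``H``   — unit: a full genotype pair; indicator of the all-homozygous class
  iiii inverted through the four-gene class formula; denominator
  p_i q_i (1 − 6 p_i q_i) vanishes where p_i q_i = 1/6

The observation unit always matches the number of genes the coefficient
concerns; estimators built on richer units (e.g. averaging a triplet
statistic over both genes of B) would be different — typically more
efficient — estimators with the same expectation.

Components are unbiased given the true values of the lower-order coefficients
they condition on.  Moments are computed exactly: the observation units are
enumerated and weighted by the model probabilities at the stated truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AlleleFrequencyVector, RelatednessParameters
from .genoprob import genotype_pair_spectrum

__all__ = ["ComponentSystem", "component_system", "minimum_variance_weights"]

TARGETS = ("F", "R", "G_A", "G_B", "H")


@dataclass
class ComponentSystem:
    """Exact joint distribution of the per-allele component estimators."""

    target: str
    freqs: AlleleFrequencyVector
    values: np.ndarray  # (n_units, n_alleles) component value per configuration
    probs: np.ndarray  # (n_units,) configuration probabilities at the truth
    estimable: np.ndarray  # (n_alleles,) bool
    configurations: list

    def moments(self):
        """Mean vector and covariance matrix of the components."""
        m = self.probs @ self.values
        centred = self.values - m
        V = (centred * self.probs[:, None]).T @ centred
        return m, V


def _genotypes(k: int):
    return [(i, j) for i in range(k) for j in range(i, k)]


def component_system(
    target: str,
    freqs: AlleleFrequencyVector,
    truth: RelatednessParameters | None = None,
) -> ComponentSystem:
    """Enumerate the observation unit and evaluate every per-allele component.

    ``truth`` fixes both the distribution of configurations and the known
    lower-order coefficients the G and H components subtract off; default is
    the null (all coefficients zero).
    """
    if target not in TARGETS:
        raise ValueError(f"target must be one of {TARGETS}")
    truth = truth or RelatednessParameters()
    p = freqs.p
    q = 1.0 - p
    k = freqs.n_alleles

    if target == "F":
        genos = _genotypes(k)
        probs = np.empty(len(genos))
        F = truth.F_A
        for u, (i, j) in enumerate(genos):
            probs[u] = (
                p[i] ** 2 + p[i] * q[i] * F if i == j else 2 * p[i] * p[j] * (1 - F)
            )
        values = np.zeros((len(genos), k))
        for a in range(k):
            ind = np.array([1.0 if g == (a, a) else 0.0 for g in genos])
            values[:, a] = (ind - p[a] ** 2) / (p[a] * q[a])
        estim = (p > 1e-12) & (p < 1 - 1e-12)
        return ComponentSystem(target, freqs, values, probs, estim, genos)

    if target == "R":
        # unit: one unordered cross-individual gene pair
        pairs = _genotypes(k)
        R = truth.R
        probs = np.empty(len(pairs))
        for u, (i, j) in enumerate(pairs):
            probs[u] = (
                p[i] ** 2 + p[i] * q[i] * R if i == j else 2 * p[i] * p[j] * (1 - R)
            )
        values = np.zeros((len(pairs), k))
        for a in range(k):
            ind = np.array([1.0 if g == (a, a) else 0.0 for g in pairs])
            values[:, a] = (ind - p[a] ** 2) / (p[a] * q[a])
        estim = (p > 1e-12) & (p < 1 - 1e-12)
        return ComponentSystem(target, freqs, values, probs, estim, pairs)

    if target in ("G_A", "G_B"):
        # unit: the focal individual's genotype plus one gene of the other
        from .genoprob import _classify_triplet, triplet_probability

        F = truth.F_A if target == "G_A" else truth.F_B
        R = truth.R
        G = truth.G_A if target == "G_A" else truth.G_B
        genos = _genotypes(k)
        units = [(g, b) for g in genos for b in range(k)]
        probs = np.empty(len(units))
        for u, (g, b) in enumerate(units):
            pattern, alleles = _classify_triplet(g, b)
            probs[u] = triplet_probability(freqs, F, R, G, pattern, alleles)
        values = np.zeros((len(units), k))
        estim = np.ones(k, dtype=bool)
        for a in range(k):
            denom = p[a] * q[a] * (1 - 2 * p[a])
            if abs(denom) < 1e-12:
                estim[a] = False
                continue
            ind = np.array([1.0 if u == ((a, a), a) else 0.0 for u in units])
            null3 = p[a] ** 3 + p[a] ** 2 * q[a] * (F + 2 * R)
            values[:, a] = (ind - null3) / denom
        return ComponentSystem(target, freqs, values, probs, estim, units)

    # H observes a full genotype pair
    genos = _genotypes(k)
    units = [(gA, gB) for gA in genos for gB in genos]
    spec = genotype_pair_spectrum(freqs, truth)
    probs = np.array([spec[u] for u in units])
    values = np.zeros((len(units), k))
    estim = np.ones(k, dtype=bool)
    if target == "H":
        for a in range(k):
            denom = p[a] * q[a] * (1 - 6 * p[a] * q[a])
            if abs(denom) < 1e-12:
                estim[a] = False
                continue
            ind = np.array(
                [1.0 if u == ((a, a), (a, a)) else 0.0 for u in units]
            )
            # f_iiii with H stripped off (the class is affine in H with
            # slope equal to the order-4 normalisation constant)
            f_iiii_h0 = spec[((a, a), (a, a))] - denom * truth.H
            values[:, a] = (ind - f_iiii_h0) / denom

    return ComponentSystem(target, freqs, values, probs, estim, units)


def minimum_variance_weights(V: np.ndarray, estimable: np.ndarray):
    """Weights minimising w'Vw subject to Σw = 1 over the estimable components.

    Returns ``(weights, fallback)``; on a singular covariance the weights fall
    back to equal weights over the estimable components with ``fallback=True``.
    """
    k = V.shape[0]
    w = np.zeros(k)
    idx = np.nonzero(estimable)[0]
    if idx.size == 0:
        return w, True
    sub = V[np.ix_(idx, idx)]
    try:
        x = np.linalg.solve(sub, np.ones(idx.size))
        if not np.all(np.isfinite(x)) or abs(x.sum()) < 1e-300:
            raise np.linalg.LinAlgError
        w[idx] = x / x.sum()
        return w, False
    except np.linalg.LinAlgError:
        w[idx] = 1.0 / idx.size
        return w, True
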