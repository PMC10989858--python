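"""Method-of-moments and linear estimators inverting the probability model.

All estimators share three properties by construction:

* fed the exact expected spectrum generated at known parameters, they return
  those parameters (estimator ∘ forward model = identity on the estimable
  subspace);
* they are unbiased over the full enumeration of configurations;
* they are **not** truncated to [0, 1] — out-of-range values are flagged,
  never clamped, because unbiasedness requires an unbounded estimator and the
  covariance-bearing coefficients can legitimately exceed probability bounds.

Non-estimable components (zero denominators at special frequencies: p = 1/2
for three-gene patterns, p·q = 1/6 for the iiii-pattern four-gene component,
p = 1/3 for the joint three-class closed forms) are flagged, never silently
zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    COEFFICIENT_NAMES,
    AlleleFrequencyVector,
    RelatednessParameters,
)
from .components import component_system, minimum_variance_weights
from .genoprob import ClassSpectrum, design_matrix

__all__ = [
    "EstimateResult",
    "estimate_R",
    "estimate_G",
    "g_hat_iii",
    "g_hat_iij",
    "g_hat_ijk",
    "estimate_H_Fab",
    "estimate_H_F_R",
    "weir_identity_disequilibrium",
    "estimate_all_eight",
    "allele_weights",
    "joint_forward_2x2",
    "joint_forward_3x3",
]


@dataclass
class EstimateResult:
    """Point estimates with per-allele components, weights and flags."""

    estimates: dict[str, float]
    method: str
    components: dict[str, dict] = field(default_factory=dict)
    weights: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]


def _normalise_counts(probs: dict) -> dict:
    total = float(sum(probs.values()))
    if total <= 0:
        raise ValueError("spectrum has no mass")
    return {k: v / total for k, v in probs.items()}


# --------------------------------------------------------------------------
# two genes
# --------------------------------------------------------------------------

def estimate_R(spectrum: ClassSpectrum, weights=None) -> EstimateResult:
    """Pairwise coefficient from a two-gene spectrum of cross-individual pairs.

    Per allele, R̂_ii = (f_ii − p_i²)/(p_i q_i); components combine with the
    zero-prior minimum-variance weights w_i = (1 − p_i)/(n − 1) unless a weight
    vector is supplied.  Alleles with degenerate frequency are excluded with a
    flag.
    """
    if spectrum.n_genes != 2:
        raise ValueError("estimate_R expects a two-gene spectrum")
    freqs = spectrum.freqs
    f = _normalise_counts(spectrum.probs)
    p = freqs.p
    comps, flags = {}, []
    usable = []
    for a, lab in enumerate(freqs.alleles):
        if p[a] < 1e-12 or p[a] > 1 - 1e-12:
            flags.append(f"allele {lab} excluded (frequency {p[a]:.3g})")
            continue
        fii = f.get((a, a), 0.0)
        comps[lab] = (fii - p[a] ** 2) / (p[a] * (1 - p[a]))
        usable.append(a)
    if not usable:
        return EstimateResult({"R": np.nan}, "moment:R", comps, {}, flags + ["non-estimable"])
    if weights is None:
        # zero-prior closed form (1−p_i)/(n−1) over the usable alleles
        if len(usable) > 1:
            w = (1 - p[usable]) / (len(usable) - 1)
        else:
            w = np.ones(1)
        w = w / w.sum()
    else:
        w = np.asarray([weights[freqs.alleles[a]] for a in usable], dtype=float)
        w = w / w.sum()
    wmap = {freqs.alleles[a]: float(wi) for a, wi in zip(usable, w)}
    est = float(sum(wmap[lab] * comps[lab] for lab in wmap))
    if not -1e-9 <= est <= 1 + 1e-9:
        flags.append(f"estimate outside [0, 1] ({est:.4g})")
    return EstimateResult({"R": est}, "moment:R", {"R": comps}, wmap, flags)


# --------------------------------------------------------------------------
# three genes
# --------------------------------------------------------------------------

def g_hat_iii(f_iii, p_i, F, R):
    """Invert the iii class for G: denominator p q (1 − 2p)."""
    denom = p_i * (1 - p_i) * (1 - 2 * p_i)
    if abs(denom) < 1e-12:
        return np.nan
    return (f_iii - p_i**3 - p_i**2 * (1 - p_i) * (F + 2 * R)) / denom

def g_hat_iij(f_iij, p_i, p_j, F, R):
    """Invert the iij class (A homozygous i, B gene j): denominator
    p_i p_j (2p_i − 1)."""
    denom = p_i * p_j * (2 * p_i - 1)
    if abs(denom) < 1e-12:
        return np.nan
    return (f_iij - p_i**2 * p_j - p_i * p_j * F + p_i**2 * p_j * (F + 2 * R)) / denom

def g_hat_ijk(f_ijk, p_i, p_j, p_k, F, R):
    """Invert the (ordered) ijk class: Ĝ = (f/(p_i p_j p_k) − 1 + F + 2R)/2."""
    return (f_ijk / (p_i * p_j * p_k) - 1 + F + 2 * R) / 2.0


def estimate_G(
    spectrum: ClassSpectrum, F: float, R: float, weights=None
) -> EstimateResult:
    """Three-gene coefficient from an observed triplet spectrum with F and R
    supplied (they are jointly estimated elsewhere).

    Per-allele components invert the iii pattern; alleles at p = 1/2 are
    flagged non-estimable (zero denominator).  Default weights minimise the
    exact component variance at the null prior.
    """
    if spectrum.n_genes != 3:
        raise ValueError("estimate_G expects a three-gene spectrum")
    freqs = spectrum.freqs
    f = _normalise_counts(spectrum.probs)
    p = freqs.p
    comps, flags = {}, []
    estimable = []
    for a, lab in enumerate(freqs.alleles):
        val = g_hat_iii(f.get(((a, a), a), 0.0), p[a], F, R)
        if np.isnan(val):
            flags.append(f"component {lab} non-estimable (p = 1/2)")
            continue
        comps[lab] = float(val)
        estimable.append(a)
    if not estimable:
        return EstimateResult(
            {"G": np.nan}, "moment:G", {"G": comps}, {}, flags + ["non-estimable"]
        )
    if weights is None:
        wres = allele_weights(freqs, target="G_A")
        w = {lab: wres.weights[lab] for lab in comps}
        tot = sum(w.values())
        w = {lab: wi / tot for lab, wi in w.items()}
    else:
        tot = sum(weights[lab] for lab in comps)
        w = {lab: weights[lab] / tot for lab in comps}
    est = float(sum(w[lab] * comps[lab] for lab in comps))
    if not -1e-9 <= est <= 1 + 1e-9:
        flags.append(f"estimate outside [0, 1] ({est:.4g})")
    return EstimateResult({"G": est}, "moment:G", {"G": comps}, w, flags)


# --------------------------------------------------------------------------
# joint closed-form solvers for the focal-allele class triples
# --------------------------------------------------------------------------

def joint_forward_2x2(p: float, q: float) -> np.ndarray:
    """Forward matrix mapping (H, F_ab) to the excess (above-null) frequencies
    of the double-homozygote classes (f'_AAAA, f'_AAaa); third-allele mass is
    1 − p − q.  det = −2p³q(p−1)(2p−1)(p+q−1): singular iff p = 1/2 or
    p + q = 1."""
    return np.array(
        [
            [p * (1 - p) * (1 - 6 * p * (1 - p)), p**2 * (1 - p) ** 2],
            [-2 * p * q * (1 - 2 * p - 2 * q + 6 * p * q), 2 * p**2 * q**2],
        ]
    )


def estimate_H_Fab(f_AAAA, f_AAaa, p, q, *, residual=False) -> EstimateResult:
    """Joint (Ĥ, F̂_ab) from the AAAA and AA/aa homozygote classes.

    ``f_AAAA`` is the frequency of both individuals homozygous for the focal
    allele A (frequency p); ``f_AAaa`` the frequency of opposite homozygotes
    (both orientations), allele a at frequency q.  Unless ``residual`` is
    true the null expectations (p⁴, 2p²q²) are subtracted internally.
    Requires a third allele (p + q < 1); singular at p = 1/2.
    """
    M = joint_forward_2x2(p, q)
    det = float(np.linalg.det(M))
    flags = []
    if abs(det) < 1e-12:
        why = "p = 1/2" if abs(p - 0.5) < 1e-9 else "p + q = 1 (needs third allele)"
        return EstimateResult(
            {"H": np.nan, "F_ab": np.nan},
            "joint:2x2",
            flags=[f"singular system ({why})"],
        )
    rhs = np.array([f_AAAA, f_AAaa], dtype=float)
    if not residual:
        rhs -= np.array([p**4, 2 * p**2 * q**2])
    h, fab = np.linalg.solve(M, rhs)
    return EstimateResult(
        {"H": float(h), "F_ab": float(fab)}, "joint:2x2", flags=flags,
        extras={"det": det},
    )


def joint_forward_3x3(p: float, q: float) -> np.ndarray:
    """Forward matrix mapping (H, F_ab, R_abab) to the excess frequencies of
    (f'_AAAA, f'_AaAa, f'_AAaa).  det = −8p³q²(p−1)(3p−1)(p+q−1)²: at least
    three alleles are required and p = 1/3 is noninformative."""
    return np.array(
        [
            [p * (1 - p) * (1 - 6 * p * (1 - p)), p**2 * (1 - p) ** 2, 2 * p**2 * (1 - p) ** 2],
            [-4 * p * q * (1 - 2 * p - 2 * q + 6 * p * q), 4 * p**2 * q**2,
             4 * p * q * ((1 - p) * (1 - q) + p * q)],
            [-2 * p * q * (1 - 2 * p - 2 * q + 6 * p * q), 2 * p * q * (1 - p - q + p * q),
             4 * p**2 * q**2],
        ]
    )


def estimate_H_F_R(f_AAAA, f_AaAa, f_AAaa, p, q, *, residual=False) -> EstimateResult:
    """Joint (Ĥ, F̂_ab, R̂_abab) from the three focal-allele classes
    AAAA (double homozygote), AaAa (double heterozygote) and AA/aa (opposite
    homozygotes).  Singular at p = 1/3 or p + q = 1."""
    M = joint_forward_3x3(p, q)
    det = float(np.linalg.det(M))
    if abs(det) < 1e-12:
        why = "p = 1/3" if abs(p - 1 / 3) < 1e-9 else "p + q = 1 (needs third allele)"
        return EstimateResult(
            {"H": np.nan, "F_ab": np.nan, "R_abab": np.nan},
            "joint:3x3",
            flags=[f"singular system ({why})"],
        )
    rhs = np.array([f_AAAA, f_AaAa, f_AAaa], dtype=float)
    if not residual:
        rhs -= np.array([p**4, 4 * p**2 * q**2, 2 * p**2 * q**2])
    h, fab, rabab = np.linalg.solve(M, rhs)
    return EstimateResult(
        {"H": float(h), "F_ab": float(fab), "R_abab": float(rabab)},
        "joint:3x3",
        extras={"det": det},
    )


def weir_identity_disequilibrium(f_AAAA, f_AA_aa, p, q) -> EstimateResult:
    """Classic double-homozygote excess estimator of identity disequilibrium.

    R̂_AB = (a·f_AAAA − b·f_AA,aa)/c with a = 6(6pq − 2p − 2q + 1),
    b = 1 − 6pq, c = 6pq(1 − p − q)(1 − 3p).  ``f_AA_aa`` is the double
    homozygote frequency expected with no zygotic association (callers may
    supply observed or expected values).  c changes sign and vanishes at
    p = 1/3; the sign is reported alongside the estimate.
    """
    a = 6 * (6 * p * q - 2 * p - 2 * q + 1)
    b = 1 - 6 * p * q
    c = 6 * p * q * (1 - p - q) * (1 - 3 * p)
    if abs(c) < 1e-12:
        why = "p = 1/3" if abs(p - 1 / 3) < 1e-9 else "p + q = 1"
        return EstimateResult(
            {"R_AB": np.nan}, "weir", flags=[f"singular (c = 0, {why})"],
            extras={"a": a, "b": b, "c": c},
        )
    est = (a * f_AAAA - b * f_AA_aa) / c
    return EstimateResult(
        {"R_AB": float(est)},
        "weir",
        extras={"a": a, "b": b, "c": c, "sign_c": int(np.sign(c))},
    )


# --------------------------------------------------------------------------
# the full eight-coefficient linear solve
# --------------------------------------------------------------------------

def estimate_all_eight(
    spectrum: ClassSpectrum, allele_choice=(0, 1, 2)
) -> EstimateResult:
    """Solve the 8×8 linear system for all eight relatedness coefficients.

    Observed frequencies of the eight chosen classes, minus their null
    expectations, are solved against the design matrix.  The condition number
    is reported; a singular matrix (e.g. two chosen alleles at equal
    frequency) is flagged with the offending frequencies.
    """
    if spectrum.n_genes != 4:
        raise ValueError("estimate_all_eight expects a four-gene spectrum")
    freqs = spectrum.freqs
    dm = design_matrix(freqs, allele_choice)
    if dm.singular:
        return EstimateResult(
            {n: np.nan for n in COEFFICIENT_NAMES},
            "linear:8x8",
            flags=[
                "singular design matrix at frequencies "
                + str([float(freqs.p[a]) for a in dm.alleles])
            ],
        )
    f = _normalise_counts(spectrum.probs)
    flags = []
    obs = []
    for key, f0 in zip(dm.class_keys, dm.null):
        if f0 <= 0:
            flags.append(f"class {key} has zero null probability; excluded")
        obs.append(f.get(key, 0.0))
    theta = np.linalg.solve(dm.matrix, np.array(obs) - dm.null)
    est = dict(zip(COEFFICIENT_NAMES, map(float, theta)))
    for n, v in est.items():
        if not -1e-9 <= v <= 1 + 1e-9:
            flags.append(f"{n} outside [0, 1] ({v:.4g})")
    return EstimateResult(
        est, "linear:8x8", flags=flags,
        extras={"condition_number": dm.cond, "det": dm.det, "alleles": dm.alleles},
    )


# --------------------------------------------------------------------------
# weights
# --------------------------------------------------------------------------

def allele_weights(
    freqs: AlleleFrequencyVector,
    prior: RelatednessParameters | None = None,
    target: str = "R",
) -> EstimateResult:
    """Minimum-variance combination weights for per-allele components.

    Minimises w'Vw subject to Σw = 1, with V the exact covariance matrix of
    the per-allele component estimators under the prior (default: all
    coefficients zero).  For the two-gene targets at zero prior this
    reproduces the closed form w_i = (1 − p_i)/(n − 1).  A singular V falls
    back to equal weights with a warning flag.
    """
    sys = component_system(target if target != "F_A" else "F", freqs, prior)
    _, V = sys.moments()
    w, fallback = minimum_variance_weights(V, sys.estimable)
    flags = []
    if fallback:
        flags.append("covariance singular; equal weights over estimable components")
    for a, lab in enumerate(freqs.alleles):
        if not sys.estimable[a]:
            flags.append(f"component {lab} non-estimable")
    return EstimateResult(
        {},
        f"weights:{target}",
        weights={lab: float(w[a]) for a, lab in enumerate(freqs.alleles)},
        flags=flags,
        extras={"covariance": V, "estimable": sys.estimable},
    )
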