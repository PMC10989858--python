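"""Expected identity-by-state genotype(-pair) class probabilities at one locus.

Two routes to the same quantities exist and are kept deliberately separate:

* the **analytic route** — closed-form class probabilities, affine in the
  eight relatedness coefficients, hard-coded below after symbolic derivation
  from the generative model (several published transcriptions of these
  formulas are corrupted; the generative definition is authoritative, see
  docs/methods.md for the discrepancy table);
* the **generative route** (:func:`mode_pair_spectrum`,
  :func:`spectrum_from_delta`) — direct enumeration of allele assignments to
  the identity classes of each condensed Jacquard mode.  This is the oracle
  the analytic forms are tested against.

Genotypes are unordered within individuals throughout (no phase).  A
four-gene class key is ``((a1, a2), (b1, b2))`` with each genotype sorted;
a three-gene key is ``((a1, a2), b)``; a two-gene key is the sorted pair
``(g1, g2)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    COEFFICIENT_NAMES,
    AlleleFrequencyVector,
    RelatednessParameters,
    coefficient_consistency_report,
)

__all__ = [
    "MODE_CONFIGURATIONS",
    "InadmissibleParameterError",
    "ClassSpectrum",
    "DesignMatrix",
    "mode_pair_spectrum",
    "spectrum_from_delta",
    "pair_probability",
    "triplet_probability",
    "quartet_class_probability",
    "classify_pair",
    "genotype_pair_spectrum",
    "class_spectrum",
    "design_matrix",
]

# Detailed ibd partitions of the four gene slots (0,1 = individual A; 2,3 = B)
# realising each condensed mode; a condensed mode expands uniformly over its
# configurations, which is what puts the 1/2 and 1/4 factors into the
# Δ→coefficient map.
MODE_CONFIGURATIONS: dict[int, list[list[tuple[int, ...]]]] = {
    1: [[(0, 1, 2, 3)]],
    2: [[(0, 1), (2, 3)]],
    3: [[(0, 1, 2), (3,)], [(0, 1, 3), (2,)]],
    4: [[(0, 1), (2,), (3,)]],
    5: [[(0, 2, 3), (1,)], [(1, 2, 3), (0,)]],
    6: [[(2, 3), (0,), (1,)]],
    7: [[(0, 2), (1, 3)], [(0, 3), (1, 2)]],
    8: [
        [(0, 2), (1,), (3,)],
        [(0, 3), (1,), (2,)],
        [(1, 2), (0,), (3,)],
        [(1, 3), (0,), (2,)],
    ],
    9: [[(0,), (1,), (2,), (3,)]],
}


class InadmissibleParameterError(ValueError):
    """A coefficient combination produced a negative class probability."""


def mode_pair_spectrum(freqs: AlleleFrequencyVector, mode: int) -> dict:
    """Genotype-pair spectrum under a pure condensed identity mode.

    Every ibd class of every detailed configuration independently receives an
    allele drawn from the population frequencies; the resulting unordered
    genotype pair is tallied.  This is the generative definition of the model.
    """
    p = freqs.p
    k = freqs.n_alleles
    out: dict = {}
    cfgs = MODE_CONFIGURATIONS[mode]
    for part in cfgs:
        for alleles in itertools.product(range(k), repeat=len(part)):
            pr = 1.0
            slot = [0, 0, 0, 0]
            for cls, a in zip(part, alleles):
                pr *= p[a]
                for s in cls:
                    slot[s] = a
            key = (tuple(sorted(slot[:2])), tuple(sorted(slot[2:])))
            out[key] = out.get(key, 0.0) + pr / len(cfgs)
    return out


def spectrum_from_delta(freqs: AlleleFrequencyVector, delta) -> dict:
    """Genotype-pair spectrum as a Δ-weighted mixture of pure modes."""
    delta = np.asarray(delta, dtype=float)
    out: dict = {}
    for m in range(1, 10):
        if delta[m - 1] == 0.0:
            continue
        for key, v in mode_pair_spectrum(freqs, m).items():
            out[key] = out.get(key, 0.0) + delta[m - 1] * v
    return out


# --------------------------------------------------------------------------
# two genes
# --------------------------------------------------------------------------

def pair_probability(
    freqs: AlleleFrequencyVector, theta: float, i, j
) -> float:
    """Probability of an unordered pair of genes given an ibd coefficient.

    f_ii = p_i² + p_i q_i θ and f_ij = 2 p_i p_j (1 − θ); θ is the ibd
    probability of the sampled gene pair (F within an individual, R across
    individuals).
    """
    if not -1e-12 <= theta <= 1 + 1e-12:
        raise ValueError("theta must lie in [0, 1]")
    ii = freqs.index(i) if isinstance(i, str) else int(i)
    jj = freqs.index(j) if isinstance(j, str) else int(j)
    p = freqs.p
    if ii == jj:
        return p[ii] ** 2 + p[ii] * (1 - p[ii]) * theta
    return 2.0 * p[ii] * p[jj] * (1.0 - theta)


# --------------------------------------------------------------------------
# three genes
# --------------------------------------------------------------------------

def _triplet_weights(F: float, R: float, G: float) -> dict[str, float]:
    # identity-mode mixture over three genes (two of A, one of B):
    # all three ibd (G), within-A pair only (F−G), each cross pair (R−G),
    # no identity (1−F−2R+2G)
    return {
        "all": G,
        "within": F - G,
        "cross": R - G,  # each of the two cross pairings
        "none": 1.0 - F - 2.0 * R + 2.0 * G,
    }


def triplet_probability(
    freqs: AlleleFrequencyVector, F: float, R: float, G: float, pattern: str, alleles
) -> float:
    """Probability of a concrete three-gene class (A's unordered genotype plus
    one gene of B).

    Patterns: ``iii`` (A = ii, B gene = i), ``iij`` (A = ii, B gene = j),
    ``iji`` (A heterozygous ij, B gene = i, i.e. sharing with B), ``ijk``
    (A heterozygous, B gene distinct from both).
    """
    w = _triplet_weights(F, R, G)
    idx = [freqs.index(a) if isinstance(a, str) else int(a) for a in alleles]
    p = freqs.p
    if pattern == "iii":
        (i,) = idx
        val = (
            w["none"] * p[i] ** 3
            + (w["within"] + 2 * w["cross"]) * p[i] ** 2
            + w["all"] * p[i]
        )
    elif pattern == "iij":
        i, j = idx
        if i == j:
            raise ValueError("pattern iij needs distinct alleles")
        val = w["none"] * p[i] ** 2 * p[j] + w["within"] * p[i] * p[j]
    elif pattern == "iji":
        i, j = idx
        if i == j:
            raise ValueError("pattern iji needs distinct alleles")
        # A = {i, j} unordered, B gene = i: both orderings of A's genes
        val = 2.0 * (w["none"] * p[i] ** 2 * p[j] + w["cross"] * p[i] * p[j])
    elif pattern == "ijk":
        i, j, k = idx
        if len({i, j, k}) != 3:
            raise ValueError("pattern ijk needs three distinct alleles")
        val = 2.0 * w["none"] * p[i] * p[j] * p[k]
    else:
        raise ValueError(f"unknown three-gene pattern {pattern!r}")
    if val < -1e-12:
        raise InadmissibleParameterError(
            f"negative probability {val:.3g} for class {pattern}{tuple(alleles)} "
            f"at (F={F}, R={R}, G={G})"
        )
    return max(val, 0.0)


# --------------------------------------------------------------------------
# four genes: corrected closed forms, affine in the eight coefficients
# --------------------------------------------------------------------------
#
# Each entry maps a class family to (null probability, {coefficient: slope})
# as functions of the frequencies of the alleles in role order.  Derived
# symbolically from the mode-mixture model; they agree with the clean parts of
# the published transcriptions (f_iiii, f_ijik verbatim) and correct the
# corrupted ones.

def _terms_iiii(p):
    (pi,) = p
    qi = 1 - pi
    return pi**4, {
        "F_A": pi**3 * qi,
        "F_B": pi**3 * qi,
        "R": 4 * pi**3 * qi,
        "G_A": 2 * pi**2 * qi * (1 - 2 * pi),
        "G_B": 2 * pi**2 * qi * (1 - 2 * pi),
        "F_AB": pi**2 * qi**2,
        "R_AB": 2 * pi**2 * qi**2,
        "H": pi * qi * (1 - 6 * pi * qi),
    }


def _terms_ijij(p):
    pi, pj = p
    s = pi + pj - 4 * pi * pj
    return 4 * pi**2 * pj**2, {
        "F_A": -4 * pi**2 * pj**2,
        "F_B": -4 * pi**2 * pj**2,
        "R": 4 * pi * pj * s,
        "G_A": -4 * pi * pj * s,
        "G_B": -4 * pi * pj * s,
        "F_AB": 4 * pi**2 * pj**2,
        "R_AB": 4 * pi * pj * (1 - pi - pj + 2 * pi * pj),
        "H": -4 * pi * pj * (1 - 2 * pi - 2 * pj + 6 * pi * pj),
    }


def _terms_iijj(p):
    # single orientation: A homozygous for the first allele, B for the second
    pi, pj = p
    qi, qj = 1 - pi, 1 - pj
    return pi**2 * pj**2, {
        "F_A": pi * qi * pj**2,
        "F_B": pi**2 * pj * qj,
        "R": -4 * pi**2 * pj**2,
        "G_A": -2 * pi * pj**2 * (1 - 2 * pi),
        "G_B": -2 * pi**2 * pj * (1 - 2 * pj),
        "F_AB": pi * pj * qi * qj,
        "R_AB": 2 * pi**2 * pj**2,
        "H": -pi * pj * (1 - 2 * pi - 2 * pj + 6 * pi * pj),
    }


def _terms_iiij(p):
    # A = ii, B = {i, j}
    pi, pj = p
    qi = 1 - pi
    return 2 * pi**3 * pj, {
        "F_A": 2 * pi**2 * pj * qi,
        "F_B": -2 * pi**3 * pj,
        "R": 4 * pi**2 * pj * (1 - 2 * pi),
        "G_A": 2 * pi * pj * (1 - 2 * pi) ** 2,
        "G_B": -4 * pi**2 * pj * (1 - 2 * pi),
        "F_AB": -2 * pi**2 * pj * qi,
        "R_AB": -4 * pi**2 * pj * qi,
        "H": -2 * pi * pj * (1 - 6 * pi * qi),
    }


def _terms_ijjj(p):
    # A = {i, j}, B = jj: mirror of iiij with individuals exchanged
    pi, pj = p
    qj = 1 - pj
    return 2 * pi * pj**3, {
        "F_A": -2 * pi * pj**3,
        "F_B": 2 * pi * pj**2 * qj,
        "R": 4 * pi * pj**2 * (1 - 2 * pj),
        "G_A": -4 * pi * pj**2 * (1 - 2 * pj),
        "G_B": 2 * pi * pj * (1 - 2 * pj) ** 2,
        "F_AB": -2 * pi * pj**2 * qj,
        "R_AB": -4 * pi * pj**2 * qj,
        "H": -2 * pi * pj * (1 - 6 * pj * qj),
    }


def _terms_iijk(p):
    # A = ii, B = {j, k}: the pair shared only within A
    pi, pj, pk = p
    qi = 1 - pi
    base = 2 * pi * pj * pk
    return pi * base, {
        "F_A": base * qi,
        "F_B": -base * pi,
        "R": -4 * base * pi,
        "G_A": -2 * base * (1 - 2 * pi),
        "G_B": 4 * base * pi,
        "F_AB": -base * qi,
        "R_AB": 2 * base * pi,
        "H": 2 * base * (1 - 3 * pi),
    }


def _terms_ijkk(p):
    # A = {i, j}, B = kk: mirror of iijk
    pi, pj, pk = p
    qk = 1 - pk
    base = 2 * pi * pj * pk
    return pk * base, {
        "F_A": -base * pk,
        "F_B": base * qk,
        "R": -4 * base * pk,
        "G_A": 4 * base * pk,
        "G_B": -2 * base * (1 - 2 * pk),
        "F_AB": -base * qk,
        "R_AB": 2 * base * pk,
        "H": 2 * base * (1 - 3 * pk),
    }


def _terms_ijik(p):
    # A = {i, j}, B = {i, k}: one allele shared once between A and B
    pi, pj, pk = p
    base = 4 * pi * pj * pk
    return pi * base, {
        "F_A": -base * pi,
        "F_B": -base * pi,
        "R": base * (1 - 4 * pi),
        "G_A": -base * (1 - 4 * pi),
        "G_B": -base * (1 - 4 * pi),
        "F_AB": base * pi,
        "R_AB": -base * (1 - 2 * pi),
        "H": 2 * base * (1 - 3 * pi),
    }


def _terms_ijkl(p):
    pi, pj, pk, pl = p
    base = 4 * pi * pj * pk * pl
    return base, {
        "F_A": -base,
        "F_B": -base,
        "R": -4 * base,
        "G_A": 4 * base,
        "G_B": 4 * base,
        "F_AB": base,
        "R_AB": 2 * base,
        "H": -6 * base,
    }


_CLASS_TERMS = {
    "iiii": (_terms_iiii, 1),
    "ijij": (_terms_ijij, 2),
    "iijj": (_terms_iijj, 2),
    "iiij": (_terms_iiij, 2),
    "ijjj": (_terms_ijjj, 2),
    "iijk": (_terms_iijk, 3),
    "ijkk": (_terms_ijkk, 3),
    "ijik": (_terms_ijik, 3),
    "ijkl": (_terms_ijkl, 4),
}

QUARTET_PATTERNS = tuple(_CLASS_TERMS)


def classify_pair(gA: tuple[int, int], gB: tuple[int, int]):
    """Canonical class of an unordered genotype pair.

    Returns ``(pattern, alleles)`` where ``alleles`` are in the role order the
    pattern's formula expects.  Within-individual allele order is ignored; the
    ibs partition of the four slots, tagged by individual of origin, decides
    the class.
    """
    a1, a2 = sorted(gA)
    b1, b2 = sorted(gB)
    homA, homB = a1 == a2, b1 == b2
    if homA and homB:
        return ("iiii", (a1,)) if a1 == b1 else ("iijj", (a1, b1))
    if homA:
        if a1 == b1 or a1 == b2:
            return "iiij", (a1, b2 if a1 == b1 else b1)
        return "iijk", (a1, b1, b2)
    if homB:
        if b1 == a1 or b1 == a2:
            return "ijjj", (a2 if b1 == a1 else a1, b1)
        return "ijkk", (a1, a2, b1)
    if (a1, a2) == (b1, b2):
        return "ijij", (a1, a2)
    shared = set((a1, a2)) & set((b1, b2))
    if shared:
        (s,) = shared
        ja = a2 if a1 == s else a1
        kb = b2 if b1 == s else b1
        return "ijik", (s, ja, kb)
    return "ijkl", (a1, a2, b1, b2)


def quartet_class_probability(
    freqs: AlleleFrequencyVector,
    params: RelatednessParameters,
    pattern: str,
    alleles,
    *,
    check_admissible: bool = True,
) -> float:
    """Probability of one concrete four-gene class, affine in the coefficients.

    ``alleles`` follow the pattern's role order (e.g. ``ijik`` takes the shared
    allele first, then A's other, then B's other).  A warning-free override is
    available by setting ``check_admissible=False``; negative probabilities
    always raise, naming the class.
    """
    try:
        fn, nall = _CLASS_TERMS[pattern]
    except KeyError:
        raise ValueError(f"unknown four-gene pattern {pattern!r}") from None
    idx = [freqs.index(a) if isinstance(a, str) else int(a) for a in alleles]
    if len(idx) != nall or len(set(idx)) != nall:
        raise ValueError(f"pattern {pattern!r} needs {nall} distinct alleles")
    if check_admissible:
        issues = coefficient_consistency_report(params)
        if issues:
            import warnings

            warnings.warn(
                "coefficient set violates ordering constraints: " + "; ".join(issues),
                stacklevel=2,
            )
    null, slopes = fn([freqs.p[i] for i in idx])
    c = params.as_dict()
    val = null + sum(slopes[n] * c[n] for n in COEFFICIENT_NAMES)
    if val < -1e-12:
        raise InadmissibleParameterError(
            f"negative probability {val:.3g} for class {pattern}{tuple(alleles)} "
            f"at {c}"
        )
    return val


def genotype_pair_spectrum(
    freqs: AlleleFrequencyVector, params: RelatednessParameters
) -> dict:
    """Analytic spectrum over all unordered genotype pairs; sums to 1."""
    k = freqs.n_alleles
    out = {}
    genos = [(i, j) for i in range(k) for j in range(i, k)]
    for gA in genos:
        for gB in genos:
            pattern, alleles = classify_pair(gA, gB)
            out[(gA, gB)] = quartet_class_probability(
                freqs, params, pattern, alleles, check_admissible=False
            )
    return out


@dataclass
class ClassSpectrum:
    """Expected probabilities or observed counts of ibs classes at one locus."""

    n_genes: int
    freqs: AlleleFrequencyVector
    probs: dict
    locus: str | None = None

    def total(self) -> float:
        return float(sum(self.probs.values()))

    def as_dataframe(self) -> pd.DataFrame:
        rows = []
        lab = self.freqs.alleles
        for key in sorted(self.probs):
            if self.n_genes == 2:
                pattern = "ii" if key[0] == key[1] else "ij"
                alleles = "/".join(lab[i] for i in key)
            elif self.n_genes == 3:
                (gA, b) = key
                pattern, _ = _classify_triplet(gA, b)
                alleles = "/".join(lab[i] for i in (*gA, b))
            else:
                gA, gB = key
                pattern, _ = classify_pair(gA, gB)
                alleles = "/".join(lab[i] for i in (*gA, *gB))
            rows.append((pattern, alleles, self.probs[key]))
        return pd.DataFrame(rows, columns=["pattern", "alleles", "probability"])


def _classify_triplet(gA, b):
    a1, a2 = gA
    if a1 == a2:
        if b == a1:
            return "iii", (a1,)
        return "iij", (a1, b)
    if b == a1 or b == a2:
        return "iji", (b, a2 if b == a1 else a1)
    return "ijk", (a1, a2, b)


def class_spectrum(
    freqs: AlleleFrequencyVector,
    params: RelatednessParameters,
    n_genes: int,
    locus: str | None = None,
) -> ClassSpectrum:
    """Complete expected spectrum for 2, 3 or 4 genes.

    Two genes use θ = R (a gene of A paired with a gene of B); three genes use
    (F_A, R, G_A) — A's genotype plus one gene of B; four genes use the full
    eight-coefficient model.
    """
    k = freqs.n_alleles
    if n_genes == 2:
        probs = {
            (i, j): pair_probability(freqs, params.R, i, j)
            for i in range(k)
            for j in range(i, k)
        }
    elif n_genes == 3:
        probs = {}
        for i in range(k):
            for j in range(i, k):
                for b in range(k):
                    pattern, alleles = _classify_triplet((i, j), b)
                    probs[((i, j), b)] = triplet_probability(
                        freqs, params.F_A, params.R, params.G_A, pattern, alleles
                    )
    elif n_genes == 4:
        probs = genotype_pair_spectrum(freqs, params)
    else:
        raise ValueError("n_genes must be 2, 3 or 4")
    return ClassSpectrum(n_genes, freqs, probs, locus)


# --------------------------------------------------------------------------
# the 8×8 design system
# --------------------------------------------------------------------------

# class array used for the joint linear solve, in role notation over a chosen
# allele triple (i, j, k)
DESIGN_CLASSES = (
    "iiii", "ijij", "iijj", "iiij", "ijjj", "iijk", "ijkk", "ijik",
)


def _design_keys(i: int, j: int, k: int):
    keys = {
        "iiii": ((i, i), (i, i)),
        "ijij": (tuple(sorted((i, j))), tuple(sorted((i, j)))),
        "iijj": ((i, i), (j, j)),
        "iiij": ((i, i), tuple(sorted((i, j)))),
        "ijjj": (tuple(sorted((i, j))), (j, j)),
        "iijk": ((i, i), tuple(sorted((j, k)))),
        "ijkk": (tuple(sorted((i, j))), (k, k)),
        "ijik": (tuple(sorted((i, j))), tuple(sorted((i, k)))),
    }
    return [keys[c] for c in DESIGN_CLASSES]


@dataclass
class DesignMatrix:
    """Jacobian of the eight chosen class probabilities in the coefficients."""

    matrix: np.ndarray  # (8, 8): rows classes, columns coefficients
    null: np.ndarray  # class probabilities with all coefficients zero
    alleles: tuple[int, int, int]
    class_keys: list
    det: float
    cond: float
    singular: bool


def design_matrix(
    freqs: AlleleFrequencyVector, allele_choice=(0, 1, 2), rel_tol: float = 1e-12
) -> DesignMatrix:
    """Build the 8×8 coefficient→class-probability matrix for an allele triple.

    Because class probabilities are affine in the coefficients, column c is
    exactly the class-probability vector at unit coefficient c minus the null
    vector.  Singularity is decided numerically (|det| below ``rel_tol`` of its
    scale): it occurs e.g. when two chosen alleles share a frequency; the
    offending frequencies are reported via the flag.
    """
    idx = tuple(
        freqs.index(a) if isinstance(a, str) else int(a) for a in allele_choice
    )
    if len(set(idx)) != 3:
        raise ValueError("need three distinct alleles")
    keys = _design_keys(*idx)
    M = np.zeros((8, 8))
    null_params = RelatednessParameters()
    b0 = np.array(
        [
            quartet_class_probability(
                freqs, null_params, *classify_pair(*key), check_admissible=False
            )
            for key in keys
        ]
    )
    for ci, name in enumerate(COEFFICIENT_NAMES):
        params = RelatednessParameters(**{name: 1.0})
        for ri, key in enumerate(keys):
            pattern, alleles = classify_pair(*key)
            fn, _ = _CLASS_TERMS[pattern]
            _, slopes = fn([freqs.p[a] for a in alleles])
            M[ri, ci] = slopes[name]
    det = float(np.linalg.det(M))
    scale = float(np.prod(np.linalg.norm(M, axis=0))) or 1.0
    singular = abs(det) < rel_tol * scale
    cond = float(np.linalg.cond(M)) if not singular else float("inf")
    return DesignMatrix(M, b0, idx, keys, det, cond, singular)
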