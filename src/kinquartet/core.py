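"""Parameter spaces of pairwise gene identity and the mappings among them.

Two diploid individuals A and B carry four genes at a locus.  The distribution
of identity-by-descent (ibd) among those four genes is fully described by the
nine condensed Jacquard identity modes Δ1…Δ9; equivalently by eight marginal
coefficients of relatedness:

========  =============================================================
F_A, F_B  inbreeding coefficients (the two genes within A, resp. B, ibd)
R         kinship-scale pairwise coefficient: one random gene of A and
          one of B are ibd
G_A, G_B  three-gene coefficients: both genes of one individual plus one
          random gene of the other are all ibd
F_AB      both within-individual pairs are simultaneously ibd
R_AB      both cross pairings of A's genes with B's genes are ibd
H         all four genes ibd; equals the normalised fourth cumulant of
          allele indicators
========  =============================================================

F_AB and R_AB are covariance-bearing: under a population mixture they carry
Cov(F_A, F_B) and Cov(R, R') on top of the products F_A·F_B and R².  This
module also provides the normalisation constants (maximum attainable central
moments of an allele indicator), moment→cumulant conversions, and exact pooled
moments under finite population mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "COEFFICIENT_NAMES",
    "AlleleFrequencyVector",
    "JacquardVector",
    "RelatednessParameters",
    "CumulantSet",
    "MixtureComponent",
    "MixtureModel",
    "validate_frequencies",
    "jacquard_to_coefficients",
    "coefficients_to_delta",
    "delta_from_F_R",
    "normalization_constant",
    "central_moments_to_cumulants",
    "fourth_cross_cumulant",
    "mixture_moments",
    "effective_selfing",
    "coefficient_consistency_report",
]

COEFFICIENT_NAMES = ("F_A", "F_B", "R", "G_A", "G_B", "F_AB", "R_AB", "H")


class FrequencyError(ValueError):
    """Raised when an allele-frequency specification is invalid."""


@dataclass(frozen=True)
class AlleleFrequencyVector:
    """Ordered allele labels with strictly positive frequencies summing to 1."""

    alleles: tuple[str, ...]
    p: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        if len(self.alleles) != len(self.p):
            raise FrequencyError("allele labels and frequencies differ in length")
        if len(self.alleles) < 2:
            raise FrequencyError(
                "need at least two alleles; a monomorphic locus is uninformative"
            )
        if len(set(self.alleles)) != len(self.alleles):
            raise FrequencyError("duplicate allele labels")
        if np.any(self.p <= 0.0):
            raise FrequencyError("allele frequencies must be strictly positive")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise FrequencyError(
                f"frequencies sum to {self.p.sum():.8g}, not 1 (use validate_frequencies)"
            )

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def index(self, label: str) -> int:
        try:
            return self.alleles.index(label)
        except ValueError:
            raise KeyError(f"unknown allele label {label!r}") from None


def validate_frequencies(raw) -> AlleleFrequencyVector:
    """Build an :class:`AlleleFrequencyVector` from ``(label, frequency)`` pairs.

    Frequencies must be strictly positive and sum to 1 within 1e-6; the sum is
    then renormalised exactly.  Ordering of the input is preserved.
    """
    raw = list(raw)
    if not raw:
        raise FrequencyError("empty frequency list")
    labels = tuple(str(lab) for lab, _ in raw)
    p = np.array([float(f) for _, f in raw])
    if np.any(p <= 0.0):
        bad = [labels[i] for i in np.nonzero(p <= 0.0)[0]]
        raise FrequencyError(f"non-positive frequency for allele(s) {bad}")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise FrequencyError(f"frequencies sum to {total:.8g}, expected 1 within 1e-6")
    if len(labels) < 2:
        raise FrequencyError(
            "need at least two alleles; a monomorphic locus is uninformative"
        )
    return AlleleFrequencyVector(labels, p / total)


@dataclass(frozen=True)
class JacquardVector:
    """The nine condensed identity-mode probabilities Δ1…Δ9."""

    delta: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.delta, dtype=float)
        if d.shape != (9,):
            raise ValueError("expected exactly nine Δ probabilities")
        if np.any(d < -1e-12) or np.any(d > 1 + 1e-12):
            raise ValueError("each Δ must lie in [0, 1]")
        if abs(d.sum() - 1.0) > 1e-8:
            raise ValueError(f"Δ sum to {d.sum():.8g}, not 1")
        d = np.clip(d, 0.0, 1.0)
        object.__setattr__(self, "delta", d / d.sum())

    @classmethod
    def pure(cls, mode: int) -> "JacquardVector":
        if not 1 <= mode <= 9:
            raise ValueError("mode must be in 1..9")
        d = np.zeros(9)
        d[mode - 1] = 1.0
        return cls(d)


@dataclass(frozen=True)
class RelatednessParameters:
    """The eight marginal coefficients of relatedness for a pair of diploids."""

    F_A: float = 0.0
    F_B: float = 0.0
    R: float = 0.0
    G_A: float = 0.0
    G_B: float = 0.0
    F_AB: float = 0.0
    R_AB: float = 0.0
    H: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in COEFFICIENT_NAMES])

    @classmethod
    def from_array(cls, arr) -> "RelatednessParameters":
        return cls(**dict(zip(COEFFICIENT_NAMES, map(float, arr))))

    @classmethod
    def null(cls) -> "RelatednessParameters":
        return cls()

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in COEFFICIENT_NAMES}


def jacquard_to_coefficients(d: JacquardVector) -> RelatednessParameters:
    """Map condensed identity modes to the eight relatedness coefficients.

    Modes that realise an identity event only for some of the equally likely
    detailed configurations contribute with the corresponding fraction:
    Δ3, Δ5 and Δ7 realise a given cross pairing half the time, Δ8 a quarter.
    """
    d1, d2, d3, d4, d5, d6, d7, d8, d9 = d.delta
    return RelatednessParameters(
        F_A=d1 + d2 + d3 + d4,
        F_B=d1 + d2 + d5 + d6,
        R=d1 + (d3 + d5 + d7) / 2 + d8 / 4,
        G_A=d1 + d3 / 2,
        G_B=d1 + d5 / 2,
        F_AB=d1 + d2,
        R_AB=d1 + d7 / 2,
        H=d1,
    )


def coefficients_to_delta(params: RelatednessParameters) -> np.ndarray:
    """Invert :func:`jacquard_to_coefficients` (the map is affine and bijective).

    The result is a 9-vector summing to 1 but may leave the probability simplex
    when the coefficients do not derive from a proper Jacquard vector; the
    linear extension is what makes class probabilities affine in the
    coefficients.
    """
    c = params
    d1 = c.H
    d2 = c.F_AB - c.H
    d3 = 2 * (c.G_A - c.H)
    d5 = 2 * (c.G_B - c.H)
    d4 = c.F_A - c.F_AB - d3
    d6 = c.F_B - c.F_AB - d5
    d7 = 2 * (c.R_AB - c.H)
    d8 = 4 * (c.R + 2 * c.H - c.G_A - c.G_B - c.R_AB)
    d9 = 1.0 - (d1 + d2 + d3 + d4 + d5 + d6 + d7 + d8)
    return np.array([d1, d2, d3, d4, d5, d6, d7, d8, d9])


def delta_from_F_R(F: float, R: float) -> JacquardVector:
    """Jacquard vector for two equally inbred individuals with independent
    inbreeding (F_AB = F²) and independent cross-pair identity (R_AB = R²),
    no three- or four-gene identity beyond those products."""
    if not (0 <= F <= 1 and 0 <= R <= 1):
        raise ValueError("F and R must lie in [0, 1]")
    d = np.zeros(9)
    d[1] = F * F
    d[3] = F - F * F
    d[5] = F - F * F
    d[6] = 2 * R * R
    d[7] = 4 * R * (1 - R)
    d[8] = 1 - d[:8].sum()
    if d[8] < -1e-12:
        raise ValueError(f"(F={F}, R={R}) admits no such identity-mode vector")
    d[8] = max(d[8], 0.0)
    return JacquardVector(d)


def normalization_constant(order: int, p_i: float) -> float:
    """Maximum attainable central moment of a Bernoulli(p) allele indicator.

    order 2: p·q,  order 3: p·q·(1−2p),  order 4 (cumulant): p·q·(1−6pq),
    with q = 1−p.  These are the denominators converting raw configuration
    frequencies into probability-scale coefficients.
    """
    if not 0.0 < p_i < 1.0:
        raise ValueError("p_i must lie strictly in (0, 1)")
    q = 1.0 - p_i
    if order == 2:
        return p_i * q
    if order == 3:
        return p_i * q * (1.0 - 2.0 * p_i)
    if order == 4:
        return p_i * q * (1.0 - 6.0 * p_i * q)
    raise ValueError("order must be 2, 3 or 4")


@dataclass(frozen=True)
class CumulantSet:
    """Cumulants κ1..κ4 of a univariate random variable.

    Cumulants equal central moments through order 3; at order 4,
    κ4 = μ4c − 3κ2², the part of the fourth moment not explained by the
    variance (the excess-kurtosis numerator).
    """

    kappa1: float
    kappa2: float
    kappa3: float
    kappa4: float

    @classmethod
    def from_central_moments(cls, mean, mu2, mu3, mu4) -> "CumulantSet":
        return cls(mean, mu2, mu3, mu4 - 3.0 * mu2 * mu2)

    @classmethod
    def bernoulli(cls, p: float) -> "CumulantSet":
        q = 1.0 - p
        return cls.from_central_moments(
            p, p * q, p * q * (q - p), p * q * (1 - 3 * p * q)
        )


def central_moments_to_cumulants(mean, mu2, mu3, mu4) -> CumulantSet:
    """Univariate central moments through order 4 → cumulants."""
    return CumulantSet.from_central_moments(mean, mu2, mu3, mu4)


def fourth_cross_cumulant(mu4c: float, cov: np.ndarray) -> float:
    """Four-variate cumulant κ_1234 from the fourth central cross moment.

    κ_1234 = μ_1234c − σ12σ34 − σ13σ24 − σ14σ23, the standard three-pairing
    expansion; ``cov`` is the 4×4 covariance matrix of the variates.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (4, 4):
        raise ValueError("cov must be a 4x4 covariance matrix")
    return (
        mu4c
        - cov[0, 1] * cov[2, 3]
        - cov[0, 2] * cov[1, 3]
        - cov[0, 3] * cov[1, 2]
    )


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    freqs: AlleleFrequencyVector
    F: float = 0.0
    R: float = 0.0


@dataclass(frozen=True)
class MixtureModel:
    """Finite mixture of subpopulations differing in allele frequency (and
    optionally in within-component F and R).  Mixtures generate identity
    disequilibrium: per-component cumulants covary, so E[κ_i,m·κ_j,m] ≠ κ_i·κ_j."""

    components: tuple[MixtureComponent, ...]

    def __post_init__(self):
        if not self.components:
            raise ValueError("mixture needs at least one component")
        w = np.array([c.weight for c in self.components])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixing weights must be nonnegative and sum to 1")
        labels = {c.freqs.alleles for c in self.components}
        if len(labels) != 1:
            raise ValueError("all components must share one allele label set")

    @classmethod
    def two_population(cls, p: float, a: float) -> "MixtureModel":
        """Canonical biallelic two-component model with frequencies p±a in
        equal proportions — the simplest generator of covariance of
        homozygosity across loci."""
        if not (0 < p - a and p + a < 1):
            raise ValueError("need 0 < p−a and p+a < 1")
        if a == 0.0:
            f = validate_frequencies([("A", p), ("a", 1 - p)])
            return cls((MixtureComponent(0.5, f), MixtureComponent(0.5, f)))
        hi = validate_frequencies([("A", p + a), ("a", 1 - p - a)])
        lo = validate_frequencies([("A", p - a), ("a", 1 - p + a)])
        return cls((MixtureComponent(0.5, hi), MixtureComponent(0.5, lo)))


def mixture_moments(model: MixtureModel) -> dict:
    """Exact pooled moments of allele indicators under a finite mixture.

    Brute-force expectation over components: for each allele, the pooled mean
    frequency, the pooled central moments/cumulants of the allele indicator,
    the across-component variance of the component frequency and of the
    component homozygosity p_m² (the driver of covariance of homozygosity),
    plus the expected and across-component-variance of total HWE homozygosity
    Σ_i p_{m,i}².  With identical components every across-component variance
    is exactly zero.
    """
    w = np.array([c.weight for c in model.components])
    labels = model.components[0].freqs.alleles
    P = np.array([c.freqs.p for c in model.components])  # (m, k)
    pooled = w @ P
    out_alleles = {}
    for j, lab in enumerate(labels):
        pm = P[:, j]
        pbar = pooled[j]
        # pooled central moments of the indicator X ~ mixture of Bernoulli(pm)
        mus = []
        for order in (2, 3, 4):
            mom = w @ (pm * (1 - pbar) ** order + (1 - pm) * (0 - pbar) ** order)
            mus.append(float(mom))
        cum = CumulantSet.from_central_moments(pbar, *mus)
        var_pm = float(w @ (pm - pbar) ** 2)
        hom = pm**2
        var_hom = float(w @ (hom - w @ hom) ** 2)
        out_alleles[lab] = {
            "pooled_p": float(pbar),
            "central_moments": dict(zip(("mu2", "mu3", "mu4"), mus)),
            "cumulants": cum,
            "var_component_freq": var_pm,
            "var_component_homozygosity": var_hom,
        }
    total_hom = (P**2).sum(axis=1)
    return {
        "alleles": out_alleles,
        "pooled_frequencies": dict(zip(labels, map(float, pooled))),
        "expected_homozygosity": float(w @ total_hom),
        "var_component_total_homozygosity": float(
            w @ (total_hom - w @ total_hom) ** 2
        ),
    }


def effective_selfing(R: float, G: float) -> tuple[float, bool]:
    """Effective selfing rate s = 2R − G (R: relatedness between mates, G the
    three-gene coefficient over the two maternal genes and the paternal gene).

    Returns ``(s, in_range)``; values outside [0, 1] are flagged, never clamped.
    """
    if not (0 <= R <= 1 and 0 <= G <= 1):
        raise ValueError("R and G must lie in [0, 1]")
    s = 2.0 * R - G
    return s, 0.0 <= s <= 1.0


# ordering constraints every Δ-derived coefficient set satisfies
_ORDER_CONSTRAINTS = [
    ("H", "G_A"), ("H", "G_B"), ("G_A", "F_A"), ("G_B", "F_B"),
    ("H", "F_AB"), ("F_AB", "F_A"), ("F_AB", "F_B"),
    ("H", "R_AB"), ("R_AB", "R"),
]


def coefficient_consistency_report(
    params: RelatednessParameters, tol: float = 1e-12
) -> list[str]:
    """Ordering inequalities violated by a coefficient set.

    Empty for any coefficients derived from a proper Jacquard vector; used as a
    soft admissibility diagnostic for estimator output (covariance-bearing
    F_AB/R_AB under mixtures may legitimately exceed pure-probability bounds).
    """
    vals = params.as_dict()
    out = []
    for lo, hi in _ORDER_CONSTRAINTS:
        if vals[lo] > vals[hi] + tol:
            out.append(f"{lo} ≤ {hi} violated ({vals[lo]:.6g} > {vals[hi]:.6g})")
    for name, v in vals.items():
        if v < -tol or v > 1 + tol:
            out.append(f"{name} outside [0, 1] ({v:.6g})")
    return out
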