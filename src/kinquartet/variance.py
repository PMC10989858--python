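"""Exact sampling variances of single-locus estimators by full enumeration.

Single-locus estimators of relatedness coefficients have notoriously large —
and at special frequencies infinite — sampling variances.  This module
enumerates every genotype (for F) or ordered genotype pair (for R, G, H)
configuration, weights it by the exact model probability at stated true
values, applies the estimator, and reports its exact mean and variance.  The
mean always equals the true value wherever the estimator is estimable
(unbiasedness is asserted, not assumed).

Weighting variants for combining per-allele components:

* ``minvar``            — exact minimum-variance weights at the truth
* ``zero_prior``        — the closed form w_i = (1 − p_i)/(n − 1)
* ``equal``             — equal weights over estimable components
* ``inverse_variance``  — weights ∝ 1/Var(component), covariances ignored
* ``("single", i)``     — all weight on one allele (component variance)

The G columns of the reference-style table additionally expose the
single-pattern component variances Var(Ĝ_iii) and Var(Ĝ_iij) at a designated
allele pair, which is the only identifiable convention behind published
single-locus variance tables; cells whose focal component is singular are
marked "x".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AlleleFrequencyVector, RelatednessParameters, validate_frequencies
from .components import component_system, minimum_variance_weights

__all__ = [
    "VarianceEntry",
    "VarianceReport",
    "exact_estimator_variance",
    "g_pattern_component_variance",
    "variance_table",
]

_TRUTH_ATTR = {"F": "F_A", "R": "R", "G_A": "G_A", "G_B": "G_B", "H": "H"}


@dataclass
class VarianceEntry:
    estimator: str
    freqs: AlleleFrequencyVector
    mean: float
    variance: float
    weighting: object
    weights: dict
    estimable: bool
    flags: list[str] = field(default_factory=list)
    n_configurations: int = 0


@dataclass
class VarianceReport:
    entries: list[VarianceEntry]

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "estimator": e.estimator,
                    "array": ",".join(f"{x:g}" for x in e.freqs.p),
                    "mean": e.mean,
                    "variance": e.variance,
                    "estimable": e.estimable,
                }
                for e in self.entries
            ]
        )


def exact_estimator_variance(
    estimator: str,
    freqs: AlleleFrequencyVector,
    truth: RelatednessParameters | None = None,
    weighting="minvar",
) -> VarianceEntry:
    """Exact mean and variance of a weighted single-locus estimator.

    ``estimator`` is one of F, R, G_A, G_B, H.  The enumeration covers the
    relevant observation unit completely; mean equals the corresponding truth
    component to numerical precision wherever estimable.
    """
    truth = truth or RelatednessParameters()
    sys = component_system("F" if estimator == "F" else estimator, freqs, truth)
    mean_c, V = sys.moments()
    flags = []
    estimable = sys.estimable.copy()
    for a, lab in enumerate(freqs.alleles):
        if not estimable[a]:
            flags.append(f"component {lab} non-estimable at p = {freqs.p[a]:g}")

    k = freqs.n_alleles
    w = np.zeros(k)
    if isinstance(weighting, tuple) and weighting[0] == "single":
        a = weighting[1]
        if not estimable[a]:
            return VarianceEntry(
                estimator, freqs, np.nan, np.nan, weighting, {},
                False, flags + ["requested single component non-estimable"],
                len(sys.probs),
            )
        w[a] = 1.0
    elif not estimable.any():
        return VarianceEntry(
            estimator, freqs, np.nan, np.nan, weighting, {}, False,
            flags + ["no estimable component"], len(sys.probs),
        )
    elif weighting == "minvar":
        w, fb = minimum_variance_weights(V, estimable)
        if fb:
            flags.append("covariance singular; equal weights used")
    elif weighting == "zero_prior":
        q = (1 - freqs.p) * estimable
        w = q / q.sum()
    elif weighting == "equal":
        w[estimable] = 1.0 / estimable.sum()
    elif weighting == "inverse_variance":
        inv = np.where(estimable, 1.0 / np.maximum(np.diag(V), 1e-300), 0.0)
        w = inv / inv.sum()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    mean = float(w @ mean_c)
    var = float(w @ V @ w)
    target = _TRUTH_ATTR[estimator]
    expected = getattr(truth, target)
    if abs(mean - expected) > 1e-8:
        flags.append(
            f"enumeration mean {mean:.6g} deviates from truth {expected:.6g}"
        )
    return VarianceEntry(
        estimator, freqs, mean, var, weighting,
        {lab: float(w[a]) for a, lab in enumerate(freqs.alleles)},
        True, flags, len(sys.probs),
    )


def g_pattern_component_variance(
    freqs: AlleleFrequencyVector,
    pattern: str,
    alleles: tuple[int, int] | tuple[int],
    truth: RelatednessParameters | None = None,
) -> float:
    """Exact null-truth variance of a single-pattern three-gene component.

    ``iii``: Ĝ from the indicator of (A homozygous i, B gene = i), denominator
    p q (1 − 2p); ``iij``: Ĝ from (A homozygous i, B gene = j), denominator
    p_i p_j (2p_i − 1).  Returns NaN at the p = 1/2 singularity.
    """
    truth = truth or RelatednessParameters()
    p = freqs.p
    k = freqs.n_alleles
    if pattern == "iii":
        (i,) = alleles
        denom = p[i] * (1 - p[i]) * (1 - 2 * p[i])
        shift = p[i] ** 3 + p[i] ** 2 * (1 - p[i]) * (truth.F_A + 2 * truth.R)
        focal = ((i, i), i)
    elif pattern == "iij":
        i, j = alleles
        denom = p[i] * p[j] * (2 * p[i] - 1)
        # inverted iij class: Ĝ = (T − p_i²p_j − p_ip_jF + p_i²p_j(F+2R)) / denom
        shift = p[i] ** 2 * p[j] + p[i] * p[j] * truth.F_A - p[i] ** 2 * p[j] * (
            truth.F_A + 2 * truth.R
        )
        focal = ((i, i), j)
    else:
        raise ValueError("pattern must be 'iii' or 'iij'")
    if abs(denom) < 1e-12:
        return float("nan")
    # the unit is a gene triplet: A's genotype plus one gene of B
    from .genoprob import _classify_triplet, triplet_probability

    vals, probs = [], []
    for gi in range(k):
        for gj in range(gi, k):
            for b in range(k):
                pat, alls = _classify_triplet((gi, gj), b)
                probs.append(
                    triplet_probability(
                        freqs, truth.F_A, truth.R, truth.G_A, pat, alls
                    )
                )
                vals.append(1.0 if ((gi, gj), b) == focal else 0.0)
    vals = (np.array(vals) - shift) / denom
    probs = np.array(probs)
    m = probs @ vals
    return float(probs @ (vals - m) ** 2)


def variance_table(
    arrays,
    truth: RelatednessParameters | None = None,
    weighting="minvar",
    g_alleles: tuple[int, int] = (0, 1),
) -> pd.DataFrame:
    """Null variances of the single-locus estimators, one row per array.

    Columns F, phi_XY (the pairwise coefficient R) and H report the weighted
    estimator variance under ``weighting``; G_A and G_B report the
    single-pattern component variances (iii resp. iij) at the designated
    allele pair ``g_alleles`` — "x" marks non-estimable cells (the p = 1/2
    singularity of the three-gene denominators).
    """
    truth = truth or RelatednessParameters()
    rows = []
    for arr in arrays:
        if isinstance(arr, AlleleFrequencyVector):
            afv = arr
        else:
            afv = validate_frequencies(
                [(f"A{i+1}", float(x)) for i, x in enumerate(arr)]
            )
        row = {"array": ",".join(f"{x:g}" for x in afv.p)}
        for col, est in (("F", "F"), ("phi_XY", "R"), ("H", "H")):
            e = exact_estimator_variance(est, afv, truth, weighting)
            row[col] = e.variance if e.estimable else float("nan")
        row["G_A"] = g_pattern_component_variance(afv, "iii", (g_alleles[0],), truth)
        row["G_B"] = g_pattern_component_variance(afv, "iij", tuple(g_alleles), truth)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["array", "F", "G_A", "G_B", "phi_XY", "H"])
    return df


def format_table(df: pd.DataFrame, digits: int = 2) -> str:
    """Serialise a variance table with 'x' for non-estimable cells."""
    out = df.copy()
    for c in out.columns[1:]:
        out[c] = [
            "x" if (isinstance(v, float) and np.isnan(v)) else f"{v:.{digits}f}"
            for v in out[c]
        ]
    return out.to_csv(sep="\t", index=False)
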