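"""Multinomial maximum likelihood for relatedness coefficients across loci.

The model is a genuine finite mixture: each genotype-pair observation carries
a latent condensed identity mode drawn from Δ, so EM applies directly on the
Δ simplex — the E-step computes posterior mode memberships, the M-step
averages them — and estimates are admissible by construction.  The fitted Δ
maps to the eight coefficients.  EM is known to converge slowly here; the
fitter therefore multi-starts (uniform Δ, an unrelated-heavy start, and a
moment-derived start) and reports iteration counts and the final
log-likelihood change.  Loci are treated as independent (single-locus
probability structure; no linkage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AlleleFrequencyVector,
    JacquardVector,
    RelatednessParameters,
    jacquard_to_coefficients,
)
from .estimators import EstimateResult
from .genoprob import mode_pair_spectrum

__all__ = ["FitConfig", "LocusCounts", "tabulate_counts", "loglikelihood", "fit_ml"]

_PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class FitConfig:
    tol: float = 1e-8  # absolute change in log-likelihood
    max_iter: int = 5000
    init: np.ndarray | None = None  # Δ start overriding the multi-start set
    multi_start: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be ≥ 1")


@dataclass
class LocusCounts:
    """Observed genotype-pair class counts at one locus, with the 9-mode
    likelihood matrix for the observed classes."""

    locus: str
    freqs: AlleleFrequencyVector
    keys: list
    counts: np.ndarray  # (n_classes,)
    mode_probs: np.ndarray  # (n_classes, 9)


def tabulate_counts(
    table: pd.DataFrame, freqs_by_locus: dict[str, AlleleFrequencyVector]
) -> list[LocusCounts]:
    """Aggregate a genotype table into per-locus class counts."""
    out = []
    for locus, sub in table.groupby("locus", sort=True):
        afv = freqs_by_locus[str(locus)]
        idx = {lab: i for i, lab in enumerate(afv.alleles)}
        keys = {}
        for a1, a2, b1, b2 in sub[["a1", "a2", "b1", "b2"]].itertuples(index=False):
            key = (
                tuple(sorted((idx[a1], idx[a2]))),
                tuple(sorted((idx[b1], idx[b2]))),
            )
            keys[key] = keys.get(key, 0) + 1
        klist = sorted(keys)
        counts = np.array([keys[k] for k in klist], dtype=float)
        L = np.zeros((len(klist), 9))
        for m in range(1, 10):
            spec = mode_pair_spectrum(afv, m)
            L[:, m - 1] = [spec.get(k, 0.0) for k in klist]
        out.append(LocusCounts(str(locus), afv, klist, counts, L))
    return out


def _delta_of(params) -> np.ndarray:
    if isinstance(params, JacquardVector):
        return params.delta
    if isinstance(params, RelatednessParameters):
        from .core import coefficients_to_delta

        return coefficients_to_delta(params)
    return np.asarray(params, dtype=float)


def loglikelihood(data: list[LocusCounts], params) -> float:
    """Σ_loci Σ_classes count · log f_class; probabilities floored at 1e-300.

    An observed class with structurally zero probability under the given
    parameters (zero for every latent mode with positive weight) is reported
    via a warning rather than silently floored.
    """
    delta = _delta_of(params)
    total = 0.0
    for lc in data:
        probs = lc.mode_probs @ delta
        bad = (probs <= 0) & (lc.counts > 0)
        if np.any(bad):
            import warnings

            warnings.warn(
                f"locus {lc.locus}: {int(bad.sum())} observed class(es) have zero "
                "probability under the supplied parameters",
                stacklevel=2,
            )
        total += float(lc.counts @ np.log(np.maximum(probs, _PROB_FLOOR)))
    return total


def _em(data: list[LocusCounts], delta0: np.ndarray, config: FitConfig):
    delta = np.maximum(np.asarray(delta0, dtype=float), 1e-12)
    delta = delta / delta.sum()
    n_obs = sum(lc.counts.sum() for lc in data)
    trace = [loglikelihood(data, delta)]
    converged = False
    for it in range(1, config.max_iter + 1):
        acc = np.zeros(9)
        for lc in data:
            num = lc.mode_probs * delta  # (classes, 9)
            denom = np.maximum(num.sum(axis=1, keepdims=True), _PROB_FLOOR)
            acc += (lc.counts[:, None] * (num / denom)).sum(axis=0)
        delta = acc / n_obs
        ll = loglikelihood(data, delta)
        trace.append(ll)
        if abs(trace[-1] - trace[-2]) < config.tol:
            converged = True
            break
    return delta, np.array(trace), converged


def _moment_start(data: list[LocusCounts]) -> np.ndarray | None:
    from .estimators import estimate_all_eight
    from .genoprob import ClassSpectrum
    from .core import coefficients_to_delta

    # pool the first adequately polymorphic locus for a rough moment start
    for lc in data:
        if lc.freqs.n_alleles < 3:
            continue
        spec = ClassSpectrum(4, lc.freqs, dict(zip(lc.keys, lc.counts)))
        p = lc.freqs.p
        order = np.argsort(-p)[:3]
        try:
            res = estimate_all_eight(spec, tuple(int(a) for a in order))
        except Exception:
            continue
        if any(np.isnan(v) for v in res.estimates.values()):
            continue
        d = coefficients_to_delta(RelatednessParameters(**res.estimates))
        if np.all(np.isfinite(d)):
            d = np.clip(d, 1e-6, None)
            return d / d.sum()
    return None


def fit_ml(
    table_or_counts,
    freqs_by_locus: dict[str, AlleleFrequencyVector] | None = None,
    config: FitConfig | None = None,
) -> EstimateResult:
    """Maximum-likelihood Δ (and coefficients) by EM over latent modes.

    Accepts either a genotype table plus per-locus frequencies, or
    pre-tabulated :class:`LocusCounts`.  The log-likelihood is non-decreasing
    at every iteration; non-convergence within the iteration budget and
    boundary estimates are flagged, never hidden.
    """
    config = config or FitConfig()
    if isinstance(table_or_counts, pd.DataFrame):
        if freqs_by_locus is None:
            raise ValueError("per-locus frequencies required with a genotype table")
        data = tabulate_counts(table_or_counts, freqs_by_locus)
    else:
        data = list(table_or_counts)
    if not data:
        raise ValueError("no loci to fit")

    if config.init is not None:
        starts = [np.asarray(config.init, dtype=float)]
    else:
        starts = [np.full(9, 1 / 9)]
        if config.multi_start:
            null_heavy = np.full(9, 0.1 / 8)
            null_heavy[8] = 0.9
            starts.append(null_heavy)
            ms = _moment_start(data)
            if ms is not None:
                starts.append(ms)

    best = None
    for d0 in starts:
        delta, trace, converged = _em(data, d0, config)
        if best is None or trace[-1] > best[1][-1]:
            best = (delta, trace, converged)
    delta, trace, converged = best

    if np.any(np.diff(trace) < -1e-7):
        raise RuntimeError("EM log-likelihood decreased; this is a bug")

    flags = []
    if not converged:
        flags.append(f"not converged after {len(trace) - 1} iterations")
    boundary = np.nonzero(delta < 1e-6)[0]
    if boundary.size:
        flags.append(
            "boundary estimate for Δ" + ",Δ".join(str(i + 1) for i in boundary)
        )
    coeffs = jacquard_to_coefficients(JacquardVector(delta / delta.sum()))
    return EstimateResult(
        estimates=coeffs.as_dict(),
        method="ml:em",
        components={"delta": {f"D{i+1}": float(d) for i, d in enumerate(delta)}},
        flags=flags,
        extras={
            "iterations": len(trace) - 1,
            "loglik": float(trace[-1]),
            "final_change": float(abs(trace[-1] - trace[-2])) if len(trace) > 1 else 0.0,
            "trace": trace,
            "converged": converged,
        },
    )
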