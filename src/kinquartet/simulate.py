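"""Genotype-pair simulation under the identity-mode model.

A pair of diploids is simulated at one locus by (i) drawing a condensed
Jacquard mode from Δ, (ii) expanding it uniformly at random to one of its
detailed configurations (which gene of B joins the triplet for Δ3/Δ5, which
cross pairing for Δ7, which single pair for Δ8), and (iii) assigning one
allele per ibd class, iid from the population frequencies.  Uniform expansion
is forced by consistency with the Δ→coefficient map and is validated against
the analytic class spectrum.

Population mixtures assign each *pair* to one component for all of its loci;
sharing the component across loci is exactly what generates identity
disequilibrium — the across-locus covariance of homozygosity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AlleleFrequencyVector, JacquardVector
from .genoprob import MODE_CONFIGURATIONS

__all__ = [
    "GenotypePair",
    "MixtureSpec",
    "SimulationDesign",
    "sample_pair",
    "simulate_dataset",
    "simulate_mixture",
    "empirical_identity_disequilibrium",
]

# flattened (mode, configuration) table: slot -> ibd-class index
_FLAT = []
for _m in range(1, 10):
    for _cfg in MODE_CONFIGURATIONS[_m]:
        slot_class = np.empty(4, dtype=np.int64)
        for ci, cls in enumerate(_cfg):
            for s in cls:
                slot_class[s] = ci
        _FLAT.append((_m, slot_class))
_FLAT_MODE = np.array([m for m, _ in _FLAT])
_FLAT_SLOTS = np.stack([s for _, s in _FLAT])  # (19, 4)
_CFG_COUNT = {m: len(MODE_CONFIGURATIONS[m]) for m in range(1, 10)}


@dataclass(frozen=True)
class GenotypePair:
    pair_id: str
    locus: str
    gA: tuple
    gB: tuple
    mode: int | None = None
    component: int | None = None


@dataclass(frozen=True)
class MixtureSpec:
    """Per-component simulation inputs: weight, Δ and per-locus frequencies."""

    weights: tuple[float, ...]
    deltas: tuple[JacquardVector, ...]
    freqs_by_component: tuple[tuple[AlleleFrequencyVector, ...], ...]

    def __post_init__(self):
        w = np.asarray(self.weights)
        if np.any(w < 0) or abs(w.sum() - 1) > 1e-9:
            raise ValueError("mixture weights must be nonnegative and sum to 1")
        if not len(self.weights) == len(self.deltas) == len(self.freqs_by_component):
            raise ValueError("component lists differ in length")


@dataclass(frozen=True)
class SimulationDesign:
    delta: JacquardVector
    freqs: tuple[AlleleFrequencyVector, ...]
    n_pairs: int
    seed: int
    mixture: MixtureSpec | None = None
    keep_latent: bool = False

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be ≥ 1")
        if len(self.freqs) < 1:
            raise ValueError("need at least one locus")

    @property
    def n_loci(self) -> int:
        return len(self.freqs)


def _expand_modes(modes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw a uniform detailed configuration (flat index) per condensed mode."""
    offsets = np.zeros(10, dtype=np.int64)
    flat = np.empty_like(modes)
    start = 0
    for m in range(1, 10):
        offsets[m] = start
        start += _CFG_COUNT[m]
    for m in range(1, 10):
        sel = modes == m
        n = int(sel.sum())
        if n:
            flat[sel] = offsets[m] + rng.integers(0, _CFG_COUNT[m], size=n)
    return flat


def _sample_block(
    delta: np.ndarray,
    p: np.ndarray,
    n: int,
    rng: np.random.Generator,
):
    """Vectorised draw of n genotype pairs at one locus; returns genotype
    arrays (n, 2) for A and B plus the latent condensed mode."""
    modes = rng.choice(np.arange(1, 10), size=n, p=delta)
    flat = _expand_modes(modes, rng)
    class_alleles = rng.choice(len(p), size=(n, 4), p=p)
    slots = _FLAT_SLOTS[flat]  # (n, 4) slot -> class
    g = np.take_along_axis(class_alleles, slots, axis=1)
    gA = np.sort(g[:, :2], axis=1)
    gB = np.sort(g[:, 2:], axis=1)
    return gA, gB, modes


def sample_pair(
    delta: JacquardVector,
    freqs: AlleleFrequencyVector,
    rng: np.random.Generator,
    pair_id: str = "pair0",
    locus: str = "L0",
) -> GenotypePair:
    """Draw a single genotype pair (scalar convenience path)."""
    gA, gB, modes = _sample_block(delta.delta, freqs.p, 1, rng)
    lab = freqs.alleles
    return GenotypePair(
        pair_id,
        locus,
        (lab[gA[0, 0]], lab[gA[0, 1]]),
        (lab[gB[0, 0]], lab[gB[0, 1]]),
        mode=int(modes[0]),
    )


def _locus_names(n: int) -> list[str]:
    return [f"L{i}" for i in range(n)]


def simulate_dataset(design: SimulationDesign) -> tuple[pd.DataFrame, dict]:
    """Simulate a genotype table under a single Jacquard vector.

    Reproducible given the seed; the returned metadata records seed and
    design.  Columns: pair_id, locus, a1, a2, b1, b2 (+ mode if latent labels
    are kept).
    """
    if design.mixture is not None:
        return simulate_mixture(design)
    rng = np.random.default_rng(design.seed)
    frames = []
    pair_ids = np.array([f"P{i}" for i in range(design.n_pairs)])
    for lname, afv in zip(_locus_names(design.n_loci), design.freqs):
        gA, gB, modes = _sample_block(design.delta.delta, afv.p, design.n_pairs, rng)
        lab = np.asarray(afv.alleles, dtype=object)
        df = pd.DataFrame(
            {
                "pair_id": pair_ids,
                "locus": lname,
                "a1": lab[gA[:, 0]],
                "a2": lab[gA[:, 1]],
                "b1": lab[gB[:, 0]],
                "b2": lab[gB[:, 1]],
            }
        )
        if design.keep_latent:
            df["mode"] = modes
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    meta = {
        "seed": design.seed,
        "n_pairs": design.n_pairs,
        "n_loci": design.n_loci,
        "delta": [float(d) for d in design.delta.delta],
        "loci": {
            ln: dict(zip(afv.alleles, map(float, afv.p)))
            for ln, afv in zip(_locus_names(design.n_loci), design.freqs)
        },
    }
    return table, meta


def simulate_mixture(design: SimulationDesign) -> tuple[pd.DataFrame, dict]:
    """Simulate under a finite mixture: one component per pair, all loci."""
    mix = design.mixture
    if mix is None:
        raise ValueError("design has no mixture specification")
    rng = np.random.default_rng(design.seed)
    comp = rng.choice(len(mix.weights), size=design.n_pairs, p=np.asarray(mix.weights))
    frames = []
    pair_ids = np.array([f"P{i}" for i in range(design.n_pairs)])
    n_loci = len(mix.freqs_by_component[0])
    for li, lname in enumerate(_locus_names(n_loci)):
        a1 = np.empty(design.n_pairs, dtype=object)
        a2 = np.empty(design.n_pairs, dtype=object)
        b1 = np.empty(design.n_pairs, dtype=object)
        b2 = np.empty(design.n_pairs, dtype=object)
        modes = np.zeros(design.n_pairs, dtype=np.int64)
        for m in range(len(mix.weights)):
            sel = np.nonzero(comp == m)[0]
            if sel.size == 0:
                continue
            afv = mix.freqs_by_component[m][li]
            gA, gB, md = _sample_block(
                mix.deltas[m].delta, afv.p, sel.size, rng
            )
            lab = np.asarray(afv.alleles, dtype=object)
            a1[sel], a2[sel] = lab[gA[:, 0]], lab[gA[:, 1]]
            b1[sel], b2[sel] = lab[gB[:, 0]], lab[gB[:, 1]]
            modes[sel] = md
        df = pd.DataFrame(
            {
                "pair_id": pair_ids,
                "locus": lname,
                "a1": a1,
                "a2": a2,
                "b1": b1,
                "b2": b2,
            }
        )
        if design.keep_latent:
            df["mode"] = modes
            df["component"] = comp
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    meta = {
        "seed": design.seed,
        "n_pairs": design.n_pairs,
        "n_loci": n_loci,
        "mixture_weights": [float(w) for w in mix.weights],
    }
    return table, meta


def empirical_identity_disequilibrium(table: pd.DataFrame, loci=None) -> pd.DataFrame:
    """Across-locus excess of joint homozygosity for each locus pair.

    For individuals A of each pair (homozygosity indicator per locus), returns
    the joint two-locus homozygosity frequency, the product of the marginal
    homozygosities, and their difference (the identity excess); monomorphic
    loci are excluded with a warning.  The final row averages over pairs of
    loci.
    """
    hom = (
        table.assign(hom=(table["a1"] == table["a2"]).astype(float))
        .pivot_table(index="pair_id", columns="locus", values="hom")
    )
    if loci is None:
        loci = list(hom.columns)
    keep = []
    for l in loci:
        if table.loc[table["locus"] == l, ["a1", "a2", "b1", "b2"]].stack().nunique() < 2:
            import warnings

            warnings.warn(f"locus {l} monomorphic; excluded", stacklevel=2)
        else:
            keep.append(l)
    rows = []
    for l1, l2 in itertools.combinations(keep, 2):
        joint = float((hom[l1] * hom[l2]).mean())
        marg = float(hom[l1].mean()) * float(hom[l2].mean())
        rows.append((l1, l2, joint, marg, joint - marg))
    out = pd.DataFrame(
        rows, columns=["locus1", "locus2", "joint_hom", "product_hom", "excess"]
    )
    if len(out):
        mean_row = pd.DataFrame(
            [("all", "all", out["joint_hom"].mean(), out["product_hom"].mean(),
              out["excess"].mean())],
            columns=out.columns,
        )
        out = pd.concat([out, mean_row], ignore_index=True)
    return out
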