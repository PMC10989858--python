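"""Readers and writers for the package's text formats.

Formats (all UTF-8, tab-delimited, headers mandatory):

* genotype table TSV — columns ``pair_id, locus, a1, a2, b1, b2``; missing
  genotypes are "." and are dropped with a logged count;
* allele-frequency TSV — columns ``locus, allele, freq``;
* parameter JSON — either ``{"delta": [9 floats]}`` or
  ``{"coefficients": {"F_A": …, "H": …}}``;
* estimation-result JSON;
* VCF ingestion (read-only) — genotype pairs for named sample pairs; phase
  is deliberately discarded (unordered genotypes throughout).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    COEFFICIENT_NAMES,
    AlleleFrequencyVector,
    JacquardVector,
    RelatednessParameters,
    validate_frequencies,
)

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_frequency_table",
    "write_frequency_table",
    "read_parameters",
    "write_result_json",
    "read_vcf_pairs",
]

log = logging.getLogger("kinquartet")

GENOTYPE_COLUMNS = ["pair_id", "locus", "a1", "a2", "b1", "b2"]


def read_genotype_table(path) -> pd.DataFrame:
    """Read and validate a genotype-pair table.

    Malformed rows raise with the offending line number; rows containing
    missing genotypes (".") are dropped and the count logged; unknown extra
    columns produce a warning but are retained.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required column(s) {missing_cols}")
    extra = [c for c in df.columns if c not in GENOTYPE_COLUMNS + ["mode", "component"]]
    if extra:
        log.warning("%s: ignoring unknown column(s) %s", path, extra)
    bad = df[GENOTYPE_COLUMNS].isna().any(axis=1)
    if bad.any():
        first = int(np.nonzero(bad.values)[0][0]) + 2  # header is line 1
        raise ValueError(f"{path}: malformed row at line {first}")
    miss = (df[["a1", "a2", "b1", "b2"]] == ".").any(axis=1)
    if miss.any():
        log.info("%s: dropped %d row(s) with missing genotypes", path, int(miss.sum()))
        df = df[~miss].reset_index(drop=True)
    return df


def write_genotype_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_frequency_table(path) -> dict[str, AlleleFrequencyVector]:
    """locus/allele/freq TSV → per-locus validated frequency vectors."""
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "allele": str})
    for c in ("locus", "allele", "freq"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    out = {}
    for locus, sub in df.groupby("locus", sort=True):
        out[str(locus)] = validate_frequencies(
            list(zip(sub["allele"], sub["freq"].astype(float)))
        )
    return out


def write_frequency_table(freqs: dict[str, AlleleFrequencyVector], path) -> None:
    rows = [
        (locus, lab, float(p))
        for locus, afv in freqs.items()
        for lab, p in zip(afv.alleles, afv.p)
    ]
    pd.DataFrame(rows, columns=["locus", "allele", "freq"]).to_csv(
        path, sep="\t", index=False
    )


def estimate_frequencies(table: pd.DataFrame) -> dict[str, AlleleFrequencyVector]:
    """Allele frequencies counted from the sample, each individual of a pair
    counted once.  (Estimator bias depends on this choice; a known-frequency
    table can be supplied instead.)"""
    out = {}
    for locus, sub in table.groupby("locus", sort=True):
        counts = (
            sub[["a1", "a2", "b1", "b2"]].stack().value_counts().sort_index()
        )
        total = counts.sum()
        out[str(locus)] = validate_frequencies(
            [(lab, c / total) for lab, c in counts.items()]
        )
    return out


def read_parameters(path):
    """Parameter JSON → JacquardVector or RelatednessParameters."""
    with open(path) as fh:
        obj = json.load(fh)
    if "delta" in obj:
        return JacquardVector(np.asarray(obj["delta"], dtype=float))
    if "coefficients" in obj:
        unknown = set(obj["coefficients"]) - set(COEFFICIENT_NAMES)
        if unknown:
            raise ValueError(f"unknown coefficient name(s) {sorted(unknown)}")
        return RelatednessParameters(**obj["coefficients"])
    raise ValueError(f"{path}: expected a 'delta' or 'coefficients' entry")


def write_result_json(result, path, **metadata) -> None:
    """Serialise an EstimateResult (or mapping) with run metadata."""
    if hasattr(result, "estimates"):
        payload = {
            "estimates": result.estimates,
            "method": result.method,
            "components": result.components,
            "weights": result.weights,
            "flags": result.flags,
            "extras": {
                k: v
                for k, v in result.extras.items()
                if isinstance(v, (int, float, str, list, tuple))
            },
        }
    else:
        payload = dict(result)
    payload["metadata"] = metadata

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)


def read_vcf_pairs(path, pairs) -> pd.DataFrame:
    """Genotype-pair table from a VCF for named sample pairs.

    ``pairs`` maps pair ids to (sample_A, sample_B).  Biallelic and
    multiallelic sites are converted alike (allele labels are REF/ALT
    strings); phase separators are ignored; sites with a missing genotype in
    either member of a pair are dropped for that pair.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wanted = {s for pair in pairs.values() for s in pair}
    absent = sorted(wanted - set(samples))
    if absent:
        raise ValueError(
            f"sample(s) {absent} not in VCF; available samples: {samples}"
        )
    col = {s: samples.index(s) for s in wanted}
    rows = []
    for var in vcf:
        labels = [var.REF] + list(var.ALT)
        locus = f"{var.CHROM}:{var.POS}"
        gts = var.genotypes  # [allele1, allele2, phased]
        for pid, (sa, sb) in pairs.items():
            ga = gts[col[sa]][:2]
            gb = gts[col[sb]][:2]
            if min(ga) < 0 or min(gb) < 0:
                log.info("site %s: missing genotype for pair %s; dropped", locus, pid)
                continue
            a1, a2 = sorted(labels[i] for i in ga)
            b1, b2 = sorted(labels[i] for i in gb)
            rows.append((pid, locus, a1, a2, b1, b2))
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
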