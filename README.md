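# kinquartet

Relatedness coefficients for **pairs, triplets and quartets of marker
genes**: a generative probability model for the genotypes of two diploid
individuals at a multiallelic locus, the moment and maximum-likelihood
estimators that invert it, exact single-locus sampling variances, and a
simulator including population mixtures that create identity disequilibrium.

## The problem

Two diploid individuals *A* and *B* carry four genes at a locus.  Classical
relatedness estimation works with *pairs* of genes — the inbreeding
coefficient *F* (the two genes within an individual identical-by-descent,
ibd) and the kinship-scale pairwise coefficient *R* (a random gene of *A*
ibd with a random gene of *B*).  Triplets and quartets of genes carry more
information: the three-gene coefficient *G* (both genes of one individual
plus one of the other all ibd, needed e.g. for effective selfing rates
*s = 2R − G* and kin-selection regressions), and three four-gene measures —
*F<sub>AB</sub>* (both within-individual pairs simultaneously ibd),
*R<sub>AB</sub>* (both cross pairings ibd) and *H* (all four genes ibd).

The four-gene measures are cumulant-level quantities: *F<sub>AB</sub>* =
*F<sub>A</sub>F<sub>B</sub>* + Cov(*F<sub>A</sub>*, *F<sub>B</sub>*) and
*R<sub>AB</sub>* = *R*² + Cov(*R*, *R*′), where the covariances exist only
when the population is a mixture of subpopulations differing in gene
frequency or pedigree — the source of *identity disequilibrium*, the excess
of joint homozygosity across loci.  *H* equals the normalised fourth
cumulant of the allele indicators: κ₄ = μ₄c − 3σ⁴, normalised by
*pq*(1 − 6*pq*).

The full ibd state of the four genes is one of the nine condensed Jacquard
identity modes Δ₁…Δ₉; the eight coefficients
(*F<sub>A</sub>*, *F<sub>B</sub>*, *R*, *G<sub>A</sub>*, *G<sub>B</sub>*,
*F<sub>AB</sub>*, *R<sub>AB</sub>*, *H*) are an equivalent, invertible affine
reparameterisation:

```
F_A = Δ1+Δ2+Δ3+Δ4        G_A  = Δ1+Δ3/2        F_AB = Δ1+Δ2
F_B = Δ1+Δ2+Δ5+Δ6        G_B  = Δ1+Δ5/2        R_AB = Δ1+Δ7/2
R   = Δ1+(Δ3+Δ5+Δ7)/2+Δ8/4                     H    = Δ1
```

Every genotype-pair class probability (f_iiii, f_ijij, f_iijj, …) is affine
in these coefficients; the closed forms implemented here are derived
symbolically from the generative definition — assign one allele per ibd
class, iid from the population frequencies — and validated against that
enumeration to machine precision.

## What the package provides

| module        | contents |
|---------------|----------|
| `core`        | parameter spaces (allele frequencies, Jacquard vectors, the eight coefficients), mappings, normalisation constants *pq*, *pq*(1 − 2*p*), *pq*(1 − 6*pq*), cumulant conversions, mixture moments, effective selfing |
| `genoprob`    | class probabilities for 2/3/4 genes, full spectra, the 8×8 design matrix of the joint system, the generative mode-enumeration oracle |
| `estimators`  | per-allele moment estimators with minimum-variance weights, closed-form joint solvers for (H, F_ab) and (H, F_ab, R_abab), the classic double-homozygote identity-disequilibrium estimator, the full eight-coefficient linear solve |
| `likelihood`  | multinomial likelihood across loci and EM over the latent identity modes (Δ simplex) |
| `simulate`    | genotype-pair simulation per mode, population mixtures (per-pair component assignment), empirical identity-disequilibrium summaries |
| `variance`    | exact sampling variances of every single-locus estimator by complete enumeration, reference variance table |
| `io` / `cli`  | TSV/JSON formats, VCF ingestion, `kinquartet` command-line tool |

## Worked example

Simulate 500 pairs at 30 loci under a known identity-mode vector, then
recover the coefficients by maximum likelihood:

```python
import numpy as np
from kinquartet import *

afv3 = validate_frequencies([("A", 0.5), ("B", 0.3), ("C", 0.2)])
afv4 = validate_frequencies([("A", 0.4), ("B", 0.3), ("C", 0.2), ("D", 0.1)])

delta = JacquardVector(np.array([0.05, 0.10, 0.05, 0.10, 0.05, 0.10, 0.20, 0.15, 0.20]))
print(jacquard_to_coefficients(delta).as_dict())
# {'F_A': 0.3, 'F_B': 0.3, 'R': 0.2375, 'G_A': 0.075, 'G_B': 0.075,
#  'F_AB': 0.15, 'R_AB': 0.15, 'H': 0.05}

design = SimulationDesign(delta=delta, freqs=(afv3, afv4) * 15, n_pairs=500, seed=42)
table, meta = simulate_dataset(design)

freqs = {f"L{i}": design.freqs[i] for i in range(30)}
fit = fit_ml(table, freqs, FitConfig())
print(fit.estimates)
# {'F_A': 0.2904, 'F_B': 0.2988, 'R': 0.2359, 'G_A': 0.0719, 'G_B': 0.0781,
#  'F_AB': 0.1540, 'R_AB': 0.1497, 'H': 0.0558}   (459 EM iterations)
```

The fit recovers every coefficient to within its sampling scale at
n = 500 × 30 observations; the log-likelihood trace is non-decreasing by
construction of EM.

The same pipeline from the shell:

```sh
kinquartet simulate --delta 0,0,0,0,0,0,0,0,1 --freqs freqs.tsv \
    --pairs 500 --seed 7 --out pairs.tsv
kinquartet estimate --table pairs.tsv --method ml --out fit.json
kinquartet variance --arrays 0.6,0.3,0.1 --weighting minvar
```

The `variance` command prints exact single-locus null variances, e.g. the
three-gene pattern-component variances 73.50 and 74.33 for the array
(0.6, 0.3, 0.1), with `x` marking the p = 1/2 non-estimable cells of the
(0.5, 0.3, 0.2) array.

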