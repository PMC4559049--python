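# snpdispersal

Individual-based natal dispersal estimation from noninvasively
collected SNP genotypes, built around the Scandinavian brown bear
(*Ursus arctos*) study design: volunteer-collected fecal samples,
genotyped on a 96-SNP panel (87 autosomal, 3 X, 2 Y, 4 mtDNA-diagnostic
markers), drive pedigree reconstruction, and mother–offspring Euclidean
distances between home-range centers measure dispersal.

The package implements the full chain as importable, tested modules,
plus a truth-known spatial-pedigree simulator so that every stage can
be validated against a known answer without any field data:

1. **`simulate`** — synthetic populations: a non-overlapping-generation
   pedigree, sex-specific dispersal kernels (female/male means
   12.9/33.8 km), Mendelian genotypes on the mixed panel, and
   replicated fecal samples with allelic dropout and per-allele
   miscalls (error rate ≈ 4 × 10⁻⁴).
2. **`qc`** — replicate consolidation, error/dropout estimation from
   replicate concordance, Y/X-based sex calling, mtDNA haplotypes,
   call rate, MAFs and the probability of identity
   PID = ∏ₗ (p⁴ + 4p²q² + q⁴).
3. **`relatedness`** — pairwise Lynch–Ritland regression estimator r̂
   with locus weighting, reciprocal averaging and missing-data
   handling; relationship categories (PO/FS/HS/GG/MT) from a pedigree.
4. **`parentage`** — genotyping-error-aware Mendelian likelihoods for
   parent pairs (triads) and single parents (dyads, unsampled co-parent
   integrated over allele frequencies), posteriors with
   candidate-pool priors (N_f^max = 663, N_m^max = 516,
   threshold 0.95), and deterministic assembly into disjoint,
   sex-consistent, acyclic pedigrees with triad-based directionality.
5. **`spatial`** — median centers of sample sites, Euclidean distances,
   Mantel permutation tests and sex-stratified isolation-by-distance.
6. **`dispersal`** — cub exclusion (full siblings co-located within
   1 km of their mother), per-sex dispersal summaries
   (N/median/mean/SE/max) and the two-sided Wilcoxon rank-sum test.

## Worked example

Reconstruct a small error-free population and recover its pedigree
exactly, then check the relatedness calibration:

```python
import numpy as np
from snpdispersal.experiments import (
    pedigree_reconstruction_run, relationship_pair_r)

res = pedigree_reconstruction_run(seed=1)
print(res.n_individuals, res.exact_match)
# 64 True            <- all 96 true parent-offspring edges recovered

r_po = relationship_pair_r("po", 2000, seed=11)
print(round(float(np.mean(r_po)), 3))
# 0.501              <- parent-offspring pairs center on r = 0.5
```

The full synthetic study is the numbered scripts under `analysis/`
(run them in order; intermediate tables land in `scratch/pipeline/`,
summaries in `results/`):

```sh
python analysis/01_simulate.py      # ~810 bears, 435 genotyped
python analysis/02_genotype_qc.py   # consolidation, error rates, sexes
python analysis/03_relatedness.py   # 94,395 pairwise r values
python analysis/04_parentage.py     # pedigrees + category-vs-r table
python analysis/05_ibd.py           # Mantel / Pearson IBD by sex
python analysis/06_dispersal.py     # cub filter, Table-2-style summary
```

On the default seed the QC step reports a call rate of 0.995, mean
autosomal MAF 0.363 and PID ≈ 2 × 10⁻³⁵; relatedness over all 94,395
pairs has mean −0.0023 (SD 0.117); and the dispersal step prints a
per-sex N/median/mean/SE/max table with the rank-sum test against the
generating kernels.

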