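# msycnv

Copy-number analysis of multicopy genes on the horse Y chromosome from
droplet digital PCR (ddPCR), with haplogroup assignment and a simulator for
the recombination mechanism that couples *SRY* and *RBMY* copy number.

## The problem

The male-specific region of the Y chromosome (MSY) never recombines with a
homologue, and several of its genes exist as arrays of near-identical
copies (ampliconic genes: in the horse *TSPY*, *RBMY*, *HSFY*, *UBA1Y*,
*ETSTY1/2/5*).  Such arrays are unstable: nonallelic homologous
recombination (NAHR) between misaligned sister chromatids deletes or
duplicates copies, so copy number (CN) varies between individuals, breeds,
successive male generations, and even cloned horses.  Because the
single-copy sex-determining gene *SRY* sits between two *RBMY*-bearing
direct repeats, one NAHR event produces reciprocal gametes — one with
*SRY*=2/*RBMY*=3, one with no *SRY* and a single *RBMY*, the likely origin
of *SRY*-negative XY mares.

This package implements the full analysis chain for such studies, for
anyone quantifying gene copy number from partition-based PCR:

1. **Poisson quantification** (`msycnv.droplet`): per duplex well,
   λ = −ln(n_neg/n_total) copies/droplet per channel, target CN
   = 2·λ_target/λ_reference, delta-method 95 % bounds on λ and on log CN,
   and the QC rules (CN interval wider than 1 copy → `HIGH_SE`; fewer than
   8 000 droplets → `LOW_DROPLETS`).
2. **CN calling** (`msycnv.calling`): replicate merging with the retest
   policy, half-away-from-zero integer rounding, Y-profile classification
   (complete Y deletion, *SRY*-negative DSD, *SRY*/*RBMY* amplification,
   multi-gene outlier), cohort summaries.
3. **Haplogroup assignment** (`msycnv.haplotree`): sequential descent along
   a marker-bearing backbone tree gated by the Crown variant rAX,
   imputation of untyped markers from the root path, frequency tables and
   plots.
4. **Cohort statistics** (`msycnv.cohort_stats`): paired one-way ANOVA F
   and tie-corrected Kruskal–Wallis H per gene on identical group
   partitions, with small-group sensitivity reruns and optional Holm
   annotation.
5. **NAHR and CNV dynamics** (`msycnv.nahr`): the single-event gamete
   calculus plus germline (pedigree) and somatic (clone-set) gain/loss
   trajectory simulation.
6. **Synthetic data** (`msycnv.synthetic`): a generator reproducing the
   study conditions — 209 males of 22 breeds with per-breed CN
   distributions from the bundled reference table, binomially sampled
   droplet counts, tree-consistent genotypes — so every stage has an
   exact truth to test against.

## Worked example

```python
import numpy as np
from msycnv import quantify_table, simulate_wells_for_cn

wells = simulate_wells_for_cn(8.48, n_wells=30, rng=np.random.default_rng(948),
                              n_droplets=15_000, reference_lambda=0.3)
quant = quantify_table(wells)
print(round(quant["cn"].mean(), 3), round(quant["cn"].std(ddof=1), 3))
```

prints `8.491 0.144`: thirty 15 000-droplet duplex replicates at a true
target:reference ratio of 4.24 recover the encoded copy number of 8.48
(the reference stallion's *TSPY* value) with a per-well SD of ~0.15 copies.

The same pipeline is wired as numbered drivers under `analysis/`
(simulate → quantify → call CN → assign haplotypes → cohort statistics →
NAHR dynamics), each writing its tables under `results/`, and as a CLI:

```sh
msycnv simulate --seed 17 --out-dir sim
msycnv quantify --wells sim/wells.csv --out quant.tsv
msycnv call-cn  --quant quant.tsv --metadata sim/metadata.csv \
                --out-profiles profiles.tsv --out-summary breeds.tsv
msycnv call-ht  --genotypes sim/genotypes.csv --out ht.tsv
msycnv compare  --profiles profiles.tsv --group-by breed --out stats.tsv
```

On the default synthetic cohort the rounded calls match the generating
integer CN for ≥ 99 % of reported sample × gene calls, haplotype
assignments match the generating haplotypes exactly, and ~79 % of domestic
horses fall in the Crown haplogroup, as configured.

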