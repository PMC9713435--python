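# Methods

## Poisson quantification of duplex ddPCR wells

Each well partitions the template into droplets scored positive/negative
in a target (FAM) and an autosomal reference (VIC) channel.  Under Poisson
partitioning the mean copies per droplet is λ = −ln(n_neg/n_total).  The
copy number is the concentration ratio scaled by the autosomal reference
copy number:

    CN = reference_cn · λ_t / λ_r ,   reference_cn = 2.

The droplet partition volume (default 0.85 nL, the published QX200 value,
configurable per assay) cancels in the ratio; it is used only when
absolute concentrations (copies/µL) are reported.

**Uncertainty.**  The SD of λ follows from the delta method on the
binomial negative fraction p₀ = n_neg/n_total:

    sd(λ) = sqrt((1 − p₀) / (n · p₀)),

with 95 % bounds λ ∓ 1.959964·sd clipped at zero.  CN bounds propagate
both channels on the log scale, sd(log CN)² = (sd λ_t/λ_t)² +
(sd λ_r/λ_r)², treating the channels as independent Poisson draws: the
two channels share droplets, but the cross-channel covariance is not
estimable from the stored counts, and independence is standard practice.
The exact interval recipe of the vendor software is proprietary; rather
than matching it bit for bit, the implementation is validated two ways in
the test suite — agreement with a parametric-bootstrap interval (10⁵
binomial resamples) to within a few thousandths, and 93–97 % empirical
coverage of the simulating λ at the nominal 95 % level.

**Degenerate wells.**  Zero negative droplets means λ is unbounded above:
a hard `SATURATED` error at the estimator level, surfaced as a flagged NaN
row by the table API.  Zero target positives is a valid CN = 0 (the
female-control behaviour) with a degenerate interval.  λ_r = 0 marks a
failed well (`NO_REFERENCE`).

**QC rules.**  A well is flagged `HIGH_SE` when its 95 % CN interval is
wider than 1 copy and `LOW_DROPLETS` below 8 000 accepted droplets; flags
are additive.  Note an interaction documented deliberately: at 15 000
droplets and reference λ 0.3, the >1-copy width rule necessarily trips for
copy numbers above ≈13 (the interval width grows linearly in CN at roughly
2 % relative SD per well), so very-high-CN samples in the synthetic cohort
end as "needs retest" rather than as calls.  Recovery statements therefore
refer to *reported* calls; the reported fraction is itself asserted ≥ 95 %.

## Replicate merging and integer calling

Wells with any QC flag are excluded, then wells deviating from the
replicate median by more than 1.5 copies (configurable) are excluded as
"noticeably low or high" — a threshold chosen to mirror the 1-copy SE
rule's scale, since no numeric trigger is standard.  The per-sample value
is the mean over passing wells; fewer than two passing wells sets
`needs_retest`, and exclusions are visible as `n_passing` vs `n_wells`,
never silent.  Rounding is half away from zero.  Because continuous ratio
measurements near x.5 round ambiguously (observed low-CN cohorts contain
values like 1.48 that are discussed as 2 copies), calls whose fractional
part lies in 0.4–0.6 carry a `borderline` mark instead of being silently
reclassified.

Y-profile classification applies, in precedence order: complete Y deletion
(all assayed genes round to 0), *SRY*-negative DSD (*SRY* = 0, *RBMY* = 1),
*SRY*/*RBMY* amplification (*SRY* ≥ 2, *RBMY* deviation recorded as
evidence), multi-gene outlier (≥ 4 genes above cohort mean + 3 SD, both
configurable; outliers are flagged but retained in cohort means), else
normal.  *SRY* and *RBMY* calls are prerequisites.

## Cohort statistics

Breed and cohort sizes are highly unbalanced (1–47 individuals per group),
so every comparison reports both a parametric one-way ANOVA F (computed
from sums of squares; single-value groups retained, contributing to the
between-group sum) and a tie-corrected Kruskal–Wallis H on the identical
partition, with F and χ² reference p-values.  A permutation option for H
(exact enumeration when feasible, otherwise shuffled relabelings) backs
the χ² approximation in tests.  Raw per-gene p-values are reported, as is
conventional in this literature; Holm-adjusted values can be annotated
(`holm=True`, off by default).  A `report_pvalues=False` switch suppresses
p-values for heterogeneous-phenotype cohorts where a pooled test is not
meaningful.  A `min_group_size` filter supports the with/without-small-
breeds sensitivity rerun; excluded groups are listed in the result.

## Haplogroup assignment

The backbone is a rooted tree whose edges carry diagnostic variants with
ancestral/derived alleles (single-character IUPAC for SNVs, `ins`/`del`
tokens for the indel; matching is case-insensitive).  Assignment descends
from the root, at each node following the unique child edge observed in
the derived state; it stops at a leaf (resolved) or at an internal node
when all child edges are ancestral or untyped (unresolved placement).  An
untyped edge also counts as derived when markers deeper in its subtree
were observed derived — this lets complete-but-gappy vectors (array-style
genotyping with random missingness) place correctly, while derived alleles
below an edge observed *ancestral*, or on two sibling edges, raise an
inconsistency error.  The Crown gate marker rAX must be typed; otherwise
the sample is unassignable.  Untyped markers are imputed from the
root-to-node path (derived on path, ancestral elsewhere); observed alleles
are never overwritten, and contradictions raise.

The bundled fixture condenses the published horse MSY topology: the five
markers named in the primary literature (rAX, rA, rW, fYR, rAY) sit on
their documented edges; the remaining 25 of the 30-marker panel are
systematically named placeholders (`p-<edge>`); studies with access to the
full published marker map encode it via their own YAML config.  The
haplogroups I, N, O, M, Y are modelled as terminal nodes (samples cluster
*into* them; only DW1–DW4, Tb and Tb-1 take internal placements), with
placeholder leaves under DW4 and Tb-1 so those placements are reported as
unresolved.  The exact nesting of the non-Crown haplogroups under DW1 is
the package's own condensation and is irrelevant to the sequential
protocol's correctness, which is tested exhaustively node by node.

## NAHR and CNV dynamics

The default repeat region is two `direct_repeat` units, each carrying one
*RBMY* copy, flanking the single-copy *SRY*.  One simulated event picks a
misalignable pair of identical repeats (uniform over pairs at distinct
positions) and joins repeat *i* of one sister chromatid to repeat *j* > *i*
of the other, yielding the reciprocal duplication (units 0..j + i+1..end)
and deletion (units 0..i + j+1..end) products.  Copy number summed over
the two gametes is conserved exactly for any region — asserted as a
property test — and the default layout yields exactly (SRY = 2, RBMY = 3)
and (SRY = 0, RBMY = 1).  A region without two identical repeats has no
NAHR substrate and passes through unchanged.

Lineage and clone simulators apply independent per-gene gain/loss events
(±1 copy by default; larger jumps arise from repeated events or a larger
step) at each meiosis or mitosis, with losses clipped at zero and every
event logged.  A CN-proportional mode scales event probability with the
current copy number, reflecting the greater rearrangement exposure of
larger arrays; its variance-vs-founder-CN behaviour is tested.  The
default rates (gain = loss = 0.025/gene/meiosis; 0.01/gene/mitosis, with
~25 mitoses per clone in the demonstrations) are free demonstration
parameters chosen once to show pedigree- and clone-scale variability of a
few copies; they are explicitly not estimates of real rates, which the
underlying data cannot identify.  Whether inter-clone differences arise in
the donor's somatic tissue or in post-transfer mitoses is not
distinguishable; both enter through the same somatic rate knob.  Haplotype
labels are carried through unchanged by construction.

## Synthetic data: what it does and does not emulate

The generator draws, per breed, integer true CNs ~ round(N(mean, SD))
clamped at zero, using the bundled 22-breed reference table (209 males) as
default means/SDs; the published per-breed SDs conflate biological and
measurement variation, but treating them as between-individual biological
SD is the only simulatable reading, and measurement noise then enters only
through droplet sampling.  Wells draw n_total ~ N(15 000, 1 500²) floored
at 1 000, reference positives ~ Binomial(n_total, 1 − e^−λ_r) with λ_r =
0.3 copies/droplet (mid dynamic range), target positives with λ_t = λ_r ·
CN/2; two replicate wells per sample × gene.  Abnormal classes override
genes exactly (all zeros; SRY 0/RBMY 1; SRY ∈ {2,3}/RBMY ∈ {1,3}; a
multi-gene high-CN outlier) at configurable fractions, defaulting to zero
in the normal-cohort configuration with a study-proportioned preset
available.  Haplotypes are drawn from the bundled survey counts (Crown ≈
79 %) independently of breed — real haplotypes are breed-structured, so
breed × haplotype interactions are *not* emulated and cross-tabulations on
synthetic data carry no signal.  Genotypes place derived alleles exactly
on the root-to-haplotype path; missingness is either path-consistent
(only markers the sequential protocol would never have typed) or uniform
(stress mode).  PCR inhibition, rain droplets, cross-contamination and
digestion failure are out of scope.  Everything is deterministic under the
configured seed, byte for byte.

Consequently, passing tests demonstrate correctness of the estimators and
decision rules under the model's own assumptions (Poisson partitions,
independent channels, integer truth, tree-consistent genotypes); they do
not validate those assumptions against real droplet readers.

## Problem sizes and numerical choices

Default test and demonstration sizes — 209-sample cohorts, 2 replicates,
15 000 droplets, 30-replicate reference runs, 10⁵ bootstrap resamples,
2 × 10⁴ permutations — were chosen as the sizes the emulated study design
itself uses, and run in seconds on one CPU.  z = 1.959964 throughout;
ANOVA returns (0, 1) when all values are identical and (inf, 0) for zero
within-group variance with real spread; Kruskal–Wallis returns (0, 1) when
every value ties; NAHR breakpoint choice is uniform over homologous pairs;
rounding is half away from zero everywhere.

## Known limitations

- The >1-copy interval rule makes CN ≳ 13 wells systematically
  "high SE" at the default droplet count; real workflows resolve this by
  retesting/diluting, which the pipeline surfaces as `needs_retest` rather
  than emulating.
- The bundled backbone is a condensed stand-in; real studies must supply
  the full 30-marker map and topology via config.
- Whether the replicate-aware "total error" or the pure Poisson error
  should drive the >1-copy rule is not documented upstream; the pure
  Poisson reading is implemented.
- Cohort statistics assume independent individuals; pedigree structure
  within breeds is ignored, as in the emulated design.
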