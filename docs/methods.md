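# Methods

This note documents the models, estimators and design choices behind
`poolsweep`: what each component computes, the assumptions it makes, and
what the synthetic-data tests do and do not demonstrate about real data.

## Pooled data model and site filters

All pool statistics start from per-site read counts of the six pileup
classes (A, T, C, G, N, deletion) for each sequenced pool, exchanged in
the PoPoolation2 `sync` text format. Conventions:

- Coverage bounds are **exclusive on both sides**: a site is kept only if
  every pool's coverage satisfies `min_cov < cov < max_cov` (defaults
  10/100). The same single convention is applied wherever a coverage
  bound appears.
- N and deletion reads count toward coverage for filtering but never
  toward allele frequencies, mirroring mpileup semantics.
- Multi-allelic sites are reduced to the two highest-count alleles summed
  across pools; ties break by the fixed base order A<T<C<G. Downstream
  estimators are strictly biallelic.
- An allele is present in the dataset only if its summed count reaches
  `min_count` (default 3); a site is a SNP when two alleles are present.
- Positions are 1-based in sync files; all window and region arithmetic
  is 0-based half-open internally and in BED output.

## F_ST estimation

Differentiation between two pools is estimated per SNP from the unbiased
heterozygosity components

    h_within  = mean_i [ 2 a_i b_i / (n_i (n_i − 1)) ]
    h_between = (a_1 b_2 + a_2 b_1) / (n_1 n_2)

where `a_i`, `b_i` are the two allele counts in pool *i* and
`n_i = a_i + b_i` its informative coverage. Windowed F_ST over 1000 bp
windows with 50% overlap is the **ratio of sums**
`Σ(h_between − h_within) / Σ h_between` across the window's defined SNPs
(never the mean of per-SNP ratios). Sites with `n_i < 2` in either pool,
or with `h_between = 0` (both pools monomorphic for the same allele), are
skipped. The per-SNP numerator is kept unclamped — balanced pools give a
slightly negative value because the within-pool estimator is unbiased —
and window ratios are floored at zero only in summary statistics, with
the raw value preserved.

Windows are anchored at position 1 of each chromosome; the final partial
window is dropped so every window has the nominal width.
`covered_fraction` is the fraction of window positions present in the
(all-position) input that pass the coverage bounds; the default gate of
1.0 matches full-pileup input, and variant-only input (as produced by the
synthetic generator) should set it to 0.

Genome-wide heterozygosity summaries (and the sweep/genome heterozygosity
ratio) average expected heterozygosity `2p(1−p)` over SNP sites only;
whether monomorphic sites should dilute that average is not decidable
from the quantities being emulated, and SNP-only is the declared choice.

## Sweep-region calling

The window F_ST track is thresholded at a percentile cutoff (default
95th, linear interpolation between order statistics) of the defined
windows. Above-cutoff windows cluster transitively when the gap between
one window's end and the next window's start is < 0.5 Mb (strict);
clusters never span chromosomes. Clusters with a single window or fewer
than two SNPs are removed. The cutoff comparison is strict (`>`), with
one degenerate-case exception: when the cutoff equals the maximum defined
window F_ST (a saturated track — common on sparse synthetic data where
single-SNP windows sit exactly at the estimator ceiling of 1), windows
equal to the cutoff are retained, since "the top tail" then *is* the
ceiling set. A region's SNP count uses distinct SNP positions inside its
retained windows when site positions are available (overlapping windows
would otherwise double-count).

## Neutral drift null

`driftsim` asks how much differentiation two lines accumulate by drift
alone under the breeding design: a 5 Mb locus with mutation rate
3.13 × 10⁻⁷ per site per generation (a deliberately high, mitochondrial-
scale rate that endows the base population with dense standing
variation), recombination 2.8 cM/Mb (macrochromosome-like) or 6.4 cM/Mb
(microchromosome-like), an ancestral effective size of 500, and two
independent lines of 25 diploids drifting for 39 generations.

**Standing variation.** The line founders are drawn as an equilibrium
coalescent sample (msprime) of 50 diploids from a population of size 500
with the stated mutation and recombination rates. This yields the exact
neutral site-frequency spectrum *and* equilibrium linkage disequilibrium
in one step; a forward burn-in approximating the same target would be
strictly slower and less exact. Watterson's segregating-site count and
the 1/i SFS shape are verified by tests.

**Line epoch.** Each generation every offspring draws both parents
uniformly with replacement from the 25 line members (unstructured
Wright–Fisher, Ne = 25). A sex-structured mode (`sex_structured=True`)
instead draws dams from the 20 females and sires from the 5 males,
realizing the smaller long-run Ne = 4·N_f·N_m/(N_f+N_m) = 16 of the
breeding sex ratio; its multi-generation variance behavior is tested
against `Var(p_t) = pq(1 − (1 − 1/2Ne)^t)`. The unstructured mode is the
default because the published neutral-reference window differentiation
this module reproduces (median window F_ST ≈ 0.36 after 39 generations)
identifies the realized drift level as Ne ≈ 25 per line, not 16; both
modes are first-class. New mutations enter at rate μ per site per gamete
during the line epoch and are placed at continuous coordinates so that
independently arising mutations in the two lines can never alias.

**Differentiation summaries.** A site is *differentiated* when the two
lines are fixed for alternative alleles (exact fixation of the true
frequencies; an F_ST-threshold variant is available). Differentiated
sites less than 50 kb apart merge into regions spanning first to last
site; a region ("stretch of differentiation") requires at least two
sites, since a single site has zero extent. Reported per run: the
region-length distribution (median/mean/max), the fraction of replicate
fragments containing at least one region, the percentage of fragment DNA
lying inside regions, and the median 1 kb window F_ST computed from the
exhaustive allele counts (coverage = 2N "reads" per line — tested to
agree with the pooled-read estimator to floating-point accuracy).

Two cautions for interpreting the drift null. First, with ~30% of
heterozygosity surviving 39 generations at Ne ≈ 25, essentially every
5 Mb replicate contains some fixed-opposite stretch, so the *fraction of
fragments* with a region saturates near 1; the informative quantities
are the length distribution and the percent of sequence differentiated
(≈18% under both recombination classes at 200 replicates). Second,
recombination necessarily shortens differentiated stretches — the
per-site fixation probability does not depend on the recombination rate,
only the clustering of fixed sites does — so the macro class always
shows longer regions than the micro class here (≈1.5× at these
parameters).

## Selection-experiment generator

`selsim` emulates the bidirectional selection experiment end to end and
is the test harness for every empirical-analysis module.

- **Base population:** an equilibrium coalescent sample (Ne = 1000,
  μ = 10⁻⁸) over a desk-scale genome of two 15 Mb "macro" chromosomes
  (2.8 cM/Mb) and two 10 Mb "micro" chromosomes (6.4 cM/Mb); full-genome
  dimensions are configurable. Forward-in-time mutation defaults to 0:
  over 39 generations at realistic rates new mutations are negligible,
  and the experiment's premise is response from standing variation.
- **Trait:** additive, y = mean + Σ aⱼ(dosage − 2p₀ⱼ) + sex·s + ε, with
  50 QTL, exponentially distributed effects rescaled so the founder
  genetic variance matches h² = 0.3 at a phenotypic SD of 3 log2-titer
  units (founder mean 8, female sex effect +1). Phenotypes are floored
  at 0 — titers cannot be negative — which lets the low line plateau.
- **Breeding:** 30 male and 60 female candidates per generation; the top
  (high line) or bottom (low line) 7♂/28♀ (generations 1–10) then 8♂/32♀
  become parents, with at most 2 selected offspring per dam family
  (a declared formalization of "restricted" truncation selection; the
  real rule is qualitative). Relaxed sublines branch at generation 24
  and draw parents at random for 16 generations.
- **Pooled sequencing:** pools of 30/30/20/16 individuals at mean depths
  32.3/36.7/35.4/34.8×; per site, depth ~ Poisson(mean), alternative
  reads ~ Binomial(depth, pooled frequency). No sequencing-error model
  beyond binomial sampling.
- **F2 intercross:** reciprocal line crosses give 64 F1; F1 intermating
  gives 256 F2, of which the 64 highest and 64 lowest phenotypes
  (balanced within sex) are genotyped at up to 1024 markers segregating
  among the F1 parents, coded as dosage of the high-line allele, with
  causal sites included in the panel by default so parameter-recovery
  tests are interpretable.

What the generator does **not** emulate: dominance and epistasis,
genotyping or sequencing error, linkage-map heterogeneity within
chromosomes, immunological mechanism. Passing tests demonstrate that the
estimators recover what this additive, error-free world plants — not
that they are robust to everything real data contains.

A deliberately documented property: sampling phenotypic extremes from a
larger F2 inflates ordinary-least-squares marker effects by roughly the
variance ratio of the kept tails (~1.6–2× here, verified by simulation,
and essentially independent of effect size). Parameter-recovery tests
therefore genotype an untruncated F2 of 128; the truncated
256 → 128-extremes design remains the generator default, and its
inflation is itself asserted by a test.

## Association analysis

Markers with a pooled line-frequency difference > 0.7 (strict) are
clustered along each chromosome (single linkage, gaps < 5 Mb). Stage 1
reduces each multi-marker cluster to one representative by within-cluster
backward elimination (the surviving marker with the smallest joint-model
p, or the last-eliminated marker when none survives). Stage 2 fits all
representatives jointly — intercept, fixed sex effect, additive dosages —
by OLS on log2 day-5 titers and eliminates backwards: at each step marker
p-values are Benjamini–Hochberg-adjusted and, while any adjusted p
exceeds the working threshold, the largest-p marker is removed (ties
break toward the later genome position) and the model refit. The 20%
tier's survivors are reported with effects from that joint model; the
subset that survives continued elimination at 5% is flagged, making the
strict tier nested by construction.

The BH multiplicity denominator stays **fixed at the number of markers
that entered the elimination** — eliminated markers count as accepted
nulls with p = 1 — rather than shrinking with the current model. A
shrinking denominator degenerates into testing the last survivor at raw
α, which retains a null marker in the majority of null datasets; the
fixed-denominator step-down keeps the null retention probability near α
(measured ≈3.6% at the 5% tier over 500 null datasets of 20 markers).
The exact adaptive-FDR rule of the emulated analysis is not specified in
its source; this stand-in is isolated in `bh_adjust` for replacement.

Missing genotypes are mean-imputed per marker; markers with >20%
missingness, and markers exactly aliased with the existing design
(detected by incremental Gram–Schmidt), are dropped with a warning —
aliasing is routine in an F2, where tightly linked markers are often
identical across 128 individuals.

## Haplotype inference from pooled frequencies

Within a strong sweep region, one pool is typically fixed for a single
haplotype. `find_reference_pool` selects the pool whose major-allele
frequency is ≥ 0.95 at the largest fraction of sites (failing explicitly
if no pool is fixed at ≥ 90% of sites); the fixation tolerance is below
1.0 because 30–35× pooled reads carry sampling noise. Polarization drops
sites where the reference pool is not fixed and re-expresses every
pool's frequency as that of the non-reference allele.

Sites are then clustered by their cross-pool polarized-frequency
profiles (k-means, k chosen as the smallest value that resolves bands
within the frequency tolerance, capped at 2^(k_max−1) − 1 classes;
classes below 5 sites merge into their nearest neighbor). Each class is
assigned a subset of the alternative haplotypes — shared across pools,
because site membership, unlike frequency, is a property of the
haplotypes — and per-pool haplotype frequencies are solved from the
class band centers by non-negative least squares over all admissible
assignments, preferring fewer haplotypes at comparable fit. A model
whose best residual exceeds the tolerance is flagged ambiguous. The
reference haplotype takes the complement; frequencies are clipped to the
simplex. The underlying real-data procedure is explicitly ad hoc; this
algorithm is one declared formalization of it, and all its tolerances
are package defaults, not values taken from the emulated analysis.
Recovery on three-haplotype pools at 35× depth is ≤ 0.05 RMSE over 100
replicates (tested).

## Problem sizes and reproducibility

Every stochastic component takes a seed (CLI `--seed`, config `seed`
fields) and is reproducible bit-for-bit given one. The test suite and
the acceptance script use desk-scale problem sizes chosen to exercise
the full pipelines: 200 replicates per recombination class for the drift
null, 100 replicates for parameter and haplotype recovery, 500 null
datasets for FDR calibration, and a 50 Mb four-chromosome genome for the
end-to-end synthetic study. Output files carry the package version, the
seed and a configuration hash in their headers.

## Known limitations

- The drift null's two epochs (equilibrium base, constant-size lines)
  ignore the real pedigree structure, overlapping generations and
  family-size caps of the breeding program.
- The Karlsson-component estimator treats reads as independent draws;
  it ignores that reads from one individual are correlated (no effective
  pool-size correction).
- Haplotype inference assumes at most `k_max` haplotypes and clean
  band structure; recombinant haplotypes inside the region violate the
  shared-site-membership assumption.
- The association model is a fixed-effects OLS; no kinship/mixed-model
  correction, dominance, or genotype uncertainty.
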