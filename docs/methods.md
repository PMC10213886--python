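# Methods

`aquagsel` evaluates low-cost genotyping strategies for genomic selection
in aquaculture-style breeding populations: a small HD-genotyped broodstock,
large full-sib families, offspring genotyped on a low-density (LD) subset
of the HD panel, pedigree-based imputation back to HD, and GBLUP
cross-validation to measure what each strategy costs in prediction
accuracy. This note records the models, the defaults and why they were
chosen, and what the synthetic populations do and do not emulate.

## Synthetic populations

**Structure.** Two generations: `n_sires + n_dams` founders, full-sib
families formed by factorial mating (distinct sire x dam pairs drawn
uniformly) or monogamous pairing, a fixed number of offspring per family.
Phenotypes are recorded on offspring only, the sib-testing design of
commercial programmes. The salmon-like preset uses 60 parents, 100
families and 1,000 offspring with 10,000 SNPs on 20 chromosomes of 50 Mb /
50 cM each; the oyster-like preset is smaller (44 parents, 30 families)
with faster LD decay.

**Founder haplotypes and LD.** Founder haplotypes are mosaics of a small
pool of ancestral haplotypes (salmon-like: 8; oyster-like: 16). Between
adjacent SNPs the ancestor switches with probability
`1 - exp(-switch_rate * gap_bp)`, giving geometric segment lengths with a
single LD knob: `switch_rate = 0` copies ancestral haplotypes intact,
large values give free recombination. Two loci on the same ancestral
segment have expected r² of roughly `1/n_ancestral`; loci on different
segments are nearly independent, so the mean segment length
(`1/switch_rate` bp) sets the LD decay distance. The salmon-like preset
uses `2e-7`/bp (~5 Mb segments: elevated r² over a few Mb, near zero
beyond ~15 Mb, the long-range LD typical of salmonid broodstocks); the
oyster-like preset `2e-6`/bp (~0.5 Mb segments, rapid decay). The real
populations' LD decay is not known precisely, so these are loose "slow"
and "fast" presets, not calibrated fits. Per-SNP ancestral allele
frequencies default to Uniform(0.05, 0.5).

**Marker maps.** SNP positions are *clustered*: cluster centres uniform
along the chromosome, cluster weights Dirichlet(0.3), Laplace scatter
around the centre. This emulates the uneven coverage of RAD-seq and
array genotyping, which is the reason evenly-spaced panel selection exists
at all; with uniformly spread markers a random SNP subset covers the
genome as well as an evenly spaced one and the comparison between
selection strategies becomes vacuous. `clustering=0` restores uniform
positions.

**Recombination.** Gene-drop transmits recombinant gametes down the
pedigree: crossover counts per chromosome are Poisson with mean
`genetic_length_cM / 100` (Haldane, no interference), positions uniform on
the genetic map with a uniform cM/bp rate. Unspecified genetic lengths
default to 1 cM/Mb. Genotyping error is an optional symmetric
per-genotype flip, default 0.

**Traits.** Additive model `y = mu + Xb + Za + e`. QTL are drawn among
segregating SNPs with probability proportional to the physical interval
each SNP represents, so causal positions are uniform along the genome
rather than proportional to assay density — drawing QTL uniformly over
marker *columns* would concentrate genetic variance wherever the assay is
dense and invert the comparison between evenly-spaced and random panels.
Effects are Normal and rescaled so the realized breeding-value variance is
exactly `h2` of the phenotypic variance (residual variance
`(1-h2)/h2`, breeding values variance 1). Binary traits threshold the
liability at its empirical `1 - prevalence` quantile and are analysed
with the linear model on 0/1 codes; a logit-link GLMM is out of scope.
All randomness flows from one root seed through named substreams.

**What the generator does not emulate.** No half-sib structure from
repeated matings across years, no selection over generations, no
genotyping-batch artefacts, no misplaced markers, no sex chromosomes, and
founder LD comes from a mosaic model rather than a population-genetic
history. Passing tests therefore show that the pipeline behaves correctly
under the assumed family structure and LD, not that real datasets will
reproduce specific accuracy values.

## Quality control

Individuals are removed for missingness above 20% or for having exactly
one of their two parents genotyped (parents themselves are exempt). SNPs
are screened on missingness (>10%), exact Hardy-Weinberg deviation
(p < 1e-6, Wigginton-style exact test summing configurations no more
probable than the observed one), MAF (<0.05, strict inequality so
boundary values survive) and trio Mendelian-error rate (>10%). All four
statistics are computed on the input matrix — the kept set is the
intersection — and the removal reason records the first failure in that
fixed order. Mendelian-inconsistent genotypes are reported but never
altered or re-imputed. Per-individual missingness is computed on the raw
input, before SNP filtering. After imputation the MAF filter is applied
again, since frequency-based random fill can drain rare alleles.

## Panel design

**Physical.** The target count is split across chromosomes proportionally
to length (bp of the last mapped SNP, so no external assembly resource is
needed) by largest remainder, minimum 2 per chromosome. Within a
chromosome the first and last SNPs are always selected and the remaining
targets are equally spaced positions, each resolved to the nearest
not-yet-selected SNP (equidistant ties take the higher-bp SNP). A
chromosome with fewer SNPs than its allocation contributes all of them and
the shortfall is not redistributed.

**LD-based.** Windowed greedy r² pruning in the PLINK
`--indep-pairwise` style: within each window (50 SNPs, step 5, never
crossing a chromosome boundary) the highest-r² offending pair loses its
lower-MAF member (ties: the later SNP in map order) until no kept pair
exceeds the threshold. The threshold is bisected until the pruned set size
is as close to the target as achievable; exact density is then enforced by
trimming evenly indexed surplus SNPs or topping up with the highest-MAF
excluded SNPs, and the adjustment is logged. The pair-removal rule is this
package's own deterministic choice; bit-compatibility with PLINK is not
claimed. r² of a degenerate pair (no variance, fewer than two complete
observations) is defined as 0 so it never drives pruning.

**Random.** Uniform sample without replacement over the whole map.

Masking sets off-panel genotypes of the target individuals to missing;
reference parents keep their HD genotypes.

## Imputation

The reference imputer exploits the two-generation structure directly.

1. **Parent phasing.** Iterative haplotype-library phasing over
   overlapping marker windows (sized so the average parent holds ~6
   heterozygous sites, sliding by a third of their width, bit-coded for
   speed). Each parent is reassigned the compatible haplotype pair with
   the best library score — strict improvement only, which damps
   oscillation — oriented by agreement with the freshly updated left
   overlap so phase chains along the chromosome. With few parents
   (<= 24) exact-match frequencies are too sparse to bootstrap, so
   candidates also earn credit for genotype-compatibility with other
   parents. A final repair pass fixes orientation across long homozygous
   runs by long-match voting against other parents' haplotypes. An oracle
   mode accepts the simulator's true phases, which separates phasing error
   from decoding error in experiments. Phase remains ambiguous at sites
   where no other parent anchors the allele; those resolve arbitrarily.
2. **Offspring-transmission refinement.** At a parent-heterozygous
   informative marker the transmitted allele identifies the carried
   haplotype without decoding. A parent phase-switch error makes every
   offspring gamete appear to recombine in the same interval, whereas a
   true crossover affects one gamete; intervals where more than half of
   at least four spanning gametes flip are treated as phase errors and the
   parent's haplotypes are swapped from the interval's right edge on.
3. **Mendelian fill.** Offspring genotypes forced by hom x hom parent
   pairs are filled directly.
4. **Gamete-origin decoding.** Per offspring, chromosome and gamete, a
   two-state minimal-cost path over the informative markers (mismatch 1.0
   per disagreement; switch penalty `ln(informative markers per expected
   crossover)`, floored at 0.5), ties preferring fewer switches then
   haplotype 1. Informative markers are those whose transmitted allele is
   determined (offspring homozygous, or heterozygous with the other
   parent homozygous) and where the focal parent is heterozygous.
5. **Copying and random fill.** Parental alleles are copied along the
   decoded path; parent-homozygous sites are forced regardless of state.
   Sites strictly inside a switch interval (the crossover cannot be
   localised further), gametes with no informative markers, and
   individuals without two phased parents fall back to drawing each
   allele copy independently from the reference (parent) allele
   frequency — deliberate, honest noise rather than a guess, matching the
   random-fill convention of family imputation tools. Observed genotypes
   are never altered, and every entry carries a provenance tag
   (observed / mendelian / haplotype-copy / random-fill).

An adapter runs external imputers through PED/MAP or VCF files and
validates completeness and congruence; external tools are not bundled.

## Genomic evaluation

The GRM is `g_jk = (1/N) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2p_i(1-p_i))`
with allele frequencies from the supplied genotypes; monomorphic SNPs are
excluded, residual missing genotypes are mean-imputed (logged). REML for
`y = Xb + a + e`, `a ~ N(0, G sigma_a^2)` eigendecomposes G once, clamping
the spectrum at 0 — low-density GRMs are rank-deficient by construction
(rank bounded by the SNP count), and clamping in the eigenbasis makes G
PSD without a separate jitter-and-refactor step; the residual variance
term conditions every linear solve downstream. The restricted likelihood
profiles the phenotypic variance and is optimised over
`h2 in [1e-6, 1-1e-6]` with bounded scalar minimisation (xatol 1e-8).
GBLUP breeding values are `sigma_a^2 G[p,t] V_t^{-1} (y_t - X_t b_hat)`,
algebraically the mixed-model-equation solution without inverting G.
Prediction accuracy is `cor(EBV, y) / sqrt(h2)` with `h2` estimated once
from the full data on HD genotypes and reused for every panel.
Cross-validation runs 20 replicates of 5 folds drawn uniformly over
phenotyped individuals (no family stratification); variance components
are re-estimated on each training set; fold accuracies are averaged,
except singleton folds whose predictions are pooled per replicate.
A permuted-GRM control and an iid-limit closed form guard the solver in
the tests.

## Problem sizes

The shipped experiments run at desk scale on one CPU: the headline
evaluation uses the salmon-like preset (10,000 SNPs, 1,060 individuals)
with panels at 300 / 1,000 / 3,000 SNPs and 20x5-fold CV;
heritability-recovery experiments use 2,000-SNP genomes with 1,000
phenotyped offspring and 20 replicates per heritability. These sizes give
standard errors comfortably inside the tolerances asserted in the tests.

## Known limitations

- Founder LD is phenomenological; r² decay is tuned by one rate, not by
  demographic history.
- The two-state decoder treats gametes independently; markers where both
  parents and the offspring are heterozygous carry joint information it
  does not use.
- Random fill makes imputed rare-allele dosages noisy by design; the
  post-imputation MAF filter removes the worst-affected SNPs before GBLUP.
- Binary traits are analysed with a linear model on 0/1 codes; threshold
  or logit models are not implemented.
- The REML surface is unimodal in all tested settings, but the bounded
  scalar optimiser will sit at the boundary (flagged unconverged) when G
  carries no signal.
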