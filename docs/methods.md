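# Methods

This note records the models, estimators, parameter choices and known
limitations behind each module, in the order the pipeline runs.

## Genotype matrix, filtering, polarization

All statistics consume a diploid genotype matrix over biallelic SNPs (ALT
dosage 0/1/2, missing −1), with optional phased haplotypes. Coordinates
are 1-based at the VCF boundary and 0-based half-open wherever windows are
formed: a site at VCF position p lies in window [start, end) iff
start ≤ p−1 < end.

Filtering uses strict inequalities throughout: sites kept at QD > 2,
QUAL > 40, MQ > 30; calls kept at 2 < depth < 100 (outside set missing);
sites kept when the missing-call fraction is strictly below 20%. Absent
quality fields pass (and are logged), so pre-filtered VCFs flow through
unchanged. Half-missing diploid calls (`./1`) are treated as missing —
the upstream convention is not observable from a merged VCF, and dropping
half-calls avoids inventing an allele. Filtering is idempotent.

Ancestral alleles come from the outgroup genotypes alone: a site is
polarized iff at least one outgroup call is non-missing and every
non-missing outgroup call is homozygous for the same allele; anything
polymorphic (including a single heterozygote) leaves the site
unpolarized, a deliberately conservative guard against incomplete lineage
sorting. Polarization never alters genotype codes; the derived-dosage
view is genotype (ancestral = REF) or 2 − genotype (ancestral = ALT).

## Synthetic cohorts (the truth channel)

The generator emulates the statistical structure of the study panel
rather than its sequences. Defaults are the study conditions: group sizes
12 (CULAPO), 7 (CULSEX), 24 (WILDAPO), 11 (WILDSEX1), 17 (WILDSEX2) plus
15 outgroup accessions; two 5-Mb chromosomes; 5000 sites.

* Ancestral derived-allele frequencies are drawn with density ∝ 1/p on
  [0.02, 0.98] (a neutral-like spectrum truncated away from fixation).
* Group frequencies drift under the Balding–Nichols model,
  Beta(p(1−F)/F, (1−p)(1−F)/F). Drift defaults (F = 0.13 for the two wild
  sexual subpopulations, 0.02 WILDAPO, 0.05 cultivated) were chosen so the
  emulated differentiation echoes the reported structure — the two wild
  sexual subpopulations most differentiated (F_st ≈ 0.133), sexual-vs-
  apomict weaker. Under this model the Hudson ratio-of-sums F_st between
  two groups with drift F₁, F₂ has closed form (F₁+F₂)/2, which the tests
  exploit.
* Apomictic groups draw their two haplotypes from two independently
  drifted source pools (pool drift 0.08), producing the elevated
  heterozygosity apomixis preserves.
* A configurable fraction of sites (default 5%) is species-diagnostic:
  fixed derived in the cultivated groups, fixed ancestral in all wild
  groups and the outgroup. These are the recoverable species-specific
  markers, and they give introgressed tracts a measurable diagnostic-
  allele dosage.
* Introgression is planted by copying contiguous donor-drawn haplotype
  tracts (default 250 kb) into target haplotypes until the requested
  fraction of the sample's total haplotype content is reached; the
  realized fraction (exact to one tract) and every interval are recorded.
* Deleterious sites (default 2% of sites, disjoint from diagnostic sites)
  are annotated with score ≤ 0.05 and the per-sample heterozygous /
  homozygous-derived counts recorded exactly from the emitted genotypes.
* The outgroup is fixed ancestral at a configurable fraction of sites
  (default 1.0); the remainder is fixed derived, emulating
  outgroup-specific substitutions that polarization then gets wrong.

What the generator does *not* emulate: linkage disequilibrium within
groups (sites are exchangeable given the tract structure), recombination
maps, selection (which lives in the forward simulator), and sequence
context. Passing recovery tests therefore demonstrates estimator
correctness under the stated sampling model, not robustness to LD or
calling artefacts of real data.

The climate generator emits two 19-dimensional Gaussian clouds (default
244 wild / 152 cultivated records) sharing a two-factor covariance whose
pooled leading principal components carry ≈47.5% and ≈20.6% of the
variance — the shares reported for the real 396-record panel — with the
centre separation applied along the dominant factor. The default
separation (3.19 Mahalanobis units) is the closed-form solution of
P(χ²_nc(19, d²) ≤ χ²₁₉(0.95)) = 0.58, so the *true-distribution*
directional overlap matches the ~58% reported for the real ranges.
Finite-sample overlap estimates run below this truth (see Niche overlap).

## Windowed statistics

Per-site components are combined as ratio-of-sums within windows, so
adjacent windows recombine exactly. π and D_xy are normalized by window
length in bp by default (variant-only normalization is available via
`per_site=True`); windows need ≥10 usable sites by default (configurable;
the statistic is otherwise reported missing). The F_st estimator is fixed
as Hudson ratio-of-sums — robust, window-combinable — and stated in run
manifests. Tajima's D uses the 1989 constants at the group's full
haplotype count; sites with any missing call in the group are excluded so
a single n applies, and S = 0 windows are missing, not zero. Window sizes
default to 25 kb (π, F_st, D_xy, f_d) and 100 kb (Tajima's D,
heterozygosity peaks).

The uSFS bins derived-allele frequencies in (0, 1] into ten half-open
clusters ((k/10, (k+1)/10]; edge values fall in the lower bin);
unpolarized sites are dropped rather than folded.

## Runs of homozygosity

A 50-SNP sliding window is "homozygous" iff it contains ≤3 heterozygous
calls (missing calls are not heterozygous). A SNP is run-eligible iff the
proportion of overlapping homozygous windows is ≥0.05 (the upstream
tool's default hit rate, unstated in the study). Maximal eligible runs are
split at inter-SNP gaps ≥100 kb and kept iff ≥50 SNPs, span >500 kb
(strict) and density ≥10 SNPs/100 kb. Segment bounds are the first/last
SNP positions.

## Introgression statistics

Site patterns use per-group derived-allele frequencies at polarized
sites; ABBA = (1−p₁)p₂p₃(1−p₄), BABA = p₁(1−p₂)p₃(1−p₄). Patterson's D is
the genome-wide ratio of sums; its Z score comes from a delete-one block
jackknife over contiguous 5-Mb blocks (configurable; synthetic runs use
500 kb to keep ≥20 blocks), with the unweighted delete-one SE formula.
Uninformative (zero-denominator) blocks are dropped from the jackknife.

Windowed f_d substitutes, at each site, whichever of P2/P3 has the higher
derived frequency into both donor positions of the denominator. Windows
with D < 0 are masked by default, because f_d quantifies admixture in the
positive-D direction — but masking truncates the null distribution and
biases the mean of retained windows upward, so *null calibration* is
performed on the signed per-window values (`mask_negative_d=False`).
Per-window ratios are only stable with enough informative sites; the
calibration runs use ≥200 sites per window, in the direction of the real
panel's variant density (~760 variants per 25 kb).

The f-branch matrix assigns excess allele sharing to branches of a rooted
group tree: f_b(C) = median over A in the sister clade of [min over B
below the branch of f̂(A,B,C,O)], with f̂'s denominator the
homozygous-donor substitution (P2 := P3) — chosen over donor-splitting to
avoid within-group haplotype subsampling; the choice is recorded in run
manifests. Negative estimates floor at 0; cells for donors descended from
the branch are masked; significance is flagged at p < 0.001
(one-sided jackknife Z).

Species-specific markers require: all non-missing cultivated calls
homozygous for one allele, all non-missing wild-reference calls
homozygous for the other, per-group missingness ≤ a tolerance (default
0), and a fully genotyped, monomorphic outgroup — one concrete reading of
"use the outgroup to filter unfixed variants" as an ILS guard. The
per-individual introgression proportion is then the diagnostic-allele
dosage over genotyped markers: deterministic and assumption-free at fully
diagnostic sites, replacing supervised-ancestry software with the same
estimand. It is validated against planted tract fractions (±0.02 over 20
seeds).

## Genetic load

Deleterious status is taken from supplied scores (≤0.05 deleterious,
>0.05 tolerated; computing the scores is out of scope). Counts are
per-individual over polarized deleterious sites: total derived
deleterious alleles = heterozygous sites + 2 × homozygous-derived sites.
Sites that cannot be polarized are excluded and their number reported,
since the counting unit is the derived allele.

## Haplotype divergence

Genetic distance is the p-distance (proportion of differing sites among
jointly non-missing sites) between phased haplotypes in 25-kb windows.
Standardization divides by the window's mean pairwise distance over *all*
cohort haplotype pairs (the study's "mean value of each window" without a
named pair set; a per-sample alternative is available via the `samples`
argument). Which haplotype is "Hap2" is the caller's designation — the
original definition relies on tree clustering, which is out of scope.
`fraction_exceeding` uses a strict inequality; ties do not count.

## Forward simulation

Discrete-generation diploid Wright–Fisher on a 1-Mb sequence,
μ = 2.2×10⁻⁸ and r = 1×10⁻⁷ per bp per generation. Offspring pick their
parent(s) — self with probability equal to the selfing rate, otherwise
two distinct parents — and each gamete gets Poisson(rL) crossovers and
Poisson(μL) new mutations. New exonic mutations are deleterious with
probability 1 in the deleterious scenario, with |s| ~ gamma(shape 0.186,
mean 0.01) — stand-in values for the cited but unprinted DFE — and
h = 0. Fitness is multiplicative across homozygous-derived sites and acts
as viability (accept-reject) selection on offspring. The exon mask is
synthetic (exponential exon lengths, mean 250 bp, ~30% coverage),
standing in for the reference chromosome-1 exon table, which is not
shipped.

Timeline (times counted back from the present): burn-in 10N generations
at N, then bottleneck to 0.25N from 10,000 to 2,000 generations BP, then
a split into two 0.1N subpopulations (selfing rate 1 vs 0) until the
present. The caption-level "100k generations" conflicts with 10N = 10,000
at N = 1000; burn-in is exposed as a parameter and defaults to 10N for
internal consistency. The SNM control is constant-N, random-mating,
neutral-only, run for the same total generations by default
(`snm_generations` overrides; 10N suffices for equilibrium). Final
summaries (π per bp, heterozygosity, mean per-individual het/hom
deleterious counts, with fixed deleterious sites counted as homozygous)
come from a 20-diploid sample.

Scaled-down runs used by the reproduction script put N = 500 with every
schedule time halved (burn-in 5000, bottleneck 5000→1000 BP, SNM 5000
generations) and 30 replicates — sizes chosen so the three-arm contrast
(π_selfing < π_outcrossing < π_SNM, paired Wilcoxon) is well resolved.
Closed-form checks: the SNM arm at constant N matches π = 4Nμ (within 15%
over ≥20 replicates); complete selfing at constant size halves diversity
(Ne = N/(1+F), F→1), checked as a ratio of 0.5 ± 0.1; one-locus recessive
selection follows q' = q(1+sq)/(1+sq²).

Determinism: one generator seeded per replicate via a spawned seed
sequence; identical (config, seed) gives byte-identical results. A
replicate whose population's fitness collapses is retried on a fresh
derived seed (capped) and recorded.

## Niche overlap

The niche region of a label is {x : (x−μ)ᵀΣ⁻¹(x−μ) ≤ χ²₁₉(α)} at
α = 0.95. Directional overlap A→B is P(X ∈ region_B) for
X ~ N(μ_A, Σ_A), by Monte Carlo. The Bayesian estimator draws (μ, Σ) per
label from the noninformative normal–inverse-Wishart posterior
(Σ ~ IW(n−1, S), μ|Σ ~ N(x̄, Σ/n); 1000 draws × ≥100 points by default)
and reports the posterior mean and central 95% interval; the plug-in
estimator uses sample moments and is the deterministic test surface.
Overlap is directional and both directions are always reported. PCA
z-scores each variable before decomposition (a flag accepts
pre-standardized tables); percent variances sum to 100.

Known limitation: at d = 19 with 150–250 records per label, both
estimators are biased downward relative to the true-distribution overlap
(the inverse sample covariance inflates Mahalanobis distances;
E[Σ̂⁻¹] = Σ⁻¹(n−1)/(n−d−2)), so a panel whose true overlap is 58%
typically yields estimates near 40–50%. This is a property of the
estimator family, not of this implementation, and it affects the real
analysis identically.

## Problem sizes in the reproduction script

The script uses: one 71+15-accession cohort (5000 sites) for
differentiation and dosage; 50 no-flow cohorts (20,000 sites each) for
null calibration; 20 seeds for introgression recovery; N = 500 / 30
replicates for the simulation contrast; 5000 coalescent-drawn sites for
the uSFS check; and the 244/152-record climate panel with 10⁵ Monte Carlo
draws. These sizes were chosen as the smallest at which each check's
sampling error is comfortably inside its assertion band.
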