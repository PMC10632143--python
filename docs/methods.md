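# Methods

This note documents the statistical models implemented in `microclone`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Filtering model

Candidate mutations arrive as per-patient count matrices (alt reads and
depth per microbiopsy).  A mutation is *supported* if some sample covers
it at depth ≥ 4 with ≥ 3 alt reads; unsupported rows are set aside as
`low_support` and excluded from all downstream rates.

**Germline test.**  A heterozygous germline variant is present in every
cell, so its reads pooled over all of a patient's microbiopsies follow
Binomial(n, 0.5) (0.95 on the sex chromosomes of males, where the
reference bias of hemizygous calls shifts the expectation).  We test
two-sided (the minimum-likelihood exact test, with the customary
1 + 10⁻⁷ tie tolerance): depletion argues for a somatic origin, while
excess can arise from contamination, so both tails count against the
germline hypothesis.  Benjamini–Hochberg correction runs across the
patient's testable mutations; q > 10⁻³ is classified germline — note the
direction: a *large* q means the data are consistent with VAF 0.5.

**Overdispersion (ρ) filter.**  Recurrent sequencing artifacts hit a
small fraction of reads in *every* sample; true clonal mutations are at
substantial VAF in carrier samples and absent elsewhere.  Both are
captured by a beta-binomial with mean μ and overdispersion ρ: artifacts
have ρ ≈ 0, clonal calls large ρ.  ρ is maximized on a 100-point
log-spaced grid spanning [10⁻⁶, 10⁻⁰·⁰⁵] (the endpoints are part of the
filter's definition; the resolution is ours) and calls with ρ̂ < 0.1 are
artifacts.

The mean μ is *profiled over two candidates* rather than fixed at the
pooled VAF: the pooled VAF (the natural mean for a process spread evenly
across samples) and the mean VAF of alt-bearing samples (the natural
mean for a clone confined to few samples).  With the mean pinned to the
pooled VAF, a clonal mutation supported by 3–4 reads in one sample out
of ten has its maximum-likelihood ρ land just below 0.1 — the pooled
mean conflates low *prevalence* with low *overdispersion* — and the
filter would discard essentially every minimum-support true call at 56×.
Profiling the mean leaves artifact calls untouched (their two candidates
coincide) while keeping the verdict driven by overdispersion alone.
This choice is part of the filter's contract and the test-suite oracles
profile the same two candidates.  A limitation is intrinsic and worth
stating: a clone at carrier VAF ≲ 0.08 spread over two or more samples
is statistically indistinguishable from a thin artifact at this depth —
even the full (μ, ρ) profile puts such patterns below ρ = 0.1 — so some
loss of very-low-VAF calls is a property of the ρ < 0.1 rule itself, not
of the implementation.

**DBS merging** uses a two-sided Fisher exact test on the alt/ref counts
of adjacent substitutions in the best shared carrier sample; p ≥ 0.05
("not significantly different") merges, runs merge greedily left to
right, and the merged record carries the left site's counts.

**Sensitivity** is the fraction of one near-replicate's calls recovered
in its partner, symmetrized by averaging both directions per pair; the
median across pairs is reported.

## VAF clustering

Mutations are clustered by their VAF vectors with a Dirichlet-process
mixture: Chinese-restaurant-process prior over partitions,
Binomial(depth, θ) emissions per microbiopsy, θ ~ Beta(1, 1) integrated
out (collapsed Gibbs).  Samples with zero depth at a mutation contribute
no likelihood term — missing coverage is not evidence of absence, and
consequently an uncovered dimension's centroid stays at the prior mean.
The concentration α is resampled every sweep from a Gamma(1, 1)
hyperprior by the Escobar–West auxiliary-variable scheme, so the number
of occupied clusters is inferred (a per-sweep trace is attached to the
result for chain diagnostics).  Defaults: 3000 sweeps, 1000 burn-in,
thinning 5, initialized from a single cluster; scaled-down chains
(300–600 sweeps) are used throughout the tests, where the
label-switching-free quantities we consume (partitions, co-clustering
frequencies) stabilize within a few hundred sweeps at test problem
sizes.  The point estimate is the saved partition with the highest joint
posterior; clusters below `min_cluster_size` are dissolved into their
likeliest surviving cluster.  Clustering operates on the VAF scale;
cellular fractions are derived afterwards as CF = 2·VAF (diploid,
copy-neutral — copy-number analysis is out of scope).

## Clone phylogeny

For clusters A, B with per-microbiopsy CFs, evidence that B ⊂ A is
*strong* when CF_A + CF_B > 1 in at least one shared microbiopsy and
CF_B ≤ CF_A + ε in all of them (ε = 0.05 absorbs sampling noise at
moderate depth; the combined-CF test may be met in a single microbiopsy
while dominance must hold in all), *weak* when only dominance holds, and
the pair is independent when each exceeds the other somewhere.  Strong
evidence in both directions (near-identical profiles) is flagged as a
conflict and left unresolved.  Each cluster attaches to its smallest
strong — else smallest weak — superset, which effects the transitive
reduction; remaining clusters are root-level clones.  Pruning removes
nested nodes supported only by weak evidence (re-attaching their
children upward) and root-level childless clusters whose median VAF is
≤ 0.3, where a single "cluster" may in truth mix independent clones of
similar VAF.  Burdens are root-to-tip branch-length sums.

## Signatures

Spectra are counts over the canonical 96 pyrimidine-centred
trinucleotide classes.  The catalog bundles four entries: a UV-like
spectrum (C>T concentrated at 5'-pyrimidine contexts), a merged
clock-like SBS1/5 entry (C>T at NpCpG plus a flat component — the two
clock processes are correlated in tissue and are deliberately fitted as
one), an APOBEC-like entry (C>T/C>G at TpC) and the psoralen signature.
The three non-psoralen vectors are stylized, package-constructed spectra
(built programmatically, not copied from an external catalog): they
reproduce the qualitative shape of the corresponding processes, which is
all the synthetic experiments require; analyses of real cohorts should
substitute measured reference spectra via `SignatureCatalog.from_frame`.
The psoralen reference puts all mass on N[T>A]A, N[T>C]A and N[T>G]A —
mutated thymines with a 3' adenine, the interstrand-crosslink target of
photoactivated psoralens — with the T>A channel emphasized (0.5/0.3/0.2
over the three channels, uniform over 5' context; configurable).

Exposure attribution maximizes the multinomial mixture likelihood over
catalog weights by EM (stopping at relative log-likelihood change
< 10⁻⁸ or 10⁴ iterations); exposures are weights × total count, weights
below 10⁻³ are zeroed into an `unassigned` remainder, and
exposures + unassigned equals the spectrum total exactly.  Attribution
is scale-equivariant and matches a brute-force simplex grid search on
small catalogs.  On synthetic clones, attributed SBS1/5 burdens run
~4–6 % low because the flat clock component overlaps the UV spectrum;
this propagates into the recovered clock age effect (≈ 0.62 vs a
generative 0.65) and is the main systematic error of the supervised
replacement of de-novo extraction.

Damage potential enumerates every possible SBS in a gene set (toy gene
models with introns; splice sites are the 2 bp at each intron end;
pyrimidine-pair third-position changes and all other codon effects are
classified against the standard code, with stop-loss counted as
missense).  Each possible mutation of 96-class k carries weight
signature(k)/n_k with n_k the class's site count, so a uniform signature
against a uniform baseline gives ratios of exactly 1 by construction;
baselines (uniform or any signature) run through the same enumeration.

## Strand and replication analyses

The strand carrying the mutated T is read off ref/alt (ref T ⇒ reference
strand); the untranscribed strand of a gene is its coding strand.
Mutations in genes overlapping on both strands are excluded.  The TSS
analysis counts T>(ACG)/A>(CGT) mutations at TpA/ApT in twenty 1-kb bins
spanning ±10 kb of the TSS per expression quintile and per strand, rates
relative to the −10 kb bin; transcription-coupled damage (TCD) is tested
by a likelihood-ratio test between Gaussian linear models of the
untranscribed-strand per-bin counts with and without a
downstream-of-TSS indicator (bins unweighted by covered bp), and TCR
analogously on the transcribed strand.  Expression-decile rates are
counts per bp per decile relative to decile 1.  Replication effects
report the leading:lagging count ratio for the mutated-T strand (the
track stores the replication role of the reference strand per window;
the role flips with the mutated strand) and counts across timing bins
ascending early → late.  Pentanucleotide enrichment normalizes 5-mer
mutation counts by genomic 5-mer frequencies; ranks are invariant to
duplicating the mutation set.

## Burden models

Clone burdens are modelled with linear mixed models carrying random
intercepts for patient and for biopsy nested within patient
(statsmodels MixedLM; the nested term enters as a variance component).
ML fits are mandatory wherever two fits are compared by likelihood
ratio; REML is available for final variance estimates.  When the nested
structure is degenerate (e.g. one clone per biopsy) the biopsy component
is dropped and the fit is flagged as boundary rather than failed.  The
PUVA dose–response model regresses psoralen-attributed burden on the
ordinal exposure band (reference: no PUVA) with the same random effects.
The clonality analysis regresses per-patient median microbiopsy VAF on
age by OLS and tests a psoralen-positivity indicator by LRT.  Basal
stem-cell counts divide microbiopsy surface area by the footprint of a
9-μm-diameter cell (π·4.5² μm²).  A model-consistent detection
correction is isolated in one function: the probability that a mutation
at VAF v is genotyped, Σ_d Poisson(d; depth)·P(Bin(d, v) ≥ 3, d ≥ 4),
by which observed burdens can be divided.

## Synthetic cohorts: what they emulate, and what they do not

The generator produces patients (ages uniform 18–88, disease duration
uniform up to 40 y capped by age, PUVA bands 0 / 1–50 / 51–200 / >200
with probabilities 0.55/0.15/0.15/0.15), two biopsies each (lesional and
nonlesional), five microbiopsies per biopsy placed uniformly in a
2-mm section, with lognormal areas calibrated so the median founding
stem-cell count is ~30.

**Clonal geometry.**  Clones seed at microbiopsies (~1.2 seeds per
microbiopsy) and take a Beta(5, 2) share of the cells not yet occupied
by earlier clones, so fractions tile each microbiopsy and stay feasible
by construction.  A clone spans another microbiopsy with probability
base·exp(−d/500 μm) — spanning scales with clone extent because a small
clone covers little area — and is entirely absent (CF exactly 0)
otherwise.  Nested subclones (probability 0.3) take a Beta(3, 1.5) share
of the parent and localize to the parent's main microbiopsy.  This
geometry is calibrated so the median VAF of post-filter calls per
microbiopsy sits near 0.26–0.29, the oligoclonal regime of lesional
epidermis; it does not emulate stem-cell competition dynamics, selection
or real spatial clone shapes.

**Burdens.**  Per-clone process burdens follow the linear generative
model: non-psoralen totals grow by 14.6 exonic mutations/exome/year of
age (intercept 80, residual SD 150, patient SD 90, biopsy SD 60 — the
UV micro-heterogeneity of real skin is far larger; these SDs are chosen
to keep desk-scale cohorts informative); the clock-like component grows
by 0.65/year of age plus 0.16/year of disease duration (patient SD 2);
APOBEC episodes hit 2 % of clones (~120 mutations); psoralen burdens are
0 / 60 / 180 / 616 mutations per clone by PUVA band (clone SD 150,
patient SD 80), with 10 % of no-PUVA patients carrying a ~100-mutation
psoralen exposure (psoralen signatures occur without documented PUVA —
historical sunscreen or dietary psoralens).  Counts are Poisson; spectra
are multinomial draws from the catalog.  Reads are
Binomial(depth, CF/2) at Poisson(56) depth.  Germline spikes are
Binomial(depth, 0.5) in every sample (0.95 on male sex chromosomes);
artifacts share one success probability drawn U(0.01, 0.08) across all
samples.  Replicate pairs share a true mutation set with independent
89 % detection per member.

**Genic mutagenesis** places TpA mutations on a toy annotation
(1000 genes of 20 kb; spacing deliberately incommensurate with the
10-kb replication windows so genes sample all window phases), with a
1.72× untranscribed:transcribed ratio inside transcripts, expression-
dependent gene weights, a 1.09× leading:lagging ratio imposed by
rejection (exact in expectation) and a late>early timing gradient.

Passing recovery tests on these cohorts shows the estimators are
unbiased and correctly calibrated under the generative model; it does
not validate the pipeline against alignment artifacts, copy-number
variation, contamination between samples, or non-binomial read noise,
none of which the generator emulates.

## Numerical choices and degenerate inputs

Exact binomial p-values are computed by the minimum-likelihood rule with
a 1 + 10⁻⁷ tie tolerance, vectorized per unique depth.  Beta-binomial
likelihoods drop binomial coefficients (constant in ρ) and clip μ to
[10⁻³, 1 − 10⁻³].  Empty count matrices, single mutations, all-zero
spectra, one-sided strand sets, missing replication tracks, zero-depth
cells and zero-volume tissues all return defined results or explicit
errors (documented per function).  Ties in the max-VAF selection rule
break by genomic position.  Experiment sizes in tests (cohorts of
4–70 patients, chains of 300–600 sweeps, 10⁴–10⁵ genic mutations,
1000 null replicates) were chosen as the smallest sizes at which the
quantities under test are statistically decisive.

## Known limitations

- CF = 2·VAF assumes diploid copy-neutral genomes throughout.
- The ρ filter cannot retain clones below carrier VAF ≈ 0.08 at 56×
  (see above); burden comparisons should use the detection correction.
- Supervised attribution cannot discover signatures absent from the
  catalog; the bundled spectra are stylized stand-ins.
- Indels and DBS are not decomposed into signatures (spectra are
  computed and compared only); indel/DBS calls are assigned to clusters
  post hoc by VAF if needed.
- The clustering model is per-patient; no hierarchical sharing of
  cluster locations across patients.
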