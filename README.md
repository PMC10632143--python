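# microclone

Clonal deconvolution and mutagenesis analysis of laser-capture
microbiopsies of epidermis.

Somatic-mosaicism studies of skin dissect hundreds of tiny epidermal
fragments (microbiopsies, each descended from a few dozen basal stem
cells) and sequence each one to moderate depth.  Every microbiopsy is an
oligoclonal mixture, so nothing downstream — mutation burdens, signature
exposures, selection estimates — can be computed per sample; it has to
be computed per *clone*.  `microclone` implements that pipeline for
researchers analysing such data (or building methods for it):

1. **Call filtering** (`microclone.filtering`) — genotyping thresholds
   (depth ≥ 4, alt ≥ 3 in ≥ 1 sample), a pooled two-sided exact-binomial
   test against the germline hypothesis (VAF 0.5; 0.95 on male sex
   chromosomes) with Benjamini–Hochberg control (germline if q > 10⁻³),
   a beta-binomial overdispersion filter (grid-ML ρ over
   [10⁻⁶, 10⁻⁰·⁰⁵]; artifact if ρ̂ < 0.1), Fisher-test merging of
   adjacent substitutions into DBS calls, and replicate-based
   sensitivity estimation.
2. **VAF clustering** (`microclone.clustering`) — a Dirichlet-process
   mixture over per-mutation VAF vectors across a patient's
   microbiopsies (collapsed Gibbs, Binomial emissions with Beta(1,1)
   priors, Escobar–West resampling of the concentration α).
3. **Clone phylogeny** (`microclone.phylogeny`) — the statistical
   pigeonhole principle: clusters whose combined cellular fractions
   exceed 100 % in a microbiopsy must be nested; forests are built from
   the nesting relation and pruned where the principle is not decisive.
   Root-to-tip branch sums define clone burdens.
4. **Signature attribution** (`microclone.signatures`) — 96-class
   spectra, a psoralen reference signature (T>A/T>C/T>G confined to TpA
   dinucleotides, the footprint of PUVA photochemotherapy), supervised
   maximum-likelihood exposure attribution by multinomial EM, and
   damage-potential enumeration by annotation class.
5. **Strand & replication analyses** (`microclone.strand`) —
   untranscribed:transcribed asymmetry of genic TpA mutations, TSS
   ±10 kb profiles with transcription-coupled damage/repair LRTs,
   expression-decile rates, leading/lagging replication ratios and
   pentanucleotide (ApTpApT) enrichment.
6. **Burden models** (`microclone.burden`) — linear mixed models with
   patient and biopsy-in-patient random intercepts for age, disease
   duration and PUVA dose–response effects; median-VAF-vs-age clonality
   regression; basal-stem-cell estimates from microbiopsy area.
7. **Selection summaries** (`microclone.selection`) — volume-weighted
   per-gene mutated-cell fractions and paired Wilcoxon comparisons of
   lesional vs nonlesional skin.
8. **Synthetic cohorts** (`microclone.synthetic`) — a fully seeded
   generator producing all of the structure above with ground truth:
   spatially bounded nested clones, binomial reads at Poisson depth,
   germline/artifact contaminants, signature-mixture spectra with
   age/duration/PUVA effects, strand-asymmetric genic mutagenesis and
   near-replicate dissection pairs.

## Model sketch

For mutation *i* with alt/depth counts $(x_{ij}, d_{ij})$ over
microbiopsies *j*, cluster assignment follows a Chinese restaurant
process with collapsed Beta–Binomial likelihood
$x_{ij} \sim \mathrm{Bin}(d_{ij}, \theta_{z_i j})$,
$\theta_{kj} \sim \mathrm{Beta}(1,1)$.  Under the diploid copy-neutral
assumption the cellular fraction of cluster *k* in microbiopsy *j* is
$\mathrm{CF}_{kj} = 2\,\hat\theta_{kj}$; clusters A ⊃ B are nested when
$\mathrm{CF}_A + \mathrm{CF}_B > 1$ somewhere and
$\mathrm{CF}_B \le \mathrm{CF}_A$ everywhere.  Clone burdens $y_c$ are
modelled as
$y_c = \beta_0 + \beta_{\mathrm{age}}\,\mathrm{age} + \beta_{\mathrm{dur}}\,\mathrm{duration} + u_{\mathrm{patient}} + u_{\mathrm{biopsy}} + \varepsilon$
with nested random intercepts, ML fits for likelihood-ratio tests.

## Worked example

```python
import numpy as np
from microclone import (SimulationConfig, simulate_cohort, emit_reads,
                        spike_contaminants, filter_calls)

cfg = SimulationConfig(n_patients=2, rng_seed=7)
cohort, truth = simulate_cohort(cfg)
rng = np.random.default_rng(8)
pat = cohort.patients[0]
matrix = emit_reads(truth, cfg.mean_depth, cohort, pat.patient_id, rng)
matrix, flags = spike_contaminants(matrix, 0.05, 0.05, sex=pat.sex, rng=rng)
result = filter_calls(matrix, sex=pat.sex)
print(result["verdict"].value_counts())
```

prints (seed 7):

```
verdict
somatic        18718
artifact        1671
low_support     1107
germline        1024
```

i.e. of 22,520 candidate rows for this patient, 1,107 lack a sample with
≥ 3 alt reads at depth ≥ 4, 1,024 sit at VAF ≈ 0.5 in every sample (the
germline contaminants spiked above), 1,671 are thinly and evenly spread
across samples (recurrent artifacts, ρ̂ < 0.1 — the 1,024 artifact
spikes plus low-VAF borderline calls), and 18,718 survive as somatic
calls for clustering.  The same stages are scriptable from a shell:

```
microclone simulate --config cohort.yaml --out cohort/ --seed 7
microclone filter --matrix cohort/counts_P001.tsv --out flagged.tsv
microclone cluster --matrix counts.tsv --out clusters.tsv --seed 1
microclone tree --clusters clusters.centroids.tsv --sizes sizes.tsv --out tree.nwk
```

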