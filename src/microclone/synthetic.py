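"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates an LCM microbiopsy study of chronically inflamed
skin: patients carry nested, spatially decaying clones across
microbiopsies; reads are binomial samples of clone cellular fractions at
Poisson depth; germline contaminants sit near VAF 0.5 in every sample of
a patient; recurrent artifacts share a common low success probability
across samples (overdispersion ≈ 0); clone mutation spectra are mixtures
of UV, clock-like, APOBEC and psoralen processes whose burdens carry age,
disease-duration and PUVA-dose effects; genic mutagenesis is
strand-asymmetric.  Every emitted mutation has exactly one ground-truth
record, and all output is a pure function of the configuration seed.

Default effect sizes (the generator's study conditions):

* total non-psoralen exonic burden grows by 14.6 mutations/exome/year,
* the clock-like SBS1/5 component grows by 0.65 mutations/exome/year of
  age plus 0.16 mutations/exome/year of disease duration,
* the highest PUVA band (>200 cycles) adds 616 psoralen mutations/clone,
* per-dissection detection sensitivity is 0.89,
* genic TpA mutations fall 1.72× more often on the untranscribed strand,
* the leading replication strand carries 1.09× the lagging-strand rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    AnnotationTrack,
    CountMatrix,
    Microbiopsy,
    MutationCall,
    Patient,
    parse_class_label,
    CLASSES_96,
    revcomp,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: skin-surface area of one basal stem cell footprint (9 μm diameter), μm²
STEM_CELL_AREA = np.pi * 4.5**2


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort."""

    n_patients: int = 50
    age_range: tuple = (18.0, 88.0)
    duration_max: float = 40.0
    biopsies_per_patient: int = 2
    microbiopsies_per_biopsy: int = 5
    mean_clones_per_microbiopsy: float = 1.2
    mean_depth: float = 56.0

    # burden model (exonic mutations per exome; exome scale ~3e7 bp)
    age_effect: float = 14.6            # non-psoralen total, per year of age
    clock_age_effect: float = 0.65      # SBS1/5, per year of age
    duration_effect_sbs15: float = 0.16  # SBS1/5, per year of disease
    clock_intercept: float = 5.0
    burden_intercept: float = 80.0
    burden_noise_sd: float = 150.0
    patient_sd: float = 90.0
    biopsy_sd: float = 60.0
    clock_patient_sd: float = 2.0

    # PUVA / psoralen
    puva_band_probs: tuple = (0.55, 0.15, 0.15, 0.15)  # bands 0, 1-50, 51-200, >200
    puva_extra_burden: float = 616.0     # >200-cycle band, psoralen muts/clone
    puva_band_burdens: dict = field(
        default_factory=lambda: {"0": 0.0, "1-50": 60.0, "51-200": 180.0}
    )
    psoralen_clone_sd: float = 150.0
    psoralen_patient_sd: float = 80.0
    nonpuva_psoralen_rate: float = 0.1   # signature without documented PUVA
    nonpuva_psoralen_mean: float = 100.0

    # APOBEC episodes
    apobec_clone_rate: float = 0.02
    apobec_mean_burden: float = 120.0

    # signature mixture override (process -> weight); None = burden-driven
    signature_mixture: Optional[dict] = None

    # clonal geometry
    clone_spread_scale: float = 500.0    # μm, exponential decay of clone sharing
    # clone share of the unoccupied cells of its seed microbiopsy;
    # calibrated so the median VAF of detected mutations per microbiopsy
    # sits near 0.26, the oligoclonal regime of lesional epidermis
    base_cf_alpha: float = 5.0
    base_cf_beta: float = 2.0
    nest_prob: float = 0.3
    section_size: float = 2000.0         # μm
    median_area: float = 30.0 * STEM_CELL_AREA  # ≈30 founding stem cells
    area_sigma: float = 0.5
    median_volume: float = 2.0e5         # μm³
    volume_sigma: float = 0.6

    # contaminants and sensitivity
    germline_rate: float = 0.05
    artifact_rate: float = 0.05
    detection_sensitivity: float = 0.89

    # strand / replication mutagenesis
    strand_asymmetry_tpa: float = 1.72   # untranscribed : transcribed
    leading_lagging_ratio: float = 1.09
    expression_effect: float = 0.5
    timing_effect: float = 2.0           # late : early rate ratio

    rng_seed: int = 0

    def __post_init__(self):
        for r in (self.germline_rate, self.artifact_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not 0.0 < self.detection_sensitivity <= 1.0:
            raise ValueError("detection_sensitivity must be in (0, 1]")
        if self.signature_mixture is not None:
            total = sum(self.signature_mixture.values())
            if not np.isclose(total, 1.0):
                raise ValueError("signature_mixture weights must sum to 1")


PROCESSES = ("SBS7b-like", "SBS1/5-like", "APOBEC-like", "psoralen")

_SITES = ("leg", "arm", "trunk")


@dataclass
class Cohort:
    patients: list
    microbiopsies: list

    def patient_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.patients]).set_index("patient_id")

    def microbiopsy_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.microbiopsies]).set_index("sample_id")

    def samples_of(self, patient_id: str) -> list:
        return [m.sample_id for m in self.microbiopsies if m.patient_id == patient_id]


@dataclass
class CloneTruthSet:
    """Ground truth: clone table, clone × sample CF matrix, mutation table."""

    clones: pd.DataFrame      # indexed by clone_id
    cf: pd.DataFrame          # clone_id × sample_id cellular fractions
    mutations: pd.DataFrame   # one row per emitted somatic mutation


# --------------------------------------------------------------------------
# Clone-level burden generator (shared by the cohort and LMM experiments)
# --------------------------------------------------------------------------


def simulate_patients(config: SimulationConfig, rng) -> list:
    bands = ["0", "1-50", "51-200", ">200"]
    patients = []
    for i in range(config.n_patients):
        age = rng.uniform(*config.age_range)
        duration = rng.uniform(0.0, min(config.duration_max, age))
        band = bands[rng.choice(4, p=config.puva_band_probs)]
        patients.append(
            Patient(
                patient_id=f"P{i + 1:03d}",
                age=float(age),
                disease_duration=float(duration),
                puva_cycles_band=band,
                sex="male" if rng.random() < 0.5 else "female",
                uvb_history=bool(rng.random() < 0.25),
            )
        )
    return patients


def _clone_process_burdens(config, patient, n_clones, rng,
                           pso_patient_effect, b_patient, b_biopsy):
    """Per-clone expected burdens of each process, with stated noise."""
    age, dur = patient.age, patient.disease_duration or 0.0
    if config.signature_mixture is not None:
        total_mu = config.burden_intercept + config.age_effect * age
        total = rng.poisson(max(total_mu, 0.0), size=n_clones)
        w = np.array([config.signature_mixture.get(p, 0.0) for p in PROCESSES])
        return np.array([rng.multinomial(t, w) for t in total])

    uv_mu = (
        config.burden_intercept
        + (config.age_effect - config.clock_age_effect) * age
        + b_patient + b_biopsy
    )
    uv = np.maximum(uv_mu + rng.normal(0.0, config.burden_noise_sd, n_clones), 0.0)
    uv = rng.poisson(uv)

    clock_mu = max(
        config.clock_intercept
        + config.clock_age_effect * age
        + config.duration_effect_sbs15 * dur
        + rng.normal(0.0, config.clock_patient_sd),
        0.0,
    )
    clock = rng.poisson(clock_mu, size=n_clones)

    apo = np.where(
        rng.random(n_clones) < config.apobec_clone_rate,
        rng.poisson(config.apobec_mean_burden, n_clones),
        0,
    )

    band = patient.puva_cycles_band
    if band == ">200":
        pso_mu = config.puva_extra_burden
    else:
        pso_mu = config.puva_band_burdens.get(band, 0.0)
    pso_mu += pso_patient_effect
    pso = np.maximum(
        rng.normal(pso_mu, config.psoralen_clone_sd, n_clones), 0.0
    ) if pso_mu > 0 else np.zeros(n_clones)
    pso = rng.poisson(pso)

    return np.column_stack([uv, clock, apo, pso])


def simulate_clone_burdens(config: SimulationConfig,
                           rng=None) -> pd.DataFrame:
    """Clone-level burdens from the mixed-model generative process.

    One row per clone with patient covariates and true per-process
    mutation counts; this is the generative counterpart of the burden
    mixed models and is also used inside :func:`simulate_cohort`.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    patients = simulate_patients(config, rng)
    rows = []
    for pat in patients:
        b_p = rng.normal(0.0, config.patient_sd)
        pso_pat = (
            rng.normal(0.0, config.psoralen_patient_sd)
            if pat.puva_cycles_band != "0"
            else (config.nonpuva_psoralen_mean
                  if rng.random() < config.nonpuva_psoralen_rate else 0.0)
        )
        for b in range(config.biopsies_per_patient):
            biopsy_id = f"{pat.patient_id}_b{b + 1}"
            b_bi = rng.normal(0.0, config.biopsy_sd)
            n_clones = max(
                1,
                rng.poisson(
                    config.mean_clones_per_microbiopsy
                    * config.microbiopsies_per_biopsy / 2.0
                ),
            )
            burdens = _clone_process_burdens(
                config, pat, n_clones, rng, pso_pat, b_p, b_bi
            )
            for c in range(n_clones):
                rows.append(
                    {
                        "clone_id": f"{biopsy_id}_c{c + 1}",
                        "patient_id": pat.patient_id,
                        "biopsy_id": biopsy_id,
                        "age": pat.age,
                        "duration": pat.disease_duration,
                        "puva_band": pat.puva_cycles_band,
                        "sex": pat.sex,
                        "lesional": b == 0,
                        "site": _SITES[hash(biopsy_id) % len(_SITES)],
                        **{p: int(burdens[c, k]) for k, p in enumerate(PROCESSES)},
                    }
                )
    df = pd.DataFrame(rows).set_index("clone_id")
    df["total"] = df[list(PROCESSES)].sum(axis=1)
    return df


def sample_clone_spectra(burdens: pd.DataFrame, catalog, rng) -> pd.DataFrame:
    """Draw each clone's 96-class spectrum from its true process burdens."""
    vecs = {p: catalog[p] for p in PROCESSES}
    out = np.zeros((len(burdens), 96), dtype=np.int64)
    for i, (_, row) in enumerate(burdens.iterrows()):
        for p in PROCESSES:
            n = int(row[p])
            if n > 0:
                out[i] += rng.multinomial(n, vecs[p])
    return pd.DataFrame(out, index=burdens.index, columns=list(CLASSES_96))


# --------------------------------------------------------------------------
# Full cohort with spatial clones and mutation-level truth
# --------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, CloneTruthSet]:
    """Generate a cohort with spatially arranged clones and full ground truth.

    Each microbiopsy carries one or more clones whose cellular fractions
    decay exponentially with distance from the clone's seed microbiopsy
    (scale ``clone_spread_scale``); fractions in each microbiopsy are kept
    feasible (sum ≤ 1) by resampling.  With probability ``nest_prob`` a
    clone acquires a nested subclone confined within it.
    """
    rng = np.random.default_rng(config.rng_seed)
    patients = simulate_patients(config, rng)
    microbiopsies = []
    clone_rows, cf_rows, mut_frames = [], [], []
    catalog_vecs = _catalog_vectors()
    mut_counter = 0

    for pat in patients:
        b_p = rng.normal(0.0, config.patient_sd)
        pso_pat = (
            rng.normal(0.0, config.psoralen_patient_sd)
            if pat.puva_cycles_band != "0"
            else (config.nonpuva_psoralen_mean
                  if rng.random() < config.nonpuva_psoralen_rate else 0.0)
        )
        pat_samples = []
        for b in range(config.biopsies_per_patient):
            biopsy_id = f"{pat.patient_id}_b{b + 1}"
            b_bi = rng.normal(0.0, config.biopsy_sd)
            mbs = []
            for m in range(config.microbiopsies_per_biopsy):
                sid = f"{biopsy_id}_m{m + 1}"
                mbs.append(
                    Microbiopsy(
                        sample_id=sid,
                        patient_id=pat.patient_id,
                        biopsy_id=biopsy_id,
                        lesional=b == 0,
                        site=_SITES[hash(biopsy_id) % len(_SITES)],
                        x=float(rng.uniform(0, config.section_size)),
                        y=float(rng.uniform(0, config.section_size)),
                        volume=float(rng.lognormal(np.log(config.median_volume),
                                                   config.volume_sigma)),
                        area=float(rng.lognormal(np.log(config.median_area),
                                                 config.area_sigma)),
                        mean_depth=config.mean_depth,
                    )
                )
            microbiopsies.extend(mbs)
            pat_samples.extend(mbs)
            xy = np.array([[mb.x, mb.y] for mb in mbs])

            # seed clones at microbiopsies, CF decaying with distance
            clone_cfs, parents = [], []
            for m, mb in enumerate(mbs):
                k = 1 + rng.poisson(max(config.mean_clones_per_microbiopsy - 1, 0.0))
                for _ in range(k):
                    cf = _feasible_cf(clone_cfs, xy, m, config, rng)
                    clone_cfs.append(cf)
                    parents.append(None)
                    if rng.random() < config.nest_prob:
                        share = rng.beta(3.0, 1.5)
                        child = cf * share
                        # subclones localize: present in the parent's main
                        # microbiopsy, elsewhere only for large subclones
                        keep = rng.random(len(cf)) < share
                        keep[int(np.argmax(cf))] = True
                        child = child * keep
                        clone_cfs.append(child)
                        parents.append(len(clone_cfs) - 2)

            n_clones = len(clone_cfs)
            burdens = _clone_process_burdens(
                config, pat, n_clones, rng, pso_pat, b_p, b_bi
            )
            sample_ids = [mb.sample_id for mb in mbs]
            for c in range(n_clones):
                clone_id = f"{biopsy_id}_c{c + 1}"
                parent = parents[c]
                clone_rows.append(
                    {
                        "clone_id": clone_id,
                        "patient_id": pat.patient_id,
                        "biopsy_id": biopsy_id,
                        "parent": f"{biopsy_id}_c{parent + 1}" if parent is not None else None,
                        "age": pat.age,
                        "duration": pat.disease_duration,
                        "puva_band": pat.puva_cycles_band,
                        "lesional": b == 0,
                        "site": _SITES[hash(biopsy_id) % len(_SITES)],
                        **{p: int(burdens[c, k]) for k, p in enumerate(PROCESSES)},
                    }
                )
                cf_rows.append(pd.Series(clone_cfs[c], index=sample_ids, name=clone_id))
                mut_frames.append(
                    _clone_mutations(clone_id, pat.patient_id, burdens[c],
                                     catalog_vecs, mut_counter, rng)
                )
                mut_counter += int(burdens[c].sum())

    cohort = Cohort(patients=patients, microbiopsies=microbiopsies)
    clones = pd.DataFrame(clone_rows).set_index("clone_id")
    clones["total"] = clones[list(PROCESSES)].sum(axis=1)
    cf = pd.DataFrame(cf_rows)
    mutations = pd.concat(mut_frames, ignore_index=True)
    return cohort, CloneTruthSet(clones=clones, cf=cf, mutations=mutations)


def _feasible_cf(existing, xy, seed_idx, config, rng):
    """Draw a clone CF profile keeping per-microbiopsy totals ≤ 1.

    The clone is always present in its seed microbiopsy, where it takes a
    Beta-distributed share of the cells not yet occupied by earlier
    clones (so clones tile the microbiopsy and fractions stay feasible by
    construction).  It spans another microbiopsy with probability
    decaying exponentially in spatial distance and is entirely absent
    (CF exactly 0) otherwise.
    """
    d = np.linalg.norm(xy - xy[seed_idx], axis=1)
    occupancy = np.sum(existing, axis=0) if existing else np.zeros(len(xy))
    head = np.clip(1.0 - occupancy, 0.0, None)
    base = head[seed_idx] * rng.beta(config.base_cf_alpha, config.base_cf_beta)
    # spanning probability scales with clone extent: a clone occupying a
    # small cell fraction covers little area and rarely reaches neighbours
    present = rng.random(len(xy)) < base * np.exp(-d / config.clone_spread_scale)
    present[seed_idx] = True
    cf = np.minimum(
        base * present * rng.uniform(0.6, 1.0, size=len(xy)), 0.95 * head
    )
    cf[seed_idx] = base
    return cf


_CLASS_TRI = [parse_class_label(lab) for lab in CLASSES_96]


def _catalog_vectors():
    from .signatures import default_catalog

    cat = default_catalog()
    return {p: cat[p] for p in PROCESSES}


def _clone_mutations(clone_id, patient_id, burdens, vecs, start, rng):
    counts = {p: int(burdens[k]) for k, p in enumerate(PROCESSES)}
    total = sum(counts.values())
    if total == 0:
        return pd.DataFrame(
            columns=["mut_id", "clone_id", "patient_id", "process", "class96",
                     "chrom", "pos", "ref", "alt", "flag"]
        )
    class_idx, procs = [], []
    for p, n in counts.items():
        if n:
            draws = rng.multinomial(n, vecs[p])
            class_idx.append(np.repeat(np.arange(96), draws))
            procs.append(np.full(draws.sum(), p, dtype=object))
    class_idx = np.concatenate(class_idx)
    procs = np.concatenate(procs)
    flip = rng.random(total) < 0.5  # report on the purine strand half the time
    ref = np.array([_CLASS_TRI[i][0][1] for i in class_idx])
    alt = np.array([_CLASS_TRI[i][1] for i in class_idx])
    ref = np.where(flip, [_COMP[r] for r in ref], ref)
    alt = np.where(flip, [_COMP[a] for a in alt], alt)
    ids = start + np.arange(total)
    return pd.DataFrame(
        {
            "mut_id": ids,
            "clone_id": clone_id,
            "patient_id": patient_id,
            "process": procs,
            "class96": class_idx.astype(np.int16),
            "chrom": "chr1",
            "pos": 1000 + 7 * ids,
            "ref": ref,
            "alt": alt,
            "flag": "somatic",
        }
    )


# --------------------------------------------------------------------------
# Read emission and contaminant spiking
# --------------------------------------------------------------------------


def emit_reads(truth: CloneTruthSet, mean_depth: float, cohort: Cohort,
               patient_id: str, rng=None) -> CountMatrix:
    """Binomial read sampling for one patient's mutations.

    depth ~ Poisson(mean_depth); alt ~ Binomial(depth, CF/2) in samples
    where the mutation's clone is present, 0 elsewhere.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    samples = cohort.samples_of(patient_id)
    muts = truth.mutations[truth.mutations["patient_id"] == patient_id]
    cf = truth.cf.reindex(muts["clone_id"])[samples].to_numpy()
    cf = np.nan_to_num(cf, nan=0.0)
    depth = rng.poisson(mean_depth, size=cf.shape)
    alt = rng.binomial(depth, np.clip(cf / 2.0, 0.0, 1.0))
    calls = [
        MutationCall(chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt,
                     mut_class="SBS",
                     trinucleotide=CLASSES_96[int(r.class96)])
        for r in muts.itertuples(index=False)
    ]
    return CountMatrix(calls, samples, alt, depth)


def spike_contaminants(matrix: CountMatrix, germline_rate: float,
                       artifact_rate: float, sex: str = "female",
                       rng=None) -> tuple[CountMatrix, pd.Series]:
    """Add germline and artifact rows; returns (matrix, per-row truth flags).

    Germline spikes are Binomial(depth, 0.5) in *every* sample (0.95 on
    sex chromosomes in men); artifact spikes share one low success
    probability across all samples, the overdispersion-free profile of a
    recurrent sequencing error.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n, s = matrix.shape
    flags = ["somatic"] * n
    n_germ = int(round(germline_rate * n))
    n_art = int(round(artifact_rate * n))
    if n_germ == 0 and n_art == 0:
        return matrix, pd.Series(flags, name="flag")

    extra_calls, alt_rows, dep_rows = [], [], []
    base = 10**8
    for g in range(n_germ):
        on_x = sex == "male" and rng.random() < 0.1
        p0 = 0.95 if on_x else 0.5
        depth = rng.poisson(max(matrix.depth.mean(), 1.0), size=s)
        alt = rng.binomial(depth, p0)
        extra_calls.append(
            MutationCall(chrom="chrX" if on_x else "chr2", pos=base + g,
                         ref="A", alt="G")
        )
        alt_rows.append(alt)
        dep_rows.append(depth)
        flags.append("germline")
    for a in range(n_art):
        p_err = rng.uniform(0.01, 0.08)
        depth = rng.poisson(max(matrix.depth.mean(), 1.0), size=s)
        alt = rng.binomial(depth, p_err)
        extra_calls.append(
            MutationCall(chrom="chr3", pos=base + n_germ + a, ref="C", alt="T")
        )
        alt_rows.append(alt)
        dep_rows.append(depth)
        flags.append("artifact")

    extra = CountMatrix(extra_calls, list(matrix.samples),
                        np.array(alt_rows), np.array(dep_rows))
    return matrix.append_rows(extra), pd.Series(flags, name="flag")


def simulate_replicate_pairs(n_pairs: int, detection_sensitivity: float,
                             n_mutations: int = 400, rng=None) -> list:
    """Near-replicate dissections of the same tissue feature.

    Each pair shares one true mutation set; each mutation enters each
    member's call set independently with probability
    ``detection_sensitivity``.
    """
    if not 0.0 < detection_sensitivity <= 1.0:
        raise ValueError("sensitivity must be in (0, 1]")
    rng = np.random.default_rng(0) if rng is None else rng
    pairs = []
    for p in range(n_pairs):
        n = rng.poisson(n_mutations)
        ids = [f"pair{p}_mut{i}" for i in range(n)]
        in_a = rng.random(n) < detection_sensitivity
        in_b = rng.random(n) < detection_sensitivity
        pairs.append(
            (
                {m for m, keep in zip(ids, in_a) if keep},
                {m for m, keep in zip(ids, in_b) if keep},
            )
        )
    return pairs


# --------------------------------------------------------------------------
# Genic / strand-resolved mutations over a toy annotation
# --------------------------------------------------------------------------


def make_toy_annotation(n_genes: int = 1000, gene_length: int = 20_000,
                        spacing: int = 43_700, window: int = 10_000,
                        seed: int = 0) -> AnnotationTrack:
    """A toy single-chromosome annotation for strand analyses.

    Genes of fixed length alternate along the chromosome with lognormal
    expression; replication windows alternate leading/lagging in blocks
    with timing increasing along the chromosome (early → late).  The
    default spacing is deliberately incommensurate with the window size
    so gene positions sample all replication-window phases evenly.
    """
    rng = np.random.default_rng(seed)
    starts = spacing * np.arange(n_genes) + 15_000
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
    genes = pd.DataFrame(
        {
            "chrom": "chr1",
            "strand": strands,
            "start": starts,
            "end": starts + gene_length,
            "expression": rng.lognormal(2.0, 1.5, n_genes),
        },
        index=pd.Index([f"G{i + 1:04d}" for i in range(n_genes)], name="gene_id"),
    )
    genes["tss"] = np.where(strands == "+", genes["start"], genes["end"] - 1)
    span = int(starts[-1] + gene_length + window)
    w_start = np.arange(0, span, window)
    replication = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": w_start + 1,
            "end": w_start + window + 1,
            "timing": np.linspace(0.0, 1.0, len(w_start)),
            "rep_strand": np.where((w_start // window) % 2 == 0,
                                   "leading", "lagging"),
        }
    )
    return AnnotationTrack(genes=genes, replication=replication)


def simulate_genic_mutations(annotation: AnnotationTrack, n: int,
                             strand_asymmetry_tpa: float = 1.72,
                             expression_effect: float = 0.0,
                             leading_lagging_ratio: float = 1.09,
                             tcd_factor: float = 1.0,
                             tcr_factor: float = 1.0,
                             p_upstream: float = 0.25,
                             ata_enrichment: float = 1.0,
                             timing_effect: float = 1.0,
                             rng=None) -> pd.DataFrame:
    """TpA mutations over the annotation with stated strand asymmetries.

    Within transcripts the mutated T falls on the untranscribed strand
    ``strand_asymmetry_tpa`` times more often than on the transcribed
    strand (optionally modulated by TCD/TCR factors downstream of the
    TSS); genes are sampled with a rate declining in expression by
    ``expression_effect``; a thinning step imposes the genome-wide
    leading:lagging replication ratio and the late-vs-early timing effect.
    """
    if n <= 0:
        return pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "gene_id", "gene_strand",
                     "t_strand", "region", "on_tpa", "class96",
                     "pentanucleotide", "rep_strand", "timing"]
        )
    if annotation.genes["expression"].nunique() < 2:
        raise ValueError("annotation needs at least two expression levels")
    rng = np.random.default_rng(0) if rng is None else rng
    genes = annotation.genes
    expr_norm = genes["expression"].rank(pct=True).to_numpy()
    w_gene = np.exp(-expression_effect * expr_norm)
    w_gene /= w_gene.sum()
    rep = annotation.replication
    window = int(rep["end"].iloc[0] - rep["start"].iloc[0])
    rep_strand_plus = rep["rep_strand"].to_numpy()
    timing = rep["timing"].to_numpy()
    channels = ["A", "C", "G"]  # alt for a mutated T (T>A, T>C, T>G)
    chan_p = np.array([0.5, 0.3, 0.2])
    L = leading_lagging_ratio

    rows = []
    gene_ids = genes.index.to_numpy()
    tss = genes["tss"].to_numpy()
    gstrand = genes["strand"].to_numpy()
    while len(rows) < n:
        gi = rng.choice(len(gene_ids), p=w_gene)
        upstream = rng.random() < p_upstream
        offset = rng.integers(1, 10_000)
        sign = 1 if gstrand[gi] == "+" else -1
        pos = int(tss[gi] - sign * offset) if upstream else int(tss[gi] + sign * offset)
        if pos < 1:
            continue
        # transcription-strand choice for the mutated T
        if upstream:
            w_untx = w_tx = 1.0
        else:
            w_untx = strand_asymmetry_tpa * tcd_factor
            w_tx = 1.0 / tcr_factor
        on_untx = rng.random() < w_untx / (w_untx + w_tx)
        # untranscribed strand is the gene's coding strand
        t_strand = gstrand[gi] if on_untx else ("-" if gstrand[gi] == "+" else "+")
        # replication thinning: accept lagging-strand placements w.p. 1/L
        wi = min(pos // window, len(rep_strand_plus) - 1)
        plus_role = rep_strand_plus[wi]
        t_role = plus_role if t_strand == "+" else (
            "lagging" if plus_role == "leading" else "leading"
        )
        if t_role == "lagging" and rng.random() > 1.0 / max(L, 1e-9):
            continue
        # replication-timing thinning (late regions mutate more)
        if timing_effect != 1.0:
            t_norm = timing[wi]
            accept = (1.0 + (timing_effect - 1.0) * t_norm) / max(timing_effect, 1.0)
            if rng.random() > accept:
                continue
        chan = channels[rng.choice(3, p=chan_p)]
        if t_strand == "+":
            ref, alt = "T", chan
        else:
            ref, alt = "A", _COMP[chan]
        five = "ACGT"[rng.integers(4)]
        lab = f"{five}[T>{chan}]A"
        if rng.random() < ata_enrichment / (1.0 + ata_enrichment) and ata_enrichment != 1.0:
            penta = "ACGT"[rng.integers(4)] + "ATAT"
        else:
            penta = ("ACGT"[rng.integers(4)] + "ACGT"[rng.integers(4)]
                     + "TA" + "ACGT"[rng.integers(4)])
        rows.append(
            {
                "chrom": "chr1",
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene_id": gene_ids[gi],
                "gene_strand": gstrand[gi],
                "t_strand": t_strand,
                "region": "upstream" if upstream else "genic",
                "on_tpa": True,
                "class96": lab,
                "pentanucleotide": penta,
                "rep_strand": t_role,
                "timing": float(timing[wi]),
            }
        )
    return pd.DataFrame(rows)
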