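"""Shared domain types for the microbiopsy mutation pipeline.

The pipeline operates on candidate somatic mutations observed across many
laser-capture microbiopsies of epidermis from the same patient.  The central
container is :class:`CountMatrix` — a mutations × microbiopsies matrix of
alt-read and total-depth counts from which variant allele fractions (VAFs)
are derived.  Under the diploid, copy-neutral assumption used throughout,
the cellular fraction (CF) of a heterozygous mutation is twice its VAF.

Coordinates are 1-based (VCF convention); intervals are half-open
``[start, end)`` for window arithmetic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Trinucleotide (96-class) machinery
# --------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: The six pyrimidine-centred substitution types, COSMIC order.
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_BASES = ("A", "C", "G", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _build_classes() -> tuple:
    labels = []
    for sub in SUBSTITUTIONS:
        for five in _BASES:
            for three in _BASES:
                labels.append(f"{five}[{sub}]{three}")
    return tuple(labels)


#: Canonical ordering of the 96 trinucleotide substitution classes.
CLASSES_96 = _build_classes()

_CLASS_INDEX = {label: i for i, label in enumerate(CLASSES_96)}


def normalize_substitution(trinucleotide: str, alt: str) -> tuple[str, str]:
    """Pyrimidine-normalize a substitution given its reference trinucleotide.

    ``trinucleotide`` is the 3-mer of reference sequence centred on the
    mutated base.  If the central base is a purine the context is reverse
    complemented and the alt complemented, so that the central base is
    always C or T.  Applying the transformation twice is the identity.
    """
    tri = trinucleotide.upper()
    alt = alt.upper()
    if len(tri) != 3:
        raise ValueError(f"trinucleotide must be a 3-mer, got {trinucleotide!r}")
    if tri[1] in "AG":
        tri = revcomp(tri)
        alt = alt.translate(_COMPLEMENT)
    return tri, alt


def class_label(trinucleotide: str, alt: str) -> str:
    """Canonical 96-class label (e.g. ``"T[C>T]A"``) for an SBS."""
    tri, alt = normalize_substitution(trinucleotide, alt)
    ref = tri[1]
    if ref == alt:
        raise ValueError("ref and alt identical after normalization")
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


def class_index(trinucleotide: str, alt: str) -> int:
    """Index of an SBS in :data:`CLASSES_96`."""
    return _CLASS_INDEX[class_label(trinucleotide, alt)]


def parse_class_label(label: str) -> tuple[str, str]:
    """Inverse of :func:`class_label`: return (trinucleotide, alt)."""
    five, rest = label[0], label[2:-2]
    three = label[-1]
    ref, alt = rest.split(">")
    return five + ref + three, alt


def is_tpa_class(label: str) -> bool:
    """True when the class is a mutated T with a 3' A (psoralen target).

    Psoralen photoadducts crosslink thymines at TpA dinucleotides, producing
    T>A, T>C and T>G substitutions in the ``N[T>*]A`` classes.
    """
    tri, _alt = parse_class_label(label)
    return tri[1] == "T" and tri[2] == "A"


# --------------------------------------------------------------------------
# Clinical / sample metadata
# --------------------------------------------------------------------------

#: Ordinal PUVA-exposure bands (number of photochemotherapy cycles).
PUVA_BANDS = ("0", "1-50", "51-200", ">200", "unknown")


@dataclass(frozen=True)
class Patient:
    """A study participant."""

    patient_id: str
    age: float
    disease_duration: Optional[float] = None
    puva_cycles_band: str = "0"
    sex: str = "female"
    uvb_history: bool = False

    def __post_init__(self):
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.disease_duration is not None and self.disease_duration > self.age:
            raise ValueError("disease duration cannot exceed age")
        if self.puva_cycles_band not in PUVA_BANDS:
            raise ValueError(f"unknown PUVA band {self.puva_cycles_band!r}")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")


@dataclass(frozen=True)
class Microbiopsy:
    """One LCM-dissected fragment of epidermis.

    ``x``/``y`` are positions within the tissue section in μm; ``volume``
    is the dissected volume in μm³ and ``area`` the skin-surface projection
    in μm² (used to estimate the number of founding basal stem cells).
    """

    sample_id: str
    patient_id: str
    biopsy_id: str
    lesional: bool = True
    site: str = "unknown"
    x: float = 0.0
    y: float = 0.0
    volume: float = 1.0
    area: float = 1.0
    mean_depth: float = 0.0

    def __post_init__(self):
        if self.volume <= 0 or self.area <= 0:
            raise ValueError("volume and area must be positive")


@dataclass
class MutationCall:
    """A candidate somatic mutation (SBS, DBS or indel)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    mut_class: str = "SBS"
    trinucleotide: Optional[str] = None  # 96-class label, e.g. "T[C>T]A"
    pentanucleotide: Optional[str] = None
    gene_id: Optional[str] = None
    on_tpa: bool = False

    def __post_init__(self):
        if self.mut_class == "SBS":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError(f"invalid SBS {self.ref}>{self.alt}")
        if self.trinucleotide is not None and self.mut_class == "SBS":
            if self.trinucleotide not in _CLASS_INDEX:
                raise ValueError(f"unknown 96-class label {self.trinucleotide!r}")
            if not self.on_tpa:
                self.on_tpa = is_tpa_class(self.trinucleotide)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def infer_mut_class(ref: str, alt: str) -> str:
    """Classify a call as SBS / DBS / indel from allele lengths."""
    if len(ref) == 1 and len(alt) == 1:
        return "SBS"
    if len(ref) == 2 and len(alt) == 2:
        return "DBS"
    return "indel"


# --------------------------------------------------------------------------
# Count matrix
# --------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Alt-read and depth counts for mutations × microbiopsies.

    VAF is defined as alt/depth where depth > 0 and is undefined (NaN),
    not zero, at uncovered cells.
    """

    mutations: list
    samples: list
    alt: np.ndarray
    depth: np.ndarray

    def __post_init__(self):
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        n, s = len(self.mutations), len(self.samples)
        if self.alt.shape != (n, s) or self.depth.shape != (n, s):
            raise ValueError("alt/depth shapes inconsistent with labels")
        if (self.alt < 0).any() or (self.depth < 0).any():
            raise ValueError("negative counts")
        bad = np.argwhere(self.alt > self.depth)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"alt > depth at mutation {self.mutations[i].key}, "
                f"sample {self.samples[j]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.alt.shape

    def vaf(self) -> np.ndarray:
        """VAF matrix with NaN where depth is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.alt / np.where(self.depth > 0, self.depth, np.nan)
        return v

    def keys(self) -> list[str]:
        return [m.key for m in self.mutations]

    def subset_rows(self, idx: Sequence[int]) -> "CountMatrix":
        idx = list(idx)
        return CountMatrix(
            [self.mutations[i] for i in idx], list(self.samples),
            self.alt[idx], self.depth[idx],
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        cols = [self.samples.index(s) for s in sample_ids]
        return CountMatrix(
            list(self.mutations), [self.samples[c] for c in cols],
            self.alt[:, cols], self.depth[:, cols],
        )

    def append_rows(self, other: "CountMatrix") -> "CountMatrix":
        if other.samples != self.samples:
            raise ValueError("sample sets differ")
        return CountMatrix(
            self.mutations + other.mutations, list(self.samples),
            np.vstack([self.alt, other.alt]),
            np.vstack([self.depth, other.depth]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy TSV-ready frame: chrom, pos, ref, alt, then ALT_/DEP_ columns."""
        rec = {
            "chrom": [m.chrom for m in self.mutations],
            "pos": [m.pos for m in self.mutations],
            "ref": [m.ref for m in self.mutations],
            "alt": [m.alt for m in self.mutations],
        }
        df = pd.DataFrame(rec)
        for j, s in enumerate(self.samples):
            df[f"ALT_{s}"] = self.alt[:, j]
            df[f"DEP_{s}"] = self.depth[:, j]
        return df


# --------------------------------------------------------------------------
# Annotation track
# --------------------------------------------------------------------------


@dataclass
class AnnotationTrack:
    """Gene and replication annotation used by the strand analyses.

    ``genes``: DataFrame indexed by gene_id with columns
    ``chrom, strand ('+'/'-'), tss, start, end, expression`` — positions
    1-based, intervals half-open [start, end).

    ``replication``: optional DataFrame of windows with columns
    ``chrom, start, end, timing, rep_strand`` where ``rep_strand`` is the
    replication role ('leading'/'lagging') of the *reference* (+) strand
    in that window and ``timing`` increases from early to late.
    """

    genes: pd.DataFrame
    replication: Optional[pd.DataFrame] = None

    def __post_init__(self):
        required = {"chrom", "strand", "tss", "start", "end", "expression"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"gene table missing columns {sorted(missing)}")
        if not self.genes["strand"].isin(["+", "-"]).all():
            raise ValueError("gene strand must be '+' or '-'")
        if self.replication is not None:
            req = {"chrom", "start", "end", "timing", "rep_strand"}
            missing = req - set(self.replication.columns)
            if missing:
                raise ValueError(f"replication track missing {sorted(missing)}")

    def expression_bins(self, n_bins: int) -> pd.Series:
        """Assign genes to ``n_bins`` equal-size bins of ascending expression."""
        ranks = self.genes["expression"].rank(method="first")
        return pd.Series(
            pd.qcut(ranks, n_bins, labels=False), index=self.genes.index,
            name="expression_bin",
        )
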