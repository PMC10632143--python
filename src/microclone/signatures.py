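"""Mutational-signature spectra and supervised exposure attribution.

Each clone's SBS calls are summarized as counts over the 96
trinucleotide substitution classes and decomposed against a fixed catalog
of reference spectra by maximum-likelihood multinomial mixture fitting
(EM).  The catalog bundles stylized spectra for the processes active in
sun-exposed skin — UV (SBS7b-like), the clock-like SBS1/5 pair (which are
correlated and fitted as one entry), APOBEC (SBS2/13-like) — plus the
psoralen signature: T>A, T>C and T>G substitutions restricted to TpA
dinucleotides, the mutational footprint of psoralen photoadducts formed
during PUVA photochemotherapy.

The bundled non-psoralen spectra are synthetic, package-constructed
vectors that mimic the qualitative shape of the corresponding processes;
they are built programmatically, not copied from an external catalog.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CLASSES_96, class_label, parse_class_label, revcomp

__all__ = [
    "SignatureCatalog",
    "default_catalog",
    "psoralen_reference",
    "spectrum_96",
    "fit_exposures",
    "cosine_similarity",
    "damage_potential",
    "ToyGene",
    "make_toy_genes",
]

_SUB_OF = [lab[2:5] for lab in CLASSES_96]
_FIVE_OF = [lab[0] for lab in CLASSES_96]
_THREE_OF = [lab[-1] for lab in CLASSES_96]


@dataclass
class SignatureCatalog:
    """Reference spectra: rows are signatures over the 96 classes."""

    names: list
    matrix: np.ndarray  # K × 96, rows sum to 1

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.names), 96):
            raise ValueError("catalog matrix must be K × 96")
        if (self.matrix < 0).any():
            raise ValueError("negative signature probabilities")
        rows = self.matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("signature rows must sum to 1")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.matrix[self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.T, index=list(CLASSES_96), columns=self.names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureCatalog":
        return cls(list(df.columns), df.reindex(list(CLASSES_96)).to_numpy().T)


def _normalized(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    return w / w.sum()


def _uv_like() -> np.ndarray:
    # C>T dominated, strongly favouring a 5' pyrimidine (dipyrimidine UV damage)
    w = np.full(96, 0.05)
    for i, lab in enumerate(CLASSES_96):
        if _SUB_OF[i] == "C>T":
            w[i] = 12.0 if _FIVE_OF[i] in "CT" else 1.5
        elif _SUB_OF[i] == "C>A":
            w[i] = 0.15
    return _normalized(w)


def _clock_like() -> np.ndarray:
    # merged SBS1 (C>T at NpCpG) + SBS5 (flat, mild T>C lean) entry
    sbs1 = np.zeros(96)
    for i, lab in enumerate(CLASSES_96):
        if _SUB_OF[i] == "C>T" and _THREE_OF[i] == "G":
            sbs1[i] = 1.0
    sbs5 = np.ones(96)
    for i in range(96):
        if _SUB_OF[i] == "T>C":
            sbs5[i] = 2.0
    return _normalized(0.25 * _normalized(sbs1) + 0.75 * _normalized(sbs5))


def _apobec_like() -> np.ndarray:
    # C>T and C>G at TpC (SBS2 + SBS13 merged)
    w = np.full(96, 0.02)
    for i in range(96):
        if _FIVE_OF[i] == "T" and _SUB_OF[i] in ("C>T", "C>G"):
            w[i] = 6.0
    return _normalized(w)


def psoralen_reference(t_to_a: float = 0.5, t_to_c: float = 0.3,
                       t_to_g: float = 0.2) -> np.ndarray:
    """The psoralen signature: T>A/T>C/T>G confined to TpA sites.

    All probability mass sits on the ``N[T>*]A`` classes (a mutated T with
    a 3' A on either strand).  Within-class weights are configurable with
    the T>A channel emphasized by default.
    """
    weights = {"T>A": t_to_a, "T>C": t_to_c, "T>G": t_to_g}
    w = np.zeros(96)
    for i in range(96):
        if _SUB_OF[i] in weights and _THREE_OF[i] == "A":
            w[i] = weights[_SUB_OF[i]] / 4.0  # uniform over the four 5' bases
    return _normalized(w)


def default_catalog() -> SignatureCatalog:
    """Four-entry catalog used for attribution on synthetic cohorts."""
    return SignatureCatalog(
        names=["SBS7b-like", "SBS1/5-like", "APOBEC-like", "psoralen"],
        matrix=np.vstack([_uv_like(), _clock_like(), _apobec_like(),
                          psoralen_reference()]),
    )


# --------------------------------------------------------------------------
# Spectra
# --------------------------------------------------------------------------


def spectrum_96(mutations) -> tuple[np.ndarray, int]:
    """Counts over the canonical 96 classes; returns (vector, n_excluded).

    Mutations without a trinucleotide context (or non-SBS calls) are
    excluded and counted.
    """
    counts = np.zeros(96)
    excluded = 0
    index = {lab: i for i, lab in enumerate(CLASSES_96)}
    for m in mutations:
        lab = getattr(m, "trinucleotide", None) if not isinstance(m, str) else m
        if lab is None or lab not in index:
            excluded += 1
            continue
        counts[index[lab]] += 1
    return counts, excluded


def cosine_similarity(a, b) -> float:
    """Cosine similarity of two non-negative spectra; 0 if either is empty."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("spectra must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("cosine similarity of an all-zero spectrum is reported as 0")
        return 0.0
    return float(np.dot(a, b) / (na * nb))


# --------------------------------------------------------------------------
# Exposure fitting
# --------------------------------------------------------------------------


def fit_exposures(spectrum, catalog: SignatureCatalog,
                  sparsity_threshold: float = 1e-3,
                  tol: float = 1e-8, max_iter: int = 10_000) -> pd.Series:
    """Maximum-likelihood multinomial-mixture attribution of a spectrum.

    EM on mixture weights over the catalog rows; exposures are weights ×
    total count.  Weights below ``sparsity_threshold`` (as a fraction of
    the total) are zeroed and their mass reported as ``unassigned``, so
    that exposures + unassigned always equals the spectrum total.
    """
    x = np.asarray(spectrum, dtype=float)
    if (x < 0).any():
        raise ValueError("spectrum must be non-negative")
    S = catalog.matrix  # K × 96
    K = S.shape[0]
    total = x.sum()
    out_index = list(catalog.names) + ["unassigned"]
    if total == 0:
        return pd.Series(np.zeros(K + 1), index=out_index)
    w = np.full(K, 1.0 / K)
    ll_old = -np.inf
    for _ in range(max_iter):
        mix = w @ S  # 96
        mix = np.where(mix > 0, mix, 1e-300)
        ll = float(x @ np.log(mix))
        if ll - ll_old < tol * max(1.0, abs(ll)):
            break
        ll_old = ll
        resp = (w[:, None] * S) / mix[None, :]  # K × 96
        w = resp @ x
        w /= w.sum()
    exposures = w * total
    small = w < sparsity_threshold
    exposures[small] = 0.0
    unassigned = total - exposures.sum()
    if abs(unassigned) < 1e-9:
        unassigned = 0.0
    return pd.Series(np.concatenate([exposures, [unassigned]]), index=out_index)


def attribute_clones(spectra: pd.DataFrame, catalog: SignatureCatalog,
                     **kwargs) -> pd.DataFrame:
    """Fit exposures for each clone (rows of ``spectra`` are 96-vectors)."""
    rows = {cid: fit_exposures(row.to_numpy(), catalog, **kwargs)
            for cid, row in spectra.iterrows()}
    return pd.DataFrame(rows).T


# --------------------------------------------------------------------------
# Damage potential by annotation class
# --------------------------------------------------------------------------

_CODON_TABLE = {}


def _translate(codon: str) -> str:
    if not _CODON_TABLE:
        bases = "TCAG"
        aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
        for i, b1 in enumerate(bases):
            for j, b2 in enumerate(bases):
                for k, b3 in enumerate(bases):
                    _CODON_TABLE[b1 + b2 + b3] = aas[16 * i + 4 * j + k]
    return _CODON_TABLE[codon]


@dataclass
class ToyGene:
    """A small gene model on its own sequence (always + strand).

    ``exons`` are half-open [start, end) intervals in 0-based sequence
    coordinates; their concatenation is the CDS.
    """

    name: str
    seq: str
    exons: list

    def cds(self) -> str:
        return "".join(self.seq[s:e] for s, e in self.exons)

    def splice_positions(self) -> set:
        """2 bp at each intron end (donor and acceptor sites)."""
        pos = set()
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            pos.update((e1, e1 + 1, s2 - 2, s2 - 1))
        return pos


def make_toy_genes(n_genes: int = 6, n_codons: int = 40, seed: int = 7) -> list:
    """Programmatically built toy gene models with introns and flanks."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
              if _translate(a + b + c) != "*"]
    genes = []
    for g in range(n_genes):
        body = ["ATG"] + [codons[i] for i in rng.integers(0, len(codons), n_codons - 2)]
        body.append("TAA")
        cds = "".join(body)
        # split CDS into three exons with 30 bp introns between
        cut1, cut2 = len(cds) // 3, 2 * len(cds) // 3
        intron = lambda: "GT" + "".join(rng.choice(bases, 26)) + "AG"
        flank = lambda: "".join(rng.choice(bases, 10))
        f5, i1, i2, f3 = flank(), intron(), intron(), flank()
        seq = f5 + cds[:cut1] + i1 + cds[cut1:cut2] + i2 + cds[cut2:] + f3
        e1 = (len(f5), len(f5) + cut1)
        e2 = (e1[1] + len(i1), e1[1] + len(i1) + (cut2 - cut1))
        e3 = (e2[1] + len(i2), e2[1] + len(i2) + (len(cds) - cut2))
        genes.append(ToyGene(name=f"gene{g + 1}", seq=seq, exons=[e1, e2, e3]))
    return genes


def _enumerate_site_classes(genes) -> pd.DataFrame:
    """All possible SBS in the gene set with 96-class and annotation class."""
    rows = []
    for gene in genes:
        cds = gene.cds()
        if len(cds) % 3 != 0 or "*" in [
            _translate(cds[i:i + 3]) for i in range(0, len(cds) - 3, 3)
        ]:
            warnings.warn(f"{gene.name} has no valid ORF; excluded")
            continue
        cds_map = {}
        k = 0
        for s, e in gene.exons:
            for p in range(s, e):
                cds_map[p] = k
                k += 1
        splice = gene.splice_positions()
        for p in sorted(set(cds_map) | splice):
            if p < 1 or p >= len(gene.seq) - 1:
                continue
            tri = gene.seq[p - 1:p + 2]
            ref = gene.seq[p]
            for alt in "ACGT":
                if alt == ref:
                    continue
                lab = class_label(tri, alt)
                if p in splice and p not in cds_map:
                    ann = "splice"
                else:
                    ci = cds_map[p]
                    codon_i, off = divmod(ci, 3)
                    codon = cds[3 * codon_i:3 * codon_i + 3]
                    new = codon[:off] + alt + codon[off + 1:]
                    aa_old, aa_new = _translate(codon), _translate(new)
                    if aa_new == aa_old:
                        ann = "synonymous"
                    elif aa_new == "*":
                        ann = "nonsense"
                    else:
                        ann = "missense"
                rows.append((lab, ann))
    return pd.DataFrame(rows, columns=["class96", "annotation"])


def _expected_fractions(signature: np.ndarray, sites: pd.DataFrame) -> pd.Series:
    """Expected fraction of mutations per annotation class under a signature.

    Each possible SBS of 96-class k carries weight signature[k] / n_k,
    where n_k is the number of possible SBS of that class in the region;
    fractions are normalized over the annotation classes present.
    """
    idx = {lab: i for i, lab in enumerate(CLASSES_96)}
    n_k = sites["class96"].value_counts()
    weight = sites["class96"].map(
        lambda lab: signature[idx[lab]] / n_k[lab]
    )
    f = weight.groupby(sites["annotation"]).sum()
    return f / f.sum()


def damage_potential(signature, genes, baseline="uniform") -> pd.DataFrame:
    """Normalized damage-potential ratios per annotation class.

    For each class (synonymous / missense / nonsense / splice) the
    expected fraction of mutations under ``signature`` is divided by the
    expected fraction under the baseline signature (``"uniform"``, a
    96-vector, or a catalog-style array), both computed by exhaustive
    enumeration of every possible SBS in the gene set.
    """
    signature = np.asarray(signature, dtype=float)
    if isinstance(baseline, str):
        if baseline != "uniform":
            raise ValueError("baseline must be 'uniform' or a 96-vector")
        base_vec = np.full(96, 1.0 / 96)
    else:
        base_vec = np.asarray(baseline, dtype=float)
    sites = _enumerate_site_classes(genes)
    if sites.empty:
        raise ValueError("no valid gene models")
    f_sig = _expected_fractions(signature / signature.sum(), sites)
    f_base = _expected_fractions(base_vec / base_vec.sum(), sites)
    order = [c for c in ("synonymous", "missense", "nonsense", "splice")
             if c in f_sig.index]
    out = pd.DataFrame({
        "fraction_signature": f_sig.reindex(order),
        "fraction_baseline": f_base.reindex(order),
    })
    out["ratio"] = out["fraction_signature"] / out["fraction_baseline"]
    return out
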