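"""Per-gene mutated-cell fractions and lesional vs nonlesional comparison.

The fraction of a patient's (tissue-specific) cells carrying a mutation
in a gene is estimated volumetrically: each mutation contributes twice
its VAF (the diploid cellular fraction) weighted by the volume of the
microbiopsy it was observed in, divided by the total dissected volume of
that patient's microbiopsies in that tissue.  When a clone carries
several mutations in one gene only the highest-VAF mutation is counted,
so clones are not double-counted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import CountMatrix

__all__ = ["mutated_cell_fraction", "compare_tissues"]


def mutated_cell_fraction(matrix: CountMatrix, microbiopsies: pd.DataFrame,
                          gene_map: dict, clone_labels: dict = None) -> pd.DataFrame:
    """Per-gene, per-tissue mutated-cell fractions for one patient.

    ``microbiopsies`` is indexed by sample_id with columns ``volume`` and
    ``lesional``; ``gene_map`` maps mutation keys to gene ids;
    ``clone_labels`` (optional, from the clustering output) maps mutation
    keys to clone ids — within a (clone, gene) only the mutation with the
    highest pooled VAF is counted (ties broken by genomic position).
    Without clone labels the rule is applied per microbiopsy.  Fractions
    are capped at 1 with a flag.
    """
    vols = microbiopsies.loc[matrix.samples, "volume"].to_numpy(dtype=float)
    lesional = microbiopsies.loc[matrix.samples, "lesional"].to_numpy(dtype=bool)
    vaf = np.nan_to_num(matrix.vaf(), nan=0.0)
    keys = matrix.keys()
    genes = np.array([gene_map.get(k) for k in keys], dtype=object)

    rows = []
    for tissue, mask in (("lesional", lesional), ("nonlesional", ~lesional)):
        if not mask.any():
            continue
        total_volume = vols[mask].sum()
        if total_volume <= 0:
            raise ValueError(f"zero total microbiopsy volume in {tissue} tissue")
        for gene in sorted({g for g in genes if g is not None}):
            idx = np.flatnonzero(genes == gene)
            contrib, n_used = _gene_contribution(
                matrix, idx, keys, vaf, vols, mask, clone_labels
            )
            fraction = contrib / total_volume
            rows.append(
                {
                    "gene": gene,
                    "tissue": tissue,
                    "fraction": min(fraction, 1.0),
                    "capped": fraction > 1.0,
                    "n_mutations": n_used,
                }
            )
    return pd.DataFrame(rows)


def _gene_contribution(matrix, idx, keys, vaf, vols, mask, clone_labels):
    if clone_labels is not None:
        # keep one mutation per (clone, gene): the one with highest pooled VAF
        chosen = []
        by_clone = {}
        for i in idx:
            by_clone.setdefault(clone_labels.get(keys[i], keys[i]), []).append(i)
        for members in by_clone.values():
            pooled = [
                (matrix.alt[i].sum() / max(matrix.depth[i].sum(), 1),
                 -matrix.mutations[i].pos, i)
                for i in members
            ]
            chosen.append(max(pooled)[2])
        contrib = sum(
            float(np.sum(2.0 * vaf[i, mask] * vols[mask])) for i in chosen
        )
        return contrib, len(chosen)
    # no clone labels: per microbiopsy, count only the top-VAF mutation
    per_sample_max = vaf[np.ix_(idx, mask)].max(axis=0)
    contrib = float(np.sum(2.0 * per_sample_max * vols[mask]))
    return contrib, len(idx)


def compare_tissues(fractions: pd.DataFrame) -> pd.DataFrame:
    """Paired Wilcoxon test per gene of lesional vs nonlesional fractions.

    ``fractions`` has columns ``patient_id, gene, tissue, fraction``.
    Patients lacking either tissue for a gene are dropped; genes with no
    complete pairs are skipped with a note.  BH correction across genes.
    """
    from statsmodels.stats.multitest import multipletests

    rows = []
    for gene, sub in fractions.groupby("gene"):
        wide = sub.pivot_table(index="patient_id", columns="tissue",
                               values="fraction")
        if not {"lesional", "nonlesional"} <= set(wide.columns):
            warnings.warn(f"gene {gene}: no complete tissue pairs; skipped")
            continue
        wide = wide.dropna()
        if len(wide) == 0:
            warnings.warn(f"gene {gene}: no complete tissue pairs; skipped")
            continue
        diff = wide["lesional"] - wide["nonlesional"]
        if np.allclose(diff, 0.0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(wide["lesional"], wide["nonlesional"],
                                     zero_method="zsplit").pvalue)
        rows.append({"gene": gene, "n_pairs": len(wide),
                     "median_difference": float(diff.median()), "p_value": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
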