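"""Transcription- and replication-linked asymmetries of TpA mutagenesis.

Psoralen photoadducts damage thymines; transcription-coupled repair (TCR)
removes damage from the transcribed strand while transcription-coupled
damage (TCD) adds it to the untranscribed strand, so genic TpA mutation
rates are strand-asymmetric and decline with gene expression.  These
analyses quantify the asymmetry ratio, decompose TCD and TCR in 1-kb bins
around transcription start sites with likelihood-ratio tests, measure
expression-decile rates, replication-strand and timing effects, and rank
extended (pentanucleotide) sequence contexts.

Mutations are supplied as a tidy frame with columns ``chrom, pos, ref,
alt`` plus ``gene_id``/``gene_strand`` where genic; the strand carrying
the mutated T is resolved from ref/alt (ref T ⇒ plus strand, ref A ⇒
minus strand).  Mutations falling in overlapping genes on both strands
are excluded (their strand is undefined).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnnotationTrack

__all__ = [
    "StrandProfile",
    "strand_asymmetry",
    "tss_profile",
    "expression_decile_rates",
    "replication_effects",
    "pentanucleotide_enrichment",
]

_OPP = {"+": "-", "-": "+"}


def mutated_t_strand(df: pd.DataFrame) -> pd.Series:
    """Genomic strand carrying the mutated T (requires TpA-type calls)."""
    strand = pd.Series(index=df.index, dtype=object)
    strand[df["ref"] == "T"] = "+"
    strand[df["ref"] == "A"] = "-"
    return strand


def _untranscribed_mask(df: pd.DataFrame) -> pd.Series:
    """True where the mutated T lies on the untranscribed (coding) strand."""
    t_strand = df.get("t_strand")
    if t_strand is None:
        t_strand = mutated_t_strand(df)
    return t_strand == df["gene_strand"]


# --------------------------------------------------------------------------
# Overall strand asymmetry
# --------------------------------------------------------------------------


def strand_asymmetry(mutations: pd.DataFrame, annotation=None) -> dict:
    """Untranscribed : transcribed ratio of genic TpA mutations.

    Returns the ratio, the strand counts and a two-sided exact binomial
    test of strand symmetry.  With no genic mutations the result is an
    explicit empty record; a fully one-sided set is flagged degenerate
    (infinite ratio).
    """
    genic = mutations[mutations["gene_id"].notna()]
    if "region" in genic.columns:
        genic = genic[genic["region"] == "genic"]
    if len(genic) == 0:
        return {"ratio": float("nan"), "n_untranscribed": 0, "n_transcribed": 0,
                "p_value": float("nan"), "degenerate": False}
    untx = _untranscribed_mask(genic)
    n_u, n_t = int(untx.sum()), int((~untx).sum())
    degenerate = n_u == 0 or n_t == 0
    ratio = float("inf") if n_t == 0 else n_u / n_t
    p = stats.binomtest(n_u, n_u + n_t, 0.5).pvalue
    return {"ratio": ratio, "n_untranscribed": n_u, "n_transcribed": n_t,
            "p_value": float(p), "degenerate": degenerate}


# --------------------------------------------------------------------------
# TSS profile with TCD / TCR likelihood-ratio tests
# --------------------------------------------------------------------------


@dataclass
class StrandProfile:
    """Per-bin strand-resolved counts and relative rates around TSSs.

    ``counts``: frame indexed by (quintile, strand, bin) with raw counts;
    bins are 1-kb offsets −10 … +9 (bin b covers [b kb, (b+1) kb) from
    the TSS in the direction of transcription).  ``relative`` holds rates
    relative to the −10 kb bin of the same quintile and strand.
    """

    counts: pd.DataFrame
    relative: pd.DataFrame
    tcd_p: float
    tcr_p: float


def tss_profile(mutations: pd.DataFrame, annotation: AnnotationTrack,
                n_quantiles: int = 5) -> StrandProfile:
    """1-kb binned TpA mutation profile around TSSs by expression quantile.

    The TCD test compares linear models of the untranscribed-strand
    per-bin counts with and without an upstream/downstream indicator
    (likelihood-ratio test); the TCR test does the same on the
    transcribed strand.
    """
    genes = annotation.genes
    quint = annotation.expression_bins(n_quantiles)
    df = mutations[mutations["gene_id"].notna()].copy()
    df["gene_strand"] = df["gene_id"].map(genes["strand"])
    df["tss"] = df["gene_id"].map(genes["tss"])
    df["quintile"] = df["gene_id"].map(quint)
    sign = np.where(df["gene_strand"] == "+", 1, -1)
    rel = (df["pos"] - df["tss"]) * sign
    df["bin"] = np.floor(rel / 1000.0).astype(int)
    df = df[(df["bin"] >= -10) & (df["bin"] <= 9)]
    untx = _untranscribed_mask(df)
    df["strand_class"] = np.where(untx, "untranscribed", "transcribed")

    bins = np.arange(-10, 10)
    index = pd.MultiIndex.from_product(
        [range(n_quantiles), ["untranscribed", "transcribed"], bins],
        names=["quintile", "strand", "bin"],
    )
    counts = (
        df.groupby(["quintile", "strand_class", "bin"]).size()
        .reindex(index, fill_value=0).rename("count").to_frame()
    )
    for q in range(n_quantiles):
        if quint.eq(q).sum() == 0:
            warnings.warn(f"expression quantile {q} has no genes; skipped")

    ref = counts.xs(-10, level="bin")["count"].replace(0, np.nan)
    relative = counts["count"].div(ref, axis=0).rename("relative_rate").to_frame()

    def lrt(strand_name: str) -> float:
        sub = counts.xs(strand_name, level="strand").reset_index()
        y = sub["count"].to_numpy(dtype=float)
        down = (sub["bin"] >= 0).astype(float).to_numpy()
        return _gaussian_lrt(y, down)

    return StrandProfile(
        counts=counts,
        relative=relative,
        tcd_p=lrt("untranscribed"),
        tcr_p=lrt("transcribed"),
    )


def _gaussian_lrt(y: np.ndarray, indicator: np.ndarray) -> float:
    """LRT p-value for adding an indicator to a Gaussian linear model."""
    import statsmodels.api as sm

    x0 = np.ones((len(y), 1))
    x1 = np.column_stack([np.ones(len(y)), indicator])
    ll0 = sm.OLS(y, x0).fit().llf
    ll1 = sm.OLS(y, x1).fit().llf
    stat = 2.0 * (ll1 - ll0)
    return float(stats.chi2.sf(max(stat, 0.0), df=1))


# --------------------------------------------------------------------------
# Expression deciles
# --------------------------------------------------------------------------


def expression_decile_rates(mutations: pd.DataFrame,
                            annotation: AnnotationTrack) -> pd.DataFrame:
    """Per-bp genic mutation rate in ten expression deciles, relative to decile 1."""
    genes = annotation.genes
    deciles = annotation.expression_bins(10)
    lengths = (genes["end"] - genes["start"]).groupby(deciles).sum()
    if (lengths <= 0).any():
        raise ValueError("expression decile with zero total gene length")
    genic = mutations[mutations["gene_id"].notna()]
    if "region" in genic.columns:
        genic = genic[genic["region"] == "genic"]
    counts = genic["gene_id"].map(deciles).value_counts()
    counts = counts.reindex(range(10), fill_value=0).sort_index()
    rate = counts / lengths.reindex(range(10))
    out = pd.DataFrame({"count": counts, "bp": lengths, "rate": rate})
    out["relative_rate"] = out["rate"] / out["rate"].iloc[0]
    out.index.name = "decile"
    return out


# --------------------------------------------------------------------------
# Replication strand and timing
# --------------------------------------------------------------------------


def replication_effects(mutations: pd.DataFrame,
                        annotation: AnnotationTrack,
                        n_timing_bins: int = 5) -> dict:
    """Leading : lagging ratio for the mutated-T strand and timing-bin rates.

    Requires the annotation's replication track; returns an explicit
    unavailable result otherwise.  Timing rates ascend early → late.
    """
    rep = annotation.replication
    if rep is None:
        return {"available": False}
    df = mutations.copy()
    if "rep_strand" not in df.columns or "timing" not in df.columns:
        window = int(rep["end"].iloc[0] - rep["start"].iloc[0])
        wi = np.minimum(df["pos"] // window, len(rep) - 1).astype(int)
        plus_role = rep["rep_strand"].to_numpy()[wi]
        t_strand = mutated_t_strand(df)
        df["rep_strand"] = np.where(
            t_strand == "+", plus_role,
            np.where(plus_role == "leading", "lagging", "leading"),
        )
        df["timing"] = rep["timing"].to_numpy()[wi]
    n_lead = int((df["rep_strand"] == "leading").sum())
    n_lag = int((df["rep_strand"] == "lagging").sum())
    ratio = float("inf") if n_lag == 0 else n_lead / n_lag
    p = stats.binomtest(n_lead, n_lead + n_lag, 0.5).pvalue if n_lead + n_lag else np.nan
    timing_bin = pd.cut(df["timing"], bins=np.linspace(0, 1, n_timing_bins + 1),
                        labels=False, include_lowest=True)
    timing_counts = timing_bin.value_counts().reindex(range(n_timing_bins),
                                                      fill_value=0).sort_index()
    return {
        "available": True,
        "leading_lagging_ratio": ratio,
        "percent_excess_leading": 100.0 * (ratio - 1.0),
        "n_leading": n_lead,
        "n_lagging": n_lag,
        "p_value": float(p),
        "timing_counts": timing_counts,
    }


# --------------------------------------------------------------------------
# Pentanucleotide context
# --------------------------------------------------------------------------


def pentanucleotide_enrichment(mutations: pd.DataFrame,
                               genome_counts: dict) -> pd.DataFrame:
    """Mutation rate per 5-mer normalized by genomic 5-mer frequency, ranked.

    ``genome_counts`` maps each pentanucleotide to its occurrence count in
    the reference; contexts absent from the mutation table get rate 0.
    Rate ranks are invariant to duplicating the mutation set.
    """
    if "pentanucleotide" not in mutations.columns or mutations["pentanucleotide"].isna().all():
        raise ValueError("pentanucleotide contexts are absent")
    counts = mutations["pentanucleotide"].value_counts()
    table = pd.DataFrame({
        "count": counts.reindex(genome_counts.keys(), fill_value=0),
        "genomic": pd.Series(genome_counts),
    })
    table["rate"] = table["count"] / table["genomic"]
    table["contains_atat"] = table.index.str.contains("ATAT")
    return table.sort_values("rate", ascending=False)
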