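"""Post-calling genotyping and filtering of candidate somatic mutations.

Four stages, applied per patient:

1. **Genotyping** — a mutation is supported only if some sample covers it
   at depth ≥ 4 with ≥ 3 alt reads.
2. **Germline filter** — heterozygous germline variants sit at VAF 0.5 in
   every sample of a patient (0.95 on the sex chromosomes in men).  Alt
   and depth are pooled over the patient's samples and tested two-sided
   against Binomial(pooled_depth, p₀); after Benjamini–Hochberg
   correction, mutations with q > 10⁻³ are classified germline.
3. **Overdispersion (ρ) filter** — recurrent sequencing artifacts are
   spread thinly but evenly across samples (beta-binomial ρ ≈ 0), whereas
   true clonal mutations are present in some samples and absent from
   others (high ρ).  ρ is maximized on a log-spaced grid over
   [10⁻⁶, 10⁻⁰·⁰⁵] with the beta-binomial mean fixed at the pooled VAF;
   calls with ρ̂ < 0.1 are artifacts.
4. **DBS merging** — adjacent substitutions whose alt/ref read counts do
   not differ significantly (two-sided Fisher test) are merged into
   double-base substitutions.

Sensitivity of the whole pipeline is estimated from near-replicate
dissection pairs as the fraction of one member's calls recovered in the
other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom, fisher_exact

from .core import CountMatrix, MutationCall, infer_mut_class

__all__ = [
    "RHO_GRID",
    "genotype_mutations",
    "germline_filter",
    "rho_filter",
    "filter_calls",
    "merge_dbs",
    "estimate_sensitivity",
    "binom_test_two_sided",
]

#: log-spaced overdispersion grid between the stated endpoints
RHO_GRID = np.logspace(-6.0, -0.05, 100)

_SEX_CHROMS = {"chrX", "chrY", "X", "Y"}

MIN_DEPTH = 4
MIN_ALT = 3
GERMLINE_Q = 1e-3
RHO_CUTOFF = 0.1


# --------------------------------------------------------------------------
# Exact two-sided binomial test (minimum-likelihood method), vectorized
# --------------------------------------------------------------------------


def binom_test_two_sided(x, n, p0) -> np.ndarray:
    """Two-sided exact binomial p-values for arrays of (x, n).

    The two-sided p-value sums the probabilities of all outcomes no more
    likely than the observed one (with the customary 1 + 1e-7 relative
    tolerance for ties).
    """
    x = np.atleast_1d(np.asarray(x, dtype=np.int64))
    n = np.atleast_1d(np.asarray(n, dtype=np.int64))
    p0 = np.broadcast_to(np.atleast_1d(np.asarray(p0, dtype=float)), x.shape)
    out = np.ones(x.shape, dtype=float)
    for n_val in np.unique(n):
        if n_val == 0:
            continue
        for p_val in np.unique(p0[n == n_val]):
            mask = (n == n_val) & (p0 == p_val)
            k = np.arange(n_val + 1)
            pmf = binom.pmf(k, n_val, p_val)
            obs = pmf[x[mask]]
            include = pmf[None, :] <= obs[:, None] * (1.0 + 1e-7)
            out[mask] = np.minimum((pmf[None, :] * include).sum(axis=1), 1.0)
    return out


# --------------------------------------------------------------------------
# Genotyping
# --------------------------------------------------------------------------


def genotype_mutations(matrix: CountMatrix) -> np.ndarray:
    """Boolean mask: supported in ≥ 1 sample at depth ≥ 4 with ≥ 3 alt reads."""
    return np.any((matrix.depth >= MIN_DEPTH) & (matrix.alt >= MIN_ALT), axis=1)


# --------------------------------------------------------------------------
# Germline filter
# --------------------------------------------------------------------------


def germline_filter(matrix: CountMatrix, sex: str = "female") -> pd.DataFrame:
    """Pooled exact-binomial test against the germline hypothesis.

    Returns a frame with pooled counts, p, BH-adjusted q, and a boolean
    ``germline`` column (q > 10⁻³ ⇒ consistent with germline).  Mutations
    with pooled depth 0 get q = NaN and ``low_support`` True.
    """
    from statsmodels.stats.multitest import multipletests

    pooled_alt = matrix.alt.sum(axis=1)
    pooled_depth = matrix.depth.sum(axis=1)
    p0 = np.array(
        [
            0.95 if (sex == "male" and m.chrom in _SEX_CHROMS) else 0.5
            for m in matrix.mutations
        ]
    )
    testable = pooled_depth > 0
    p = np.full(len(pooled_alt), np.nan)
    p[testable] = binom_test_two_sided(
        pooled_alt[testable], pooled_depth[testable], p0[testable]
    )
    q = np.full_like(p, np.nan)
    if testable.any():
        q[testable] = multipletests(p[testable], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "pooled_alt": pooled_alt,
            "pooled_depth": pooled_depth,
            "germline_p": p,
            "germline_q": q,
            "germline": np.where(testable, q > GERMLINE_Q, False),
            "low_support": ~testable,
        },
        index=matrix.keys(),
    )


# --------------------------------------------------------------------------
# Beta-binomial overdispersion filter
# --------------------------------------------------------------------------


def _betabinom_grid_loglik(alt: np.ndarray, depth: np.ndarray,
                           mu: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Log-likelihood matrix (mutations × grid) of the beta-binomial model.

    The mean is fixed at the pooled VAF ``mu``; binomial coefficients are
    omitted (constant in ρ).
    """
    n_mut = alt.shape[0]
    ll = np.empty((n_mut, len(grid)))
    covered = depth > 0
    for g, rho in enumerate(grid):
        a = mu * (1.0 - rho) / rho
        b = (1.0 - mu) * (1.0 - rho) / rho
        A = a[:, None]
        B = b[:, None]
        term = (
            gammaln(alt + A) - gammaln(A)
            + gammaln(depth - alt + B) - gammaln(B)
            - gammaln(depth + A + B) + gammaln(A + B)
        )
        ll[:, g] = np.where(covered, term, 0.0).sum(axis=1)
    return ll


def rho_candidate_means(alt: np.ndarray, depth: np.ndarray) -> list:
    """The two candidate beta-binomial means the ρ search profiles over.

    The pooled VAF describes a process spread evenly across samples; the
    mean VAF of alt-bearing samples describes a clone confined to few
    samples.  Profiling over both keeps the verdict driven by
    overdispersion rather than by prevalence: a minimum-support clonal
    mutation (a few alt reads in one sample, absent elsewhere) is not
    mistaken for a thinly spread artifact just because its pooled VAF is
    tiny.
    """
    pooled_depth = depth.sum(axis=1)
    pooled = np.divide(
        alt.sum(axis=1), pooled_depth,
        out=np.full(len(pooled_depth), 0.5), where=pooled_depth > 0,
    )
    carrier = alt > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(carrier & (depth > 0), alt / np.maximum(depth, 1), np.nan)
        n_carrier = np.maximum(carrier.sum(axis=1), 1)
        carrier_mean = np.nansum(np.where(carrier, vaf, 0.0), axis=1) / n_carrier
    carrier_mean = np.where(np.isfinite(carrier_mean), carrier_mean, pooled)
    clip = lambda m: np.clip(m, 1e-3, 1.0 - 1e-3)
    return [clip(pooled), clip(carrier_mean)]


def rho_filter(matrix: CountMatrix) -> pd.DataFrame:
    """Grid maximum-likelihood overdispersion per mutation.

    The beta-binomial likelihood is maximized over the log-spaced ρ grid
    with the mean profiled over the candidates of
    :func:`rho_candidate_means`.  Returns ``rho_hat`` (never outside the
    grid) and a boolean ``artifact`` column (ρ̂ < 0.1).  Mutations with no
    covered sample get NaN and ``low_support`` True.
    """
    pooled_depth = matrix.depth.sum(axis=1)
    testable = pooled_depth > 0
    rho_hat = np.full(len(pooled_depth), np.nan)
    if testable.any():
        alt = matrix.alt[testable]
        depth = matrix.depth[testable]
        ll = None
        for mu in rho_candidate_means(alt, depth):
            ll_mu = _betabinom_grid_loglik(alt, depth, mu, RHO_GRID)
            ll = ll_mu if ll is None else np.maximum(ll, ll_mu)
        rho_hat[testable] = RHO_GRID[np.argmax(ll, axis=1)]
    return pd.DataFrame(
        {
            "rho_hat": rho_hat,
            "artifact": np.where(testable, rho_hat < RHO_CUTOFF, False),
            "low_support": ~testable,
        },
        index=matrix.keys(),
    )


# --------------------------------------------------------------------------
# Combined verdicts
# --------------------------------------------------------------------------


def filter_calls(matrix: CountMatrix, sex: str = "female") -> pd.DataFrame:
    """Run genotyping, germline and ρ filters; one verdict per mutation.

    Verdicts partition the input: ``low_support`` (genotyping failure or
    uncovered), ``germline`` (q > 10⁻³), ``artifact`` (ρ̂ < 0.1 among
    non-germline), else ``somatic``.
    """
    supported = genotype_mutations(matrix)
    germ = germline_filter(matrix, sex=sex)
    rho = rho_filter(matrix)
    verdict = np.where(
        ~supported | germ["low_support"].to_numpy(),
        "low_support",
        np.where(
            germ["germline"].to_numpy(),
            "germline",
            np.where(rho["artifact"].to_numpy(), "artifact", "somatic"),
        ),
    )
    out = germ.join(rho[["rho_hat"]])
    out["verdict"] = verdict
    return out


# --------------------------------------------------------------------------
# DBS merging
# --------------------------------------------------------------------------


def merge_dbs(calls: list, matrix: CountMatrix, alpha: float = 0.05) -> list:
    """Merge adjacent SBS pairs into DBS calls by Fisher's exact test.

    For adjacent positions on the same chromosome, the alt/ref read
    counts of the two sites are compared in the sample where the pair is
    best supported; a two-sided Fisher p ≥ ``alpha`` ("not significantly
    different") merges the pair.  Overlapping runs merge greedily
    left-to-right.
    """
    key_to_row = {m.key: i for i, m in enumerate(matrix.mutations)}
    order = sorted(range(len(calls)), key=lambda i: (calls[i].chrom, calls[i].pos))
    merged: list = []
    skip = set()
    for oi, i in enumerate(order):
        if i in skip:
            continue
        a = calls[i]
        partner = None
        if oi + 1 < len(order):
            j = order[oi + 1]
            b = calls[j]
            if (
                a.mut_class == "SBS" and b.mut_class == "SBS"
                and b.chrom == a.chrom and b.pos == a.pos + 1
            ):
                ra, rb = key_to_row[a.key], key_to_row[b.key]
                support = np.minimum(matrix.alt[ra], matrix.alt[rb])
                s = int(np.argmax(support))
                table = [
                    [matrix.alt[ra, s], matrix.depth[ra, s] - matrix.alt[ra, s]],
                    [matrix.alt[rb, s], matrix.depth[rb, s] - matrix.alt[rb, s]],
                ]
                if fisher_exact(table)[1] >= alpha:
                    partner = j
        if partner is not None:
            b = calls[partner]
            merged.append(
                MutationCall(chrom=a.chrom, pos=a.pos, ref=a.ref + b.ref,
                             alt=a.alt + b.alt, mut_class="DBS")
            )
            skip.add(partner)
        else:
            merged.append(a)
    return merged


# --------------------------------------------------------------------------
# Replicate-based sensitivity
# --------------------------------------------------------------------------


def estimate_sensitivity(pairs: list) -> dict:
    """Per-pair shared-call fractions and their median.

    For each near-replicate pair the fraction of the first member's calls
    present in the second and the symmetric fraction are averaged.  Pairs
    with an empty member are skipped with a warning.
    """
    if not pairs:
        raise ValueError("need at least one replicate pair")
    fractions = []
    for a, b in pairs:
        a, b = set(a), set(b)
        if not a or not b:
            warnings.warn("replicate pair with an empty member skipped")
            continue
        inter = len(a & b)
        fractions.append(0.5 * (inter / len(a) + inter / len(b)))
    return {
        "per_pair": fractions,
        "median": float(np.median(fractions)) if fractions else float("nan"),
    }
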