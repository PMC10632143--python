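"""Dirichlet-process clustering of mutations by multi-sample VAF.

Clones of cells extend across microbiopsies and manifest as groups of
mutations sharing similar VAF vectors over a patient's samples.  We model
mutation assignment with a Chinese-restaurant-process mixture: each cluster
has an independent per-microbiopsy VAF with a Beta(1, 1) prior, alt reads
are Binomial(depth, vaf), and the Beta–Binomial conjugacy lets the VAFs be
integrated out, giving a collapsed Gibbs sampler over assignments only.
Clusters are created and destroyed as the chain moves, so the number of
clusters is inferred rather than prespecified.  The concentration
parameter α is resampled each sweep from a Gamma(1, 1) hyperprior using
the Escobar–West auxiliary-variable scheme.

Microbiopsies with zero depth at a mutation contribute no likelihood term:
missing coverage is not evidence of absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln

from .core import CountMatrix

__all__ = ["ClusteringConfig", "MutationCluster", "fit_dp_clusters", "cluster_quality"]


@dataclass
class ClusteringConfig:
    """Sampler settings for :func:`fit_dp_clusters`."""

    alpha: float = 1.0          # initial DP concentration; resampled each sweep
    n_iter: int = 3000
    burn_in: int = 1000
    thin: int = 5
    min_cluster_size: int = 5
    rng_seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class MutationCluster:
    """A cluster of mutations with shared per-microbiopsy VAF."""

    cluster_id: str
    members: list                  # indices into the input matrix
    vaf_centroid: np.ndarray       # posterior mean VAF per microbiopsy
    median_vaf: float              # median observed VAF over members/samples
    samples: list
    assignment_posterior: Optional[np.ndarray] = None  # per-member co-cluster prob

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def cf_centroid(self) -> np.ndarray:
        """Cellular fraction per microbiopsy: 2 × VAF (diploid, copy-neutral)."""
        return 2.0 * self.vaf_centroid


def _betaln(a, b):
    return gammaln(a) + gammaln(b) - gammaln(a + b)


def fit_dp_clusters(matrix: CountMatrix, config: ClusteringConfig) -> list[MutationCluster]:
    """Cluster autosomal SBS calls of one patient by their VAF vectors.

    Returns the point clustering (the post-burn-in sampled partition of
    highest joint posterior), with posterior-mean VAF centroids and a
    co-clustering posterior recorded per cluster member.  Clusters smaller
    than ``min_cluster_size`` are dissolved into the likeliest remaining
    cluster.  A diagnostic trace of the number of occupied clusters is
    attached to the returned list as the attribute ``trace_n_clusters``.
    """
    n, s = matrix.shape
    result: list[MutationCluster] = []
    if n == 0:
        return _with_trace(result, [])
    x = matrix.alt.astype(float)
    d = matrix.depth.astype(float)
    rng = np.random.default_rng(config.rng_seed)
    alpha = float(config.alpha)

    # state: assignment z, per-cluster sufficient statistics
    z = np.zeros(n, dtype=int)
    stats_a = {0: x.sum(axis=0)}
    stats_d = {0: d.sum(axis=0)}
    counts = {0: n}
    next_id = 1

    const = _betaln(1.0, 1.0)  # log B(1,1) = 0, kept for clarity

    def log_marginal_new(i):
        return np.sum(_betaln(x[i] + 1.0, d[i] - x[i] + 1.0) - const)

    saved = []
    trace = []
    n_sweeps = config.n_iter
    for sweep in range(n_sweeps):
        order = rng.permutation(n)
        for i in order:
            k = z[i]
            counts[k] -= 1
            stats_a[k] -= x[i]
            stats_d[k] -= d[i]
            if counts[k] == 0:
                del counts[k], stats_a[k], stats_d[k]
            ks = list(counts.keys())
            if not ks:  # the only mutation: it must reopen a cluster
                z[i] = next_id
                counts[next_id] = 1
                stats_a[next_id] = x[i].copy()
                stats_d[next_id] = d[i].copy()
                next_id += 1
                continue
            A = np.array([stats_a[k2] for k2 in ks])   # K × S
            D = np.array([stats_d[k2] for k2 in ks])
            nk = np.array([counts[k2] for k2 in ks], dtype=float)
            # collapsed predictive: Beta-Binomial with cluster pseudo-counts
            ll = np.sum(
                _betaln(A + x[i] + 1.0, D - A + d[i] - x[i] + 1.0)
                - _betaln(A + 1.0, D - A + 1.0),
                axis=1,
            )
            logp = np.concatenate([np.log(nk) + ll, [np.log(alpha) + log_marginal_new(i)]])
            logp -= logp.max()
            p = np.exp(logp)
            choice = rng.choice(len(p), p=p / p.sum())
            if choice == len(ks):
                k_new = next_id
                next_id += 1
                z[i] = k_new
                counts[k_new] = 1
                stats_a[k_new] = x[i].copy()
                stats_d[k_new] = d[i].copy()
            else:
                k_new = ks[choice]
                z[i] = k_new
                counts[k_new] += 1
                stats_a[k_new] += x[i]
                stats_d[k_new] += d[i]
        # Escobar–West resampling of alpha under Gamma(1, 1) hyperprior
        k_occ = len(counts)
        eta = rng.beta(alpha + 1.0, n)
        w = (1.0 + k_occ - 1.0) / (n * (1.0 - np.log(eta)) + 1.0 + k_occ - 1.0)
        shape = 1.0 + k_occ if rng.random() < w else 1.0 + k_occ - 1.0
        alpha = rng.gamma(shape, 1.0 / (1.0 - np.log(eta)))
        alpha = max(alpha, 1e-3)

        trace.append(k_occ)
        if sweep >= config.burn_in and (sweep - config.burn_in) % config.thin == 0:
            saved.append((z.copy(), _joint_logpost(z, x, d, alpha)))

    if not saved:  # very short chains: fall back to final state
        saved.append((z.copy(), _joint_logpost(z, x, d, alpha)))

    # point estimate: sampled partition of maximal joint posterior
    z_best = max(saved, key=lambda t: t[1])[0]
    # co-clustering posterior across saved sweeps
    co = np.zeros((n, n))
    for zs, _ in saved:
        co += zs[:, None] == zs[None, :]
    co /= len(saved)

    z_best = _dissolve_small(z_best, x, d, config.min_cluster_size)
    labels = [k for k in dict.fromkeys(z_best)]  # deterministic order of appearance
    vaf_all = matrix.vaf()
    for idx, k in enumerate(labels, start=1):
        members = np.flatnonzero(z_best == k)
        A = x[members].sum(axis=0)
        D = d[members].sum(axis=0)
        centroid = (A + 1.0) / (D + 2.0)
        obs = vaf_all[members]
        med = float(np.nanmedian(obs)) if np.isfinite(obs).any() else float("nan")
        result.append(
            MutationCluster(
                cluster_id=f"cluster{idx}",
                members=members.tolist(),
                vaf_centroid=centroid,
                median_vaf=med,
                samples=list(matrix.samples),
                assignment_posterior=co[np.ix_(members, members)].mean(axis=1),
            )
        )
    return _with_trace(result, trace)


def _with_trace(result, trace):
    class _ClusterList(list):
        pass

    out = _ClusterList(result)
    out.trace_n_clusters = list(trace)
    return out


def _joint_logpost(z, x, d, alpha):
    """Joint log posterior of a partition (CRP prior × marginal likelihood)."""
    lp = 0.0
    for k in np.unique(z):
        members = z == k
        nk = int(members.sum())
        lp += np.log(alpha) + gammaln(nk)
        A = x[members].sum(axis=0)
        D = d[members].sum(axis=0)
        lp += np.sum(_betaln(A + 1.0, D - A + 1.0))
        # per-observation binomial coefficients are constant across partitions
    return lp


def _dissolve_small(z, x, d, min_size):
    z = z.copy()
    while True:
        ks, sizes = np.unique(z, return_counts=True)
        small = ks[sizes < min_size]
        big = ks[sizes >= min_size]
        if small.size == 0 or big.size == 0:
            return z
        # move members of the smallest cluster to their likeliest big cluster
        k_small = small[np.argmin([sizes[list(ks).index(k)] for k in small])]
        A = np.array([x[z == k].sum(axis=0) for k in big])
        D = np.array([d[z == k].sum(axis=0) for k in big])
        for i in np.flatnonzero(z == k_small):
            ll = np.sum(
                _betaln(A + x[i] + 1.0, D - A + d[i] - x[i] + 1.0)
                - _betaln(A + 1.0, D - A + 1.0),
                axis=1,
            )
            z[i] = big[np.argmax(ll)]


def cluster_quality(clusters, truth_labels) -> dict:
    """Adjusted Rand index and per-cluster purity against known labels."""
    from sklearn.metrics import adjusted_rand_score

    truth_labels = np.asarray(truth_labels)
    n = sum(c.size for c in clusters)
    pred = np.empty(n, dtype=int)
    for idx, c in enumerate(clusters):
        pred[np.asarray(c.members)] = idx
    ari = adjusted_rand_score(truth_labels, pred)
    purity = {}
    for c in clusters:
        lab = truth_labels[np.asarray(c.members)]
        _, counts = np.unique(lab, return_counts=True)
        purity[c.cluster_id] = counts.max() / counts.sum()
    return {"ari": float(ari), "purity": purity}
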