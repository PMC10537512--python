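"""Population structure: IBS distance, Ward clustering, PCA, admixture EM
and Evanno delta-K model selection.

The admixture estimator maximizes the standard binomial admixture
log-likelihood

    L(Q, F) = sum_im [ g_im log p_im + (2 - g_im) log(1 - p_im) + log C(2, g_im) ]

with p_im = sum_k q_ik f_km, by alternating EM updates of the membership
matrix Q and cluster allele frequencies F, with multiple random restarts.
Its per-replicate log-likelihoods feed the Evanno delta-K table the same way
replicate STRUCTURE runs would.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from heterokit.io import GenotypeMatrix

MIXED = "mixed"

#: membership probability needed for a subgroup call (>= comparison)
MEMBERSHIP_THRESHOLD = 0.60


@dataclass
class DistanceMatrix:
    samples: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.samples), len(self.samples)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


@dataclass
class ClusterResult:
    samples: list[str]
    linkage_matrix: np.ndarray
    k: int
    labels: dict[str, int]  # sample -> cluster id (1..K)

    def members(self, cluster: int) -> list[str]:
        return [s for s in self.samples if self.labels[s] == cluster]

    @property
    def clusters(self) -> list[int]:
        return sorted(set(self.labels.values()))


@dataclass
class AdmixtureResult:
    samples: list[str]
    q: pd.DataFrame  # samples x K membership proportions
    loglik: float
    replicate_logliks: list[float]
    assignments: dict[str, object]  # sample -> cluster index (1-based) or "mixed"
    n_iter: int
    loglik_trajectory: list[float] = field(default_factory=list)


@dataclass
class EvannoTable:
    table: pd.DataFrame  # columns: K, mean_loglik, sd_loglik, delta_k
    best_k: int


def ibs_distance(geno: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise identity-by-state distances.

    Per marker non-missing in both samples, similarity = (2 - |gi - gj|)/2;
    distance = 1 - mean similarity over the shared markers.
    """
    if geno.n_samples < 2:
        raise ValueError("need >= 2 samples")
    calls = geno.calls.astype(float)
    present = ~geno.missing_mask()
    n = geno.n_samples
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = present[i] & present[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"samples {geno.samples[i]!r} and {geno.samples[j]!r} "
                    "share no non-missing markers"
                )
            diff = np.abs(calls[i, shared] - calls[j, shared])
            dist[i, j] = dist[j, i] = (diff / 2.0).mean()
    return DistanceMatrix(samples=list(geno.samples), values=dist)


def ward_cluster(dist: DistanceMatrix, k: int) -> ClusterResult:
    """Ward minimum-variance agglomeration on the distance matrix.

    Uses the Lance-Williams Ward update on squared input distances (the
    "ward.D2"-style convention); flat labels come from cutting the tree at
    K clusters.
    """
    n = len(dist.samples)
    if not 1 <= k <= n:
        raise ValueError(f"K={k} out of range [1, {n}]")
    z = linkage(squareform(dist.values, checks=False), method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterResult(
        samples=list(dist.samples),
        linkage_matrix=z,
        k=k,
        labels={s: int(c) for s, c in zip(dist.samples, labels)},
    )


def pca_genotypes(
    geno: GenotypeMatrix, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the column-centered dosage matrix (missing = marker mean).

    Returns (scores DataFrame samples x components, eigenvalues of the
    covariance matrix, non-increasing).  ``n_components`` beyond the matrix
    rank is truncated with a warning.
    """
    if geno.n_markers < 2:
        raise ValueError("need >= 2 markers for PCA")
    x = geno.calls.astype(float)
    miss = geno.missing_mask()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.where(
            miss.all(axis=0), 0.0, np.nanmean(np.where(miss, np.nan, x), axis=0)
        )
    x = np.where(miss, col_mean, x) - col_mean

    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2 / max(geno.n_samples - 1, 1)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    scores = u[:, :n_components] * s[:n_components]
    frame = pd.DataFrame(
        scores,
        index=geno.samples,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, eigvals


def _admixture_loglik(g, present, q, f):
    p = np.clip(q @ f, 1e-12, 1 - 1e-12)
    ll = g * np.log(p) + (2 - g) * np.log1p(-p)
    ll = np.where(present, ll, 0.0)
    n_het = int(((g == 1) & present).sum())
    return float(ll.sum()) + n_het * np.log(2.0)


def _admixture_fit_once(g, present, k, rng, max_iter, tol):
    n, m = g.shape
    q = rng.dirichlet(np.ones(k), size=n)
    # start F near pooled frequencies with jitter
    with np.errstate(invalid="ignore"):
        pooled = np.where(
            present.sum(axis=0) > 0,
            np.where(present, g, 0).sum(axis=0) / (2.0 * np.maximum(present.sum(axis=0), 1)),
            0.5,
        )
    f = np.clip(pooled + rng.normal(0, 0.05, size=(k, m)), 0.01, 0.99)

    ll_prev = -np.inf
    trajectory: list[float] = []
    g2 = np.where(present, g, 0).astype(float)
    g2c = np.where(present, 2 - g, 0).astype(float)
    for it in range(1, max_iter + 1):
        p = np.clip(q @ f, 1e-12, 1 - 1e-12)
        # expected allele-origin counts (EM E-step, marginalized over markers)
        alt_w = g2 / p  # n x m
        ref_w = g2c / (1 - p)
        # per-sample, per-cluster expected allele counts
        a = q * (alt_w @ f.T)  # n x k: alt alleles from cluster k
        b = q * (ref_w @ (1 - f).T)  # n x k: ref alleles from cluster k
        denom = 2.0 * present.sum(axis=1, keepdims=True)
        q = (a + b) / np.maximum(denom, 1e-12)
        q /= q.sum(axis=1, keepdims=True)

        p = np.clip(q @ f, 1e-12, 1 - 1e-12)
        # cluster x marker expected alt / total allele counts
        alt_counts = (q.T @ (g2 / p)) * f
        tot_counts = alt_counts + (q.T @ (g2c / (1 - p))) * (1 - f)
        f = np.clip(alt_counts / np.maximum(tot_counts, 1e-12), 1e-6, 1 - 1e-6)

        ll = _admixture_loglik(g, present, q, f)
        trajectory.append(ll)
        if ll - ll_prev < tol and it > 1:
            ll_prev = ll
            break
        ll_prev = ll
    return q, f, ll_prev, it, trajectory


def admixture_em(
    geno: GenotypeMatrix,
    k: int,
    n_replicates: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> AdmixtureResult:
    """Maximum-likelihood admixture proportions via EM with restarts.

    Missing calls drop out of the likelihood for that sample.  The best
    replicate's Q is returned together with all replicate log-likelihoods
    (inputs to :func:`evanno_delta_k`).  Assignments apply the membership
    threshold: argmax cluster iff max Q >= 0.60, else "mixed".
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > geno.n_samples:
        raise ValueError(f"K={k} exceeds sample count {geno.n_samples}")
    g = geno.calls.astype(float)
    present = ~geno.missing_mask()

    if k == 1:
        with np.errstate(invalid="ignore"):
            pooled = np.where(present, g, 0).sum(axis=0) / (
                2.0 * np.maximum(present.sum(axis=0), 1)
            )
        q = np.ones((geno.n_samples, 1))
        ll = _admixture_loglik(g, present, q, pooled[None, :])
        logliks = [ll] * n_replicates
        qf = pd.DataFrame(q, index=geno.samples, columns=["K1"])
        return AdmixtureResult(
            samples=list(geno.samples),
            q=qf,
            loglik=ll,
            replicate_logliks=logliks,
            assignments={s: 1 for s in geno.samples},
            n_iter=0,
        )

    best = None
    logliks = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, k, rep])
        q, f, ll, n_iter, traj = _admixture_fit_once(
            g, present, k, rng, max_iter, tol
        )
        logliks.append(ll)
        if best is None or ll > best[2]:
            best = (q, f, ll, n_iter, traj)

    q, _, ll, n_iter, traj = best
    qf = pd.DataFrame(
        q, index=geno.samples, columns=[f"K{i + 1}" for i in range(k)]
    )
    assignments: dict[str, object] = {}
    for i, s in enumerate(geno.samples):
        if q[i].max() >= MEMBERSHIP_THRESHOLD:
            assignments[s] = int(np.argmax(q[i])) + 1
        else:
            assignments[s] = MIXED
    return AdmixtureResult(
        samples=list(geno.samples),
        q=qf,
        loglik=ll,
        replicate_logliks=logliks,
        assignments=assignments,
        n_iter=n_iter,
        loglik_trajectory=traj,
    )


def evanno_delta_k(logliks: dict[int, list[float]]) -> EvannoTable:
    """Evanno second-difference statistic over replicate log-likelihoods.

    delta_K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)),
    defined for interior K with sd > 0; best_K maximizes delta_K.
    """
    ks = sorted(logliks)
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    if len(ks) < 3:
        raise ValueError("need >= 3 consecutive K values for an interior K")
    means = {k: float(np.mean(logliks[k])) for k in ks}
    sds = {k: float(np.std(logliks[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        delta = np.nan
        if ks[0] < k < ks[-1]:
            if sds[k] > 0:
                delta = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sds[k]
        rows.append(
            {"K": k, "mean_loglik": means[k], "sd_loglik": sds[k], "delta_k": delta}
        )
    table = pd.DataFrame(rows)
    interior = table.dropna(subset=["delta_k"])
    if interior.empty:
        raise ValueError("delta_K undefined for every interior K (zero sd)")
    best_k = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    return EvannoTable(table=table, best_k=best_k)
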