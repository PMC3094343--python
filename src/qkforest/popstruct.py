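"""Population-structure inference.

Two complementary routes, mirroring common practice for dominant marker data:

* distance-based: Jaccard distances -> principal coordinates -> kernel-density
  mode clustering (density hill-climbing with bootstrap stability);
* model-based: a haploid admixture Gibbs sampler with independent
  Beta(1,1)-prior subpopulation allele frequencies and Dirichlet(1) membership
  priors, returning the posterior-mean membership matrix Q.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .simdata import MarkerMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "PCOResult",
    "ClusterResult",
    "AdmixtureQ",
    "jaccard_distance",
    "pco",
    "modeclus",
    "estimate_admixture",
    "select_k",
    "assign_members",
]


@dataclass
class DistanceMatrix:
    values: np.ndarray
    accession_ids: list[str]
    metric: str = "jaccard"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have zero diagonal")


@dataclass
class PCOResult:
    coordinates: np.ndarray  # accessions x retained axes
    eigenvalues: np.ndarray  # retained, non-increasing, positive
    variance_fraction: np.ndarray
    accession_ids: list[str]
    dropped_negative_mass: float = 0.0


@dataclass
class ClusterResult:
    labels: np.ndarray  # 1-based cluster labels
    n_clusters: int
    densities: np.ndarray
    stability: np.ndarray  # per-cluster, in [0, 1]
    accession_ids: list[str] = field(default_factory=list)


@dataclass
class AdmixtureQ:
    """Accessions x K membership probabilities; rows sum to one."""

    memberships: np.ndarray
    accession_ids: list[str]
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.memberships = np.asarray(self.memberships, dtype=float)
        rs = self.memberships.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")

    @property
    def n_subpops(self) -> int:
        return self.memberships.shape[1]

    def design_columns(self) -> np.ndarray:
        """K-1 membership columns for regression (rows sum to one)."""
        return self.memberships[:, :-1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"Q{k + 1}" for k in range(self.n_subpops)]
        return pd.DataFrame(self.memberships,
                            index=pd.Index(self.accession_ids, name="accession"),
                            columns=cols)


def jaccard_distance(markers: MarkerMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distances d = 1 - |intersection|/|union| over bands."""
    X = markers.scores.astype(bool)
    empty = ~X.any(axis=1)
    if empty.any():
        bad = markers.accession_ids[int(np.flatnonzero(empty)[0])]
        raise ValueError(
            f"accession {bad!r} has an all-zero marker profile; Jaccard undefined")
    D = squareform(pdist(X, metric="jaccard"))
    return DistanceMatrix(values=D, accession_ids=list(markers.accession_ids))


def pco(dist: DistanceMatrix, n_axes: int = 2) -> PCOResult:
    """Classical scaling (principal coordinates) of a distance matrix."""
    D = dist.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, U = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    pos = w > 1e-10
    neg_mass = float(np.abs(w[w < 0]).sum())
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating")
        n_axes = n_pos
    wk, Uk = w[:n_axes], U[:, :n_axes]
    coords = Uk * np.sqrt(wk)
    total = w[pos].sum()
    frac = wk / total if total > 0 else np.zeros(n_axes)
    return PCOResult(coordinates=coords, eigenvalues=wk, variance_fraction=frac,
                     accession_ids=list(dist.accession_ids),
                     dropped_negative_mass=neg_mass)


def _silverman_bandwidth(X: np.ndarray) -> float:
    n, d = X.shape
    sigma = X.std(axis=0, ddof=1).mean()
    if sigma == 0:
        return 1.0
    return float(sigma * (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4)))


def _kde_densities(X: np.ndarray, h: float) -> np.ndarray:
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    return np.exp(-d2 / (2.0 * h * h)).sum(axis=1)


LINK_FACTOR = 3.0  # linking radius in units of the kernel bandwidth


def _hill_climb_labels(X: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Density hill-climbing: each point links to its nearest neighbor of
    higher kernel density; links longer than LINK_FACTOR * h are cut, and the
    stranded points become modes, seeding clusters in decreasing density
    order."""
    n = X.shape[0]
    dens = _kde_densities(X, h)
    d = squareform(pdist(X))
    parent = np.arange(n)
    rank = dens + np.arange(n)[::-1] * 1e-12  # deterministic strict ordering
    for i in range(n):
        higher = np.flatnonzero(rank > rank[i])
        if higher.size == 0:
            continue  # global mode
        j = higher[np.argmin(d[i, higher])]
        if d[i, j] <= LINK_FACTOR * h:
            parent[i] = j
    # follow parent pointers to the mode
    labels = np.full(n, -1, dtype=int)
    order = np.argsort(dens)[::-1]
    next_label = 0
    for i in order:
        path = []
        j = i
        while labels[j] < 0 and parent[j] != j:
            path.append(j)
            j = parent[j]
        if labels[j] < 0:  # j is a mode
            labels[j] = next_label
            next_label += 1
        for k in path:
            labels[k] = labels[j]
    return labels + 1, dens


def modeclus(pco_result: PCOResult, n_axes_used: int | None = None,
             bandwidth: float | str = "auto", n_boot: int = 50,
             seed: int = 0) -> ClusterResult:
    """Kernel-density mode clustering in the retained PCO space.

    Clusters are seeded at local density maxima in decreasing density order;
    stability is the bootstrap fraction of replicates preserving within-cluster
    co-assignment.
    """
    X = pco_result.coordinates
    if n_axes_used is not None:
        X = X[:, :n_axes_used]
    n = X.shape[0]
    h = _silverman_bandwidth(X) if bandwidth == "auto" else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be > 0")
    labels, dens = _hill_climb_labels(X, h)
    n_clusters = int(labels.max())
    if n_clusters == n and n > 1:
        warnings.warn("bandwidth so small that every point is its own mode")

    # bootstrap co-assignment stability per cluster
    rng = np.random.default_rng(seed)
    agree = np.zeros(n_clusters)
    tries = np.zeros(n_clusters)
    for _ in range(n_boot):
        idx = rng.choice(n, size=n, replace=True)
        bl, _ = _hill_climb_labels(X[idx], h)
        for c in range(1, n_clusters + 1):
            members = np.flatnonzero(labels[idx] == c)
            if len(members) < 2:
                continue
            pairs = min(len(members) - 1, 20)
            anchor = members[0]
            same = bl[members[1:pairs + 1]] == bl[anchor]
            agree[c - 1] += same.mean()
            tries[c - 1] += 1
    stability = np.where(tries > 0, agree / np.maximum(tries, 1), 1.0)
    return ClusterResult(labels=labels, n_clusters=n_clusters, densities=dens,
                         stability=stability,
                         accession_ids=list(pco_result.accession_ids))


# ---------------------------------------------------------------------------
# haploid admixture Gibbs sampler

def _gibbs_loglik(X: np.ndarray, Qm: np.ndarray, P: np.ndarray) -> float:
    mix = Qm @ P
    mix = np.clip(mix, 1e-12, 1 - 1e-12)
    return float((X * np.log(mix) + (1 - X) * np.log1p(-mix)).sum())


def _align_to_ref(counts: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Greedy label matching: permutation of columns of `counts` onto `ref`."""
    K = counts.shape[1]
    sim = counts.T @ ref  # K x K agreement
    perm = np.full(K, -1, dtype=int)
    used_r, used_c = set(), set()
    for _ in range(K):
        best, bi, bj = -np.inf, -1, -1
        for i in range(K):
            if i in used_c:
                continue
            for j in range(K):
                if j in used_r:
                    continue
                if sim[i, j] > best:
                    best, bi, bj = sim[i, j], i, j
        perm[bi] = bj
        used_c.add(bi)
        used_r.add(bj)
    return perm


def estimate_admixture(markers: MarkerMatrix, K: int, n_iter: int = 3000,
                       burnin: int = 1000, seed: int = 0) -> AdmixtureQ:
    """Haploid admixture Gibbs sampler returning posterior-mean memberships.

    Latent per-accession-per-marker ancestries z_ij are updated against
    Beta(1,1)-prior subpopulation frequencies and Dirichlet(1)-prior
    memberships; samples after burn-in are label-aligned to the first retained
    sample by greedy matching before averaging.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_iter <= burnin:
        raise ValueError("n_iter must exceed burnin")
    X = markers.scores.astype(np.float64)
    n, m = X.shape
    if K == 1:
        return AdmixtureQ(memberships=np.ones((n, 1)),
                          accession_ids=list(markers.accession_ids),
                          loglik_trace=np.full(n_iter, _gibbs_loglik(
                              X, np.ones((n, 1)), X.mean(axis=0, keepdims=True))))

    rng = np.random.default_rng(seed)
    z = rng.integers(0, K, size=(n, m))
    q_sum = np.zeros((n, K))
    n_kept = 0
    trace = np.empty(n_iter)
    ref_counts: np.ndarray | None = None
    onehot = np.eye(K)

    for it in range(n_iter):
        Z = onehot[z]                       # n x m x K
        ones_k = np.einsum("ijk,ij->kj", Z, X)
        tot_k = Z.sum(axis=0).T             # K x m
        P = rng.beta(1.0 + ones_k, 1.0 + (tot_k - ones_k))
        counts = Z.sum(axis=1)              # n x K
        Qm = rng.gamma(1.0 + counts)        # Dirichlet(1 + counts) via gammas
        Qm /= Qm.sum(axis=1, keepdims=True)
        # z | q, p:  prob ∝ q_ik * p_kj^x * (1-p_kj)^(1-x)
        Pc = np.clip(P, 1e-12, 1 - 1e-12)
        like = np.where(X[:, :, None] == 1, Pc.T[None, :, :], (1 - Pc).T[None, :, :])
        w = like * Qm[:, None, :]
        w /= w.sum(axis=2, keepdims=True)
        cum = np.cumsum(w, axis=2)
        u = rng.random((n, m, 1))
        z = (u > cum).sum(axis=2)
        trace[it] = _gibbs_loglik(X, Qm, P)
        if it >= burnin:
            counts_now = onehot[z].sum(axis=1)
            if ref_counts is None:
                ref_counts = counts_now
                perm = np.arange(K)
            else:
                perm = _align_to_ref(counts_now, ref_counts)
            # perm maps sample column i -> reference column perm[i]
            q_sum[:, perm] += Qm
            n_kept += 1

    Qhat = q_sum / n_kept
    Qhat /= Qhat.sum(axis=1, keepdims=True)
    return AdmixtureQ(memberships=Qhat, accession_ids=list(markers.accession_ids),
                      loglik_trace=trace)


def select_k(markers: MarkerMatrix, k_range=range(1, 11), replicates: int = 1,
             n_iter: int = 1500, burnin: int = 500, seed: int = 0) -> pd.DataFrame:
    """Mean post-burn-in log-likelihood per assumed K.

    No automatic choice is made; the table is reported for the analyst.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    rows = []
    for K in k_range:
        lls = []
        for r in range(replicates):
            q = estimate_admixture(markers, K, n_iter=n_iter, burnin=burnin,
                                   seed=seed + 1000 * r + K)
            lls.append(float(q.loglik_trace[burnin:].mean()))
        rows.append({"K": K, "mean_loglik": float(np.mean(lls)),
                     "sd_loglik": float(np.std(lls)) if replicates > 1 else 0.0})
    return pd.DataFrame(rows)


def assign_members(Q: AdmixtureQ, threshold: float = 0.70) -> pd.DataFrame:
    """Hard assignment: argmax subpopulation when max membership > threshold
    (strict), otherwise "admixed"."""
    mx = Q.memberships.max(axis=1)
    arg = Q.memberships.argmax(axis=1) + 1
    labels = [str(a) if m > threshold else "admixed" for a, m in zip(arg, mx)]
    df = pd.DataFrame({"accession": Q.accession_ids, "label": labels,
                       "max_membership": mx})
    counts = df["label"].value_counts()
    logger.info("membership assignment at >%.2f: %s", threshold, counts.to_dict())
    return df
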