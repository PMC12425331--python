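"""Closed-form communication metrics on a weighted connectome.

The central quantity is the commute time C_ij: the expected number of
random-walk steps to travel from region i to region j and back, for a walker
whose one-step transition probabilities are proportional to streamline
counts.  C_ij has a closed form in the pseudoinverse of the graph Laplacian,

    H_ij = Σ_k ([Γ⁺]_ik − [Γ⁺]_ij − [Γ⁺]_jk + [Γ⁺]_jj) D_kk
    C_ij = H_ij + H_ji = ([Γ⁺]_ii + [Γ⁺]_jj − 2 [Γ⁺]_ij) Σ_k D_kk ,

and is proportional to the effective resistance Ω_ij when edges are read as
conductors, C_ij = Ω_ij · Σ_k D_kk.  The module also provides the competing
communication measures the analysis compares against: communicability (a
factorially damped walk sum, i.e. the matrix exponential of a degree
normalized adjacency), search information (bits needed to steer a random
walker down the shortest path), and the mean-first-passage-time variant of
commute time computed from the chain's fundamental matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
from scipy.linalg import expm
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .core import GraphOperators, PairwiseMetric, StructuralConnectome


@dataclass(frozen=True)
class MetricConfig:
    """Conventions for the metrics whose published definitions are ambiguous.

    ``si_sign_convention``: ``bits_positive`` stores SI as −log2(path
    probability) ≥ 0; ``as_printed`` stores the raw log2 (≤ 0).
    ``communicability_form``: the walk-sum is realized as a matrix exponential
    (``matrix_exp``) or, for comparison, as an elementwise exponential of the
    normalized adjacency (``elementwise_exp``).
    """

    si_sign_convention: Literal["bits_positive", "as_printed"] = "bits_positive"
    mfpt_method: Literal["fundamental_matrix"] = "fundamental_matrix"
    communicability_form: Literal["matrix_exp", "elementwise_exp"] = "matrix_exp"
    communicability_normalization: Literal["symmetric_sqrt_degree"] = "symmetric_sqrt_degree"

    def as_metadata(self) -> dict:
        return asdict(self)


DEFAULT_CONFIG = MetricConfig()


def hitting_time(ops: GraphOperators) -> PairwiseMetric:
    """Expected steps H_ij for a random walk started at i to first reach j.

    Closed form in the Laplacian pseudoinverse; asymmetric in general, zero
    diagonal, and ≥ 1 off-diagonal (at least one step is always needed).
    """
    g = ops.laplacian_pinv
    d = ops.degree_vector
    total = d.sum()
    gd = g @ d  # gd_i = Σ_k G_ik D_kk
    # H_ij = gd_i − gd_j + (G_jj − G_ij) Σ_k D_kk   (using symmetry of Γ⁺)
    h = gd[:, None] - gd[None, :] + total * (np.diag(g)[None, :] - g)
    np.fill_diagonal(h, 0.0)
    return PairwiseMetric(values=h, metric_tag="hitting_time", symmetric=False)


def commute_time(ops: GraphOperators) -> PairwiseMetric:
    """Commute time C_ij = (Γ⁺_ii + Γ⁺_jj − 2 Γ⁺_ij) · Σ_k D_kk."""
    g = ops.laplacian_pinv
    total = ops.degree_vector.sum()
    gd = np.diag(g)
    c = (gd[:, None] + gd[None, :] - 2.0 * g) * total
    c = (c + c.T) / 2.0  # enforce exact symmetry against rounding
    np.fill_diagonal(c, 0.0)
    return PairwiseMetric(values=c, metric_tag="commute_time")


def resistance_distance(ops: GraphOperators) -> PairwiseMetric:
    """Effective resistance Ω_ij = Γ⁺_ii + Γ⁺_jj − 2 Γ⁺_ij.

    Proportional to commute time: C = Ω · Σ_k D_kk with the same
    pseudoinverse, which serves as a mandatory cross-check downstream.
    """
    g = ops.laplacian_pinv
    gd = np.diag(g)
    omega = gd[:, None] + gd[None, :] - 2.0 * g
    omega = (omega + omega.T) / 2.0
    np.fill_diagonal(omega, 0.0)
    return PairwiseMetric(values=omega, metric_tag="resistance")


def mfpt_commute_time(ops: GraphOperators, config: MetricConfig = DEFAULT_CONFIG) -> PairwiseMetric:
    """Commute time built from mean first passage times of the Markov chain.

    MFPT is computed from the fundamental matrix Z = (I − M + 1πᵀ)⁻¹ of the
    chain with stationary distribution π_i = D_ii / Σ_k D_kk:
    m_ij = (Z_jj − Z_ij) / π_j.  The commute variant m_ij + m_ji is symmetric
    with zero diagonal.
    """
    m = ops.transition
    n = m.shape[0]
    pi = ops.degree_vector / ops.degree_vector.sum()
    z = np.linalg.inv(np.eye(n) - m + np.outer(np.ones(n), pi))
    mfpt = (np.diag(z)[None, :] - z) / pi[None, :]
    np.fill_diagonal(mfpt, 0.0)
    c = mfpt + mfpt.T
    return PairwiseMetric(
        values=c, metric_tag="mfpt_commute", metadata={"mfpt_method": config.mfpt_method}
    )


def communicability(ops: GraphOperators, config: MetricConfig = DEFAULT_CONFIG) -> PairwiseMetric:
    """Communicability: factorially damped sum over walks of all lengths.

    The adjacency is degree-normalized, A'_ij = A_ij / √(D_ii D_jj), and the
    walk sum Σ_n (A')ⁿ/n! is the matrix exponential exp(A').  The
    ``elementwise_exp`` form applies exp entrywise to A' instead.
    """
    d = ops.degree_vector
    if np.any(d <= 0):
        raise ValueError("communicability requires every node to have positive degree")
    norm = ops.adjacency / np.sqrt(np.outer(d, d))
    if config.communicability_form == "matrix_exp":
        cmy = expm(norm)
    else:
        cmy = np.exp(norm)
    cmy = (cmy + cmy.T) / 2.0
    return PairwiseMetric(
        values=cmy,
        metric_tag="communicability",
        metadata={"communicability_form": config.communicability_form},
    )


def _shortest_path_lexicographic(dist_row: np.ndarray, lengths: np.ndarray, i: int, j: int) -> list[int]:
    """Reconstruct the i→j shortest path, breaking ties by smallest index.

    Walks backwards from j: the predecessor of node v is the smallest-index
    neighbor u with dist(i,u) + length(u,v) == dist(i,v).
    """
    path = [j]
    v = j
    tol = 1e-9 * max(dist_row[j], 1.0)
    while v != i:
        nbrs = np.flatnonzero(lengths[:, v] > 0)
        ok = nbrs[np.abs(dist_row[nbrs] + lengths[nbrs, v] - dist_row[v]) <= tol]
        if ok.size == 0:  # pragma: no cover - connected graph guarantees a predecessor
            raise RuntimeError("shortest-path reconstruction failed")
        v = int(ok.min())
        path.append(v)
    return path[::-1]


def search_information(
    c: StructuralConnectome,
    ops: GraphOperators,
    config: MetricConfig = DEFAULT_CONFIG,
) -> PairwiseMetric:
    """Bits a random walker needs to follow the shortest path from i to j.

    Shortest paths are measured on the tract-length graph (falling back to
    distances 1/A_ij when no lengths are available); the walker's step
    probabilities come from the streamline-count transition matrix M.
    SI(i,j) = −log2(M_ia · M_ab · … · M_zj) under the ``bits_positive``
    convention.  Asymmetric in general; see :func:`symmetrize` for the
    pair-level mean used in correlations.
    """
    if c.lengths is not None:
        lengths = c.lengths.astype(float)
    else:
        w = c.weights
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    n = ops.n_regions
    dist = dijkstra(csr_matrix(lengths), directed=False)
    logm = np.full_like(ops.transition, -np.inf)
    np.log2(ops.transition, where=ops.transition > 0, out=logm)
    si = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            path = _shortest_path_lexicographic(dist[i], lengths, i, j)
            bits = 0.0
            for u, v in zip(path[:-1], path[1:]):
                bits -= logm[u, v]
            si[i, j] = bits
    if config.si_sign_convention == "as_printed":
        si = -si
    return PairwiseMetric(
        values=si,
        metric_tag="search_information",
        symmetric=False,
        metadata={"si_sign_convention": config.si_sign_convention},
    )


def symmetrize(m: PairwiseMetric) -> PairwiseMetric:
    """Pair-level symmetrization: mean of m(i,j) and m(j,i)."""
    sym = (m.values + m.values.T) / 2.0
    return PairwiseMetric(
        values=sym,
        metric_tag=m.metric_tag,
        symmetric=True,
        metadata={**m.metadata, "symmetrized": "mean"},
    )


def compute_all_metrics(
    c: StructuralConnectome,
    ops: GraphOperators,
    config: MetricConfig = DEFAULT_CONFIG,
) -> dict[str, PairwiseMetric]:
    """The four compared structural metrics, each as a symmetric matrix.

    ``connectivity`` is the raw adjacency itself; search information is
    symmetrized by the pair mean.
    """
    return {
        "connectivity": PairwiseMetric(values=ops.adjacency.copy(), metric_tag="connectivity"),
        "search_information": symmetrize(search_information(c, ops, config)),
        "communicability": communicability(ops, config),
        "commute_time": commute_time(ops),
    }
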