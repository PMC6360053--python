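"""KNN network augmentation and quadrangular common-neighbor scoring.

The known association network is sparse, so it is densified twice before
scoring.  For each disease, its K most similar other diseases vote on
candidate miRNAs: when at least ``vote_threshold`` of them share a miRNA,
that edge is recommended, yielding the disease-driven network SDA.  The
miRNA-driven network SMA is the mirror construction.  Both keep every
original edge (augmentation only adds).

A candidate pair (d_i, m_j) is then scored, in each of the three networks
(original, disease-augmented, miRNA-augmented), by a local-community index
over its quadrangular closures: the common neighbors (CN) are the interior
nodes of length-3 paths d_i - m_k - d_l - m_j, the local community links
(LCL) are the network edges whose two endpoints are both common neighbors,
and

    CJC(i, j) = CN * LCL / (deg(d_i) + deg(m_j)).

If the seed pair itself is an edge it is removed before counting, and
degrees are taken after removal.  The final score is the geometric mean of
the three per-network CJC values, so a pair must close quadrangles with
internal links in all three networks to score above zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AssociationMatrix, RankedPredictions

__all__ = [
    "PairNeighborhood",
    "NetworkTriple",
    "ScoreMatrix",
    "knn_neighbors",
    "knn_augment_by_disease",
    "knn_augment_by_mirna",
    "build_network_triple",
    "pair_neighborhood",
    "cjc",
    "cjc_matrix",
    "score_all",
    "rank_for_disease",
]


@dataclass(frozen=True)
class PairNeighborhood:
    """Quadrangular neighborhood of one (disease, miRNA) pair in one network."""

    cn_mirnas: frozenset[int]
    cn_diseases: frozenset[int]
    lcl_count: int
    degree_sum: int

    @property
    def cn_count(self) -> int:
        return len(self.cn_mirnas) + len(self.cn_diseases)


@dataclass
class NetworkTriple:
    """The original and two augmented association networks on shared labels."""

    mda: np.ndarray
    sda: np.ndarray
    sma: np.ndarray
    k: int
    vote_threshold: int

    def __post_init__(self) -> None:
        if not (self.mda.shape == self.sda.shape == self.sma.shape):
            raise ValueError("the three networks must share one shape")
        if np.any(self.sda < self.mda) or np.any(self.sma < self.mda):
            raise ValueError("augmented networks must contain every original edge")


@dataclass
class ScoreMatrix:
    """Dense disease x miRNA scores, optionally with per-network diagnostics."""

    scores: np.ndarray
    per_network_cjc: dict[str, np.ndarray] | None = None


def knn_neighbors(S: np.ndarray, k: int) -> np.ndarray:
    """Indices of each row's k most similar *other* items, ties by index.

    Returns an (n, k) integer array.  Row ``i`` never contains ``i``;
    similarity ties at the cut are broken toward the smaller index so runs
    are deterministic.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of items ({n})")
    out = np.empty((n, k), dtype=np.intp)
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        # stable sort on descending similarity keeps ascending-index ties
        order = np.argsort(-S[i, others], kind="stable")
        out[i] = others[order[:k]]
    return out


def knn_augment_by_disease(
    A: np.ndarray, Sd: np.ndarray, k: int = 3, vote_threshold: int | None = None
) -> np.ndarray:
    """SDA: add (d_i, m) edges endorsed by d_i's K nearest diseases.

    An edge is recommended when at least ``vote_threshold`` of the k
    neighbors already carry it (default: strict majority, floor(k/2)+1).
    The result is the union of recommendations with the original edges.
    """
    A = np.asarray(A)
    if vote_threshold is None:
        vote_threshold = k // 2 + 1
    if not 1 <= vote_threshold <= k:
        raise ValueError(f"vote_threshold must lie in [1, {k}]")
    nbrs = knn_neighbors(np.asarray(Sd), k)
    votes = A[nbrs].sum(axis=1)  # (N_d, N_m): neighbor endorsements per miRNA
    return ((votes >= vote_threshold) | (A == 1)).astype(np.int8)


def knn_augment_by_mirna(
    A: np.ndarray, Sm: np.ndarray, k: int = 3, vote_threshold: int | None = None
) -> np.ndarray:
    """SMA: the mirror construction, miRNA neighbors voting over diseases."""
    return knn_augment_by_disease(np.asarray(A).T, Sm, k, vote_threshold).T


def build_network_triple(
    A: np.ndarray,
    Sd: np.ndarray,
    Sm: np.ndarray,
    k: int = 3,
    vote_threshold: int | None = None,
) -> NetworkTriple:
    if vote_threshold is None:
        vote_threshold = k // 2 + 1
    sda = knn_augment_by_disease(A, Sd, k, vote_threshold)
    sma = knn_augment_by_mirna(A, Sm, k, vote_threshold)
    return NetworkTriple(np.asarray(A, dtype=np.int8), sda, sma, k, vote_threshold)


def pair_neighborhood(X: np.ndarray, i: int, j: int) -> PairNeighborhood:
    """CN / LCL / degree counts for the pair (disease i, miRNA j) in ``X``.

    The seed edge (i, j), when present, is removed before anything is
    counted, including the endpoint degrees.
    """
    Xp = np.asarray(X, dtype=np.int8)
    if Xp[i, j]:
        Xp = Xp.copy()
        Xp[i, j] = 0
    row_i = Xp[i, :].astype(bool)  # miRNAs adjacent to d_i
    col_j = Xp[:, j].astype(bool)  # diseases adjacent to m_j
    # m_k is a common neighbor iff d_i-m_k and some d_l closes m_k-d_l-m_j
    closes_to_j = (Xp[col_j, :].sum(axis=0) > 0) if col_j.any() else np.zeros(Xp.shape[1], bool)
    cn_m = row_i & closes_to_j
    closes_to_i = (Xp[:, row_i].sum(axis=1) > 0) if row_i.any() else np.zeros(Xp.shape[0], bool)
    cn_d = col_j & closes_to_i
    lcl = int(Xp[np.ix_(cn_d, cn_m)].sum())
    degree_sum = int(row_i.sum() + col_j.sum())
    return PairNeighborhood(
        cn_mirnas=frozenset(np.flatnonzero(cn_m).tolist()),
        cn_diseases=frozenset(np.flatnonzero(cn_d).tolist()),
        lcl_count=lcl,
        degree_sum=degree_sum,
    )


def cjc(X: np.ndarray, i: int, j: int) -> float:
    """The per-network index CN * LCL / (deg(d_i) + deg(m_j)); 0 if isolated."""
    nb = pair_neighborhood(X, i, j)
    if nb.degree_sum == 0:
        return 0.0
    return nb.cn_count * nb.lcl_count / nb.degree_sum


def cjc_matrix(X: np.ndarray) -> np.ndarray:
    """CJC for every pair of one network, vectorised.

    For pairs that are non-edges in ``X`` the seed removal is a no-op and
    the whole computation reduces to boolean matrix products plus one
    four-index contraction for the LCL counts.  Pairs that are edges need
    the removal and are recomputed individually (they are few in a sparse
    network).
    """
    Xf = np.asarray(X, dtype=float)
    n_d, n_m = Xf.shape
    co_dis = Xf.T @ Xf  # (m, m): # diseases shared by two miRNAs
    co_mir = Xf @ Xf.T  # (d, d): # miRNAs shared by two diseases
    reach_m = (co_dis > 0).astype(float)  # m_k closes to m_j via some disease
    reach_d = (co_mir > 0).astype(float)
    cn_m_count = Xf @ reach_m
    cn_d_count = reach_d @ Xf
    cn = cn_m_count + cn_d_count
    # LCL(i,j) = sum_{l,k} [co_mir(i,l)>0] X(l,j) X(l,k) X(i,k) [co_dis(k,j)>0]
    lcl = np.einsum("il,lj,lk,ik,kj->ij", reach_d, Xf, Xf, Xf, reach_m, optimize=True)
    deg_sum = Xf.sum(axis=1)[:, None] + Xf.sum(axis=0)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(deg_sum > 0, cn * lcl / np.maximum(deg_sum, 1), 0.0)
    # existing edges: the vectorised counts included paths through the seed
    # edge itself; redo those pairs with the edge removed
    for i, j in np.argwhere(np.asarray(X) == 1):
        out[i, j] = cjc(X, i, j)
    return out


def score_all(triple: NetworkTriple, *, diagnostics: bool = False) -> ScoreMatrix:
    """Geometric mean of the per-network CJC values for every pair."""
    parts = {
        "mda": cjc_matrix(triple.mda),
        "sda": cjc_matrix(triple.sda),
        "sma": cjc_matrix(triple.sma),
    }
    scores = np.cbrt(parts["mda"] * parts["sda"] * parts["sma"])
    return ScoreMatrix(scores, parts if diagnostics else None)


def rank_for_disease(
    scores: ScoreMatrix | np.ndarray,
    A: AssociationMatrix,
    disease: str,
    top_n: int = 50,
) -> RankedPredictions:
    """Top candidate miRNAs for one disease among pairs without known evidence.

    Ties are broken by ascending miRNA index (stable sort), and at most
    ``top_n`` rows are returned.
    """
    S = scores.scores if isinstance(scores, ScoreMatrix) else np.asarray(scores)
    i = A.disease_index(disease)
    unknown = np.flatnonzero(A.matrix[i] == 0)
    order = unknown[np.argsort(-S[i, unknown], kind="stable")][:top_n]
    rows = [(A.mirna_labels[j], float(S[i, j])) for j in order]
    return RankedPredictions(disease=disease, rows=rows)
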