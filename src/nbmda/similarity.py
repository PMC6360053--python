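"""Similarity layers: disease semantic similarity, Gaussian interaction
profile kernels, and their fusion into integrated similarities.

Three sources of pairwise similarity feed the predictor:

* **Semantic similarity (SS)** between disease ontology terms.  Each term
  ``D`` spans a sub-DAG of its ancestors ``T(D)``; an ancestor ``t``
  contributes ``delta**depth`` (along the best path) to ``D``'s semantic
  value, and two diseases are similar in proportion to the contributions of
  the ancestors they share.
* **Gaussian interaction-profile kernels (KM, KD)** computed from the
  binary association matrix: two miRNAs (columns) or two diseases (rows)
  are similar when their interaction profiles are close in Hamming terms,
  with the bandwidth normalised by the mean squared profile norm so the
  kernel is insensitive to overall network density.
* **Integrated similarities (Sm, Sd)**: the kernel value where the primary
  similarity (functional for miRNAs, semantic for diseases) is zero, and
  the arithmetic mean of the two otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import DiseaseDAG

__all__ = [
    "SemanticParams",
    "KernelParams",
    "semantic_contribution",
    "semantic_value",
    "disease_semantic_similarity",
    "gaussian_kernel",
    "mirna_kernel",
    "disease_kernel",
    "integrate",
]

#: below this magnitude a file-read similarity counts as exactly zero
ZERO_TOL = 1e-12


@dataclass(frozen=True)
class SemanticParams:
    """Decay factor for ancestor contributions, in (0, 1]."""

    delta: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.delta <= 1:
            raise ValueError(f"delta must be in (0, 1], got {self.delta}")


@dataclass(frozen=True)
class KernelParams:
    """Bandwidth bases for the interaction-profile kernels (both > 0)."""

    gamma_prime_m: float = 1.0
    gamma_prime_d: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_prime_m <= 0 or self.gamma_prime_d <= 0:
            raise ValueError("kernel bandwidth bases must be positive")


def semantic_contribution(
    dag: DiseaseDAG, D: str, params: SemanticParams = SemanticParams()
) -> dict[str, float]:
    """Contribution of every term in T(D) to the semantic value of ``D``.

    ``D`` itself contributes 1; any other ancestor ``t`` contributes
    ``delta`` times the largest contribution among its children that lie in
    T(D) (children off every path from ``D`` contribute nothing).  The map
    is computed by memoised traversal restricted to T(D).
    """
    if D not in dag:
        raise KeyError(f"term {D!r} not in the disease hierarchy")
    ancestors = dag.ancestors(D)
    contrib: dict[str, float] = {}

    def value(t: str) -> float:
        if t in contrib:
            return contrib[t]
        if t == D:
            contrib[t] = 1.0
            return 1.0
        kids = [c for c in dag.children(t) if c in ancestors]
        contrib[t] = params.delta * max(value(c) for c in kids)
        return contrib[t]

    # order by increasing reachability guarantees children-first, but the
    # memoised recursion handles any order; T(D) is finite and acyclic.
    for t in ancestors:
        value(t)
    return contrib


def semantic_value(
    dag: DiseaseDAG, D: str, params: SemanticParams = SemanticParams()
) -> float:
    """DV(D): sum of ancestor contributions over T(D); always >= 1."""
    return float(sum(semantic_contribution(dag, D, params).values()))


def disease_semantic_similarity(
    dag: DiseaseDAG,
    labels: Sequence[str],
    params: SemanticParams = SemanticParams(),
    term_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Pairwise semantic similarity over ``labels``.

    SS(i, j) sums, over shared ancestors ``t`` of the two terms, the
    contribution of ``t`` to each, normalised by the sum of the two
    semantic values.  The diagonal is exactly 1 and disjoint ancestor sets
    give 0.  Labels that do not map into the DAG (directly or via
    ``term_map``) get an all-zero row apart from the unit diagonal, leaving
    the kernel as the only disease-similarity source downstream.
    """
    term_map = dict(term_map or {})
    contribs: dict[int, dict[str, float]] = {}
    dvs: dict[int, float] = {}
    unmapped: list[str] = []
    for i, lab in enumerate(labels):
        node = term_map.get(lab, lab)
        if node in dag:
            c = semantic_contribution(dag, node, params)
            contribs[i] = c
            dvs[i] = sum(c.values())
        else:
            unmapped.append(lab)
    if unmapped:
        import warnings

        warnings.warn(
            f"{len(unmapped)} disease label(s) not found in the hierarchy "
            f"(e.g. {unmapped[:3]}); their semantic-similarity rows are 0",
            stacklevel=2,
        )
    n = len(labels)
    ss = np.zeros((n, n), dtype=float)
    idx = sorted(contribs)
    for a, i in enumerate(idx):
        ci, dvi = contribs[i], dvs[i]
        for j in idx[a + 1 :]:
            cj, dvj = contribs[j], dvs[j]
            shared = ci.keys() & cj.keys()
            if shared:
                num = sum(ci[t] + cj[t] for t in shared)
                ss[i, j] = ss[j, i] = num / (dvi + dvj)
    np.fill_diagonal(ss, 1.0)
    return pd.DataFrame(ss, index=list(labels), columns=list(labels))


def gaussian_kernel(profiles: np.ndarray, gamma_prime: float = 1.0) -> np.ndarray:
    """Gaussian kernel over binary interaction profiles (one per row).

    The bandwidth is ``gamma_prime`` divided by the mean squared profile
    norm, so entry (a, b) is ``exp(-gamma * ||IP_a - IP_b||^2)``.  Raises
    if every profile is zero (the bandwidth is then undefined); individual
    zero profiles are fine.
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2:
        raise ValueError("profiles must be a 2-D array (one profile per row)")
    sq_norms = (P * P).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq <= 0:
        raise ValueError("degenerate kernel: every interaction profile is zero")
    gamma = gamma_prime / mean_sq
    # ||a-b||^2 = ||a||^2 + ||b||^2 - 2 a.b
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (P @ P.T)
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-gamma * d2)
    np.fill_diagonal(K, 1.0)
    return K


def mirna_kernel(A: np.ndarray, gamma_prime: float = 1.0) -> np.ndarray:
    """KM: Gaussian kernel over the columns (miRNA profiles) of ``A``."""
    return gaussian_kernel(np.asarray(A).T, gamma_prime)


def disease_kernel(A: np.ndarray, gamma_prime: float = 1.0) -> np.ndarray:
    """KD: Gaussian kernel over the rows (disease profiles) of ``A``."""
    return gaussian_kernel(np.asarray(A), gamma_prime)


def integrate(sim_primary: np.ndarray, sim_kernel: np.ndarray) -> np.ndarray:
    """Fuse a primary similarity with its kernel counterpart.

    Where the primary similarity (functional for miRNAs, semantic for
    diseases) is zero the kernel value is used alone; elsewhere the two are
    averaged.  Zero is tested with a small tolerance because the primary
    matrix typically arrives from a file of printed floats.
    """
    S = np.asarray(sim_primary, dtype=float)
    K = np.asarray(sim_kernel, dtype=float)
    if S.shape != K.shape:
        raise ValueError(f"shape mismatch: {S.shape} vs {K.shape}")
    out = np.where(np.abs(S) <= ZERO_TOL, K, (S + K) / 2.0)
    return out
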