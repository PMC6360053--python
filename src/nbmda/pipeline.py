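"""End-to-end scoring pipeline: training matrix in, score matrix out.

Order of operations, all driven by the training adjacency matrix alone:
interaction-profile kernels for miRNAs and diseases, fusion with the
(static) functional and semantic similarities, KNN augmentation into the
disease- and miRNA-driven networks, then the quadrangular common-neighbor
score geometric-averaged over the three networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .augment import ScoreMatrix, build_network_triple, score_all
from .io_formats import AssociationMatrix, align_similarity
from .similarity import disease_kernel, integrate, mirna_kernel

__all__ = ["ModelParams", "nbmda_scores", "predict"]


@dataclass(frozen=True)
class ModelParams:
    """Model hyperparameters with their conventional defaults.

    k: neighbor count for the KNN recommendation (sweeps of 1-5 favour 3).
    vote_threshold: neighbors that must agree before an edge is
        recommended; None means strict majority, floor(k/2)+1.
    delta: semantic contribution decay per ontology level.
    gamma_prime_m / gamma_prime_d: kernel bandwidth bases.
    """

    k: int = 3
    vote_threshold: int | None = None
    delta: float = 0.5
    gamma_prime_m: float = 1.0
    gamma_prime_d: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        vt = self.vote_threshold
        if vt is not None and not 1 <= vt <= self.k:
            raise ValueError(f"vote_threshold must lie in [1, k={self.k}]")
        if not 0 < self.delta <= 1:
            raise ValueError("delta must be in (0, 1]")
        if self.gamma_prime_m <= 0 or self.gamma_prime_d <= 0:
            raise ValueError("kernel bandwidth bases must be positive")


def nbmda_scores(
    A_train: np.ndarray,
    fs: np.ndarray | None,
    ss: np.ndarray | None,
    params: ModelParams = ModelParams(),
) -> np.ndarray:
    """Score every disease-miRNA pair from a training adjacency matrix.

    ``fs`` and ``ss`` are the miRNA functional and disease semantic
    similarity matrices aligned to the adjacency axes; ``None`` stands for
    "no information" (all-zero off-diagonal), which leaves the respective
    kernel as the sole similarity source.
    """
    A_train = np.asarray(A_train)
    n_d, n_m = A_train.shape
    km = mirna_kernel(A_train, params.gamma_prime_m)
    kd = disease_kernel(A_train, params.gamma_prime_d)
    if fs is None:
        fs = np.eye(n_m)
    if ss is None:
        ss = np.eye(n_d)
    sm = integrate(fs, km)
    sd = integrate(ss, kd)
    triple = build_network_triple(A_train, sd, sm, params.k, params.vote_threshold)
    return score_all(triple).scores


def predict(
    assoc: AssociationMatrix,
    fs: "pd.DataFrame | None" = None,
    ss: "pd.DataFrame | None" = None,
    params: ModelParams = ModelParams(),
    *,
    diagnostics: bool = False,
) -> ScoreMatrix:
    """Label-aware front door: align similarity inputs, then score.

    ``fs`` / ``ss`` are label-indexed square DataFrames; labels missing
    from them fall back to zero similarity (kernel-only fusion).
    """
    fs_m = align_similarity(fs, assoc.mirna_labels, what="miRNA functional") if fs is not None else None
    ss_m = align_similarity(ss, assoc.disease_labels, what="disease semantic") if ss is not None else None
    params_ok = params  # validated at construction
    A = assoc.matrix
    km = mirna_kernel(A, params_ok.gamma_prime_m)
    kd = disease_kernel(A, params_ok.gamma_prime_d)
    sm = integrate(fs_m if fs_m is not None else np.eye(assoc.n_mirnas), km)
    sd = integrate(ss_m if ss_m is not None else np.eye(assoc.n_diseases), kd)
    triple = build_network_triple(A, sd, sm, params_ok.k, params_ok.vote_threshold)
    return score_all(triple, diagnostics=diagnostics)
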