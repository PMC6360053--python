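"""Synthetic fixtures: planted-block bipartite networks, random disease
hierarchies, and block-consistent functional-similarity matrices.

Real association catalogues are sparse bipartite networks in which groups
of functionally related miRNAs attach to groups of related diseases.  The
generators here emulate exactly that structure at toy scale: diseases and
miRNAs are split into aligned blocks, within-block pairs get edges with a
high probability and cross-block pairs with a low one, and the similarity
fixtures echo the same block assignment.  The planted signal is what the
end-to-end tests try to recover; degree heterogeneity and annotation bias
of real catalogues are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import AssociationMatrix, DiseaseDAG

__all__ = ["PlantedBlockSpec", "make_bipartite", "make_dag", "make_fs", "block_assignment"]


@dataclass(frozen=True)
class PlantedBlockSpec:
    """Parameters of the planted-block bipartite generator."""

    n_diseases: int = 30
    n_mirnas: int = 30
    n_blocks: int = 3
    p_in: float = 0.5
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out <= 1 and 0 <= self.p_in <= 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if self.p_in <= self.p_out:
            raise ValueError("p_in must exceed p_out (planted structure)")
        if self.n_blocks < 1 or self.n_blocks > min(self.n_diseases, self.n_mirnas):
            raise ValueError("n_blocks must be in [1, min(n_diseases, n_mirnas)]")


def block_assignment(n: int, n_blocks: int) -> np.ndarray:
    """Assign n items to n_blocks contiguous groups whose sizes differ by <=1."""
    return np.repeat(np.arange(n_blocks), np.diff(np.linspace(0, n, n_blocks + 1).astype(int)))


def make_bipartite(spec: PlantedBlockSpec) -> AssociationMatrix:
    """Draw a planted-block binary association matrix, deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    bd = block_assignment(spec.n_diseases, spec.n_blocks)
    bm = block_assignment(spec.n_mirnas, spec.n_blocks)
    same = bd[:, None] == bm[None, :]
    p = np.where(same, spec.p_in, spec.p_out)
    A = (rng.random(p.shape) < p).astype(np.int8)
    diseases = [f"disease_{i:03d}" for i in range(spec.n_diseases)]
    mirnas = [f"mirna_{j:03d}" for j in range(spec.n_mirnas)]
    return AssociationMatrix(A, diseases, mirnas)


def make_dag(
    n: int,
    extra_edge_prob: float = 0.1,
    seed: int = 0,
    names: list[str] | None = None,
) -> DiseaseDAG:
    """Random rooted ontology: node i's parent is drawn among 0..i-1.

    Extra child -> lower-index edges are added with ``extra_edge_prob``,
    giving multi-parent terms; acyclicity holds by construction because
    every edge points from a higher to a lower index.
    """
    if n < 1:
        raise ValueError("need at least one node")
    if names is not None and len(names) != n:
        raise ValueError("names must have length n")
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    if names is None:
        names = [f"term_{i:03d}" for i in range(n)]
    g.add_nodes_from(names)
    for i in range(1, n):
        parent = int(rng.integers(0, i))
        g.add_edge(names[i], names[parent])
        for q in range(i):
            if q != parent and rng.random() < extra_edge_prob:
                g.add_edge(names[i], names[q])
    return DiseaseDAG(g)


def make_fs(
    blocks: np.ndarray,
    noise_sd: float = 0.05,
    seed: int = 0,
    labels: list[str] | None = None,
    *,
    base_in: float = 0.8,
    base_out: float = 0.1,
) -> pd.DataFrame:
    """Block-consistent functional-similarity matrix with Gaussian noise.

    Base similarity ``base_in`` within a block and ``base_out`` across,
    plus symmetric Gaussian noise clipped back into [0, 1]; the diagonal is
    exactly 1.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    blocks = np.asarray(blocks)
    n = blocks.size
    rng = np.random.default_rng(seed)
    S = np.where(blocks[:, None] == blocks[None, :], base_in, base_out).astype(float)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        S = S + (noise + noise.T) / 2.0
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    if labels is None:
        labels = [f"mirna_{j:03d}" for j in range(n)]
    return pd.DataFrame(S, index=labels, columns=labels)
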