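"""On-disk formats and core containers for miRNA-disease association data.

Everything the pipeline touches on disk is plain TSV: a two-column
association list (disease, miRNA), a labelled square similarity matrix, a
two-column disease-ontology edge list (child, parent), and a three-column
ranked-prediction table.  Lines starting with ``#`` are comments in every
dialect.  Downstream modules index by label, never by position, so the
first-appearance ordering imposed here is cosmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "DiseaseDAG",
    "RankedPredictions",
    "FormatError",
    "read_associations",
    "read_similarity_matrix",
    "read_dag",
    "write_predictions",
    "write_similarity_matrix",
]


class FormatError(ValueError):
    """Malformed input file (ragged rows, symmetry violations, cycles...)."""


def _clean_label(raw: str, normalize_case: bool) -> str:
    s = raw.strip()
    return s.lower() if normalize_case else s


@dataclass
class AssociationMatrix:
    """Binary disease x miRNA adjacency matrix with label registries.

    Row ``i`` is the interaction profile of disease ``disease_labels[i]``;
    column ``j`` is the interaction profile of miRNA ``mirna_labels[j]``.
    """

    matrix: np.ndarray
    disease_labels: list[str]
    mirna_labels: list[str]
    _d_index: dict[str, int] = field(init=False, repr=False)
    _m_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if self.matrix.shape != (len(self.disease_labels), len(self.mirna_labels)):
            raise ValueError("matrix shape does not match label counts")
        if len(set(self.disease_labels)) != len(self.disease_labels):
            raise ValueError("duplicate disease labels")
        if len(set(self.mirna_labels)) != len(self.mirna_labels):
            raise ValueError("duplicate miRNA labels")
        vals = np.unique(self.matrix)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("association matrix entries must be 0 or 1")
        self.matrix = self.matrix.astype(np.int8)
        self._d_index = {d: i for i, d in enumerate(self.disease_labels)}
        self._m_index = {m: j for j, m in enumerate(self.mirna_labels)}

    @property
    def n_diseases(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_mirnas(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.matrix.sum())

    def disease_index(self, label: str) -> int:
        try:
            return self._d_index[label]
        except KeyError:
            raise KeyError(f"unknown disease label: {label!r}") from None

    def mirna_index(self, label: str) -> int:
        try:
            return self._m_index[label]
        except KeyError:
            raise KeyError(f"unknown miRNA label: {label!r}") from None

    def positive_pairs(self) -> np.ndarray:
        """(P, 2) array of (disease index, miRNA index) for every known pair."""
        return np.argwhere(self.matrix == 1)


@dataclass
class DiseaseDAG:
    """Directed acyclic ancestor graph of disease ontology terms.

    Edges point child -> parent, so the ancestor closure ``T(D)`` of a term
    is its forward reachable set (including ``D`` itself).
    """

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise FormatError(f"disease hierarchy contains a cycle: {cycle}")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def ancestors(self, node: str) -> set[str]:
        """T(D): the node itself plus every ancestor term."""
        if node not in self.graph:
            raise KeyError(f"term {node!r} not in the disease hierarchy")
        return nx.descendants(self.graph, node) | {node}

    def parents(self, node: str) -> set[str]:
        return set(self.graph.successors(node))

    def children(self, node: str) -> set[str]:
        return set(self.graph.predecessors(node))


@dataclass
class RankedPredictions:
    """Ranked candidate miRNAs for one disease, strongest first."""

    disease: str
    rows: list[tuple[str, float]]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.rows]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValueError("prediction scores must be non-increasing")


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n").rstrip("\r")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            yield lineno, stripped


def read_associations(
    path: str | Path,
    *,
    header: bool = False,
    normalize_case: bool = False,
) -> AssociationMatrix:
    """Read a two-column (disease, miRNA) TSV into an adjacency matrix.

    Duplicate pairs collapse to a single 1.  Label order along each axis is
    first-appearance order.  Labels are stripped of surrounding whitespace;
    ``normalize_case`` additionally lowercases them (off by default: ontology
    names are case-sensitive in practice).
    """
    diseases: list[str] = []
    mirnas: list[str] = []
    d_idx: dict[str, int] = {}
    m_idx: dict[str, int] = {}
    pairs: list[tuple[int, int]] = []
    first = header
    any_line = False
    for lineno, line in _data_lines(path):
        if first:
            first = False
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(
                f"{path}: line {lineno}: expected >=2 tab-separated columns, got {len(fields)}"
            )
        d = _clean_label(fields[0], normalize_case)
        m = _clean_label(fields[1], normalize_case)
        if not d or not m:
            raise FormatError(f"{path}: line {lineno}: empty label")
        if d not in d_idx:
            d_idx[d] = len(diseases)
            diseases.append(d)
        if m not in m_idx:
            m_idx[m] = len(mirnas)
            mirnas.append(m)
        pairs.append((d_idx[d], m_idx[m]))
        any_line = True
    if not any_line:
        raise FormatError(f"{path}: no association records found")
    A = np.zeros((len(diseases), len(mirnas)), dtype=np.int8)
    rows, cols = zip(*pairs)
    A[rows, cols] = 1
    return AssociationMatrix(A, diseases, mirnas)


def read_similarity_matrix(
    path: str | Path,
    *,
    normalize_case: bool = False,
    tol: float = 1e-8,
) -> "pd.DataFrame":
    """Read a labelled square similarity TSV into a label-indexed DataFrame.

    The first row and first column carry labels.  Row and column label sets
    must agree; asymmetry beyond ``tol`` is an error; values slightly outside
    [0, 1] (within ``tol``) are clipped, larger excursions are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.empty:
        raise FormatError(f"{path}: empty similarity matrix")
    df.index = [_clean_label(str(x), normalize_case) for x in df.index]
    df.columns = [_clean_label(str(x), normalize_case) for x in df.columns]
    if list(df.index) != list(df.columns):
        rows_only = [x for x in df.index if x not in set(df.columns)]
        cols_only = [x for x in df.columns if x not in set(df.index)]
        if rows_only or cols_only:
            raise FormatError(
                f"{path}: row/column labels differ "
                f"(rows only: {rows_only[:5]}, columns only: {cols_only[:5]})"
            )
        df = df.loc[:, list(df.index)]  # same set, different order
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise FormatError(f"{path}: non-finite similarity values")
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym > tol:
        i, j = np.unravel_index(np.abs(values - values.T).argmax(), values.shape)
        raise FormatError(
            f"{path}: matrix not symmetric: ({df.index[i]},{df.index[j]}) "
            f"differs from its transpose by {asym:.3g}"
        )
    if values.min() < -tol or values.max() > 1 + tol:
        raise FormatError(
            f"{path}: similarity values outside [0,1]: "
            f"range [{values.min():.6g}, {values.max():.6g}]"
        )
    values = np.clip(values, 0.0, 1.0)
    values = (values + values.T) / 2.0
    return pd.DataFrame(values, index=df.index, columns=df.index)


def write_similarity_matrix(df: "pd.DataFrame", path: str | Path) -> None:
    """Write a labelled square similarity matrix in the TSV dialect."""
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_dag(path: str | Path, *, normalize_case: bool = False) -> DiseaseDAG:
    """Read a two-column child<TAB>parent edge list into a disease DAG.

    Self-edges and cycles are rejected.
    """
    g = nx.DiGraph()
    any_edge = False
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(
                f"{path}: line {lineno}: expected child<TAB>parent, got {len(fields)} columns"
            )
        child = _clean_label(fields[0], normalize_case)
        parent = _clean_label(fields[1], normalize_case)
        if child == parent:
            raise FormatError(f"{path}: line {lineno}: self-edge on {child!r}")
        g.add_edge(child, parent)
        any_edge = True
    if not any_edge:
        raise FormatError(f"{path}: no edges found")
    return DiseaseDAG(g)


def write_predictions(preds: RankedPredictions, path: str | Path) -> None:
    """Write a ranked-prediction table: rank, mirna, score (6 sig. digits)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tmirna\tscore\n")
        for rank, (mirna, score) in enumerate(preds.rows, start=1):
            fh.write(f"{rank}\t{mirna}\t{score:.6g}\n")


def align_similarity(
    df: "pd.DataFrame", labels: Sequence[str], *, what: str = "similarity"
) -> np.ndarray:
    """Re-index a labelled similarity matrix to a target label order.

    Labels absent from the matrix get zero off-diagonal similarity and a
    unit diagonal (no information: kernel-only fallback downstream).
    """
    missing = [lab for lab in labels if lab not in df.index]
    n = len(labels)
    out = np.zeros((n, n), dtype=float)
    present = [lab for lab in labels if lab in df.index]
    if present:
        sub = df.loc[present, present].to_numpy(dtype=float)
        pos = [i for i, lab in enumerate(labels) if lab in df.index]
        out[np.ix_(pos, pos)] = sub
    np.fill_diagonal(out, 1.0)
    if missing:
        import warnings

        warnings.warn(
            f"{len(missing)} label(s) missing from the {what} matrix "
            f"(e.g. {missing[:3]}); their rows fall back to 0",
            stacklevel=2,
        )
    return out
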