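"""Cross-validated evaluation of the predictor: global LOOCV, repeated
k-fold CV, and rank-based ROC/AUC.

The evaluation protocol holds out known associations, rescores the network
from the remaining training edges, and asks how highly each held-out pair
ranks among all pairs with no known association evidence.  Each positive is
compared against the negative pool of its own iteration (the negatives'
scores move when the training network changes), so the ROC is built on
normalised ranks: for a positive with mid-rank r among n negatives, u =
r / n, TPR(f) is the fraction of positives with u <= f, and FPR(f) = f.
The area under that step curve equals the Mann-Whitney AUC with mid-rank
tie handling.

Two similarity regimes are supported.  ``dynamic`` (default) recomputes
the Gaussian kernels, the integrated similarities, and the KNN-augmented
networks from the training matrix of every iteration or fold, so no signal
from a held-out edge can reach any stage of the scorer.  ``static``
computes everything once from the full matrix and relies on the seed-edge
removal inside the scoring index; it is cheaper and matches what several
peer models report, but lets held-out edges shape the kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .io_formats import AssociationMatrix
from .pipeline import ModelParams, nbmda_scores

__all__ = ["CVConfig", "EvalResult", "roc_auc", "run_loocv", "run_kfold"]

Scorer = Callable[[np.ndarray], np.ndarray]


@dataclass
class CVConfig:
    """Cross-validation settings."""

    mode: str = "loocv"
    folds: int = 5
    repeats: int = 100
    seed: int = 0
    similarity_mode: str = "dynamic"

    def __post_init__(self) -> None:
        if self.mode not in ("loocv", "kfold"):
            raise ValueError(f"mode must be 'loocv' or 'kfold', got {self.mode!r}")
        if self.similarity_mode not in ("dynamic", "static"):
            raise ValueError("similarity_mode must be 'dynamic' or 'static'")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class EvalResult:
    """AUC, the ROC polyline, and the settings that produced them."""

    auc: float
    roc_points: list[tuple[float, float]]
    per_repeat_aucs: list[float] = field(default_factory=list)
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "per_repeat_aucs": self.per_repeat_aucs,
            "settings": self.settings,
            "roc_points": [[float(x), float(y)] for x, y in self.roc_points],
        }


def _normalized_rank(pos_score: float, neg_scores: np.ndarray) -> float:
    """Mid-rank of one positive among its negatives, scaled to [0, 1].

    0 means the positive outranks every negative, 1 means it trails all of
    them; a tie with every negative gives exactly 0.5.
    """
    greater = np.count_nonzero(neg_scores > pos_score)
    ties = np.count_nonzero(neg_scores == pos_score)
    return (greater + 0.5 * ties) / neg_scores.size


def _rank_roc(us: np.ndarray) -> tuple[float, list[tuple[float, float]]]:
    """ROC step curve and its exact area from normalised ranks."""
    us = np.asarray(us, dtype=float)
    n = us.size
    auc = float(1.0 - us.mean())
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    passed = 0
    for u in np.unique(us):
        frac_before = passed / n
        passed += int(np.count_nonzero(us == u))
        if (u, frac_before) != points[-1]:
            points.append((float(u), frac_before))
        points.append((float(u), passed / n))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return auc, points


def roc_auc(pos_scores, neg_scores) -> EvalResult:
    """Mann-Whitney AUC with mid-rank ties, plus the ROC threshold sweep.

    The rank-sum AUC and the trapezoidal area under the swept ROC curve are
    the same number; both are computed and cross-checked here.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    auc = (r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, _ = roc_curve(y, np.concatenate([pos, neg]), drop_intermediate=False)
    trap = float(np.trapezoid(tpr, fpr))
    if abs(trap - auc) > 1e-9:
        raise AssertionError(f"rank-sum AUC {auc} != trapezoidal area {trap}")
    return EvalResult(auc=float(auc), roc_points=list(zip(fpr.tolist(), tpr.tolist())))


def _make_scorer(params: ModelParams, fs: np.ndarray, ss: np.ndarray) -> Scorer:
    return lambda A_train: nbmda_scores(A_train, fs, ss, params)


def run_loocv(
    A: AssociationMatrix,
    fs: np.ndarray | None = None,
    ss: np.ndarray | None = None,
    params: ModelParams | None = None,
    cfg: CVConfig | None = None,
    scorer: Scorer | None = None,
) -> EvalResult:
    """Global leave-one-out cross validation.

    Each known association in turn is zeroed in a copy of the adjacency
    matrix; the scorer sees only that training copy.  The held-out pair's
    score is ranked against the scores of every pair unknown in the *full*
    data, recomputed in the same iteration.  ``scorer`` overrides the
    default full pipeline (used for harness calibration with stub scorers).
    """
    params = params or ModelParams()
    cfg = cfg or CVConfig(mode="loocv")
    Afull = A.matrix.astype(np.int8)
    positives = np.argwhere(Afull == 1)
    if len(positives) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")
    if scorer is None:
        scorer = _make_scorer(params, fs, ss)
    neg_mask = Afull == 0

    if cfg.similarity_mode == "static":
        S = scorer(Afull.copy())
        neg = S[neg_mask]
        us = np.array([_normalized_rank(S[i, j], neg) for i, j in positives])
    else:
        us = np.empty(len(positives))
        for t, (i, j) in enumerate(positives):
            A_train = Afull.copy()
            A_train[i, j] = 0
            S = scorer(A_train)
            us[t] = _normalized_rank(S[i, j], S[neg_mask])
    auc, points = _rank_roc(us)
    return EvalResult(
        auc=auc,
        roc_points=points,
        settings={"cv": asdict(cfg), "model": asdict(params)},
    )


def _fold_assignments(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Shuffle 0..n-1 into ``folds`` near-equal disjoint groups."""
    order = rng.permutation(n)
    assign = np.empty(n, dtype=np.intp)
    for f, chunk in enumerate(np.array_split(order, folds)):
        assign[chunk] = f
    return assign


def run_kfold(
    A: AssociationMatrix,
    fs: np.ndarray | None = None,
    ss: np.ndarray | None = None,
    params: ModelParams | None = None,
    cfg: CVConfig | None = None,
    scorer: Scorer | None = None,
) -> EvalResult:
    """Repeated k-fold cross validation over the known associations.

    Per repeat r (random stream seeded ``seed + r``) the positives are
    shuffled into ``folds`` disjoint subsets; each fold's edges are zeroed
    in the training matrix, the scorer is rerun, and the fold's positives
    are ranked against that run's unknown-pair scores.  The per-repeat AUC
    pools all folds; the headline AUC is the mean over repeats.
    """
    params = params or ModelParams()
    cfg = cfg or CVConfig(mode="kfold")
    Afull = A.matrix.astype(np.int8)
    positives = np.argwhere(Afull == 1)
    n_pos = len(positives)
    if n_pos < cfg.folds:
        raise ValueError(f"need at least {cfg.folds} positives for {cfg.folds}-fold CV")
    if scorer is None:
        scorer = _make_scorer(params, fs, ss)
    neg_mask = Afull == 0

    static_S = scorer(Afull.copy()) if cfg.similarity_mode == "static" else None
    per_repeat: list[float] = []
    all_us: list[np.ndarray] = []
    for r in range(cfg.repeats):
        rng = np.random.default_rng(cfg.seed + r)
        assign = _fold_assignments(n_pos, cfg.folds, rng)
        us = np.empty(n_pos)
        for f in range(cfg.folds):
            test_idx = np.flatnonzero(assign == f)
            if cfg.similarity_mode == "static":
                S = static_S
            else:
                A_train = Afull.copy()
                A_train[positives[test_idx, 0], positives[test_idx, 1]] = 0
                S = scorer(A_train)
            neg = S[neg_mask]
            for t in test_idx:
                i, j = positives[t]
                us[t] = _normalized_rank(S[i, j], neg)
        per_repeat.append(float(1.0 - us.mean()))
        all_us.append(us)
    auc, points = _rank_roc(np.concatenate(all_us))
    return EvalResult(
        auc=float(np.mean(per_repeat)),
        roc_points=points,
        per_repeat_aucs=per_repeat,
        settings={"cv": asdict(cfg), "model": asdict(params)},
    )
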