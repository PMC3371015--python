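"""Multi-label evaluation metrics.

Six metrics standard in multi-site subcellular-localization work: three
ranking metrics (average precision, coverage, ranking loss) computed
from the per-label scores, and three set metrics (recall, precision /
F1, absolute true success rate) computed from the decided label sets.
Absolute true — exact equality of predicted and true sets — is the
strictest of them.

Conventions (documented because the literature is not uniform):

* Ranks are 1-based, rank 1 = highest score; ties are broken by lowest
  label index (stable).
* Ranking loss counts a tied (true, false) score pair as misordered
  (the pair is "not correctly ordered").
* F1 is computed from the sample-averaged precision and recall
  (macro-over-samples); per-sample F1 averaging is available as an
  option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _as_bool_Y(Y: np.ndarray) -> np.ndarray:
    """Accept {-1,+1} or boolean/0-1 label matrices."""
    Y = np.asarray(Y)
    if Y.dtype == bool:
        return Y
    return Y > 0


def _ranks(scores_row: np.ndarray) -> np.ndarray:
    """1-based rank of every label, descending score, ties by label index."""
    order = np.lexsort((np.arange(scores_row.size), -scores_row))
    ranks = np.empty(scores_row.size, dtype=int)
    ranks[order] = np.arange(1, scores_row.size + 1)
    return ranks


def average_precision(Y: np.ndarray, scores: np.ndarray) -> float:
    """Mean over samples of the average fraction of true labels ranked
    at or above each true label's rank."""
    Yb = _as_bool_Y(Y)
    scores = np.asarray(scores, dtype=float)
    vals = []
    for yi, si in zip(Yb, scores):
        true_idx = np.flatnonzero(yi)
        if true_idx.size == 0:
            raise ValueError("average_precision: sample with empty true-label set")
        r = _ranks(si)
        true_ranks = r[true_idx]
        frac = [
            np.sum(true_ranks <= rk) / rk for rk in true_ranks
        ]
        vals.append(np.mean(frac))
    return float(np.mean(vals))


def coverage(Y: np.ndarray, scores: np.ndarray) -> float:
    """Mean over samples of (worst rank among true labels) - 1: how far
    down the ranked list one must go to cover every true label."""
    Yb = _as_bool_Y(Y)
    scores = np.asarray(scores, dtype=float)
    vals = []
    for yi, si in zip(Yb, scores):
        true_idx = np.flatnonzero(yi)
        if true_idx.size == 0:
            raise ValueError("coverage: sample with empty true-label set")
        vals.append(_ranks(si)[true_idx].max() - 1)
    return float(np.mean(vals))


def ranking_loss(Y: np.ndarray, scores: np.ndarray) -> float:
    """Mean fraction of (true, false) label pairs that are not ordered
    true-above-false; ties count as misordered.

    Samples whose true set is all labels (empty complement) are skipped
    — their pair denominator is zero.
    """
    Yb = _as_bool_Y(Y)
    scores = np.asarray(scores, dtype=float)
    vals = []
    for yi, si in zip(Yb, scores):
        pos = np.flatnonzero(yi)
        neg = np.flatnonzero(~yi)
        if pos.size == 0:
            raise ValueError("ranking_loss: sample with empty true-label set")
        if neg.size == 0:
            continue
        bad = np.sum(si[pos][:, None] <= si[neg][None, :])
        vals.append(bad / (pos.size * neg.size))
    if not vals:
        raise ValueError("ranking_loss: no sample with a nonempty label complement")
    return float(np.mean(vals))


def set_metrics(
    Y: np.ndarray,
    predicted: np.ndarray,
    f1_mode: str = "macro",
) -> dict[str, float]:
    """Recall, precision, F1 and absolute-true rate of decided label sets.

    recall  = mean_i |Y_i ∩ Yhat_i| / |Y_i|
    precision = mean_i |Y_i ∩ Yhat_i| / |Yhat_i|
    f1 ("macro") = 2 P R / (P + R) on the averaged P, R; "samples"
    instead averages the per-sample F1.
    absolute_true = fraction of samples with Yhat_i == Y_i exactly.
    """
    Yb = _as_bool_Y(Y)
    Pb = _as_bool_Y(predicted)
    if Yb.shape != Pb.shape:
        raise ValueError("label and prediction matrices differ in shape")
    rec, prec, f1s, exact = [], [], [], []
    for yi, pi in zip(Yb, Pb):
        n_true = int(yi.sum())
        n_pred = int(pi.sum())
        if n_true == 0:
            raise ValueError("set_metrics: sample with empty true-label set")
        if n_pred == 0:
            raise ValueError("set_metrics: empty predicted set (decide guarantees >=1)")
        inter = int((yi & pi).sum())
        rec.append(inter / n_true)
        prec.append(inter / n_pred)
        f1s.append(2 * inter / (n_true + n_pred))
        exact.append(float(np.array_equal(yi, pi)))
    R = float(np.mean(rec))
    P = float(np.mean(prec))
    if f1_mode == "macro":
        f1 = 0.0 if P + R == 0 else 2 * P * R / (P + R)
    elif f1_mode == "samples":
        f1 = float(np.mean(f1s))
    else:
        raise ValueError(f"unknown f1_mode {f1_mode!r}")
    return {
        "recall": R,
        "precision": P,
        "f1": f1,
        "absolute_true": float(np.mean(exact)),
    }


@dataclass
class EvaluationReport:
    """All six metrics over a sample subset."""

    average_precision: float
    coverage: float
    ranking_loss: float
    recall: float
    precision: float
    f1: float
    absolute_true: float
    n_samples: int
    subset: str = "all"

    def as_dict(self) -> dict[str, float]:
        return {
            "average_precision": self.average_precision,
            "coverage": self.coverage,
            "ranking_loss": self.ranking_loss,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "absolute_true": self.absolute_true,
        }


def evaluate_all(
    Y: np.ndarray,
    scores: np.ndarray,
    predicted: np.ndarray,
    subset: str = "all",
    f1_mode: str = "macro",
) -> EvaluationReport:
    """Bundle the ranking and set metrics into one report."""
    sm = set_metrics(Y, predicted, f1_mode=f1_mode)
    return EvaluationReport(
        average_precision=average_precision(Y, scores),
        coverage=coverage(Y, scores),
        ranking_loss=ranking_loss(Y, scores),
        n_samples=int(np.asarray(Y).shape[0]),
        subset=subset,
        **sm,
    )
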