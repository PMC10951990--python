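"""Classification metrics and the partial-ROC statistic AUCn.

AUCn asks: of the n top-ranked negatives, what fraction of the positives
outranks each of them, on average? It rewards rankings that push known
cancer genes above the most score-inflated non-cancer genes, which is the
regime that matters for prioritization (standard AUROC averages over all
negatives, most of which are trivially ranked low).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)

from .core_io import LabelSet


@dataclass(frozen=True)
class EvalReport:
    accuracy: float
    auroc: float
    auprc: float
    f1: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auroc": self.auroc,
            "auprc": self.auprc,
            "f1": self.f1,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


@dataclass
class RankedGeneList:
    """Genes ordered by (score desc, gene ID asc) with per-gene labels.

    The tie-break by gene ID makes the ranking strict and deterministic,
    which AUCn assumes.
    """

    genes: tuple[str, ...]
    scores: tuple[float, ...]
    labels: tuple[str, ...]  # "positive" | "negative" | "unlabeled"

    @classmethod
    def from_scores(cls, scores: pd.Series, labels: LabelSet) -> "RankedGeneList":
        order = sorted(scores.index, key=lambda g: (-scores[g], g))
        labs = tuple(
            "positive" if g in labels.positives
            else "negative" if g in labels.negatives
            else "unlabeled"
            for g in order
        )
        return cls(tuple(order), tuple(float(scores[g]) for g in order), labs)


def binary_metrics(scores: pd.Series, labels: LabelSet, threshold: float = 0.5
                   ) -> EvalReport:
    """Accuracy/F1 at ``threshold``; AUROC and AUPRC threshold-free.

    Only labeled genes that actually carry a score are evaluated.
    """
    genes = [g for g in scores.index if g in labels.positives or g in labels.negatives]
    y = np.array([1 if g in labels.positives else 0 for g in genes])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present among scored genes")
    p = scores.loc[genes].to_numpy(dtype=float)
    yhat = (p > threshold).astype(int)
    return EvalReport(
        accuracy=float(accuracy_score(y, yhat)),
        auroc=float(roc_auc_score(y, p)),
        auprc=float(average_precision_score(y, p)),
        f1=float(f1_score(y, yhat, zero_division=0)),
        n_pos=int(y.sum()),
        n_neg=int((1 - y).sum()),
    )


def auc_n(ranked: RankedGeneList, n: int) -> float:
    """Partial ROC: AUCn = (1/(nT)) Σ_{i=1..n} T_i.

    T is the total number of positives and T_i the number of positives
    ranked strictly above the i-th highest-ranked negative. Unlabeled
    genes are dropped before ranking.
    """
    labeled = [(g, lab) for g, lab in zip(ranked.genes, ranked.labels) if lab != "unlabeled"]
    total_pos = sum(1 for _, lab in labeled if lab == "positive")
    total_neg = sum(1 for _, lab in labeled if lab == "negative")
    if total_pos == 0:
        raise ValueError("no positives in ranked list")
    if total_neg < n:
        raise ValueError(f"ranked list has {total_neg} negatives, need at least n={n}")
    acc = 0.0
    pos_above = 0
    negs_seen = 0
    for _, lab in labeled:
        if lab == "positive":
            pos_above += 1
        else:
            negs_seen += 1
            acc += pos_above
            if negs_seen == n:
                break
    return acc / (n * total_pos)


def aucn_curve(ranked: RankedGeneList, ns) -> dict[int, float]:
    return {int(n): auc_n(ranked, int(n)) for n in ns}
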