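"""Risk-group derivation: ROC cut-off optimization and two-cluster grouping.

Scores are positively oriented (higher score = higher suspicion of the
event); a sample is called positive when its score is at or above the
threshold. The ROC enumeration places one threshold at the midpoint
between every pair of adjacent distinct scores, plus -inf / +inf
sentinels, so each achievable confusion table appears exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression_io import SignatureGeneList, resolve_symbols
from .signatures import RiskAssignment


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not (len(self.thresholds) == len(self.sensitivity) == len(self.specificity)):
            raise ValueError("ROC arrays must align")


def roc_curve(scores, outcome) -> RocCurve:
    """Full ROC curve of a score against a binary outcome.

    Thresholds are midpoints between adjacent distinct scores plus
    sentinels; sensitivity = P(score >= thr | event),
    specificity = P(score < thr | no event); AUC by the trapezoid rule.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if outcome.min() == outcome.max():
        raise ValueError("both outcome classes must be present")
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    pos, neg = outcome == 1, outcome == 0
    sens = np.array([(scores[pos] >= t).mean() for t in thresholds])
    spec = np.array([(scores[neg] < t).mean() for t in thresholds])
    # thresholds ascend, so reversing makes FPR and TPR jointly ascend,
    # tracing the ROC staircase for the trapezoid rule
    fpr, tpr = (1.0 - spec)[::-1], sens[::-1]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


def optimal_cutoff(roc: RocCurve) -> float:
    """Threshold closest (Euclidean) to the ideal ROC corner (FPR 0, TPR 1).

    Ties are broken toward higher specificity, then toward the lower
    threshold. Youden's J is available via :func:`youden_cutoff`.
    """
    d2 = (1.0 - roc.specificity) ** 2 + (1.0 - roc.sensitivity) ** 2
    order = np.lexsort((roc.thresholds, -roc.specificity, d2))
    return float(roc.thresholds[order[0]])


def youden_cutoff(roc: RocCurve) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1."""
    j = roc.sensitivity + roc.specificity - 1.0
    order = np.lexsort((roc.thresholds, -roc.specificity, -j))
    return float(roc.thresholds[order[0]])


def second_cutoff_high_sensitivity(roc: RocCurve, min_sensitivity: float = 0.9) -> float:
    """Best threshold within the highly sensitive part of the curve.

    Among thresholds with sensitivity >= ``min_sensitivity`` returns the
    one maximizing specificity (ties toward the lower threshold); this is
    the low/medium boundary when three risk groups are formed.
    """
    ok = roc.sensitivity >= min_sensitivity
    if not ok.any():
        raise ValueError(
            f"no threshold attains sensitivity >= {min_sensitivity}; lower the bound"
        )
    thr, spec = roc.thresholds[ok], roc.specificity[ok]
    order = np.lexsort((thr, -spec))
    return float(thr[order[0]])


def assign_three_groups(scores: pd.Series, cut_low: float, cut_high: float) -> RiskAssignment:
    """Low / medium / high risk groups from two cut-offs.

    score < cut_low -> low; cut_low <= score < cut_high -> medium;
    score >= cut_high -> high.
    """
    if cut_low > cut_high:
        raise ValueError(f"cut_low {cut_low} exceeds cut_high {cut_high}")
    scores = pd.Series(scores)
    arr = scores.to_numpy(dtype=float)
    label = np.select([arr < cut_low, arr < cut_high], ["low", "medium"], default="high")
    return RiskAssignment(
        sample_ids=list(scores.index),
        score=scores,
        label=pd.Series(label, index=scores.index),
        classifier="three_group_cutoffs",
    )


def correlation_distance(matrix: pd.DataFrame, method: str = "pearson") -> np.ndarray:
    """Condensed 1 - correlation distance between samples (columns)."""
    corr = matrix.corr(method=method).to_numpy()
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return squareform(dist, checks=False)


def two_cluster_risk(
    matrix: pd.DataFrame,
    genes: SignatureGeneList,
    correlation: str = "pearson",
    event_labels=None,
    linkage: str = "average",
) -> RiskAssignment:
    """Two main clusters of samples on signature genes, labelled by risk.

    Agglomerative clustering with 1 - correlation distance (average
    linkage by default, matching the dChip convention); the tree is cut
    into two clusters and the cluster with the higher observed event
    proportion is labelled ``bad`` (high risk). With no event labels the
    clusters are labelled by mean signature expression instead.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    sub = matrix.loc[resolve_symbols(matrix, genes.symbols)]
    values = sub.to_numpy()
    if np.all(values == values[:, [0]]):
        raise ValueError("all samples identical on signature genes; no resolvable clusters")
    condensed = correlation_distance(sub, correlation)
    tree = hierarchy.linkage(condensed, method=linkage)
    assignment = hierarchy.fcluster(tree, t=2, criterion="maxclust")
    if event_labels is not None:
        ev = np.asarray(pd.Series(event_labels, index=matrix.columns), dtype=float)
        rate1 = ev[assignment == 1].mean()
        rate2 = ev[assignment == 2].mean()
        bad_cluster = 1 if rate1 > rate2 else 2
    else:
        mean1 = sub.loc[:, assignment == 1].to_numpy().mean()
        mean2 = sub.loc[:, assignment == 2].to_numpy().mean()
        bad_cluster = 1 if mean1 > mean2 else 2
    label = np.where(assignment == bad_cluster, "bad", "good")
    return RiskAssignment(
        sample_ids=list(matrix.columns),
        score=pd.Series(assignment.astype(float), index=matrix.columns),
        label=pd.Series(label, index=matrix.columns),
        classifier=f"two_cluster_{correlation}_{linkage}",
    )
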