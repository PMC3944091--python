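"""Supervised per-gene selection and leave-one-out cross-validated classification.

Per-gene association with metastasis status uses a classical two-group
one-way ANOVA (equivalent to the square of the pooled-variance t
statistic), which is sign-agnostic and therefore captures genes with
opposing expression profiles. Selection keeps genes with p <= alpha with
no multiplicity correction. Cross-validation leaves one sample out and
reselects genes within every fold, so the left-out sample never
influences its own gene list; prediction uses the centroid-correlation
rule consistent with the AGPP classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import SignatureGeneList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneTestResult:
    gene_id: str
    f_statistic: float
    p_value: float


@dataclass
class CvResult:
    """Leave-one-out confusion counts and derived metrics.

    Confusion orientation: the event (metastasis) class is positive.
    ``fold_gene_lists`` maps each left-out sample to the genes selected
    on the remaining samples.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    fold_gene_lists: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def anova_per_gene(matrix: pd.DataFrame, groups) -> list[GeneTestResult]:
    """Two-group one-way ANOVA F and p for every gene (vectorized).

    ``groups`` is a binary per-sample vector aligned with the matrix
    columns. F equals the square of the equal-variance t statistic; the
    p-value is the F(1, n-2) upper tail.
    """
    g = np.asarray(pd.Series(groups, index=matrix.columns), dtype=int)
    x = matrix.to_numpy(dtype=float)
    n0, n1 = int((g == 0).sum()), int((g == 1).sum())
    if n0 < 2 or n1 < 2:
        raise ValueError("need at least 2 samples in each group")
    x0, x1 = x[:, g == 0], x[:, g == 1]
    m0, m1 = x0.mean(axis=1), x1.mean(axis=1)
    ss_within = ((x0 - m0[:, None]) ** 2).sum(axis=1) + ((x1 - m1[:, None]) ** 2).sum(axis=1)
    if np.any(ss_within == 0):
        bad = matrix.index[ss_within == 0].tolist()
        raise ValueError(f"zero within-group variance for genes {bad[:10]}")
    df_within = n0 + n1 - 2
    grand = x.mean(axis=1)
    ss_between = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2
    f = ss_between / (ss_within / df_within)
    p = stats.f.sf(f, 1, df_within)
    return [
        GeneTestResult(gene_id=gid, f_statistic=float(fv), p_value=float(pv))
        for gid, fv, pv in zip(matrix.index, f, p)
    ]


def select_genes(results: list[GeneTestResult], alpha: float = 0.01) -> SignatureGeneList:
    """Genes with p <= alpha, ordered by ascending p (no multiplicity correction)."""
    hits = sorted(
        (r for r in results if r.p_value <= alpha),
        key=lambda r: (r.p_value, r.gene_id),
    )
    return SignatureGeneList.from_symbols("selected", [r.gene_id for r in hits])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant vectors")
    return float(np.corrcoef(x, y)[0, 1])


def nearest_centroid_predict(
    train_matrix: pd.DataFrame,
    train_labels,
    test_sample: pd.Series,
    correlation: str = "pearson",
) -> int:
    """Predict 0/1 by correlation of the test sample with the class centroids.

    Ties predict 0 (no metastasis).
    """
    if correlation != "pearson":
        raise ValueError("only pearson correlation is supported")
    labels = np.asarray(pd.Series(train_labels, index=train_matrix.columns), dtype=int)
    if (labels == 0).sum() == 0 or (labels == 1).sum() == 0:
        raise ValueError("both classes must be present in training data")
    x = test_sample.loc[train_matrix.index].to_numpy(dtype=float)
    c0 = train_matrix.loc[:, labels == 0].mean(axis=1).to_numpy()
    c1 = train_matrix.loc[:, labels == 1].mean(axis=1).to_numpy()
    r0, r1 = _pearson(x, c0), _pearson(x, c1)
    return int(r1 > r0)


def loocv_with_reselection(
    matrix: pd.DataFrame,
    event_labels,
    alpha: float = 0.01,
) -> CvResult:
    """Leave-one-out cross-validation with per-fold gene reselection.

    For each left-out sample the per-gene ANOVA and the p <= alpha
    selection are recomputed on the remaining samples; the sample is then
    classified by centroid correlation over the fold's genes. Folds whose
    selection comes back with fewer than two genes (correlation needs at
    least two) fall back to the training-majority class (logged), so
    confusion counts always sum to n.
    """
    labels = pd.Series(event_labels, index=matrix.columns).astype(int)
    n = matrix.shape[1]
    if n < 4 or labels.nunique() < 2:
        raise ValueError("need n >= 4 with both classes represented")
    tp = tn = fp = fn = 0
    fold_gene_lists: dict = {}
    for sample in matrix.columns:
        train_cols = [c for c in matrix.columns if c != sample]
        train = matrix[train_cols]
        train_y = labels[train_cols]
        if train_y.nunique() < 2:
            raise ValueError(f"fold leaving out {sample!r} loses a class entirely")
        results = anova_per_gene(train, train_y)
        selected = select_genes(results, alpha=alpha)
        fold_gene_lists[sample] = selected.symbols
        if len(selected) < 2:
            # correlation over <2 genes is undefined; degenerate folds fall
            # back to the training-majority class so counts still sum to n
            logger.info("fold %s: %d genes selected, predicting majority class",
                        sample, len(selected))
            pred = int(train_y.mean() > 0.5)
        else:
            pred = nearest_centroid_predict(
                train.loc[selected.symbols], train_y, matrix.loc[selected.symbols, sample]
            )
        truth = int(labels[sample])
        if truth == 1 and pred == 1:
            tp += 1
        elif truth == 0 and pred == 0:
            tn += 1
        elif truth == 0 and pred == 1:
            fp += 1
        else:
            fn += 1
    return CvResult(tp=tp, tn=tn, fp=fp, fn=fn, fold_gene_lists=fold_gene_lists)
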