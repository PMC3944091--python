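"""Recurrence-score and nearest-centroid (AGPP) signature classification.

The 21-gene recurrence-score algorithm combines 16 cancer-related genes
into four group scores plus three single-gene terms:

    GRB7 group          0.9*GRB7 + 0.1*ERBB2
    ER group            (0.8*ESR1 + 1.2*PGR + BCL2 + SCUBE2) / 4
    proliferation group mean(BIRC5, MKI67, MYBL2, CCNB1, AURKA)
    invasion group      (CTSL2 + MMP11) / 2

    RS_u = 0.47*GRB7g - 0.34*ERg + 1.04*PROLIFg + 0.10*INVg
           + 0.05*CD68 - 0.08*GSTM1 - 0.07*BAG1

On the original qPCR reference-normalized scale the GRB7 group is floored
at 8 and the proliferation group at 6.5 before combining, and RS_u is
rescaled to 0-100. Applied to per-gene z-scored microarray data only the
ordering of RS_u matters (risk groups come from ROC cut-offs downstream),
so the floors and rescale are off by default and available as options.

The AGPP ("average gene-expression profile of patients") classifier
computes, over a signature's genes, the mean expression profile of
training patients with and without distant metastasis and assigns each
sample to the class whose centroid it correlates with more strongly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import SignatureGeneList, resolve_symbols

# 16 target genes with their group roles (plus the 5 reference genes of the
# original assay, which play no role in the score and are omitted here).
ONCOTYPE_TARGET_GENES: tuple[tuple[str, str], ...] = (
    ("GRB7", "grb7"),
    ("ERBB2", "grb7"),
    ("ESR1", "er"),
    ("PGR", "er"),
    ("BCL2", "er"),
    ("SCUBE2", "er"),
    ("BIRC5", "proliferation"),
    ("MKI67", "proliferation"),
    ("MYBL2", "proliferation"),
    ("CCNB1", "proliferation"),
    ("AURKA", "proliferation"),
    ("CTSL2", "invasion"),
    ("MMP11", "invasion"),
    ("CD68", "single"),
    ("GSTM1", "single"),
    ("BAG1", "single"),
)

_GROUP_WEIGHTS = {
    "grb7": 0.47,
    "er": -0.34,
    "proliferation": 1.04,
    "invasion": 0.10,
    "cd68": 0.05,
    "gstm1": -0.08,
    "bag1": -0.07,
}


@dataclass(frozen=True)
class OncotypeGroupScores:
    grb7_group: float
    er_group: float
    proliferation_group: float
    invasion_group: float
    cd68: float
    gstm1: float
    bag1: float


@dataclass
class AgppCentroids:
    """Per-class mean expression profiles over the signature genes."""

    centroid_no_metastasis: pd.Series
    centroid_metastasis: pd.Series

    def __post_init__(self) -> None:
        if not self.centroid_no_metastasis.index.equals(self.centroid_metastasis.index):
            raise ValueError("centroids must be indexed on the same genes")

    @property
    def gene_ids(self) -> list:
        return list(self.centroid_no_metastasis.index)


@dataclass
class RiskAssignment:
    """Per-sample categorical risk label plus the continuous score behind it."""

    sample_ids: list
    score: pd.Series
    label: pd.Series
    classifier: str = ""

    def __post_init__(self) -> None:
        if not (len(self.sample_ids) == len(self.score) == len(self.label)):
            raise ValueError("sample_ids, score and label must align")


def _gene(sample_expr: pd.Series, symbol: str) -> float:
    lookup = {str(g).upper(): g for g in sample_expr.index}
    key = symbol.upper()
    if key not in lookup:
        raise KeyError(f"required gene {symbol!r} missing from sample expression")
    return float(sample_expr[lookup[key]])


def oncotype_group_scores(
    sample_expr: pd.Series,
    gene_roles: SignatureGeneList | None = None,
    *,
    apply_floors: bool = False,
) -> OncotypeGroupScores:
    """Compute the four group scores and three single-gene terms for one sample.

    ``sample_expr`` is a gene-indexed vector (standardized expression).
    ``gene_roles`` may remap symbols (entry role = group name); by default
    the canonical 16-gene assignment is used. ``apply_floors`` enables the
    qPCR-scale floors (GRB7 group >= 8, proliferation group >= 6.5).
    """
    roles = dict(gene_roles.entries) if gene_roles is not None else dict(ONCOTYPE_TARGET_GENES)
    by_role: dict[str, dict[str, float]] = {}
    for symbol, role in roles.items():
        by_role.setdefault(role, {})[symbol.upper()] = _gene(sample_expr, symbol)

    g = by_role["grb7"]
    grb7_group = 0.9 * g["GRB7"] + 0.1 * g["ERBB2"]
    e = by_role["er"]
    er_group = (0.8 * e["ESR1"] + 1.2 * e["PGR"] + e["BCL2"] + e["SCUBE2"]) / 4.0
    proliferation_group = float(np.mean(list(by_role["proliferation"].values())))
    inv = by_role["invasion"]
    invasion_group = (inv["CTSL2"] + inv["MMP11"]) / 2.0
    singles = by_role["single"]
    if apply_floors:
        grb7_group = max(grb7_group, 8.0)
        proliferation_group = max(proliferation_group, 6.5)
    return OncotypeGroupScores(
        grb7_group=grb7_group,
        er_group=er_group,
        proliferation_group=proliferation_group,
        invasion_group=invasion_group,
        cd68=singles["CD68"],
        gstm1=singles["GSTM1"],
        bag1=singles["BAG1"],
    )


def oncotype_rs_unscaled(groups: OncotypeGroupScores) -> float:
    """Unscaled recurrence score RS_u from the group scores."""
    return (
        _GROUP_WEIGHTS["grb7"] * groups.grb7_group
        + _GROUP_WEIGHTS["er"] * groups.er_group
        + _GROUP_WEIGHTS["proliferation"] * groups.proliferation_group
        + _GROUP_WEIGHTS["invasion"] * groups.invasion_group
        + _GROUP_WEIGHTS["cd68"] * groups.cd68
        + _GROUP_WEIGHTS["gstm1"] * groups.gstm1
        + _GROUP_WEIGHTS["bag1"] * groups.bag1
    )


def recurrence_scores(
    matrix: pd.DataFrame,
    gene_roles: SignatureGeneList | None = None,
    *,
    apply_floors: bool = False,
) -> pd.Series:
    """Unscaled recurrence score for every sample in a standardized matrix."""
    out = {}
    for sample in matrix.columns:
        groups = oncotype_group_scores(
            matrix[sample], gene_roles, apply_floors=apply_floors
        )
        out[sample] = oncotype_rs_unscaled(groups)
    return pd.Series(out, name="rs_unscaled")


def agpp_centroids(
    matrix: pd.DataFrame,
    event_labels: pd.Series | np.ndarray,
    genes: SignatureGeneList,
) -> AgppCentroids:
    """Mean expression profile of metastasis / no-metastasis patients.

    Restricted to the signature genes; requires at least one sample in
    each class.
    """
    labels = np.asarray(pd.Series(event_labels, index=matrix.columns), dtype=int)
    gene_index = resolve_symbols(matrix, genes.symbols)
    sub = matrix.loc[gene_index]
    if (labels == 0).sum() == 0 or (labels == 1).sum() == 0:
        raise ValueError("both metastasis and no-metastasis classes must be non-empty")
    return AgppCentroids(
        centroid_no_metastasis=sub.loc[:, labels == 0].mean(axis=1),
        centroid_metastasis=sub.loc[:, labels == 1].mean(axis=1),
    )


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant vectors")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def classify_agpp(
    sample_expr: pd.Series,
    centroids: AgppCentroids,
    correlation: str = "pearson",
) -> tuple[str, float, float]:
    """Assign good/bad prognosis by correlation to the two class centroids.

    Returns ``(label, r_good, r_bad)`` where ``r_good`` is the correlation
    with the no-metastasis centroid. Ties go to ``good`` (favouring the
    lower-treatment-intensity call).
    """
    x = sample_expr.loc[centroids.centroid_no_metastasis.index].to_numpy(dtype=float)
    r_good = _correlate(x, centroids.centroid_no_metastasis.to_numpy(dtype=float), correlation)
    r_bad = _correlate(x, centroids.centroid_metastasis.to_numpy(dtype=float), correlation)
    label = "bad" if r_bad > r_good else "good"
    return label, r_good, r_bad


def classify_agpp_matrix(
    matrix: pd.DataFrame,
    centroids: AgppCentroids,
    correlation: str = "pearson",
) -> RiskAssignment:
    """AGPP classification of every sample; score = r_good - r_bad."""
    labels, scores = {}, {}
    for sample in matrix.columns:
        label, r_good, r_bad = classify_agpp(matrix[sample], centroids, correlation)
        labels[sample] = label
        scores[sample] = r_good - r_bad
    return RiskAssignment(
        sample_ids=list(matrix.columns),
        score=pd.Series(scores),
        label=pd.Series(labels),
        classifier=f"agpp_{correlation}",
    )
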