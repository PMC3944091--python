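"""End-to-end analysis: cohort ingest/simulation to a per-factor survival summary report.

For each prognostic factor the pipeline forms patient groups, runs
Kaplan-Meier / log-rank comparisons and univariate Cox models, then fits
a stepwise (forward, Wald) multivariate Cox model over the univariately
significant factors. Gene-level stages compute the recurrence score with
ROC-derived three-group cut-offs, the AGPP and two-cluster MammaPrint-style
groupings, and the supervised gene selection with leave-one-out
cross-validation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression_io as eio
from . import signatures as sig
from . import stratification as strat
from . import gene_selection as gsel
from . import survival as surv
from .synthetic import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """An analysis-stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Inputs and tuning knobs for one full analysis run.

    Exactly one of (``expression_path`` + ``clinical_path``) or
    ``simulation`` must be provided.
    """

    expression_path: str | None = None
    clinical_path: str | None = None
    mammaprint_signature_path: str | None = None
    simulation: SimulationConfig | None = None
    correlation: str = "pearson"
    alpha: float = 0.01
    min_sensitivity: float = 0.9
    stepwise_direction: str = "forward"
    p_enter: float = 0.05
    univariate_p_threshold: float = 0.05
    run_loocv: bool = True
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        from_files = self.expression_path is not None and self.clinical_path is not None
        from_sim = self.simulation is not None
        if from_files == from_sim:
            raise ValueError(
                "provide exactly one of (expression_path & clinical_path) or simulation"
            )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(name, str(err)) from err

        return wrapped

    return deco


def _factor_groups(clinical: pd.DataFrame) -> list[tuple[str, pd.Series]]:
    """Clinicopathological factor dichotomizations for the survival report.

    Each entry is (factor name, ordered categorical per-sample labels);
    the first category is the reference (lower-risk) group.
    """
    c = clinical

    def need(col):
        if col not in c.columns:
            raise KeyError(f"clinical table lacks column {col!r}")
        return c[col]

    factors = [
        ("age", pd.cut(need("age"), [-np.inf, 55, np.inf], right=False, labels=["<55", ">=55"])),
        (
            "tumour_diameter",
            pd.cut(need("tumour_diameter"), [-np.inf, 2, np.inf], right=False, labels=["<2cm", ">=2cm"]),
        ),
        (
            "grade",
            pd.Series(np.where(need("grade") == 1, "1", "2-3"), index=c.index).astype("category"),
        ),
        ("er", need("er_status").map({1: "positive", 0: "negative"}).astype("category")),
        ("pr", need("pr_status").map({1: "positive", 0: "negative"}).astype("category")),
        ("her2", need("her2_status").map({0: "0-1+", 1: "2+-3+"}).astype("category")),
        ("mai10", pd.cut(need("mai"), [-np.inf, 10, np.inf], right=False, labels=["<10", ">=10"])),
        (
            "mai3",
            pd.cut(need("mai"), [-np.inf, 3, 10, np.inf], right=False, labels=["0-2", "3-9", ">=10"]),
        ),
        ("ki67", pd.cut(need("ki67"), [-np.inf, 10, np.inf], right=False, labels=["0-9%", "10-100%"])),
        ("pph3", pd.cut(need("pph3"), [-np.inf, 13, np.inf], right=False, labels=["<13", ">=13"])),
        ("ck56", need("ck56_status").map({0: "negative", 1: "positive"}).astype("category")),
        ("tnp", need("tnp_status").map({0: "non-tnp", 1: "tnp"}).astype("category")),
    ]
    return factors


def _factor_report_rows(
    name: str,
    groups: pd.Series,
    records: pd.DataFrame,
) -> tuple[list[dict], float, pd.DataFrame]:
    """KM/log-rank/univariate-Cox summary rows for one factor."""
    groups = pd.Series(groups, index=records.index)
    levels = [l for l in groups.cat.categories if (groups == l).any()] if hasattr(
        groups, "cat"
    ) else sorted(groups.dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"factor {name!r} has fewer than two populated groups")
    group_records = [records.loc[groups == l] for l in levels]
    chi2, p = surv.logrank_test(group_records)
    # univariate Cox with dummy indicators against the first (reference) level
    dummies = pd.DataFrame(
        {f"{name}:{l}": (groups == l).astype(float) for l in levels[1:]}, index=records.index
    )
    try:
        cox = surv.cox_fit(dummies, records)
        hr = {l: float(cox.hr[f"{name}:{l}"]) for l in levels[1:]}
        ci = {
            l: (
                float(cox.ci95.loc[f"{name}:{l}", "lower"]),
                float(cox.ci95.loc[f"{name}:{l}", "upper"]),
            )
            for l in levels[1:]
        }
    except (surv.CoxConvergenceError, ValueError) as err:
        logger.warning("univariate Cox failed for %s: %s", name, err)
        hr, ci = {}, {}
    rows = []
    for level, rec in zip(levels, group_records):
        events = int(rec["event"].sum())
        at_risk = int(len(rec))
        rows.append(
            {
                "factor": name,
                "group": str(level),
                "events": events,
                "at_risk": at_risk,
                "event_free_pct": surv.event_free_percent(events, at_risk),
                "logrank_p": p,
                "hr": hr.get(level, np.nan),
                "ci95_lower": ci.get(level, (np.nan, np.nan))[0],
                "ci95_upper": ci.get(level, (np.nan, np.nan))[1],
            }
        )
    return rows, p, dummies


@_stage("ingest")
def _load_inputs(config: AnalysisConfig):
    if config.simulation is not None:
        cohort = simulate_cohort(config.simulation)
        expression, clinical = cohort.expression, cohort.clinical
        mp_signature = cohort.signatures["mammaprint_like"]
    else:
        expression = eio.read_expression(config.expression_path)
        clinical = eio.read_clinical(config.clinical_path)
        if config.mammaprint_signature_path:
            mp_signature = eio.read_signature(config.mammaprint_signature_path)
        else:
            raise ValueError("a MammaPrint-style signature list is required for file input")
    if list(expression.columns) != list(clinical.index):
        clinical = clinical.loc[expression.columns]
    return expression, clinical, mp_signature


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the full pipeline; returns a result dict and writes artifacts.

    The returned dict holds the per-factor survival ``report`` (DataFrame), the
    ``results`` summary (JSON-serializable), and the KM curves per factor
    group. With ``config.outdir`` set, writes ``report.tsv``,
    ``results.json``, ``km_curves.tsv`` and ``run.log``.
    """
    expression, clinical, mp_signature = _load_inputs(config)

    records = _stage("encode_dmfs")(surv.encode_dmfs)(clinical)
    zmat = _stage("zscore")(eio.zscore_genes)(expression)
    event = records["event"].astype(int)

    # --- recurrence score + ROC three-group stratification ----------------
    @_stage("recurrence_score")
    def _rs():
        rs = sig.recurrence_scores(zmat)
        roc = strat.roc_curve(rs.to_numpy(), event.to_numpy())
        cut_high = strat.optimal_cutoff(roc)
        cut_low = strat.second_cutoff_high_sensitivity(roc, config.min_sensitivity)
        lo, hi = sorted((cut_low, cut_high))
        return rs, roc, strat.assign_three_groups(rs, lo, hi), (lo, hi)

    rs_scores, rs_roc, rs_groups, rs_cuts = _rs()

    # --- MammaPrint-style groupings ---------------------------------------
    @_stage("mammaprint")
    def _mp():
        found, missing = eio.map_signature(zmat, mp_signature)
        centroids = sig.agpp_centroids(zmat, event, found)
        agpp = sig.classify_agpp_matrix(zmat, centroids, config.correlation)
        cluster = strat.two_cluster_risk(
            zmat, found, config.correlation, event_labels=event
        )
        return found, agpp, cluster

    mp_found, mp_agpp, mp_cluster = _mp()

    # --- per-factor survival table ----------------------------------------
    @_stage("survival_table")
    def _table():
        rows: list[dict] = []
        factor_p: dict[str, float] = {}
        dummy_frames: dict[str, pd.DataFrame] = {}
        factors = _factor_groups(clinical)
        onc = pd.Series(
            pd.Categorical(rs_groups.label, categories=["low", "medium", "high"], ordered=True),
            index=rs_groups.label.index,
        )
        mp = pd.Series(
            pd.Categorical(mp_agpp.label, categories=["good", "bad"], ordered=True),
            index=mp_agpp.label.index,
        )
        mpc = pd.Series(
            pd.Categorical(mp_cluster.label, categories=["good", "bad"], ordered=True),
            index=mp_cluster.label.index,
        )
        factors = factors + [
            ("oncotype_rs", onc),
            ("mammaprint_agpp", mp),
            ("mammaprint_cluster", mpc),
        ]
        for name, groups in factors:
            r, p, dummies = _factor_report_rows(name, groups, records)
            rows.extend(r)
            factor_p[name] = p
            dummy_frames[name] = dummies
        return pd.DataFrame(rows), factor_p, dummy_frames

    report, factor_p, dummy_frames = _table()

    # --- multivariate stepwise Cox over significant factors ----------------
    @_stage("multivariate_cox")
    def _multi():
        significant = [
            n for n, p in factor_p.items() if p < config.univariate_p_threshold
        ]
        # the AGPP grouping is resubstitution-trained on the outcome, so it
        # cannot serve as a multivariate covariate; the cluster grouping is
        # the outcome-blind MammaPrint representative
        significant = [n for n in significant if n != "mammaprint_agpp"]
        if not significant:
            return None, []
        candidates = pd.concat([dummy_frames[n] for n in significant], axis=1)
        try:
            fit = surv.cox_forward_wald(
                candidates, records, config.p_enter, config.stepwise_direction
            )
        except surv.CoxConvergenceError as err:
            logger.warning("stepwise Cox selected no covariates: %s", err)
            return None, significant
        return fit, significant

    multi_fit, significant_factors = _multi()

    # --- gene selection + LOOCV -------------------------------------------
    @_stage("gene_selection")
    def _select():
        results = gsel.anova_per_gene(zmat, event)
        selected = gsel.select_genes(results, alpha=config.alpha)
        cv = gsel.loocv_with_reselection(zmat, event, alpha=config.alpha) if config.run_loocv else None
        return selected, cv

    selected_genes, cv = _select()

    # --- KM curves per factor group ---------------------------------------
    @_stage("km_curves")
    def _curves():
        curve_rows = []
        factors = set(report["factor"])
        groupings = dict(_factor_groups(clinical))
        groupings["oncotype_rs"] = rs_groups.label
        groupings["mammaprint_agpp"] = mp_agpp.label
        groupings["mammaprint_cluster"] = mp_cluster.label
        for name in sorted(factors):
            groups = pd.Series(groupings[name], index=records.index)
            for level in pd.unique(groups.dropna()):
                rec = records.loc[groups == level]
                if rec["event"].sum() == 0:
                    continue
                curve = surv.km_estimate(rec)
                for t, s, n_at, d in zip(
                    curve.event_times, curve.survival, curve.at_risk, curve.events
                ):
                    curve_rows.append(
                        {
                            "factor": name,
                            "group": str(level),
                            "time": float(t),
                            "survival": float(s),
                            "at_risk": int(n_at),
                            "events": int(d),
                        }
                    )
        return pd.DataFrame(curve_rows)

    km_curves = _curves()

    results_summary = {
        "n_patients": int(len(clinical)),
        "n_events": int(event.sum()),
        "event_rate": float(event.mean()),
        "rs_cutoffs": {"low_medium": rs_cuts[0], "medium_high": rs_cuts[1]},
        "rs_roc_auc": rs_roc.auc,
        "rs_group_sizes": rs_groups.label.value_counts().to_dict(),
        "mammaprint_agpp_sizes": mp_agpp.label.value_counts().to_dict(),
        "mammaprint_cluster_sizes": mp_cluster.label.value_counts().to_dict(),
        "mammaprint_genes_found": len(mp_found),
        "logrank_p_by_factor": factor_p,
        "significant_univariate_factors": significant_factors,
        "multivariate": None
        if multi_fit is None
        else {
            "included": multi_fit.included,
            "hr": {k: float(v) for k, v in multi_fit.hr.items()},
            "wald_p": {k: float(v) for k, v in multi_fit.wald_p.items()},
            "trace": multi_fit.trace,
        },
        "n_selected_genes": len(selected_genes),
        "selected_genes": selected_genes.symbols,
        "loocv": None
        if cv is None
        else {
            "accuracy": cv.accuracy,
            "sensitivity": cv.sensitivity,
            "specificity": cv.specificity,
            "confusion": {"tp": cv.tp, "tn": cv.tn, "fp": cv.fp, "fn": cv.fn},
        },
        "seed": config.seed,
    }

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "report.tsv", sep="\t", index=False, float_format="%.6g")
        km_curves.to_csv(outdir / "km_curves.tsv", sep="\t", index=False, float_format="%.6g")
        with open(outdir / "results.json", "w") as handle:
            json.dump(results_summary, handle, indent=1, default=str)
        cfg_dict = asdict(config)
        cfg_hash = hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest()
        with open(outdir / "run.log", "w") as handle:
            handle.write(f"seed={config.seed}\nconfig_sha256={cfg_hash}\n")
            handle.write(json.dumps(cfg_dict, indent=1, default=str) + "\n")

    return {
        "report": report,
        "results": results_summary,
        "km_curves": km_curves,
        "rs_scores": rs_scores,
        "rs_groups": rs_groups,
        "mammaprint_agpp": mp_agpp,
        "mammaprint_cluster": mp_cluster,
        "records": records,
        "cv": cv,
    }
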