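"""Synthetic node-negative breast-cancer cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
latent proliferation score drives a module of co-expressed genes, the
mitotic/proliferation markers (MAI, PPH3, Ki67) and — together with a
planted signature score — the hazard of distant metastasis. Survival is
exponential (optionally Weibull) with independent uniform censoring and
an administrative cap at the end of follow-up.

Two latents carry prognostic information: the proliferation score ``z``
(log-hazard weight ``prolif_effect``), expressed by the designated
proliferation module (``PROLIF_*`` genes) and by the tissue markers, and
the planted signature score ``s`` (weight ``signature_effect``), which
is what the commercial-signature gene sets measure. The gene space
contains, by name, the 16 Oncotype DX target genes (the five
proliferation-group genes carry the planted signature latent; the
ER-group genes load on an ER latent and GRB7/ERBB2 on a HER2 latent,
both outcome-independent structure) plus a MammaPrint-like signature
(``MP_*`` genes on ``s``) and pure-noise filler genes (``G_*``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .expression_io import SignatureGeneList, write_clinical, write_expression, write_signature
from .signatures import ONCOTYPE_TARGET_GENES


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# Monotone quantile anchors (cumulative fraction -> marker value) for the
# proliferation markers. Chosen so the conventional clinical cut-offs
# (MAI 3 and 10, PPH3 13, Ki67 10%) reproduce realistic group sizes for a
# ~94-patient node-negative cohort: MAI 0-2 / 3-9 / >=10 near 34/26/34,
# PPH3 <13 / >=13 near 45/49, Ki67 <10 / >=10 near 39/53.
_MAI_ANCHORS = ((0.0, 0.0), (0.36, 2.5), (0.64, 9.5), (0.95, 40.0), (1.0, 100.0))
_PPH3_ANCHORS = ((0.0, 0.0), (0.479, 12.5), (0.90, 60.0), (1.0, 200.0))
_KI67_ANCHORS = ((0.0, 0.0), (0.424, 9.5), (0.90, 50.0), (1.0, 100.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated cohort.

    Defaults emulate the study cohort the pipeline targets: 94 patients,
    ~24% distant-metastasis event rate, follow-up capped at 171 months
    with random censoring tuned so the median follow-up of censored
    patients is near 127 months. ``prolif_effect`` is the log hazard
    ratio per unit of the latent proliferation score (0.71 per unit makes
    a median dichotomy of the latent worth a hazard ratio of about 3);
    ``signature_effect`` is the weaker direct effect of the planted
    signature latent.
    """

    n_patients: int = 94
    n_genes: int = 1000
    n_signature_genes: int = 62
    prolif_effect: float = 0.71
    signature_effect: float = 0.25
    baseline_hazard: float = 0.002  # events per month; used if event_target_rate is None
    follow_up_max: float = 171.0  # months
    censor_rate: float = 0.65  # fraction exposed to uniform random censoring
    event_target_rate: float | None = 0.24
    noise_sd: float = 1.0
    module_size: int = 50  # proliferation-module genes (incl. the 5 Oncotype ones)
    module_loading: float = 1.0
    signature_loading: float = 0.8
    weibull_shape: float = 1.0  # 1.0 = exponential survival
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_genes", "n_signature_genes", "module_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_signature_genes + self.module_size + len(ONCOTYPE_TARGET_GENES) > self.n_genes:
            raise ConfigurationError(
                "n_genes too small for signature + proliferation module + Oncotype genes"
            )
        for name in ("censor_rate",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.event_target_rate is not None and not 0.0 < self.event_target_rate < 1.0:
            raise ConfigurationError("event_target_rate must be in (0,1)")
        if self.follow_up_max <= 0:
            raise ConfigurationError("follow_up_max must be positive")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if self.weibull_shape <= 0:
            raise ConfigurationError("weibull_shape must be positive")


@dataclass
class SyntheticCohort:
    """Expression + clinical + ground-truth tables for one simulated cohort.

    ``truth`` holds the latent scores and uncensored event times; it is
    for test assertions only and must never feed the analysis modules.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame
    signatures: dict[str, SignatureGeneList] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_expression(self.expression, outdir / "expression.tsv")
        write_clinical(self.clinical, outdir / "clinical.csv")
        truth = self.truth.copy()
        truth.index.name = "sample_id"
        truth.to_csv(outdir / "truth_not_for_analysis.csv")
        for name, sig in self.signatures.items():
            write_signature(sig, outdir / f"signature_{name}.json")


def _piecewise_quantile(u: np.ndarray, anchors) -> np.ndarray:
    xs = np.array([a[0] for a in anchors])
    ys = np.array([a[1] for a in anchors])
    return np.interp(u, xs, ys)


def _expected_event_rate(b: float, eta: np.ndarray, cfg: SimulationConfig) -> float:
    """Mean event probability given baseline hazard b and linear predictors eta.

    For exponential survival with rate lam and censoring that is U(0,F]
    with probability c (administrative at F otherwise):
    P(event) = c*(1 - (1-exp(-lam F))/(lam F)) + (1-c)*(1-exp(-lam F)).
    """
    lam = b * np.exp(eta)
    lamF = lam * cfg.follow_up_max
    p_admin = -np.expm1(-lamF)
    p_unif = 1.0 - p_admin / lamF
    return float(np.mean(cfg.censor_rate * p_unif + (1 - cfg.censor_rate) * p_admin))


def _calibrate_baseline(eta: np.ndarray, cfg: SimulationConfig) -> float:
    target = cfg.event_target_rate
    f = lambda logb: _expected_event_rate(np.exp(logb), eta, cfg) - target
    lo, hi = np.log(1e-8), np.log(1.0)
    return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-12)))


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort under ``config``; identical config ⇒ identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    ids = [f"S{i+1:03d}" for i in range(n)]

    # latents: proliferation z, signature s, ER e, HER2 h
    z = rng.standard_normal(n)
    s = rng.standard_normal(n)
    e = rng.standard_normal(n)
    h = rng.standard_normal(n)

    # --- survival ---------------------------------------------------------
    eta = cfg.prolif_effect * z + cfg.signature_effect * s
    if cfg.event_target_rate is not None:
        b = _calibrate_baseline(eta, cfg)
    else:
        b = cfg.baseline_hazard
    lam = b * np.exp(eta)
    u = rng.uniform(size=n)
    if cfg.weibull_shape == 1.0:
        t_event = -np.log(u) / lam
    else:
        t_event = (-np.log(u) / lam) ** (1.0 / cfg.weibull_shape)
    random_censored = rng.uniform(size=n) < cfg.censor_rate
    c_unif = rng.uniform(0.0, cfg.follow_up_max, size=n)
    t_censor = np.where(random_censored, c_unif, cfg.follow_up_max)
    follow_up = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    follow_up = np.maximum(follow_up, 1e-6)  # survival times strictly positive

    # --- proliferation markers: monotone noisy transforms of z ------------
    def marker(noise_sd: float, anchors, integer: bool) -> np.ndarray:
        latent = z + rng.normal(0.0, noise_sd, size=n)
        u_lat = stats.norm.cdf(latent / np.sqrt(1.0 + noise_sd**2))
        vals = _piecewise_quantile(u_lat, anchors)
        return np.round(vals).astype(int) if integer else np.round(vals, 1)

    mai = marker(0.4, _MAI_ANCHORS, integer=True)
    pph3 = marker(0.3, _PPH3_ANCHORS, integer=True)
    ki67 = marker(0.5, _KI67_ANCHORS, integer=False)

    # --- other clinical covariates ----------------------------------------
    age = np.clip(np.round(rng.normal(60.0, 12.0, size=n)), 28, 92).astype(int)
    diameter = np.round(np.exp(rng.normal(np.log(1.8), 0.45, size=n)), 1)
    grade_latent = 0.6 * z + rng.standard_normal(n)
    gsd = np.sqrt(1 + 0.6**2)
    grade = np.select(
        [grade_latent < stats.norm.ppf(0.15) * gsd, grade_latent < stats.norm.ppf(0.60) * gsd],
        [1, 2],
        default=3,
    )
    er_status = (e > stats.norm.ppf(17 / 94)).astype(int)  # ~82% positive
    pr_status = (0.7 * e + 0.714 * rng.standard_normal(n) > stats.norm.ppf(16 / 94)).astype(int)
    her2_status = (h > stats.norm.ppf(1 - 14 / 94)).astype(int)
    ck56_status = (rng.uniform(size=n) < 12 / 94).astype(int)
    tnp_status = ((er_status == 0) & (pr_status == 0) & (her2_status == 0)).astype(int)

    clinical = pd.DataFrame(
        {
            "age": age,
            "tumour_diameter": diameter,
            "grade": grade,
            "er_status": er_status,
            "pr_status": pr_status,
            "her2_status": her2_status,
            "ck56_status": ck56_status,
            "tnp_status": tnp_status,
            "mai": mai,
            "ki67": ki67,
            "pph3": pph3,
            "follow_up": np.round(follow_up, 3),
            "dmfs_event": event,
        },
        index=pd.Index(ids, name="sample_id"),
    )

    # --- expression --------------------------------------------------------
    onco = [g for g, _ in ONCOTYPE_TARGET_GENES]
    prolif_module_extra = [f"PROLIF_{i+1:03d}" for i in range(cfg.module_size - 5)]
    mp_genes = [f"MP_{i+1:03d}" for i in range(cfg.n_signature_genes)]
    n_noise = cfg.n_genes - len(onco) - len(prolif_module_extra) - len(mp_genes)
    noise_genes = [f"G_{i+1:04d}" for i in range(n_noise)]
    gene_ids = onco + prolif_module_extra + mp_genes + noise_genes

    expr = 7.0 + rng.normal(0.0, cfg.noise_sd, size=(len(gene_ids), n))
    signal = np.zeros((len(gene_ids), n))
    row = {g: i for i, g in enumerate(gene_ids)}
    for g in ("BIRC5", "MKI67", "MYBL2", "CCNB1", "AURKA"):
        signal[row[g]] = cfg.signature_loading * s
    for g in ("ESR1", "PGR", "BCL2", "SCUBE2"):
        signal[row[g]] = 1.0 * e
    for g in ("GRB7", "ERBB2"):
        signal[row[g]] = 1.0 * h
    for g in prolif_module_extra:
        signal[row[g]] = cfg.module_loading * z
    for g in mp_genes:
        signal[row[g]] = cfg.signature_loading * s
    expression = pd.DataFrame(
        expr + signal, index=pd.Index(gene_ids, name="gene_id"), columns=ids
    )

    truth = pd.DataFrame(
        {
            "prolif_score": z,
            "signature_score": s,
            "true_event_time": t_event,
            "true_risk_label": np.where(z > 0, "high", "low"),
        },
        index=pd.Index(ids, name="sample_id"),
    )

    signatures = {
        "oncotype": SignatureGeneList("oncotype", dict(ONCOTYPE_TARGET_GENES)),
        "mammaprint_like": SignatureGeneList.from_symbols("mammaprint_like", mp_genes),
    }
    return SyntheticCohort(expression, clinical, truth, signatures)


def event_counts(cohort: SyntheticCohort) -> tuple[int, int]:
    """Number of DMFS events and total patients in the cohort."""
    if cohort.clinical.empty:
        raise ValueError("empty cohort")
    return int(cohort.clinical["dmfs_event"].sum()), int(len(cohort.clinical))


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy a configuration with a new seed."""
    return replace(config, seed=seed)
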