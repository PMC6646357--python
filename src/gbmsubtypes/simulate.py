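"""Synthetic cohorts with survival-linked planted gene programs.

The generator emulates the statistical structure a transcriptome-based
prognostic-subtyping analysis assumes: normalized log-scale expression with a
small set of "poor" genes loading positively and "favorable" genes loading
negatively on a per-patient latent risk, survival times whose hazard is
log-linear in that risk, independent censoring, tumor-grade labels shifting
risk, and an MGMT-methylation status whose odds fall with risk.

The latent risk handed to the survival model is the *realized* one — the mean
z-scored expression of planted poor genes minus that of planted favorable
genes — so the survival signal flows through the expression matrix exactly as
a downstream scorer can recover it.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import Cohort, GroundTruth, SimulationConfig
from .errors import ConfigurationError

_VERHAAK_LABELS = ("classical", "mesenchymal", "neural", "proneural")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _sample_ids(n: int, prefix: str) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _expression_matrix(
    rng: np.random.Generator,
    config: SimulationConfig,
    baselines: np.ndarray,
    u: np.ndarray,
) -> np.ndarray:
    """Genes x samples matrix: planted genes load +/- on the latent factor u."""
    n_g, n_s = config.n_genes, len(u)
    n_p, n_f = config.n_poor_planted, config.n_favorable_planted
    x = baselines[:, None] + rng.normal(0.0, config.noise_sd, size=(n_g, n_s))
    x[:n_p, :] += u[None, :]
    x[n_p : n_p + n_f, :] -= u[None, :]
    return x


def _realized_latent_risk(expr: np.ndarray, n_poor: int, n_fav: int) -> np.ndarray:
    """Mean z-expression of planted poor genes minus planted favorable genes."""
    sd = expr.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (expr - expr.mean(axis=1, keepdims=True)) / sd[:, None]
    risk = np.zeros(expr.shape[1])
    if n_poor:
        risk += z[:n_poor].mean(axis=0)
    if n_fav:
        risk -= z[n_poor : n_poor + n_fav].mean(axis=0)
    return risk


def _censoring_rate_to_exp_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i c/(c + h_i) = target."""
    if target <= 0:
        return 0.0

    def frac(log_c: float) -> float:
        c = np.exp(log_c)
        return float(np.mean(c / (c + hazards))) - target

    return float(np.exp(brentq(frac, -40.0, 40.0, xtol=1e-12)))


def _survival(
    rng: np.random.Generator, config: SimulationConfig, risk: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    hazards = config.baseline_hazard * np.exp(config.effect_size_beta * risk)
    # inverse-transform Weibull with per-subject scale; shape 1 = exponential
    t_event = (rng.exponential(1.0, size=risk.size) / hazards) ** (
        1.0 / config.weibull_shape
    )
    if config.censoring_rate == 0:
        return t_event, np.ones(risk.size, dtype=int)
    c_rate = _censoring_rate_to_exp_rate(hazards, config.censoring_rate)
    t_cens = rng.exponential(1.0 / c_rate, size=risk.size)
    event = (t_event <= t_cens).astype(int)
    return np.minimum(t_event, t_cens), event


def _mgmt_status(
    rng: np.random.Generator, config: SimulationConfig, risk: np.ndarray
) -> np.ndarray:
    """Binary methylation status; odds of methylation fall with latent risk.

    Base rate 0.45 (typical methylated fraction in GBM); the log-odds shift per
    SD of risk is -log(mgmt_enrichment_or), so the favorable (low-risk) program
    is enriched for methylation by the configured odds ratio.
    """
    sd = risk.std(ddof=0) or 1.0
    z = (risk - risk.mean()) / sd
    logit = np.log(0.45 / 0.55) - np.log(config.mgmt_enrichment_or) * z
    p = 1.0 / (1.0 + np.exp(-logit))
    return (rng.random(risk.size) < p).astype(int)


def _build_cohort(
    config: SimulationConfig,
    baselines: np.ndarray,
    sample_rng: np.random.Generator,
    prefix: str,
    name: str,
    u_shift: np.ndarray | None = None,
    grade: np.ndarray | None = None,
) -> tuple[Cohort, np.ndarray]:
    u = sample_rng.normal(0.0, 1.0, size=config.n_samples)
    if u_shift is not None:
        u = u + u_shift
    expr = _expression_matrix(sample_rng, config, baselines, u)
    risk = _realized_latent_risk(expr, config.n_poor_planted, config.n_favorable_planted)
    os_months, event = _survival(sample_rng, config, risk)
    mgmt = _mgmt_status(sample_rng, config, risk)
    subtype = sample_rng.choice(_VERHAAK_LABELS, size=config.n_samples)
    sids = _sample_ids(config.n_samples, prefix)
    clinical = pd.DataFrame(
        {
            "os_months": os_months,
            "event": event,
            "mgmt_methylated": mgmt,
            "external_subtype": subtype,
        },
        index=pd.Index(sids, name="sample_id"),
    )
    if grade is not None:
        clinical["grade"] = grade
    expression = pd.DataFrame(
        expr, index=pd.Index(_gene_ids(config.n_genes), name="gene_id"), columns=sids
    )
    return Cohort(expression=expression, clinical=clinical, name=name), risk


def _planted_sets(config: SimulationConfig) -> tuple[frozenset, frozenset]:
    gids = _gene_ids(config.n_genes)
    poor = frozenset(gids[: config.n_poor_planted])
    fav = frozenset(
        gids[config.n_poor_planted : config.n_poor_planted + config.n_favorable_planted]
    )
    return poor, fav


def _rngs(config: SimulationConfig, n_streams: int) -> list[np.random.Generator]:
    seqs = np.random.SeedSequence(config.seed).spawn(n_streams)
    return [np.random.default_rng(s) for s in seqs]


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Generate one cohort plus its planted ground truth.

    Deterministic: identical config (including seed) yields bit-identical
    output. Planted poor genes correlate negatively with OS, favorable genes
    positively, with strength governed by ``effect_size_beta``.
    """
    gene_rng, sample_rng = _rngs(config, 2)
    baselines = gene_rng.normal(7.0, 1.0, size=config.n_genes)
    cohort, risk = _build_cohort(config, baselines, sample_rng, "S", "simulated")
    poor, fav = _planted_sets(config)
    truth = GroundTruth(
        poor_planted=poor,
        favorable_planted=fav,
        per_sample_latent_risk=pd.Series(risk, index=cohort.sample_ids),
    )
    return cohort, truth


def platform_transform(values: np.ndarray, shift: float, center: float = 7.0) -> np.ndarray:
    """Strictly monotone elementwise map emulating a platform change.

    y = x + shift * tanh(x - center); dy/dx = 1 + shift * sech^2 >= 1 > 0, so
    ranks are preserved within every sample and every gene.
    """
    return values + shift * np.tanh(values - center)


def simulate_cohort_pair(
    config: SimulationConfig,
) -> tuple[Cohort, Cohort, GroundTruth]:
    """Two cohorts sharing planted programs, with independent samples/noise.

    The second cohort is passed through :func:`platform_transform` of strength
    ``platform_shift`` (set it to 0 for two same-platform replicates). The
    returned GroundTruth concatenates both cohorts' latent risks.
    """
    gene_rng, rng_a, rng_b = _rngs(config, 3)
    baselines = gene_rng.normal(7.0, 1.0, size=config.n_genes)
    cohort_a, risk_a = _build_cohort(config, baselines, rng_a, "A", "cohort_a")
    cohort_b, risk_b = _build_cohort(config, baselines, rng_b, "B", "cohort_b")
    if config.platform_shift > 0:
        cohort_b = Cohort(
            expression=pd.DataFrame(
                platform_transform(cohort_b.expression.to_numpy(), config.platform_shift),
                index=cohort_b.expression.index,
                columns=cohort_b.expression.columns,
            ),
            clinical=cohort_b.clinical,
            name=cohort_b.name,
        )
    poor, fav = _planted_sets(config)
    risk = pd.Series(
        np.concatenate([risk_a, risk_b]),
        index=list(cohort_a.sample_ids) + list(cohort_b.sample_ids),
    )
    truth = GroundTruth(
        poor_planted=poor, favorable_planted=fav, per_sample_latent_risk=risk
    )
    return cohort_a, cohort_b, truth


def simulate_graded_cohort(config: SimulationConfig, grade_effect: float) -> Cohort:
    """Cohort with grade 2/3/4 labels; latent risk mean rises by
    ``grade_effect`` per grade step (grade 4 patients sit ``2 * grade_effect``
    above grade 2 on average before expression noise)."""
    if not np.isfinite(grade_effect):
        raise ConfigurationError("grade_effect must be finite")
    gene_rng, sample_rng = _rngs(config, 2)
    baselines = gene_rng.normal(7.0, 1.0, size=config.n_genes)
    grades = np.array([2, 3, 4])[np.arange(config.n_samples) % 3]
    u_shift = grade_effect * (grades - 2)
    cohort, _ = _build_cohort(
        config, baselines, sample_rng, "S", "graded", u_shift=u_shift, grade=grades
    )
    return cohort
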