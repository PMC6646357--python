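"""Selection of prognosis-associated genes (PGs) from two discovery cohorts.

Each gene's expression is Pearson-correlated with overall survival in two
independent cohorts. Genes whose correlations share a strict sign in both
cohorts are "concordant"; discordant genes are excluded. Concordant genes are
ranked by the PCC score — the sign-preserving magnitude product
sign(PCC) * |PCC_a * PCC_b| — and the k most negative (poor) and k most
positive (favorable) genes form the PG sets.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import Cohort, GeneSet
from .errors import UndefinedCorrelationError

logger = logging.getLogger(__name__)

#: Marker returned by :func:`pcc_score` for sign-discordant gene pairs.
DISCORDANT = None


class SelectionShortfallWarning(UserWarning):
    """Fewer concordant genes than requested in at least one direction."""


def pearson_correlation(x, y) -> float:
    """Pearson correlation coefficient between two equal-length vectors.

    Raises :class:`UndefinedCorrelationError` for length < 3 or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UndefinedCorrelationError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def correlate_genes_with_os(
    cohort: Cohort, use_events_only: bool = False
) -> pd.Series:
    """Per-gene Pearson correlation between expression and OS.

    ``use_events_only`` restricts to samples with an observed death
    (sensitivity switch); by default all samples with recorded OS are used.
    Genes with zero expression variance are excluded (logged).
    """
    mask = np.ones(cohort.n_samples, dtype=bool)
    if use_events_only:
        mask = cohort.event.to_numpy() == 1
    os_v = cohort.os_months.to_numpy(float)[mask]
    if os_v.size < 3:
        raise UndefinedCorrelationError("fewer than 3 samples with OS available")
    if np.ptp(os_v) == 0:
        raise UndefinedCorrelationError("OS has zero variance")
    x = cohort.expression.to_numpy(float)[:, mask]
    xc = x - x.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    oc = os_v - os_v.mean()
    so = np.sqrt((oc**2).sum())
    variable = sx > 0
    n_dropped = int((~variable).sum())
    if n_dropped:
        logger.warning("excluding %d zero-variance genes from OS correlation", n_dropped)
    r = (xc[variable] @ oc) / (sx[variable] * so)
    return pd.Series(np.clip(r, -1.0, 1.0), index=cohort.gene_ids[variable], name="pcc")


def pcc_score(pcc_a: float, pcc_b: float):
    """Sign-preserving magnitude product of two cohorts' PCCs.

    Both strictly negative -> -|a*b| (poor direction); both strictly positive
    -> +|a*b| (favorable); any sign disagreement (zeros included) -> the
    :data:`DISCORDANT` marker, meaning the gene is excluded.
    """
    if pcc_a < 0 and pcc_b < 0:
        return -abs(pcc_a * pcc_b)
    if pcc_a > 0 and pcc_b > 0:
        return abs(pcc_a * pcc_b)
    return DISCORDANT


@dataclass
class PGSelectionResult:
    """Outcome of dual-cohort PG selection.

    ``records`` has one row per gene shared by both cohorts with columns
    pcc_a, pcc_b, concordant, pcc_score (NaN when discordant).
    """

    records: pd.DataFrame
    poor_genes: list[str]
    favorable_genes: list[str]
    k: int

    def gene_sets(self, source: str = "pg_selection") -> tuple[GeneSet, GeneSet]:
        return (
            GeneSet("PG_poor", tuple(self.poor_genes), source=source),
            GeneSet("PG_favorable", tuple(self.favorable_genes), source=source),
        )


def select_pgs(
    cohort_a: Cohort,
    cohort_b: Cohort,
    k: int = 40,
    use_events_only: bool = False,
) -> PGSelectionResult:
    """Select the top-k poor and top-k favorable prognosis genes.

    Genes are matched across cohorts by exact identifier (unmatched genes are
    dropped and counted). Ties in pcc_score break by gene id, so reruns are
    bit-identical. If a direction has fewer than k concordant genes a
    :class:`SelectionShortfallWarning` is raised and the list truncated.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pcc_a = correlate_genes_with_os(cohort_a, use_events_only)
    pcc_b = correlate_genes_with_os(cohort_b, use_events_only)
    shared = pcc_a.index.intersection(pcc_b.index)
    n_unmatched = len(pcc_a.index.union(pcc_b.index)) - len(shared)
    if n_unmatched:
        logger.info("dropped %d genes absent from one cohort", n_unmatched)
    records = pd.DataFrame(
        {"pcc_a": pcc_a.loc[shared], "pcc_b": pcc_b.loc[shared]}
    )
    records.index.name = "gene_id"
    scores = [pcc_score(a, b) for a, b in zip(records.pcc_a, records.pcc_b)]
    records["concordant"] = [s is not DISCORDANT for s in scores]
    records["pcc_score"] = [np.nan if s is DISCORDANT else s for s in scores]
    records = records.sort_index()

    conc = records[records.concordant]
    poor = conc[conc.pcc_score < 0].sort_values(
        ["pcc_score", "gene_id"], ascending=[True, True]
    )
    fav = conc[conc.pcc_score > 0].sort_values(
        ["pcc_score", "gene_id"], ascending=[False, True]
    )
    for direction, frame in (("poor", poor), ("favorable", fav)):
        if len(frame) < k:
            warnings.warn(
                f"only {len(frame)} concordant {direction} genes available "
                f"(requested {k})",
                SelectionShortfallWarning,
                stacklevel=2,
            )
        elif len(frame) < 2 * k:
            warnings.warn(
                f"fewer than 2k concordant {direction} genes ({len(frame)})",
                SelectionShortfallWarning,
                stacklevel=2,
            )
    return PGSelectionResult(
        records=records,
        poor_genes=list(poor.index[:k]),
        favorable_genes=list(fav.index[:k]),
        k=k,
    )


def compare_pg_sizes(
    cohort: Cohort,
    result_k1: PGSelectionResult,
    result_k2: PGSelectionResult,
    params=None,
) -> tuple[float, float]:
    """Correlation between prognosis scores from two PG-set sizes.

    Scores ``cohort`` with each result's poor/favorable sets and returns the
    Pearson r and two-sided p between the two per-sample prognosis scores —
    the robustness check that a 20+20 signature reproduces the 40+40 one.
    """
    from .ssgsea import SsgseaParams, score_cohort

    if cohort.n_samples < 3:
        raise UndefinedCorrelationError("need >= 3 samples to correlate scores")
    params = params or SsgseaParams()
    s1 = score_cohort(cohort, *result_k1.gene_sets(), params=params)
    s2 = score_cohort(cohort, *result_k2.gene_sets(), params=params)
    x = s1["prognosis_score"].to_numpy()
    y = s2.loc[s1.index, "prognosis_score"].to_numpy()
    if np.allclose(x, y):
        return 1.0, 0.0
    r = pearson_correlation(x, y)
    p = float(stats.pearsonr(x, y).pvalue)
    return r, p
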