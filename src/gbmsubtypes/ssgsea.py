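"""Single-sample GSEA scoring of the poor/favorable prognosis gene sets.

The enrichment score (ES) for a gene set S in one sample is a weighted
ECDF-difference sum over the sample's expression ranking. With the G measured
genes ordered by decreasing expression and rank values v_j = G - j + 1 (the
top gene carries value G), the ES is

    ES = sum_{i=1..G} [ P_hit(i) - P_miss(i) ]
    P_hit(i)  = sum_{j<=i, g_j in S} v_j^tau / sum_{j in S} v_j^tau
    P_miss(i) = |{j<=i : g_j not in S}| / (G - m)

with m = |S ∩ measured|. tau defaults to 0.25. The score depends on the
sample's expression only through ranks, so any strictly monotone per-sample
transform (log, affine, platform shifts) leaves it unchanged.

Per cohort and per gene set, raw ES values are z-standardized across samples;
the prognosis score of a sample is its standardized favorable-set score minus
its standardized poor-set score.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import Cohort, GeneSet
from .errors import DegenerateCohortError, ScoringError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SsgseaParams:
    """ssGSEA variant parameters.

    tau : rank-weighting exponent (0 = unweighted Kolmogorov-Smirnov walk)
    tie_method : "average" shares the mean rank value across expression ties;
        "stable-order" breaks ties by input gene order
    min_overlap : minimum measured genes a set must contribute
    """

    tau: float = 0.25
    tie_method: str = "average"
    min_overlap: int = 5

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.tie_method not in ("average", "stable-order"):
            raise ValueError("tie_method must be 'average' or 'stable-order'")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


def _rank_values(expr: np.ndarray, tie_method: str) -> np.ndarray:
    """Rank value per gene: G for the highest-expressed gene down to 1."""
    g = expr.size
    if tie_method == "average":
        return g - rankdata(-expr, method="average") + 1.0
    return g - rankdata(-expr, method="ordinal") + 1.0


def ssgsea_enrichment(
    sample_expression: pd.Series,
    gene_set: GeneSet,
    params: SsgseaParams | None = None,
) -> float:
    """Enrichment score of one gene set in one sample.

    ``sample_expression`` is indexed by gene id. Set genes missing from the
    vector are dropped (overlap logged); fewer than ``min_overlap`` remaining,
    or a set covering every measured gene, is a :class:`ScoringError`.
    """
    params = params or SsgseaParams()
    expr = sample_expression.to_numpy(dtype=float)
    in_set = np.asarray(sample_expression.index.isin(list(gene_set.members)))
    g = expr.size
    m = int(in_set.sum())
    if m < params.min_overlap:
        raise ScoringError(
            f"set {gene_set.name!r}: overlap {m} < min_overlap {params.min_overlap}"
        )
    if m == g:
        raise ScoringError(f"set {gene_set.name!r} covers all genes; complement undefined")
    if m < len(gene_set):
        logger.debug(
            "set %s: %d of %d genes measured", gene_set.name, m, len(gene_set)
        )
    order = np.argsort(-expr, kind="stable")
    v = _rank_values(expr, params.tie_method)
    hit = np.where(in_set[order], v[order] ** params.tau, 0.0)
    p_hit = np.cumsum(hit) / hit.sum()
    p_miss = np.cumsum(np.where(in_set[order], 0.0, 1.0)) / (g - m)
    return float(np.sum(p_hit - p_miss))


def score_cohort(
    cohort: Cohort,
    poor_set: GeneSet,
    favorable_set: GeneSet,
    params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """Per-sample standardized poor/favorable scores and the prognosis score.

    Returns a DataFrame indexed by sample id with columns ``poor_score``,
    ``favorable_score`` (each z-standardized across the cohort, mean 0 / SD 1)
    and ``prognosis_score = favorable_score - poor_score``. Standardization is
    within this cohort only; score each dataset separately.
    """
    params = params or SsgseaParams()
    if cohort.n_samples < 2:
        raise DegenerateCohortError("standardization needs >= 2 samples")
    raw = {}
    for label, gene_set in (("poor", poor_set), ("favorable", favorable_set)):
        es = np.array(
            [
                ssgsea_enrichment(cohort.expression[s], gene_set, params)
                for s in cohort.sample_ids
            ]
        )
        sd = es.std(ddof=1)
        if sd == 0:
            raise DegenerateCohortError(
                f"raw enrichment scores for set {gene_set.name!r} have zero spread"
            )
        raw[label] = (es - es.mean()) / sd
    frame = pd.DataFrame(
        {
            "poor_score": raw["poor"],
            "favorable_score": raw["favorable"],
        },
        index=cohort.sample_ids.copy(),
    )
    frame.index.name = "sample_id"
    frame["prognosis_score"] = frame["favorable_score"] - frame["poor_score"]
    frame.attrs["tau"] = params.tau
    frame.attrs["tie_method"] = params.tie_method
    return frame


def score_gene_sets(
    cohort: Cohort,
    collection,
    params: SsgseaParams | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Raw or standardized ssGSEA scores for an arbitrary gene-set collection.

    Rows are samples, columns are set names. Sets failing the overlap checks
    are skipped with a log message.
    """
    params = params or SsgseaParams()
    cols = {}
    for gene_set in collection:
        try:
            es = np.array(
                [
                    ssgsea_enrichment(cohort.expression[s], gene_set, params)
                    for s in cohort.sample_ids
                ]
            )
        except ScoringError as exc:
            logger.warning("skipping set %s: %s", gene_set.name, exc)
            continue
        if standardize:
            sd = es.std(ddof=1)
            if sd == 0:
                logger.warning("skipping set %s: zero score spread", gene_set.name)
                continue
            es = (es - es.mean()) / sd
        cols[gene_set.name] = es
    frame = pd.DataFrame(cols, index=cohort.sample_ids.copy())
    frame.index.name = "sample_id"
    return frame
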