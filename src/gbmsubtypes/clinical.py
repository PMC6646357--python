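"""Clinical and phenotype indices tied to the prognostic subtypes.

MRI invasiveness contrasts the T2-FLAIR area (tumor plus invasive front)
with the T1 contrast-enhanced area (tumor core): (FLAIR - CE)/CE. The 3D
spheroid invasion assay index is the relative occupied-area growth over 72 h:
(area_72h - area_0h)/area_0h. Subtype-vs-binary-feature associations (e.g.
MGMT promoter methylation) are summarized as a 2x2 contingency table with an
odds ratio and two-sided Fisher exact p-value.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import fisher_exact_two_sided
from .errors import EstimationError, UndefinedCorrelationError
from .pg_selection import pearson_correlation

logger = logging.getLogger(__name__)


def mri_invasiveness(area_flair: float, area_ce: float) -> float:
    """(T2-FLAIR area - T1-CE area) / T1-CE area.

    Both areas in the same (arbitrary) units; the ratio is unit-free.
    Negative values (FLAIR smaller than CE, a measurement-noise case) are
    returned with a warning rather than clamped.
    """
    if area_ce <= 0:
        raise ValueError("T1-CE area must be positive")
    value = (area_flair - area_ce) / area_ce
    if value < 0:
        logger.warning("negative invasiveness (%g): FLAIR area below CE area", value)
    return float(value)


def invasion_assay_index(area_0h: float, area_72h: float) -> float:
    """Relative occupied-area change of a spheroid: (72 h - 0 h)/0 h."""
    if area_0h <= 0:
        raise ValueError("baseline area must be positive")
    return float((area_72h - area_0h) / area_0h)


def invasiveness_table(areas: pd.DataFrame) -> pd.Series:
    """Per-sample MRI invasiveness from an areas table.

    Accepts either single columns ``area_flair``/``area_ce`` or dual-rater
    pairs ``area_flair_1``/``area_flair_2`` (likewise for CE), which are
    averaged before the index is computed.
    """

    def pick(stem: str) -> pd.Series:
        if stem in areas.columns:
            return areas[stem].astype(float)
        pair = [c for c in areas.columns if c.startswith(stem + "_")]
        if not pair:
            raise ValueError(f"areas table lacks {stem!r} column(s)")
        return areas[pair].astype(float).mean(axis=1)

    flair, ce = pick("area_flair"), pick("area_ce")
    return pd.Series(
        [mri_invasiveness(f, c) for f, c in zip(flair, ce)],
        index=areas.index,
        name="invasiveness",
    )


@dataclass
class ContingencyResult:
    """2x2 subtype-by-feature association.

    ``table`` rows are (group_a, group_b), columns (feature present, absent).
    ``odds_ratio`` is (a*d)/(b*c); when any cell is zero the Haldane-Anscombe
    +0.5 correction is applied and ``corrected`` is set. ``p_fisher`` is the
    two-sided Fisher exact p on the uncorrected counts.
    """

    table: pd.DataFrame
    odds_ratio: float
    p_fisher: float
    corrected: bool = False


def feature_enrichment(
    assignment: pd.DataFrame,
    feature: pd.Series,
    group_a: str = "invasive",
    group_b: str = "mitotic",
) -> ContingencyResult:
    """Association between two subtypes and a binary per-sample feature.

    ``feature`` is 0/1 indexed by sample id (samples missing the feature are
    dropped). Rows of the table are the two subtypes; columns are feature = 1
    then feature = 0.
    """
    sub = assignment["subtype"].astype(str)
    for g in (group_a, group_b):
        if (sub == g).sum() == 0:
            raise EstimationError(f"subtype {g!r} absent from assignment")
    feat = feature.reindex(assignment.index).dropna()
    counts = np.zeros((2, 2), dtype=int)
    for i, g in enumerate((group_a, group_b)):
        ids = sub.index[(sub == g)].intersection(feat.index)
        vals = feat.loc[ids].astype(int)
        counts[i, 0] = int((vals == 1).sum())
        counts[i, 1] = int((vals == 0).sum())
    a, b = counts[0]
    c, d = counts[1]
    corrected = bool((counts == 0).any())
    if corrected:
        logger.warning("zero cell in contingency table; Haldane-Anscombe +0.5 applied")
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    _, p = fisher_exact_two_sided(counts)
    table = pd.DataFrame(
        counts,
        index=pd.Index([group_a, group_b], name="subtype"),
        columns=["feature_present", "feature_absent"],
    )
    return ContingencyResult(
        table=table, odds_ratio=float(odds), p_fisher=p, corrected=corrected
    )


def invasiveness_score_correlation(invasiveness, scores) -> tuple[float, float]:
    """Pearson r (and two-sided p) between an invasiveness index and a score."""
    from scipy import stats

    x = np.asarray(invasiveness, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 observations")
    r = pearson_correlation(x, y)
    p = float(stats.pearsonr(x, y).pvalue)
    return r, p
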