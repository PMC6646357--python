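"""Prognostic subtype assignment from prognosis scores.

Samples with prognosis score strictly below the low cutoff are "invasive"
(poor prognosis), strictly above the high cutoff "mitotic" (favorable), and
everything in between — boundaries included — "intermediate". The default
cutoffs are -1.0 and +1.0 on the standardized prognosis-score scale.

A sensitivity scan dichotomizes the cohort at each cutoff of a grid
({score < c} vs {score >= c}), records the two-group log-rank p-value, and
marks interior local minima — the evidence used to choose the cutoffs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    SUBTYPE_INTERMEDIATE,
    SUBTYPE_INVASIVE,
    SUBTYPE_MITOTIC,
    SUBTYPES,
    Cohort,
)
from .errors import AlignmentError, EmptyScanError


def assign_subtypes(
    scores: pd.DataFrame, cutoff_low: float = -1.0, cutoff_high: float = 1.0
) -> pd.DataFrame:
    """Label every sample invasive / intermediate / mitotic.

    ``scores`` must carry a ``prognosis_score`` column indexed by sample id
    (as produced by :func:`gbmsubtypes.ssgsea.score_cohort`). Boundary scores
    equal to a cutoff are intermediate (strict inequalities on both sides).
    Returns a DataFrame with columns ``prognosis_score`` and ``subtype``;
    the cutoffs used are recorded in ``.attrs``.
    """
    if not cutoff_low < cutoff_high:
        raise ValueError("cutoff_low must be < cutoff_high")
    s = scores["prognosis_score"].to_numpy(dtype=float)
    labels = np.where(
        s < cutoff_low,
        SUBTYPE_INVASIVE,
        np.where(s > cutoff_high, SUBTYPE_MITOTIC, SUBTYPE_INTERMEDIATE),
    )
    out = pd.DataFrame(
        {
            "prognosis_score": s,
            "subtype": pd.Categorical(labels, categories=list(SUBTYPES)),
        },
        index=scores.index.copy(),
    )
    out.index.name = "sample_id"
    out.attrs["cutoff_low"] = float(cutoff_low)
    out.attrs["cutoff_high"] = float(cutoff_high)
    return out


@dataclass
class CutoffScan:
    """Grid of candidate cutoffs with their two-group log-rank p-values.

    ``table`` columns: cutoff, n_low, n_high, n_events_low, n_events_high,
    valid (dichotomization left >= 2 samples and >= 1 event per side), p
    (NaN where invalid), is_local_min. ``local_minima`` lists the cutoffs of
    interior local minima (strictly below the left neighbor, at or below the
    right one, so a flat plateau reports its left edge).
    """

    table: pd.DataFrame
    local_minima: list[float]


def cutoff_sensitivity_scan(
    scores: pd.DataFrame,
    cohort: Cohort,
    grid_min: float = -2.0,
    grid_max: float = 2.0,
    step: float = 0.1,
) -> CutoffScan:
    """Log-rank p-value profile across dichotomizing cutoffs.

    At each grid cutoff c the cohort splits into {score < c} and {score >= c};
    cutoffs leaving fewer than 2 samples or no event in either group are
    flagged invalid rather than scored.
    """
    from .survival import logrank_test

    if step <= 0:
        raise ValueError("step must be positive")
    ids = scores.index
    if not set(ids) <= set(cohort.sample_ids):
        raise AlignmentError("score sample ids not found in cohort")
    grid = np.round(np.arange(grid_min, grid_max + step / 2, step), 10)
    s = scores["prognosis_score"].to_numpy(dtype=float)
    os_v = cohort.os_months.loc[ids].to_numpy(float)
    ev = cohort.event.loc[ids].to_numpy(int)

    rows = []
    for c in grid:
        low = s < c
        n_low, n_high = int(low.sum()), int((~low).sum())
        e_low, e_high = int(ev[low].sum()), int(ev[~low].sum())
        valid = n_low >= 2 and n_high >= 2 and e_low >= 1 and e_high >= 1
        p = np.nan
        if valid:
            p = logrank_test(os_v, ev, low.astype(int)).p_value
        rows.append(
            {
                "cutoff": float(c),
                "n_low": n_low,
                "n_high": n_high,
                "n_events_low": e_low,
                "n_events_high": e_high,
                "valid": valid,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    if not table["valid"].any():
        raise EmptyScanError("no cutoff admits a valid two-group comparison")

    p = table["p"].to_numpy()
    is_min = np.zeros(len(table), dtype=bool)
    for i in range(1, len(table) - 1):
        if np.isnan(p[i]) or np.isnan(p[i - 1]) or np.isnan(p[i + 1]):
            continue
        if p[i] < p[i - 1] and p[i] <= p[i + 1]:
            is_min[i] = True
    table["is_local_min"] = is_min
    return CutoffScan(
        table=table, local_minima=[float(c) for c in table.loc[is_min, "cutoff"]]
    )


def crosstab_subtypes(assignment: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Subtype x external-label contingency counts.

    ``labels`` must be indexed by the same sample ids as ``assignment`` (e.g.
    transcriptional-class calls for comparison with the prognostic classes).
    """
    if len(assignment) == 0 and len(labels) == 0:
        return pd.DataFrame()
    if set(assignment.index) != set(labels.index):
        raise AlignmentError("assignment and label sample ids differ")
    return pd.crosstab(
        assignment["subtype"], labels.loc[assignment.index], dropna=False
    )
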