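"""Functional annotation of the prognostic subtypes.

Differential expression between the invasive and mitotic subtypes (pooled-
variance two-sided t-test with Benjamini-Hochberg adjustment, DEG threshold
adjusted p < 0.001), Fisher's-exact over-representation analysis of DEG lists
against gene-set collections, Cohen's-kappa clustering of enriched terms, and
single-gene subtype markers from the PG ∩ DEG intersection.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import SUBTYPE_INVASIVE, SUBTYPE_MITOTIC, Cohort, GeneSet
from .errors import EstimationError
from .pg_selection import PGSelectionResult

logger = logging.getLogger(__name__)

DIRECTION_UP_INVASIVE = "up_in_invasive"
DIRECTION_UP_MITOTIC = "up_in_mitotic"


def fisher_exact_two_sided(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns (sample odds ratio a*d/(b*c), p). The p-value is the sum of the
    probabilities of all tables with the observed margins whose point
    probability does not exceed the observed table's. Shared by the ORA and
    clinical contingency routines so both use the identical exact test.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(odds), float(p)


def differential_expression(
    cohort: Cohort,
    assignment: pd.DataFrame,
    alpha_adj: float = 0.001,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene t-test between invasive and mitotic samples with BH-FDR.

    Intermediate samples are excluded. Returns a DataFrame indexed by gene id
    with columns mean_invasive, mean_mitotic, t_stat, p_raw, p_adj, direction,
    is_deg. Genes constant across both groups are skipped (counted in a log
    message). ``equal_var=False`` switches to Welch's t-test.
    """
    inv_ids = assignment.index[assignment["subtype"] == SUBTYPE_INVASIVE]
    mit_ids = assignment.index[assignment["subtype"] == SUBTYPE_MITOTIC]
    if len(inv_ids) < 2 or len(mit_ids) < 2:
        raise EstimationError(
            "need >= 2 invasive and >= 2 mitotic samples for the t-test "
            f"(got {len(inv_ids)}/{len(mit_ids)})"
        )
    a = cohort.expression[inv_ids].to_numpy(dtype=float)
    b = cohort.expression[mit_ids].to_numpy(dtype=float)
    testable = ~((np.ptp(a, axis=1) == 0) & (np.ptp(b, axis=1) == 0))
    n_skipped = int((~testable).sum())
    if n_skipped:
        logger.warning("skipping %d genes constant in both subtype groups", n_skipped)
    t_stat, p_raw = stats.ttest_ind(
        a[testable], b[testable], axis=1, equal_var=equal_var
    )
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    mean_a = a[testable].mean(axis=1)
    mean_b = b[testable].mean(axis=1)
    out = pd.DataFrame(
        {
            "mean_invasive": mean_a,
            "mean_mitotic": mean_b,
            "t_stat": t_stat,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": np.where(
                mean_a > mean_b, DIRECTION_UP_INVASIVE, DIRECTION_UP_MITOTIC
            ),
        },
        index=cohort.gene_ids[testable],
    )
    out["is_deg"] = out["p_adj"] < alpha_adj
    out.index.name = "gene_id"
    return out


@dataclass
class ORARecord:
    """Over-representation of one gene set in a DEG list."""

    set_name: str
    overlap: int
    set_size: int
    n_deg: int
    universe: int
    p_fisher: float
    enrichment_score: float  # -log10(p_fisher)
    group: str = ""


def fisher_ora(deg_genes, gene_set: GeneSet, universe) -> ORARecord:
    """Fisher's exact enrichment of a gene set in a DEG list over a universe."""
    uni = set(universe)
    if len(uni) < 2:
        raise ValueError("universe must contain at least two genes")
    degs = set(deg_genes) & uni
    members = gene_set.members & uni
    if not members:
        raise ValueError(f"set {gene_set.name!r} is disjoint from the universe")
    a = len(members & degs)
    b = len(members - degs)
    c = len(degs - members)
    d = len(uni) - a - b - c
    _, p = fisher_exact_two_sided([[a, b], [c, d]])
    return ORARecord(
        set_name=gene_set.name,
        overlap=a,
        set_size=len(members),
        n_deg=len(degs),
        universe=len(uni),
        p_fisher=p,
        enrichment_score=float(-np.log10(p)) if p > 0 else float("inf"),
    )


def run_ora_by_direction(
    degs: pd.DataFrame, collection, universe=None
) -> list[ORARecord]:
    """ORA of each gene set against both direction-specific DEG lists.

    Up-in-invasive DEGs annotate the "poor" group; up-in-mitotic the
    "favorable" group. The universe defaults to all genes tested for
    differential expression. Per-set failures are logged and skipped.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    uni = set(universe) if universe is not None else set(degs.index)
    records: list[ORARecord] = []
    flagged = degs[degs["is_deg"]]
    for group, direction in (
        ("poor", DIRECTION_UP_INVASIVE),
        ("favorable", DIRECTION_UP_MITOTIC),
    ):
        deg_list = set(flagged.index[flagged["direction"] == direction])
        for gene_set in collection:
            try:
                rec = fisher_ora(deg_list, gene_set, uni)
            except ValueError as exc:
                logger.warning("skipping set %s (%s): %s", gene_set.name, group, exc)
                continue
            rec.group = group
            records.append(rec)
    return records


def kappa_similarity(set_a: GeneSet, set_b: GeneSet, universe) -> float:
    """Cohen's kappa between two sets' membership indicators over a universe.

    An empty (within-universe) set yields 0 by convention (logged). Both sets
    equal to the whole universe leaves chance agreement at 1 and kappa
    undefined.
    """
    uni = set(universe)
    n = len(uni)
    if n == 0:
        raise ValueError("empty universe")
    a = set_a.members & uni
    b = set_b.members & uni
    if not a or not b:
        logger.warning("kappa with an empty set (%s/%s): 0 by convention",
                       set_a.name, set_b.name)
        return 0.0
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = n - n11 - n10 - n01
    po = (n11 + n00) / n
    pa, pb = len(a) / n, len(b) / n
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        raise ValueError("kappa undefined: both sets equal the whole universe")
    return float((po - pe) / (1 - pe))


def cluster_terms_by_kappa(
    records: list[ORARecord], collection, universe, threshold: float = 0.4
) -> list[list[str]]:
    """Single-linkage clusters of enriched terms by kappa similarity.

    Terms (unique set names among ``records``) are nodes; edges join pairs
    with kappa strictly above ``threshold``; clusters are the connected
    components, each sorted by name, components ordered by their first name.
    """
    import networkx as nx

    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    names = sorted({r.set_name for r in records})
    graph = nx.Graph()
    graph.add_nodes_from(names)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            if kappa_similarity(collection[na], collection[nb], universe) > threshold:
                graph.add_edge(na, nb)
    comps = [sorted(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: c[0])


@dataclass
class MarkerCandidate:
    """A PG that is also a DEG, with consistent directions."""

    gene_id: str
    pg_direction: str       # "poor" | "favorable"
    deg_direction: str
    effect_magnitude: float  # |t statistic|
    rank: int                # 1-based within its direction


def identify_markers(
    pgs: PGSelectionResult,
    degs: pd.DataFrame,
    exclude: set | None = None,
) -> list[MarkerCandidate]:
    """Single-gene subtype markers: PG ∩ DEG, ranked by |t| per direction.

    A poor PG must be up in invasive and a favorable PG up in mitotic to
    qualify; direction-inconsistent intersections are dropped (logged).
    ``exclude`` removes user-specified genes (e.g. secreted-protein products).
    """
    exclude = exclude or set()
    flagged = degs[degs["is_deg"]]
    out: list[MarkerCandidate] = []
    for pg_direction, genes, deg_direction in (
        ("poor", pgs.poor_genes, DIRECTION_UP_INVASIVE),
        ("favorable", pgs.favorable_genes, DIRECTION_UP_MITOTIC),
    ):
        hits = [g for g in genes if g in flagged.index and g not in exclude]
        consistent = []
        for g in hits:
            if flagged.loc[g, "direction"] == deg_direction:
                consistent.append(g)
            else:
                logger.warning(
                    "dropping %s: PG direction %s but DEG direction %s",
                    g, pg_direction, flagged.loc[g, "direction"],
                )
        ranked = sorted(
            consistent, key=lambda g: (-abs(float(flagged.loc[g, "t_stat"])), g)
        )
        for rank, g in enumerate(ranked, start=1):
            out.append(
                MarkerCandidate(
                    gene_id=g,
                    pg_direction=pg_direction,
                    deg_direction=deg_direction,
                    effect_magnitude=abs(float(flagged.loc[g, "t_stat"])),
                    rank=rank,
                )
            )
    if not out:
        logger.warning("PG and DEG lists do not intersect; no markers")
    return out
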