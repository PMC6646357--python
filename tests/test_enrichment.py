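"""Differential expression, Fisher ORA, kappa clustering, marker derivation."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gbmsubtypes import (
    GeneSet,
    GeneSetCollection,
    SUBTYPES,
    cluster_terms_by_kappa,
    differential_expression,
    fisher_exact_two_sided,
    fisher_ora,
    identify_markers,
    kappa_similarity,
    run_ora_by_direction,
)
from gbmsubtypes.errors import EstimationError
from gbmsubtypes.pg_selection import PGSelectionResult

from conftest import make_cohort


def _assignment(sample_ids, labels):
    return pd.DataFrame(
        {"prognosis_score": 0.0,
         "subtype": pd.Categorical(labels, categories=list(SUBTYPES))},
        index=sample_ids,
    )


def _two_group_cohort(n_genes=50, per_group=10, shift_gene=None, shift=5.0, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * per_group
    expr = rng.normal(0, 1, (n_genes, n))
    if shift_gene is not None:
        expr[shift_gene, :per_group] += shift
    cohort = make_cohort(expr, np.full(n, 10.0), np.ones(n, int))
    labels = ["invasive"] * per_group + ["mitotic"] * per_group
    return cohort, _assignment(list(cohort.sample_ids), labels)


class TestDifferentialExpression:
    def test_planted_shift_is_the_only_deg(self):
        cohort, assignment = _two_group_cohort(shift_gene=7)
        degs = differential_expression(cohort, assignment, alpha_adj=0.001)
        flagged = degs.index[degs["is_deg"]]
        assert list(flagged) == ["g007"]
        assert degs.loc["g007", "direction"] == "up_in_invasive"
        assert degs.loc["g007", "mean_invasive"] > degs.loc["g007", "mean_mitotic"]

    def test_matches_scipy_per_gene(self):
        cohort, assignment = _two_group_cohort(n_genes=5, seed=3)
        degs = differential_expression(cohort, assignment)
        inv = cohort.expression.iloc[:, :10].to_numpy()
        mit = cohort.expression.iloc[:, 10:].to_numpy()
        for i, gene in enumerate(cohort.gene_ids):
            t, p = stats.ttest_ind(inv[i], mit[i])
            assert degs.loc[gene, "t_stat"] == pytest.approx(t)
            assert degs.loc[gene, "p_raw"] == pytest.approx(p)
            assert degs.loc[gene, "p_adj"] >= degs.loc[gene, "p_raw"] - 1e-12

    def test_constant_gene_is_skipped(self):
        cohort, assignment = _two_group_cohort(n_genes=4, seed=1)
        cohort.expression.iloc[2] = 1.5
        degs = differential_expression(cohort, assignment)
        assert "g002" not in degs.index
        assert len(degs) == 3

    def test_direction_invariant_to_sample_order(self):
        cohort, assignment = _two_group_cohort(shift_gene=3, seed=2)
        degs1 = differential_expression(cohort, assignment)
        perm = np.random.default_rng(0).permutation(len(assignment))
        degs2 = differential_expression(cohort, assignment.iloc[perm])
        pd.testing.assert_series_equal(degs1["direction"], degs2["direction"])

    def test_requires_two_samples_per_subtype(self):
        cohort, assignment = _two_group_cohort(per_group=2)
        lone = assignment.copy()
        lone.iloc[0, lone.columns.get_loc("subtype")] = "intermediate"
        with pytest.raises(EstimationError):
            differential_expression(cohort, lone)


def enumeration_fisher_p(a, b, c, d):
    """Two-sided Fisher p by brute-force enumeration of all tables with the
    observed margins, summing point probabilities <= the observed one."""
    n = a + b + c + d
    r, col = a + b, a + c
    lo, hi = max(0, r + col - n), min(r, col)
    probs = {}
    from math import comb

    for x in range(lo, hi + 1):
        probs[x] = comb(r, x) * comb(n - r, col - x) / comb(n, col)
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestFisherOra:
    @pytest.mark.parametrize("table", [(3, 1, 1, 3), (5, 0, 2, 8), (2, 11, 8, 5)])
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        _, p = fisher_exact_two_sided([[a, b], [c, d]])
        assert p == pytest.approx(enumeration_fisher_p(a, b, c, d), abs=1e-12)

    def test_balanced_null_table_has_p_one(self):
        _, p = fisher_exact_two_sided([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_maximal_overlap_on_small_universe(self):
        universe = [f"u{i}" for i in range(20)]
        half = set(universe[:10])
        rec = fisher_ora(half, GeneSet.from_iterable("s", half), universe)
        assert rec.overlap == 10
        assert rec.p_fisher == pytest.approx(
            enumeration_fisher_p(10, 0, 0, 10), abs=1e-12
        )
        assert rec.enrichment_score == pytest.approx(-np.log10(rec.p_fisher))

    def test_disjoint_set_and_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_ora({"u1"}, GeneSet.from_iterable("s", ["zz"]), ["u1", "u2"])


class TestRunOraByDirection:
    def test_planted_invasion_set_is_collection_minimum(self):
        cohort, assignment = _two_group_cohort(n_genes=80, per_group=15, seed=4)
        invasion = [f"g{i:03d}" for i in range(10)]
        for i in range(10):
            cohort.expression.iloc[i, :15] += 4.0  # up in invasive samples
        degs = differential_expression(cohort, assignment, alpha_adj=0.01)
        collection = GeneSetCollection([
            GeneSet.from_iterable("invasion", invasion),
            GeneSet.from_iterable("random", [f"g{i:03d}" for i in range(40, 50)]),
        ])
        records = run_ora_by_direction(degs, collection)
        poor = {r.set_name: r for r in records if r.group == "poor"}
        assert poor["invasion"].p_fisher == min(r.p_fisher for r in poor.values())
        assert poor["invasion"].p_fisher < 0.001

    def test_empty_direction_yields_null_records(self):
        cohort, assignment = _two_group_cohort(n_genes=20, seed=5)
        degs = differential_expression(cohort, assignment)
        assert not degs["is_deg"].any()
        collection = GeneSetCollection(
            [GeneSet.from_iterable("s", [f"g{i:03d}" for i in range(5)])]
        )
        records = run_ora_by_direction(degs, collection)
        assert len(records) == 2
        assert all(r.overlap == 0 and r.p_fisher == pytest.approx(1.0)
                   for r in records)

    def test_set_outside_universe_is_skipped(self):
        cohort, assignment = _two_group_cohort(n_genes=20, seed=6)
        degs = differential_expression(cohort, assignment)
        collection = GeneSetCollection([
            GeneSet.from_iterable("inside", [f"g{i:03d}" for i in range(5)]),
            GeneSet.from_iterable("outside", ["none1", "none2"]),
        ])
        records = run_ora_by_direction(degs, collection)
        assert {r.set_name for r in records} == {"inside"}


class TestKappa:
    def test_identical_sets_have_unit_kappa(self):
        universe = [f"u{i}" for i in range(30)]
        s = GeneSet.from_iterable("a", universe[:6])
        assert kappa_similarity(s, s, universe) == pytest.approx(1.0)

    def test_disjoint_small_sets_match_closed_form(self):
        universe = [f"u{i}" for i in range(100)]
        a = GeneSet.from_iterable("a", universe[:5])
        b = GeneSet.from_iterable("b", universe[5:10])
        po = 90 / 100
        pe = 0.05 * 0.05 + 0.95 * 0.95
        assert kappa_similarity(a, b, universe) == pytest.approx((po - pe) / (1 - pe))

    def test_symmetry(self):
        universe = [f"u{i}" for i in range(50)]
        a = GeneSet.from_iterable("a", universe[:10])
        b = GeneSet.from_iterable("b", universe[5:20])
        assert kappa_similarity(a, b, universe) == pytest.approx(
            kappa_similarity(b, a, universe)
        )

    def test_empty_overlap_with_universe_is_zero_by_convention(self):
        universe = [f"u{i}" for i in range(10)]
        a = GeneSet.from_iterable("a", universe[:3])
        outside = GeneSet.from_iterable("b", ["zz1", "zz2"])
        assert kappa_similarity(a, outside, universe) == 0.0

    def test_full_universe_sets_are_undefined(self):
        universe = [f"u{i}" for i in range(10)]
        full = GeneSet.from_iterable("f", universe)
        with pytest.raises(ValueError):
            kappa_similarity(full, full, universe)


class TestClusterTerms:
    def _records(self, names):
        from gbmsubtypes.enrichment import ORARecord

        return [
            ORARecord(set_name=n, overlap=1, set_size=2, n_deg=1, universe=10,
                      p_fisher=0.5, enrichment_score=0.3)
            for n in names
        ]

    def test_dissimilar_terms_stay_singletons(self):
        universe = [f"u{i}" for i in range(60)]
        collection = GeneSetCollection([
            GeneSet.from_iterable("a", universe[:5]),
            GeneSet.from_iterable("b", universe[20:25]),
            GeneSet.from_iterable("c", universe[40:45]),
        ])
        clusters = cluster_terms_by_kappa(
            self._records(["a", "b", "c"]), collection, universe, 0.4
        )
        assert clusters == [["a"], ["b"], ["c"]]

    def test_identical_pair_clusters_apart_from_disjoint_term(self):
        universe = [f"u{i}" for i in range(40)]
        collection = GeneSetCollection([
            GeneSet.from_iterable("a", universe[:6]),
            GeneSet.from_iterable("b", universe[:6]),
            GeneSet.from_iterable("c", universe[20:26]),
        ])
        clusters = cluster_terms_by_kappa(
            self._records(["a", "b", "c"]), collection, universe, 0.4
        )
        assert clusters == [["a", "b"], ["c"]]

    def test_block_structure_matches_brute_force_components(self):
        universe = [f"u{i}" for i in range(60)]
        blocks = {
            "s1": universe[0:8], "s2": universe[2:10], "s3": universe[4:12],
            "s4": universe[30:38], "s5": universe[32:40], "s6": universe[50:58],
        }
        collection = GeneSetCollection(
            [GeneSet.from_iterable(n, g) for n, g in blocks.items()]
        )
        names = sorted(blocks)
        threshold = 0.4
        # brute-force union-find oracle
        parent = {n: n for n in names}

        def find(n):
            while parent[n] != n:
                n = parent[n]
            return n

        for i, na in enumerate(names):
            for nb in names[i + 1:]:
                if kappa_similarity(collection[na], collection[nb], universe) > threshold:
                    parent[find(nb)] = find(na)
        expected = {}
        for n in names:
            expected.setdefault(find(n), []).append(n)
        expected = sorted(sorted(v) for v in expected.values())
        clusters = cluster_terms_by_kappa(
            self._records(names), collection, universe, threshold
        )
        assert clusters == expected


class TestIdentifyMarkers:
    def _selection(self, poor, favorable):
        records = pd.DataFrame(
            {"pcc_a": 0.0, "pcc_b": 0.0, "concordant": True, "pcc_score": 0.0},
            index=pd.Index(poor + favorable, name="gene_id"),
        )
        return PGSelectionResult(records=records, poor_genes=poor,
                                 favorable_genes=favorable, k=len(poor))

    def _degs(self, rows):
        frame = pd.DataFrame(rows).set_index("gene_id")
        frame["is_deg"] = frame["is_deg"].astype(bool)
        return frame

    def test_deg_superset_yields_all_pgs_as_markers(self):
        sel = self._selection(["p1", "p2"], ["f1"])
        degs = self._degs([
            {"gene_id": "p1", "t_stat": 4.0, "direction": "up_in_invasive", "is_deg": True},
            {"gene_id": "p2", "t_stat": 6.0, "direction": "up_in_invasive", "is_deg": True},
            {"gene_id": "f1", "t_stat": -5.0, "direction": "up_in_mitotic", "is_deg": True},
        ])
        markers = identify_markers(sel, degs)
        assert len(markers) == 3
        poor = [m for m in markers if m.pg_direction == "poor"]
        assert [m.gene_id for m in poor] == ["p2", "p1"]  # ranked by |t|
        assert [m.rank for m in poor] == [1, 2]

    def test_disjoint_lists_give_no_markers(self):
        sel = self._selection(["p1"], ["f1"])
        degs = self._degs([
            {"gene_id": "x", "t_stat": 9.0, "direction": "up_in_invasive", "is_deg": True},
        ])
        assert identify_markers(sel, degs) == []

    def test_direction_inconsistent_genes_are_dropped(self):
        sel = self._selection(["p1"], ["f1"])
        degs = self._degs([
            {"gene_id": "p1", "t_stat": -4.0, "direction": "up_in_mitotic", "is_deg": True},
            {"gene_id": "f1", "t_stat": -5.0, "direction": "up_in_mitotic", "is_deg": True},
        ])
        markers = identify_markers(sel, degs)
        assert [m.gene_id for m in markers] == ["f1"]

    def test_exclusion_list_filters_markers(self):
        sel = self._selection(["p1", "p2"], [])
        degs = self._degs([
            {"gene_id": "p1", "t_stat": 4.0, "direction": "up_in_invasive", "is_deg": True},
            {"gene_id": "p2", "t_stat": 6.0, "direction": "up_in_invasive", "is_deg": True},
        ])
        markers = identify_markers(sel, degs, exclude={"p2"})
        assert [m.gene_id for m in markers] == ["p1"]

    def test_top_poor_marker_is_planted_on_simulated_cohort(self, pair7, selection7, scores7):
        cohort_a, _, truth = pair7
        from gbmsubtypes import assign_subtypes

        assignment = assign_subtypes(scores7)
        degs = differential_expression(cohort_a, assignment)
        markers = identify_markers(selection7, degs)
        top_poor = min(
            (m for m in markers if m.pg_direction == "poor"), key=lambda m: m.rank
        )
        assert top_poor.gene_id in truth.poor_planted
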