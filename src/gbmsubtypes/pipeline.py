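"""End-to-end orchestration: select -> score -> assign -> survival -> enrichment -> clinical.

The pipeline runs in one of two modes. With two discovery cohorts it selects
the prognosis-gene sets itself; with a pre-built PG GMT (for instance the
packaged published 40+40 signature) it skips selection and only scores,
assigns and annotates the target cohort. Every stage writes its artifact to
the output directory and the run ends with a machine-readable JSON report
(config hash, seed, per-stage row counts), so identical configurations
reproduce identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as gio
from .clinical import feature_enrichment, invasiveness_score_correlation, invasiveness_table
from .datatypes import SUBTYPE_INTERMEDIATE, SUBTYPE_INVASIVE, SUBTYPE_MITOTIC
from .enrichment import differential_expression, identify_markers, run_ora_by_direction
from .errors import GbmSubtypesError, StageError
from .pg_selection import select_pgs
from .ssgsea import SsgseaParams, score_cohort
from .subtypes import assign_subtypes, crosstab_subtypes, cutoff_sensitivity_scan
from .survival import cox_univariate, km_by_group, logrank_test, score_os_association

logger = logging.getLogger(__name__)

STAGES = ("select", "score", "assign", "survival", "enrichment", "clinical")


@dataclass
class PipelineConfig:
    """Plain-text-serializable configuration of a full run.

    Either both discovery cohorts (``expression_a``/``clinical_a`` and the
    ``_b`` pair) or ``pg_gmt`` must be given. The target cohort defaults to
    cohort A. Thresholds default to the published analysis settings: 40 genes
    per direction, ssGSEA exponent 0.25, subtype cutoffs -1/+1, DEG adjusted
    alpha 0.001, kappa threshold 0.4.
    """

    output_dir: str = "gbmsubtypes_run"
    expression_a: str | None = None
    clinical_a: str | None = None
    expression_b: str | None = None
    clinical_b: str | None = None
    target_expression: str | None = None
    target_clinical: str | None = None
    pg_gmt: str | None = None
    gene_sets_gmt: str | None = None
    areas: str | None = None
    pg_k: int = 40
    tau: float = 0.25
    cutoff_low: float = -1.0
    cutoff_high: float = 1.0
    alpha_deg: float = 0.001
    kappa_threshold: float = 0.4
    min_overlap: int = 5
    seed: int = 0

    def __post_init__(self):
        if not self.cutoff_low < self.cutoff_high:
            raise ValueError("cutoff_low must be < cutoff_high")
        if self.pg_k < 1:
            raise ValueError("pg_k must be >= 1")
        if not 0 < self.alpha_deg < 1:
            raise ValueError("alpha_deg must lie in (0, 1)")
        if not 0 < self.kappa_threshold < 1:
            raise ValueError("kappa_threshold must lie in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(report: dict, name: str):
    """Context wrapper converting stage failures into StageError."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": [],
    }
    params = SsgseaParams(tau=config.tau, min_overlap=config.min_overlap)

    def done(name: str, **outputs):
        report["stages"].append({"name": name, "status": "completed", "outputs": outputs})

    # -- stage 1: PG selection (or load a prebuilt signature) -----------------
    selection = None
    with _stage(report, "select"):
        if config.pg_gmt:
            collection = gio.read_gmt(config.pg_gmt)
            poor_name = next((n for n in collection.names if "poor" in n.lower()), None)
            fav_name = next(
                (n for n in collection.names if "favorable" in n.lower()), None
            )
            if poor_name is None or fav_name is None:
                raise GbmSubtypesError(
                    "PG GMT must contain one set named *poor* and one *favorable*"
                )
            poor_set, fav_set = collection[poor_name], collection[fav_name]
            done("select", mode="gmt", poor_genes=len(poor_set), favorable_genes=len(fav_set))
        else:
            if not (config.expression_a and config.clinical_a
                    and config.expression_b and config.clinical_b):
                raise GbmSubtypesError(
                    "need two discovery cohorts or a pg_gmt for scoring-only mode"
                )
            cohort_a = gio.read_cohort(config.expression_a, config.clinical_a, "cohort_a")
            cohort_b = gio.read_cohort(config.expression_b, config.clinical_b, "cohort_b")
            selection = select_pgs(cohort_a, cohort_b, k=config.pg_k)
            poor_set, fav_set = selection.gene_sets()
            gio.write_table(selection.records, out / "pg_records.tsv")
            from .datatypes import GeneSetCollection

            gio.write_gmt(
                GeneSetCollection([poor_set, fav_set]), out / "pg_sets.gmt"
            )
            done(
                "select",
                mode="dual-cohort",
                poor_genes=len(poor_set),
                favorable_genes=len(fav_set),
                records=len(selection.records),
            )

    # -- stage 2: ssGSEA scoring of the target cohort --------------------------
    with _stage(report, "score"):
        expr_path = config.target_expression or config.expression_a
        if not expr_path:
            raise GbmSubtypesError("no target expression matrix configured")
        expression = gio.read_expression(expr_path)
        from .datatypes import Cohort
        import pandas as pd

        # clinical is only needed from the survival stage onward
        placeholder = pd.DataFrame(
            {"os_months": 0.0, "event": 0}, index=expression.columns
        )
        scoring_cohort = Cohort(expression=expression, clinical=placeholder, name="target")
        scores = score_cohort(scoring_cohort, poor_set, fav_set, params=params)
        gio.write_table(scores, out / "scores.tsv")
        done("score", samples=len(scores))

    # -- stage 3: subtype assignment -------------------------------------------
    with _stage(report, "assign"):
        assignment = assign_subtypes(scores, config.cutoff_low, config.cutoff_high)
        gio.write_table(assignment, out / "subtypes.tsv")
        counts = assignment["subtype"].value_counts().to_dict()
        done("assign", **{str(k): int(v) for k, v in counts.items()})

    # -- stage 4: survival statistics -------------------------------------------
    with _stage(report, "survival"):
        clin_path = config.target_clinical or config.clinical_a
        if not clin_path:
            raise GbmSubtypesError("no clinical table configured")
        clinical = gio.read_clinical(clin_path)
        target = gio.read_cohort(expr_path, clin_path, "target")
        os_v = target.os_months.loc[assignment.index].to_numpy()
        ev = target.event.loc[assignment.index].to_numpy()
        groups = assignment["subtype"].astype(str).to_numpy()
        survival_summary: dict = {}
        curves = km_by_group(os_v, ev, groups)
        km_rows = []
        for label, curve in curves.items():
            for t, s, r, d in zip(curve.times, curve.survival, curve.at_risk, curve.n_events):
                km_rows.append(
                    {"group": label, "time": t, "survival": s, "at_risk": r, "events": d}
                )
        import pandas as pd

        gio.write_table(pd.DataFrame(km_rows).set_index("group"), out / "km_curves.tsv")
        if len(set(groups)) >= 2 and ev.sum() > 0:
            lr = logrank_test(os_v, ev, groups)
            survival_summary["logrank_p"] = lr.p_value
            survival_summary["logrank_chi_square"] = lr.chi_square
        cox = cox_univariate(os_v, ev, assignment["prognosis_score"].to_numpy())
        survival_summary.update(
            hr=cox.hr, hr_ci_low=cox.ci95[0], hr_ci_high=cox.ci95[1], n_events=cox.n_events
        )
        r, slope, intercept, p = score_os_association(
            assignment["prognosis_score"].to_numpy(), os_v
        )
        survival_summary.update(score_os_r=r, score_os_p=p)
        scan = cutoff_sensitivity_scan(scores, target)
        gio.write_table(scan.table.set_index("cutoff"), out / "cutoff_scan.tsv")
        with open(out / "survival.json", "w") as fh:
            json.dump(survival_summary, fh, indent=1, sort_keys=True)
        done("survival", groups=len(curves), **{
            k: v for k, v in survival_summary.items() if k in ("logrank_p", "hr")
        })

    # -- stage 5: differential expression, ORA, markers -------------------------
    with _stage(report, "enrichment"):
        degs = differential_expression(target, assignment, alpha_adj=config.alpha_deg)
        gio.write_table(degs, out / "degs.tsv")
        outputs = {"genes_tested": len(degs), "n_deg": int(degs["is_deg"].sum())}
        if config.gene_sets_gmt:
            collection = gio.read_gmt(config.gene_sets_gmt)
            records = run_ora_by_direction(degs, collection)
            import pandas as pd

            ora_frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
            gio.write_table(ora_frame.set_index("set_name"), out / "ora.tsv")
            outputs["ora_records"] = len(records)
        if selection is not None:
            markers = identify_markers(selection, degs)
            import pandas as pd

            marker_frame = pd.DataFrame([dataclasses.asdict(m) for m in markers])
            if len(marker_frame):
                marker_frame = marker_frame.set_index("gene_id")
            gio.write_table(marker_frame, out / "markers.tsv")
            outputs["markers"] = len(markers)
        done("enrichment", **outputs)

    # -- stage 6: clinical metrics ----------------------------------------------
    with _stage(report, "clinical"):
        outputs = {}
        contingency: dict = {}
        if "mgmt_methylated" in clinical.columns:
            res = feature_enrichment(
                assignment, clinical["mgmt_methylated"],
                group_a=SUBTYPE_INVASIVE, group_b=SUBTYPE_MITOTIC,
            )
            contingency["mgmt"] = {
                "table": res.table.to_numpy().tolist(),
                "odds_ratio": res.odds_ratio,
                "p_fisher": res.p_fisher,
                "corrected": res.corrected,
            }
            outputs["mgmt_odds_ratio"] = res.odds_ratio
        if config.areas:
            import pandas as pd

            areas = pd.read_csv(config.areas, sep="\t", index_col=0)
            inv = invasiveness_table(areas)
            gio.write_table(inv.to_frame(), out / "invasiveness.tsv")
            shared = inv.index.intersection(assignment.index)
            if len(shared) >= 3:
                r, p = invasiveness_score_correlation(
                    inv.loc[shared].to_numpy(),
                    assignment.loc[shared, "prognosis_score"].to_numpy(),
                )
                contingency["invasiveness_score_r"] = r
                contingency["invasiveness_score_p"] = p
                outputs["invasiveness_samples"] = int(len(shared))
        if "external_subtype" in clinical.columns:
            table = crosstab_subtypes(
                assignment, clinical["external_subtype"].loc[assignment.index]
            )
            gio.write_table(table, out / "subtype_crosstab.tsv")
            outputs["crosstab_cells"] = int(table.size)
        with open(out / "clinical.json", "w") as fh:
            json.dump(contingency, fh, indent=1, sort_keys=True)
        outputs.setdefault("records", len(contingency))
        done("clinical", **outputs)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
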