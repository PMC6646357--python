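"""Reading and writing the pipeline's plain-text formats.

Expression matrices: tab-separated (genes x samples, first column = gene id)
or GCT 1.2 ("#1.2" header, dimensions line, Name/Description columns).
Gene sets: GMT (name, description, genes, tab-separated). Clinical tables,
scores and assignments: TSV with one header row; missing values as "NA".
"""
from __future__ import annotations

import importlib.resources
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import Cohort, GeneSet, GeneSetCollection, GroundTruth
from .errors import FormatError

logger = logging.getLogger(__name__)

NA = "NA"


# --------------------------------------------------------------------------
# expression matrices
# --------------------------------------------------------------------------
def read_expression(path, format: str = "auto") -> pd.DataFrame:
    """Load a genes-x-samples matrix from TSV or GCT 1.2.

    ``format="auto"`` infers from the file extension (.gct -> GCT).
    Duplicate gene or sample identifiers raise :class:`FormatError`.
    """
    path = Path(path)
    if format == "auto":
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        frame = _read_gct(path)
    elif format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"duplicate gene identifier {dup!r} in {path}")
    if frame.columns.has_duplicates:
        raise FormatError(f"duplicate sample identifier in {path}")
    frame.index = frame.index.astype(str)
    frame.index.name = "gene_id"
    return frame.astype(float)


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise FormatError(f"{path}: malformed GCT dimensions line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t")
    if body.shape[0] != n_genes or body.shape[1] - 2 != n_samples:
        raise FormatError(
            f"{path}: dimensions line says {n_genes}x{n_samples}, body is "
            f"{body.shape[0]}x{body.shape[1] - 2}"
        )
    body = body.set_index(body.columns[0])
    return body.drop(columns=[body.columns[0]])


def write_expression(frame: pd.DataFrame, path, format: str = "auto") -> None:
    path = Path(path)
    if format == "auto":
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{frame.shape[0]}\t{frame.shape[1]}\n")
            out = frame.copy()
            out.insert(0, "Description", NA)
            out.index.name = "Name"
            out.to_csv(fh, sep="\t", na_rep=NA)
    else:
        frame.to_csv(path, sep="\t", na_rep=NA)


# --------------------------------------------------------------------------
# gene sets (GMT)
# --------------------------------------------------------------------------
def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file; duplicate genes within a set are dropped (warned)."""
    sets = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
                )
            name, source = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if len(set(genes)) != len(genes):
                logger.warning(
                    "%s:%d: duplicate genes in set %r de-duplicated", path, lineno, name
                )
            sets.append(GeneSet.from_iterable(name, genes, source=source))
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            desc = s.source or NA
            fh.write("\t".join([s.name, desc, *s.genes]) + "\n")


def load_published_pg_sets() -> GeneSetCollection:
    """The packaged published 40+40 GBM prognostic gene sets (symbols)."""
    ref = importlib.resources.files("gbmsubtypes.data") / "pg_signature.gmt"
    with importlib.resources.as_file(ref) as p:
        return read_gmt(p)


def load_published_pg_table() -> pd.DataFrame:
    """Packaged PG signature table with entrez, symbol and direction columns."""
    ref = importlib.resources.files("gbmsubtypes.data") / "pg_signature.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", dtype={"entrez": str})


# --------------------------------------------------------------------------
# clinical tables, scores, assignments, cohorts
# --------------------------------------------------------------------------
def read_clinical(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    if frame.index.has_duplicates:
        raise FormatError(f"duplicate sample identifier in {path}")
    frame.index = frame.index.astype(str)
    frame.index.name = "sample_id"
    return frame


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", na_rep=NA)


def read_cohort(expression_path, clinical_path, name: str = "cohort") -> Cohort:
    return Cohort(
        expression=read_expression(expression_path),
        clinical=read_clinical(clinical_path),
        name=name,
    )


def write_cohort(cohort: Cohort, directory, prefix: str | None = None,
                 expression_format: str = "tsv") -> dict:
    """Write a cohort's expression + clinical tables; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = prefix or cohort.name
    ext = "gct" if expression_format == "gct" else "tsv"
    expr_path = directory / f"{prefix}_expression.{ext}"
    clin_path = directory / f"{prefix}_clinical.tsv"
    write_expression(cohort.expression, expr_path, format=expression_format)
    write_table(cohort.clinical, clin_path)
    return {"expression": str(expr_path), "clinical": str(clin_path)}


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "poor_planted": sorted(truth.poor_planted),
        "favorable_planted": sorted(truth.favorable_planted),
        "per_sample_latent_risk": {
            str(k): float(v) for k, v in truth.per_sample_latent_risk.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    risk = pd.Series(payload["per_sample_latent_risk"], dtype=float)
    return GroundTruth(
        poor_planted=frozenset(payload["poor_planted"]),
        favorable_planted=frozenset(payload["favorable_planted"]),
        per_sample_latent_risk=risk,
    )
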