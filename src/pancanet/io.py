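"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything is TSV, GMT or YAML so that inputs and outputs stay diffable and
round-trip exactly: expression matrices (genes x samples, with a sidecar
sample -> group table), interactome edge lists, regulon tables, GMT
annotations, survival cohorts and DEG/consensus result tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .core import (
    DegTable,
    ExpressionStudy,
    MalformedInputError,
    RegulonEdge,
    SurvivalCohort,
)
from .synth import AnnotationSet


# -- expression studies -----------------------------------------------------

def write_expression(study: ExpressionStudy, path, labels_path) -> None:
    frame = study.values.copy()
    frame.insert(0, "gene", frame.index)
    frame.to_csv(path, sep="\t", index=False)
    labels = pd.DataFrame({"sample": study.groups.index, "group": study.groups.values})
    labels.to_csv(labels_path, sep="\t", index=False)


def read_expression(
    path, labels_path, technology: str, cancer_type: str, dataset_id: str
) -> ExpressionStudy:
    frame = pd.read_csv(path, sep="\t")
    if "gene" not in frame.columns:
        raise MalformedInputError(f"{path}: expected a 'gene' first column")
    frame = frame.set_index("gene")
    labels = pd.read_csv(labels_path, sep="\t")
    groups = pd.Series(labels["group"].values, index=labels["sample"].values, name="group")
    return ExpressionStudy(
        values=frame, groups=groups, technology=technology,
        cancer_type=cancer_type, dataset_id=dataset_id,
    )


# -- interactome edge lists -------------------------------------------------

def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges[["node_a", "node_b", "confidence"]].to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    required = {"node_a", "node_b", "confidence"}
    if not required <= set(edges.columns):
        raise MalformedInputError(f"{path}: expected columns {sorted(required)}")
    return edges


# -- regulons ---------------------------------------------------------------

def write_regulons(regulons: Iterable[RegulonEdge], path) -> None:
    frame = pd.DataFrame(regulons, columns=["tf", "target", "mode"])
    frame.to_csv(path, sep="\t", index=False)


def read_regulons(path) -> list[RegulonEdge]:
    frame = pd.read_csv(path, sep="\t")
    if not {"tf", "target", "mode"} <= set(frame.columns):
        raise MalformedInputError(f"{path}: expected columns tf, target, mode")
    return [RegulonEdge(r.tf, r.target, r.mode) for r in frame.itertuples(index=False)]


# -- GMT annotations --------------------------------------------------------

def write_gmt(annotations: AnnotationSet, path) -> None:
    """GMT: term <TAB> description (used for the category) <TAB> genes..."""
    with open(path, "w") as fh:
        for term in annotations.terms:
            category = annotations.categories.get(term, "")
            genes = "\t".join(annotations.terms[term])
            fh.write(f"{term}\t{category}\t{genes}\n")


def read_gmt(path) -> AnnotationSet:
    terms: dict[str, list[str]] = {}
    categories: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise MalformedInputError(f"{path}: malformed GMT line {line[:40]!r}")
            terms[parts[0]] = parts[2:]
            categories[parts[0]] = parts[1]
    return AnnotationSet(terms=terms, categories=categories)


# -- survival cohorts -------------------------------------------------------

def write_survival(cohort: SurvivalCohort, path) -> None:
    frame = cohort.data.copy()
    frame.insert(0, "sample", frame.index)
    frame.to_csv(path, sep="\t", index=False)


def read_survival(path, cancer_type: str = "synthetic") -> SurvivalCohort:
    frame = pd.read_csv(path, sep="\t")
    if "sample" not in frame.columns:
        raise MalformedInputError(f"{path}: expected a 'sample' first column")
    frame = frame.set_index("sample")
    return SurvivalCohort(data=frame, cancer_type=cancer_type)


# -- DEG tables -------------------------------------------------------------

def write_deg_table(table: DegTable, path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_deg_table(path, cancer_type: str, technology: str, dataset_id: str) -> DegTable:
    records = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "p", "p_adj", "direction", "significant"}
    if not required <= set(records.columns):
        raise MalformedInputError(f"{path}: expected columns {sorted(required)}")
    return DegTable(records, cancer_type, technology, dataset_id)


# -- panel manifest ---------------------------------------------------------

def write_manifest(entries: Sequence[Mapping[str, str]], path) -> None:
    """Manifest: list of {dataset_id, cancer_type, technology, expression,
    labels} with paths relative to the manifest's directory."""
    with open(path, "w") as fh:
        yaml.safe_dump({"datasets": list(entries)}, fh, sort_keys=False)


def read_manifest(path) -> list[dict[str, str]]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "datasets" not in doc:
        raise MalformedInputError(f"{path}: expected a 'datasets' list")
    return list(doc["datasets"])


def read_panel(manifest_path) -> list[ExpressionStudy]:
    """Load every study listed in a manifest (paths relative to it)."""
    base = Path(manifest_path).parent
    studies = []
    for entry in read_manifest(manifest_path):
        studies.append(read_expression(
            base / entry["expression"], base / entry["labels"],
            technology=entry["technology"], cancer_type=entry["cancer_type"],
            dataset_id=entry["dataset_id"],
        ))
    return studies
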