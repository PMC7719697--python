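"""Shared containers and exceptions for the pan-cancer consensus pipeline.

The pipeline passes around a small number of in-memory objects: per-dataset
two-group expression studies, per-dataset differential-expression (DEG)
tables tagged with a cancer type and technology, directed regulon edges, and
per-cohort survival tables. They are thin dataclasses around pandas objects
so that every stage stays inspectable and serializable to plain TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import pandas as pd

MICROARRAY = "microarray"
RNASEQ = "rnaseq"
TECHNOLOGIES = (MICROARRAY, RNASEQ)

OVER = "over"
UNDER = "under"
DIRECTIONS = (OVER, UNDER)

REGULATION_MODES = ("activation", "repression", "unknown")


class InvalidParameterError(ValueError):
    """A parameter is outside its documented legal range."""


class MalformedInputError(ValueError):
    """An input table violates its documented structure (missing flags,
    negative counts, ...)."""


class EmptyIntersectionError(ValueError):
    """Platform merging produced an empty shared gene set."""


class DegenerateGroupingError(ValueError):
    """Quartile grouping cannot be formed (e.g. constant expression)."""


class NonConvergenceError(RuntimeError):
    """An iterative numerical routine failed to converge."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class ExpressionStudy:
    """One two-group dataset: a genes x samples matrix plus group labels.

    ``values`` holds log2 intensities for microarray studies and raw
    non-negative counts for RNA-seq studies; ``groups`` maps every sample
    (column) to ``"tumor"`` or ``"normal"``.
    """

    values: pd.DataFrame
    groups: pd.Series
    technology: str
    cancer_type: str
    dataset_id: str

    def __post_init__(self) -> None:
        if self.technology not in TECHNOLOGIES:
            raise InvalidParameterError(
                f"unknown technology {self.technology!r}; expected one of {TECHNOLOGIES}"
            )
        if list(self.values.columns) != list(self.groups.index):
            raise MalformedInputError(
                f"study {self.dataset_id}: sample columns and group labels disagree"
            )
        bad = set(self.groups.unique()) - {"tumor", "normal"}
        if bad:
            raise MalformedInputError(
                f"study {self.dataset_id}: unknown group labels {sorted(bad)}"
            )

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "tumor"])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "normal"])


@dataclass
class DegTable:
    """Per-dataset DEG calls tagged with cancer type and technology.

    ``records`` columns: gene, log2fc, p, p_adj, direction, significant.
    """

    records: pd.DataFrame
    cancer_type: str
    technology: str
    dataset_id: str

    def significant_genes(self, direction: str | None = None) -> set[str]:
        rec = self.records[self.records["significant"]]
        if direction is not None:
            rec = rec[rec["direction"] == direction]
        return set(rec["gene"])


class RegulonEdge(NamedTuple):
    """Directed TF -> target regulatory relation with a regulation mode."""

    tf: str
    target: str
    mode: str


@dataclass
class SurvivalCohort:
    """Per-patient follow-up times, event indicators and gene expression.

    ``data`` is indexed by patient id with columns ``time`` (non-negative,
    one unit across the cohort), ``event`` (1 = death observed, 0 =
    censored) and one ``expr_<gene>`` column per gene.
    """

    data: pd.DataFrame
    cancer_type: str = "synthetic"

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise MalformedInputError(f"survival cohort lacks a {col!r} column")
        if (self.data["time"] < 0).any():
            raise MalformedInputError("survival times must be non-negative")

    @property
    def genes(self) -> list[str]:
        return [c[len("expr_"):] for c in self.data.columns if c.startswith("expr_")]

    def expression(self, gene: str) -> pd.Series:
        return self.data[f"expr_{gene}"]


@dataclass
class SynthStudyPanel:
    """A bundle of synthetic studies plus the planted ground truth.

    ``truth`` maps direction -> gene -> set of cancer types in which the
    gene was planted as a DEG of that direction.
    """

    studies: list[ExpressionStudy] = field(default_factory=list)
    truth: Mapping[str, Mapping[str, set[str]]] = field(default_factory=dict)

    def by_technology(self, technology: str) -> list[ExpressionStudy]:
        return [s for s in self.studies if s.technology == technology]
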