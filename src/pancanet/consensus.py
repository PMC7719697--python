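"""Probe collapsing, platform merging and the cross-cancer frequency consensus.

The consensus layer turns per-dataset DEG tables into a pan-cancer picture:

* a gene is *frequent* for a technology when it is a significant DEG of a
  given direction in at least a threshold number of distinct cancer types
  (6 for microarray, 3 for RNA-seq by default) — a cancer type counts once
  no matter how many of its datasets contain the DEG;
* the consensus gene list is the per-direction intersection of the two
  technologies' frequent sets ("shared by both"); genes frequent with
  opposite directions in the two technologies are excluded and reported;
* per-cancer-type DEG sets are screened pairwise with the Jaccard index,
  flagging pairs at or above 15% similarity;
* the machine-learning feature filter keeps features selected in at least
  3 cancer types with at least 5 total hits across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    DIRECTIONS,
    MICROARRAY,
    OVER,
    RNASEQ,
    UNDER,
    DegTable,
    EmptyIntersectionError,
    InvalidParameterError,
)

DEFAULT_FREQUENCY_THRESHOLDS: dict[str, int] = {MICROARRAY: 6, RNASEQ: 3}
DEFAULT_JACCARD_THRESHOLD = 0.15


def collapse_probes(
    matrix: pd.DataFrame, probe_map: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    For each gene, probes assigned to that single gene ("specific" probes)
    are prioritized over multi-gene probes; among equally specific probes
    the first occurrence in input row order wins. Probes with no gene
    assignment are dropped. Output rows are in sorted gene-id order.
    """
    missing = [p for p in matrix.index if p not in probe_map]
    if missing:
        raise InvalidParameterError(
            f"probes missing from the probe map: {missing[:5]}"
        )
    chosen: dict[str, tuple[int, int]] = {}  # gene -> (specificity rank, row)
    for row, probe in enumerate(matrix.index):
        genes = list(probe_map[probe])
        if not genes:
            continue
        rank = 0 if len(genes) == 1 else 1  # specific probes beat multi-gene ones
        for gene in genes:
            if gene not in chosen or (rank, row) < chosen[gene]:
                chosen[gene] = (rank, row)
    genes_sorted = sorted(chosen)
    out = matrix.iloc[[chosen[g][1] for g in genes_sorted]].copy()
    out.index = pd.Index(genes_sorted, name="gene")
    return out


def merge_platforms(
    matrices: Sequence[pd.DataFrame], names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Column-concatenate gene-level matrices on their shared gene set.

    Gene ids not present in every matrix are removed; rows come out in
    sorted gene-id order and sample ids are provenance-tagged
    ``<name>:<sample>``.
    """
    if not matrices:
        raise InvalidParameterError("at least one matrix is required")
    if names is None:
        names = [f"p{i}" for i in range(len(matrices))]
    for m in matrices:
        if m.index.has_duplicates:
            raise InvalidParameterError("matrices must have unique gene ids")
    shared = set(matrices[0].index)
    for m in matrices[1:]:
        shared &= set(m.index)
    if not shared:
        raise EmptyIntersectionError("no gene ids shared by all matrices")
    order = sorted(shared)
    pieces = []
    for name, m in zip(names, matrices):
        piece = m.loc[order].copy()
        piece.columns = [f"{name}:{c}" for c in piece.columns]
        pieces.append(piece)
    merged = pd.concat(pieces, axis=1)
    merged.index.name = "gene"
    return merged


@dataclass
class ConsensusTable:
    """Per (gene, direction, technology): the cancer types hit and the
    frequent flag. ``table`` columns: gene, direction, technology,
    cancer_types (';'-joined, sorted), n_types, frequent."""

    table: pd.DataFrame
    thresholds: dict[str, int]

    def frequent_sets(self, technology: str) -> dict[str, set[str]]:
        """Direction -> set of frequent genes for one technology."""
        sub = self.table[
            (self.table["technology"] == technology) & self.table["frequent"]
        ]
        return {
            d: set(sub.loc[sub["direction"] == d, "gene"]) for d in DIRECTIONS
        }


def frequency_consensus(
    deg_tables: Iterable[DegTable],
    thresholds: Mapping[str, int] | None = None,
) -> ConsensusTable:
    """Tally, per (gene, direction, technology), the distinct cancer types in
    which the gene is a significant DEG, and flag frequent genes.

    Duplicated datasets within a cancer type do not inflate the tally; over
    and under directions are counted separately.
    """
    thresholds = dict(thresholds or DEFAULT_FREQUENCY_THRESHOLDS)
    for t, v in thresholds.items():
        if v <= 0:
            raise InvalidParameterError(f"threshold for {t!r} must be positive")
    hits: dict[tuple[str, str, str], set[str]] = {}
    for table in deg_tables:
        if table.technology not in thresholds:
            raise InvalidParameterError(
                f"dataset {table.dataset_id}: unknown technology {table.technology!r}"
            )
        for direction in DIRECTIONS:
            for gene in table.significant_genes(direction):
                key = (gene, direction, table.technology)
                hits.setdefault(key, set()).add(table.cancer_type)
    rows = [
        {
            "gene": gene,
            "direction": direction,
            "technology": technology,
            "cancer_types": ";".join(sorted(types)),
            "n_types": len(types),
            "frequent": len(types) >= thresholds[technology],
        }
        for (gene, direction, technology), types in sorted(hits.items())
    ]
    table = pd.DataFrame(
        rows,
        columns=["gene", "direction", "technology", "cancer_types", "n_types", "frequent"],
    )
    return ConsensusTable(table=table, thresholds=thresholds)


@dataclass
class TechnologyConsensus:
    """Cross-technology consensus: per-direction shared gene lists plus the
    direction-conflict report."""

    genes: dict[str, list[str]]
    conflicts: list[str] = field(default_factory=list)

    def all_genes(self) -> list[str]:
        return sorted(set(self.genes[OVER]) | set(self.genes[UNDER]))


def combine_technologies(
    microarray_frequent: Mapping[str, set[str]],
    rnaseq_frequent: Mapping[str, set[str]],
) -> TechnologyConsensus:
    """Per-direction intersection of the two technologies' frequent sets.

    A gene frequent as over in one technology and under in the other is
    excluded from both directions and listed in the conflict report.
    """
    m_over = set(microarray_frequent.get(OVER, set()))
    m_under = set(microarray_frequent.get(UNDER, set()))
    r_over = set(rnaseq_frequent.get(OVER, set()))
    r_under = set(rnaseq_frequent.get(UNDER, set()))
    conflicts = (m_over & r_under) | (m_under & r_over)
    return TechnologyConsensus(
        genes={
            OVER: sorted((m_over & r_over) - conflicts),
            UNDER: sorted((m_under & r_under) - conflicts),
        },
        conflicts=sorted(conflicts),
    )


@dataclass
class JaccardMatrix:
    """Symmetric pairwise Jaccard similarities over cancer types."""

    matrix: pd.DataFrame
    threshold: float = DEFAULT_JACCARD_THRESHOLD

    @property
    def flagged_pairs(self) -> list[tuple[str, str, float]]:
        """Unordered pairs (a < b) at or above the similarity threshold."""
        out = []
        labels = list(self.matrix.index)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                v = float(self.matrix.loc[a, b])
                if v >= self.threshold:
                    out.append((a, b, v))
        return out


def jaccard_matrix(
    sets: Mapping[str, set[str]], threshold: float = DEFAULT_JACCARD_THRESHOLD
) -> JaccardMatrix:
    """J(A,B) = |A∩B| / |A∪B| over all pairs; two empty sets score 0 by
    convention, and the diagonal is 1 for non-empty sets."""
    labels = sorted(sets)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i:]:
            union = sets[a] | sets[b]
            value = len(sets[a] & sets[b]) / len(union) if union else 0.0
            mat.loc[a, b] = mat.loc[b, a] = value
    mat.index.name = "cancer_type"
    return JaccardMatrix(matrix=mat, threshold=threshold)


def feature_frequency_filter(
    selected_features: Mapping[str, Sequence[tuple[str, int]]],
    min_types: int = 3,
    min_hits: int = 5,
) -> list[str]:
    """Keep ML-selected features found in >= min_types cancer types with
    >= min_hits total hits across folds (both gates must pass).

    Sorted by number of cancer types, ties by total hits (both descending),
    then lexicographically.
    """
    types: dict[str, set[str]] = {}
    hits: dict[str, int] = {}
    for cancer_type, features in selected_features.items():
        for feature, count in features:
            if count < 0:
                raise InvalidParameterError("hit counts must be non-negative")
            types.setdefault(feature, set()).add(cancer_type)
            hits[feature] = hits.get(feature, 0) + int(count)
    kept = [
        f for f in hits if len(types[f]) >= min_types and hits[f] >= min_hits
    ]
    return sorted(kept, key=lambda f: (-len(types[f]), -hits[f], f))
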