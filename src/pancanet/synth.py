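"""Synthetic input generators with planted ground truth.

Every input the pipeline consumes — two-group expression studies, a
STRING-like weighted interactome, a TRRUST-like regulon table, GMT term
annotations and survival cohorts — can be generated here with known planted
structure, so every downstream stage is testable without any download.

All generators are pure functions of their parameters and a seed: the same
call yields byte-identical output.

Microarray studies are drawn as Gaussian log2 intensities around per-gene
baselines, with the planted signed effect (in log2 fold-change units) added
to the tumor group. RNA-seq studies are drawn as negative-binomial counts
parameterized by (mean, dispersion) with variance mean + dispersion * mean^2
and a constant dispersion across genes; a planted effect of e log2 units
multiplies the tumor-group mean by 2**e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    MICROARRAY,
    OVER,
    RNASEQ,
    TECHNOLOGIES,
    UNDER,
    ExpressionStudy,
    InvalidParameterError,
    RegulonEdge,
    SurvivalCohort,
    SynthStudyPanel,
)

# Cancer-type vocabulary for the synthetic panels. The microarray panel
# covers 13 solid-tumor types and the RNA-seq panel 8, matching the scale of
# multi-cancer curation efforts (skin/uterine lack microarray representation;
# bone, bladder, pancreatic, brain, gastric and ovarian lack RNA-seq).
CANCER_TYPES = (
    "bladder", "bone", "brain", "breast", "colorectal", "gastric",
    "head_neck", "liver", "lung", "ovarian", "pancreatic", "prostate",
    "renal", "skin", "uterine",
)
MICROARRAY_TYPES = (
    "bladder", "bone", "brain", "breast", "colorectal", "gastric",
    "head_neck", "liver", "lung", "ovarian", "pancreatic", "prostate",
    "renal",
)
RNASEQ_TYPES = (
    "breast", "colorectal", "head_neck", "liver", "lung", "prostate",
    "renal", "skin",
)


def default_gene_universe(n_genes: int) -> list[str]:
    """Gene ids G0001..G<n> used by all synthetic fixtures."""
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


@dataclass(frozen=True)
class SynthExpressionConfig:
    """Parameters of one synthetic two-group expression study.

    ``planted_deg`` maps gene id to a signed effect in log2 fold-change
    units (positive = higher in tumor). ``baseline_dispersion`` is the
    negative-binomial dispersion for RNA-seq and the per-observation noise
    standard deviation in log2 units for microarray.
    """

    n_genes: int
    n_tumor: int
    n_normal: int
    technology: str
    planted_deg: Mapping[str, float] = field(default_factory=dict)
    baseline_dispersion: float = 1.0
    seed: int = 0
    cancer_type: str = "synthetic"
    dataset_id: str = "SYN000001"
    gene_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise InvalidParameterError("n_genes must be positive")
        if self.n_tumor < 3 or self.n_normal < 3:
            raise InvalidParameterError(
                "at least three tumor and three normal samples are required"
            )
        if self.technology not in TECHNOLOGIES:
            raise InvalidParameterError(f"unknown technology {self.technology!r}")
        if self.baseline_dispersion <= 0:
            raise InvalidParameterError("baseline_dispersion must be positive")
        genes = self.genes()
        if len(genes) != self.n_genes:
            raise InvalidParameterError("gene_ids length must equal n_genes")
        missing = set(self.planted_deg) - set(genes)
        if missing:
            raise InvalidParameterError(
                f"planted genes outside the universe: {sorted(missing)[:5]}"
            )

    def genes(self) -> list[str]:
        if self.gene_ids is not None:
            return list(self.gene_ids)
        return default_gene_universe(self.n_genes)


def gen_expression_study(config: SynthExpressionConfig) -> ExpressionStudy:
    """Draw one two-group study according to ``config``.

    Microarray: normal samples ~ N(baseline_g, sd); tumor samples
    ~ N(baseline_g + effect_g, sd), all on the log2 scale. RNA-seq:
    NB(mean_g, dispersion) counts with tumor mean mean_g * 2**effect_g.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.genes()
    effects = np.array([config.planted_deg.get(g, 0.0) for g in genes])
    n_t, n_n = config.n_tumor, config.n_normal
    tumor_cols = [f"T{i:03d}" for i in range(1, n_t + 1)]
    normal_cols = [f"N{i:03d}" for i in range(1, n_n + 1)]

    if config.technology == MICROARRAY:
        baselines = rng.normal(8.0, 2.0, size=len(genes))
        sd = config.baseline_dispersion
        tumor = rng.normal(
            (baselines + effects)[:, None], sd, size=(len(genes), n_t)
        )
        normal = rng.normal(baselines[:, None], sd, size=(len(genes), n_n))
        values = np.hstack([tumor, normal])
    else:
        base_mean = rng.lognormal(mean=math.log(100.0), sigma=1.0, size=len(genes))
        disp = config.baseline_dispersion
        n_param = 1.0 / disp  # variance = mu + disp * mu^2
        tumor_mean = base_mean * np.exp2(effects)
        tumor = rng.negative_binomial(
            n_param, n_param / (n_param + tumor_mean[:, None]), size=(len(genes), n_t)
        )
        normal = rng.negative_binomial(
            n_param, n_param / (n_param + base_mean[:, None]), size=(len(genes), n_n)
        )
        values = np.hstack([tumor, normal]).astype(np.int64)

    columns = tumor_cols + normal_cols
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=columns)
    groups = pd.Series(
        ["tumor"] * n_t + ["normal"] * n_n, index=columns, name="group"
    )
    return ExpressionStudy(
        values=frame,
        groups=groups,
        technology=config.technology,
        cancer_type=config.cancer_type,
        dataset_id=config.dataset_id,
    )


def gen_interactome(
    n_nodes: int,
    planted_hubs: Sequence[str] = (),
    background_edge_prob: float = 0.02,
    hub_degree_boost: int = 20,
    seed: int = 0,
    node_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Erdős–Rényi background plus extra edges attached to planted hubs.

    Returns a 3-column frame (node_a, node_b, confidence) with node_a <
    node_b, no self-loops and no duplicate undirected edges; confidences
    are uniform on [0, 1].
    """
    if not 0.0 <= background_edge_prob <= 1.0:
        raise InvalidParameterError("background_edge_prob must lie in [0, 1]")
    if hub_degree_boost < 0:
        raise InvalidParameterError("hub_degree_boost must be non-negative")
    nodes = list(node_ids) if node_ids is not None else [
        f"P{i:04d}" for i in range(1, n_nodes + 1)
    ]
    if len(nodes) != n_nodes:
        raise InvalidParameterError("node_ids length must equal n_nodes")
    missing = set(planted_hubs) - set(nodes)
    if missing:
        raise InvalidParameterError(f"planted hubs outside the node set: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_nodes, k=1)
    keep = rng.random(len(iu)) < background_edge_prob
    edges = {(int(i), int(j)) for i, j in zip(iu[keep], ju[keep])}

    index = {n: i for i, n in enumerate(nodes)}
    for hub in planted_hubs:
        h = index[hub]
        neighbors = {j if i == h else i for i, j in edges if h in (i, j)}
        candidates = [i for i in range(n_nodes) if i != h and i not in neighbors]
        take = min(hub_degree_boost, len(candidates))
        chosen = rng.choice(len(candidates), size=take, replace=False)
        for c in chosen:
            i, j = sorted((h, candidates[int(c)]))
            edges.add((i, j))

    ordered = sorted(edges)
    conf = rng.uniform(0.0, 1.0, size=len(ordered))
    return pd.DataFrame(
        {
            "node_a": [nodes[i] for i, _ in ordered],
            "node_b": [nodes[j] for _, j in ordered],
            "confidence": conf,
        }
    )


def gen_regulons(
    tfs: Sequence[str],
    targets: Sequence[str],
    mode_probs: tuple[float, float, float] = (0.2, 0.5, 0.3),
    density: float = 1.0,
    seed: int = 0,
) -> list[RegulonEdge]:
    """Directed TF -> target edges with modes sampled from
    (activation, repression, unknown) probabilities."""
    if not tfs:
        raise InvalidParameterError("at least one TF is required")
    probs = np.asarray(mode_probs, dtype=float)
    if probs.shape != (3,) or (probs < 0).any() or (probs > 1).any():
        raise InvalidParameterError("mode_probs must be three values in [0, 1]")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("mode_probs must sum to 1")
    if not 0.0 <= density <= 1.0:
        raise InvalidParameterError("density must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    pairs = [(tf, tg) for tf in tfs for tg in targets]
    keep = rng.random(len(pairs)) < density if density < 1.0 else np.ones(len(pairs), bool)
    modes = rng.choice(3, size=len(pairs), p=probs)
    mode_names = ("activation", "repression", "unknown")
    return [
        RegulonEdge(tf, tg, mode_names[int(m)])
        for (tf, tg), k, m in zip(pairs, keep, modes)
        if k
    ]


def gen_annotations(
    universe: Sequence[str],
    n_terms: int,
    term_size_range: tuple[int, int] = (10, 40),
    planted_term: tuple[str, Sequence[str]] | None = None,
    seed: int = 0,
    categories: Sequence[str] = ("cell cycle", "DNA repair", "signaling", "metabolism"),
) -> "AnnotationSet":
    """Random GMT-style terms plus an optional planted term kept verbatim."""
    lo, hi = term_size_range
    if lo < 1 or hi < lo:
        raise InvalidParameterError("term_size_range must satisfy 1 <= lo <= hi")
    if hi > len(universe):
        raise InvalidParameterError("term size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    terms: dict[str, list[str]] = {}
    cats: dict[str, str] = {}
    for i in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        name = f"RT{i:04d}"
        terms[name] = sorted(universe[int(m)] for m in members)
        cats[name] = categories[int(rng.integers(0, len(categories)))]
    if planted_term is not None:
        name, genes = planted_term
        missing = set(genes) - set(universe)
        if missing:
            raise InvalidParameterError(
                f"planted term genes outside the universe: {sorted(missing)[:5]}"
            )
        terms[name] = list(genes)
        cats[name] = "planted"
    return AnnotationSet(terms=terms, categories=cats)


@dataclass
class AnnotationSet:
    """GMT-style term -> gene-set mapping with a category per term."""

    terms: dict[str, list[str]]
    categories: dict[str, str]


def gen_survival_cohort(
    n_patients: int,
    beta: float,
    censor_rate: float = 0.2,
    seed: int = 0,
    gene: str = "GENE1",
    null_genes: Sequence[str] = (),
    base_hazard: float = 0.1,
) -> SurvivalCohort:
    """Exponential event times with hazard exp(beta) for the top expression
    quartile of ``gene``; independent exponential censoring.

    Expression values are standard normal; the hazard boost is planted on
    the indicator "expression strictly above the empirical 75th percentile",
    the same grouping rule the survival screen applies downstream, so that
    recovery of exp(beta) is well defined. ``censor_rate`` is the expected
    censored fraction among baseline-hazard patients.
    """
    if n_patients < 8:
        raise InvalidParameterError("n_patients must be at least 8 (quartile split)")
    if not 0.0 <= censor_rate < 1.0:
        raise InvalidParameterError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    expr = rng.standard_normal(n_patients)
    high = expr > np.percentile(expr, 75)
    hazard = base_hazard * np.where(high, math.exp(beta), 1.0)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        cens_hazard = base_hazard * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / cens_hazard, size=n_patients)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(n_patients, dtype=int)

    data = {
        "time": time,
        "event": event,
        f"expr_{gene}": expr,
    }
    for g in null_genes:
        data[f"expr_{g}"] = rng.standard_normal(n_patients)
    frame = pd.DataFrame(
        data, index=pd.Index([f"S{i:05d}" for i in range(1, n_patients + 1)], name="sample")
    )
    return SurvivalCohort(data=frame)


def gen_study_panel(
    n_genes: int = 300,
    n_pan_over: int = 12,
    n_pan_under: int = 6,
    n_type_specific: int = 10,
    effect: float = 3.0,
    noise_sd: float = 1.0,
    dispersion: float = 0.1,
    n_tumor: int = 10,
    n_normal: int = 10,
    microarray_types: Sequence[str] = MICROARRAY_TYPES,
    rnaseq_types: Sequence[str] = RNASEQ_TYPES,
    datasets_per_type: int = 1,
    seed: int = 0,
) -> SynthStudyPanel:
    """A multi-cancer, two-technology study panel with planted pan-cancer DEGs.

    The first ``n_pan_over`` genes are planted overexpressed (+effect) and
    the next ``n_pan_under`` underexpressed (-effect) in every cancer type
    of both technologies; each cancer type additionally receives
    ``n_type_specific`` private overexpressed genes, giving the per-type DEG
    sets a realistic shared-plus-private structure for Jaccard screening.
    """
    genes = default_gene_universe(n_genes)
    pan_over = genes[:n_pan_over]
    pan_under = genes[n_pan_over:n_pan_over + n_pan_under]
    all_types = sorted(set(microarray_types) | set(rnaseq_types))
    n_specific_total = n_type_specific * len(all_types)
    start = n_pan_over + n_pan_under
    if start + n_specific_total > n_genes:
        raise InvalidParameterError(
            "gene universe too small for the requested planted structure"
        )
    specific = {
        ct: genes[start + i * n_type_specific: start + (i + 1) * n_type_specific]
        for i, ct in enumerate(all_types)
    }

    master = np.random.default_rng(seed)
    studies: list[ExpressionStudy] = []
    truth: dict[str, dict[str, set[str]]] = {OVER: {}, UNDER: {}}

    def record(direction: str, gene: str, cancer_type: str) -> None:
        truth[direction].setdefault(gene, set()).add(cancer_type)

    counter = 0
    for technology, types in ((MICROARRAY, microarray_types), (RNASEQ, rnaseq_types)):
        for cancer_type in types:
            for rep in range(datasets_per_type):
                counter += 1
                planted = {g: effect for g in pan_over}
                planted.update({g: -effect for g in pan_under})
                planted.update({g: effect for g in specific[cancer_type]})
                cfg = SynthExpressionConfig(
                    n_genes=n_genes,
                    n_tumor=n_tumor,
                    n_normal=n_normal,
                    technology=technology,
                    planted_deg=planted,
                    baseline_dispersion=(
                        noise_sd if technology == MICROARRAY else dispersion
                    ),
                    seed=int(master.integers(0, 2**31)),
                    cancer_type=cancer_type,
                    dataset_id=f"SYN{counter:06d}",
                )
                studies.append(gen_expression_study(cfg))
                for g in pan_over:
                    record(OVER, g, cancer_type)
                for g in pan_under:
                    record(UNDER, g, cancer_type)
                for g in specific[cancer_type]:
                    record(OVER, g, cancer_type)

    return SynthStudyPanel(studies=studies, truth=truth)
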