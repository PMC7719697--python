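"""End-to-end orchestration: simulate inputs, run all stages, write reports.

``run_pipeline`` executes, in order: per-dataset DEG calling -> cross-cancer
frequency consensus (with Jaccard screening) -> first-shell network
construction and HBS classification (over- and under-expression networks
separately) -> TF prospection and regulatory-core filtering -> term
enrichment -> quartile survival screening. Every stage writes its table
under the output directory, the configuration is echoed to ``config.yaml``,
and ``report.yaml`` collects the headline counts. Given the same
configuration (including the seed used to generate inputs), two runs are
byte-identical apart from timestamps in ``log.txt``.
"""

from __future__ import annotations

import contextlib
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import consensus as cons
from . import enrichment as enr
from . import io as pio
from . import network as net
from . import qc_deg
from . import regulatory as reg
from . import survival as surv
from . import synth
from .core import (
    MICROARRAY,
    OVER,
    RNASEQ,
    UNDER,
    InvalidParameterError,
    PipelineStageError,
)

STAGES = ("deg", "consensus", "network", "regulatory", "enrichment", "survival")


@dataclass
class PipelineConfig:
    """Paths to the pipeline inputs plus every stage threshold.

    Threshold defaults are the published working point: |log2FC| >= 1 with
    BH-adjusted p < 0.05 per dataset; frequency thresholds of 6 microarray /
    3 RNA-seq cancer types; Jaccard flag at 0.15; interactome confidence
    0.400 with a 200-interactor first shell; regulatory core at >= 2 DEG
    connections; Bonferroni 1e-5 enrichment cut with >= 3 terms per
    category.
    """

    manifest: str = "manifest.yaml"
    interactome: str = "interactome.tsv"
    regulons: str = "regulons.tsv"
    annotations: str = "annotations.gmt"
    survival: str = "survival.tsv"
    fc: float = 1.0
    alpha: float = 0.05
    microarray_min_types: int = 6
    rnaseq_min_types: int = 3
    jaccard: float = 0.15
    confidence: float = 0.4
    max_interactors: int = 200
    core_min_connections: int = 2
    enrich_strict_p: float = 1e-5
    min_category_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc < 0:
            raise InvalidParameterError("fc must be non-negative")
        for name in ("alpha", "jaccard", "confidence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        for name in ("microarray_min_types", "rnaseq_min_types", "core_min_connections"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")
        if self.max_interactors < 0:
            raise InvalidParameterError("max_interactors must be non-negative")
        if not 0.0 < self.enrich_strict_p <= 1.0:
            raise InvalidParameterError("enrich_strict_p must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def make_demo_inputs(directory, seed: int = 0) -> PipelineConfig:
    """Write a complete synthetic input bundle and return its config.

    The bundle mirrors a multi-cancer curation effort at desk scale: a
    13-type microarray panel and an 8-type RNA-seq panel (one dataset each,
    300 genes, 10+10 samples) with 12 over- and 6 under-expressed pan-cancer
    genes planted everywhere; a 400-node interactome in which the first two
    pan-over genes are planted hubs; a regulon table over 12 TFs; 40 random
    annotation terms plus a planted term holding the pan-over genes; and a
    600-patient survival cohort in which the first pan-over gene carries a
    log(2) hazard-ratio effect.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    panel = synth.gen_study_panel(seed=seed)
    genes = synth.default_gene_universe(300)
    pan_over = genes[:12]   # planted in every cancer type, both technologies
    pan_under = genes[12:18]

    entries = []
    for study in panel.studies:
        expr = f"{study.dataset_id}_expr.tsv"
        labels = f"{study.dataset_id}_labels.tsv"
        pio.write_expression(study, directory / expr, directory / labels)
        entries.append({
            "dataset_id": study.dataset_id,
            "cancer_type": study.cancer_type,
            "technology": study.technology,
            "expression": expr,
            "labels": labels,
        })
    pio.write_manifest(entries, directory / "manifest.yaml")

    extra = [f"P{i:04d}" for i in range(1, 101)]
    interactome = synth.gen_interactome(
        n_nodes=400,
        planted_hubs=pan_over[:2],
        background_edge_prob=0.02,
        hub_degree_boost=30,
        seed=seed + 1,
        node_ids=genes + extra,
    )
    pio.write_edge_list(interactome, directory / "interactome.tsv")

    tfs = [f"TF{i:02d}" for i in range(1, 13)]
    regulons = synth.gen_regulons(
        tfs, pan_over + pan_under + genes[18:60], density=0.35, seed=seed + 2
    )
    pio.write_regulons(regulons, directory / "regulons.tsv")

    annotations = synth.gen_annotations(
        genes, n_terms=40, term_size_range=(10, 40),
        planted_term=("pan-cancer overexpression core", pan_over),
        seed=seed + 3,
    )
    pio.write_gmt(annotations, directory / "annotations.gmt")

    cohort = synth.gen_survival_cohort(
        n_patients=600, beta=math.log(2.0), censor_rate=0.2, seed=seed + 4,
        gene=pan_over[0], null_genes=pan_over[1:] + pan_under,
    )
    pio.write_survival(cohort, directory / "survival.tsv")

    config = PipelineConfig(seed=seed)
    config.to_yaml(directory / "config.yaml")
    return config


@contextlib.contextmanager
def _stage(name: str, log: list[str]):
    start = time.perf_counter()
    try:
        yield
    except PipelineStageError:
        raise
    except Exception as err:
        raise PipelineStageError(f"stage {name!r} failed: {err}") from err
    log.append(f"[{time.strftime('%Y-%m-%dT%H:%M:%S')}] stage {name}: "
               f"done in {time.perf_counter() - start:.2f}s")


def run_pipeline(config: PipelineConfig, input_dir, out_dir) -> dict:
    """Run every stage on the inputs under ``input_dir``; write results and
    return the report dictionary."""
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    report: dict = {"stages": list(STAGES)}

    with _stage("deg", log):
        studies = pio.read_panel(input_dir / config.manifest)
        deg_tables = []
        (out_dir / "deg").mkdir(exist_ok=True)
        for study in studies:
            table = qc_deg.call_degs(study, fc_threshold=config.fc, alpha=config.alpha)
            pio.write_deg_table(table, out_dir / "deg" / f"{study.dataset_id}.tsv")
            deg_tables.append(table)
        report["n_datasets"] = len(studies)
        report["n_significant_calls"] = int(
            sum(t.records["significant"].sum() for t in deg_tables)
        )

    with _stage("consensus", log):
        thresholds = {
            MICROARRAY: config.microarray_min_types,
            RNASEQ: config.rnaseq_min_types,
        }
        ctable = cons.frequency_consensus(deg_tables, thresholds)
        ctable.table.to_csv(out_dir / "consensus.tsv", sep="\t", index=False)
        micro = ctable.frequent_sets(MICROARRAY)
        rna = ctable.frequent_sets(RNASEQ)
        combined = cons.combine_technologies(micro, rna)
        rows = [{"gene": g, "direction": d}
                for d in (OVER, UNDER) for g in combined.genes[d]]
        pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(
            out_dir / "consensus_genes.tsv", sep="\t", index=False)
        pd.DataFrame({"gene": combined.conflicts}).to_csv(
            out_dir / "conflicts.tsv", sep="\t", index=False)
        for technology in (MICROARRAY, RNASEQ):
            for direction in (OVER, UNDER):
                sets: dict[str, set[str]] = {}
                for t in deg_tables:
                    if t.technology != technology:
                        continue
                    sets.setdefault(t.cancer_type, set()).update(
                        t.significant_genes(direction))
                jm = cons.jaccard_matrix(sets, threshold=config.jaccard)
                jm.matrix.to_csv(
                    out_dir / f"jaccard_{technology}_{direction}.tsv", sep="\t")
                report[f"jaccard_flagged_{technology}_{direction}"] = len(jm.flagged_pairs)
        report["n_frequent_microarray"] = len(micro[OVER] | micro[UNDER])
        report["n_frequent_rnaseq"] = len(rna[OVER] | rna[UNDER])
        report["n_consensus_over"] = len(combined.genes[OVER])
        report["n_consensus_under"] = len(combined.genes[UNDER])
        report["n_conflicts"] = len(combined.conflicts)

    with _stage("network", log):
        interactome = pio.read_edge_list(input_dir / config.interactome)
        (out_dir / "network").mkdir(exist_ok=True)
        hbs_by_direction: dict[str, list[str]] = {}
        for direction in (OVER, UNDER):
            seeds = combined.genes[direction]
            if not seeds:
                continue
            graph = net.expand_first_shell(
                seeds, interactome,
                min_confidence=config.confidence,
                max_interactors=config.max_interactors,
            )
            profile = net.centralities(graph)
            labels = net.topology_labels(profile)
            seed_labels = net.classify_hbs(profile, seeds, graph)
            frame = profile.as_frame()
            frame["label"] = [labels[n] for n in frame["node"]]
            frame["is_seed"] = [graph.nodes[n]["is_seed"] for n in frame["node"]]
            frame.to_csv(out_dir / "network" / f"{direction}_labels.tsv",
                         sep="\t", index=False)
            edges = pd.DataFrame(
                [(a, b, d["confidence"]) for a, b, d in
                 sorted(graph.edges(data=True))],
                columns=["node_a", "node_b", "confidence"])
            edges.to_csv(out_dir / "network" / f"{direction}_edges.tsv",
                         sep="\t", index=False)
            hbs = net.extract_hbs_subnetwork(graph, labels)
            hbs_by_direction[direction] = sorted(hbs.nodes)
            report[f"net_{direction}_nodes"] = graph.number_of_nodes()
            report[f"net_{direction}_edges"] = graph.number_of_edges()
            report[f"net_{direction}_hbs_nodes"] = hbs.number_of_nodes()
            report[f"net_{direction}_hbs_edges"] = hbs.number_of_edges()
            report[f"net_{direction}_unconnected"] = graph.graph["unconnected_seeds"]
            report[f"net_{direction}_seed_hbs"] = sorted(
                s for s, lab in seed_labels.items() if lab == "HBS")

    with _stage("regulatory", log):
        regulons = pio.read_regulons(input_dir / config.regulons)
        seeds = {g: "deg_over" for g in combined.genes[OVER]}
        seeds.update({g: "deg_under" for g in combined.genes[UNDER]})
        if seeds:
            tarnet = reg.prospect_tfs(seeds, regulons)
            core = reg.core_filter(tarnet, config.core_min_connections)
            edge_rows = [(a, b, d["mode"]) for a, b, d in sorted(core.edges(data=True))]
            pd.DataFrame(edge_rows, columns=["tf", "target", "mode"]).to_csv(
                out_dir / "core_regulatory_edges.tsv", sep="\t", index=False)
            role_rows = [(n, ";".join(sorted(core.nodes[n]["roles"])))
                         for n in sorted(core.nodes)]
            pd.DataFrame(role_rows, columns=["node", "roles"]).to_csv(
                out_dir / "core_regulatory_nodes.tsv", sep="\t", index=False)
            tally = reg.edge_mode_tally(core)
            report["tarnet_nodes"] = tarnet.number_of_nodes()
            report["tarnet_edges"] = tarnet.number_of_edges()
            report["core_nodes"] = core.number_of_nodes()
            report["core_edges"] = core.number_of_edges()
            report["core_mode_tally"] = tally
            report["dropped_seeds"] = tarnet.graph["dropped_seeds"]

    with _stage("enrichment", log):
        annotations = pio.read_gmt(input_dir / config.annotations)
        universe = sorted({g for t in deg_tables for g in t.records["gene"]})
        query = combined.all_genes()
        results = enr.enrich(query, annotations.terms, universe,
                             categories=annotations.categories)
        kept = enr.filter_terms(
            results, strict_p=config.enrich_strict_p,
            min_category_count=config.min_category_count)
        kept_names = {r.term for r in kept}
        frame = pd.DataFrame([{
            "term": r.term, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
            "p": r.p_two_sided, "p_bonf": r.p_bonferroni,
            "direction": r.direction, "category": r.category,
            "kept": r.term in kept_names,
        } for r in results])
        frame.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
        report["n_terms_tested"] = len(results)
        report["n_terms_kept"] = len(kept)
        if results:
            best = min(results, key=lambda r: (r.p_bonferroni, r.term))
            report["top_term"] = best.term

    with _stage("survival", log):
        cohort = pio.read_survival(input_dir / config.survival)
        screened = surv.screen_genes(cohort, alpha=config.alpha)
        screened.to_csv(out_dir / "survival_screen.tsv", sep="\t", index=False)
        report["n_genes_screened"] = len(screened)
        report["n_risk_flagged"] = int(screened["risk_flag"].sum())
        report["risk_genes"] = sorted(screened.loc[screened["risk_flag"], "gene"])

    config.to_yaml(out_dir / "config.yaml")
    with open(out_dir / "report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)
    with open(out_dir / "log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return report
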