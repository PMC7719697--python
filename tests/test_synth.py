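"""Generator determinism, planted-structure recovery and parameter guards."""

import numpy as np
import pandas as pd
import pytest

from pancanet import enrichment, qc_deg, synth
from pancanet.core import InvalidParameterError


@pytest.mark.parametrize("technology", ["microarray", "rnaseq"])
def test_same_seed_gives_identical_study(technology):
    cfg = synth.SynthExpressionConfig(
        n_genes=30, n_tumor=5, n_normal=5, technology=technology,
        planted_deg={"G0003": 2.0}, baseline_dispersion=0.5, seed=7)
    a = synth.gen_expression_study(cfg)
    b = synth.gen_expression_study(cfg)
    pd.testing.assert_frame_equal(a.values, b.values)
    assert a.technology == technology
    if technology == "rnaseq":
        assert (a.values.to_numpy() >= 0).all()
        assert np.issubdtype(a.values.to_numpy().dtype, np.integer)


@pytest.mark.parametrize("kwargs", [
    dict(baseline_dispersion=0.0),
    dict(planted_deg={"NOT_A_GENE": 1.0}),
    dict(n_tumor=2),
    dict(n_normal=2),
])
def test_invalid_expression_config_rejected(kwargs):
    base = dict(n_genes=10, n_tumor=5, n_normal=5, technology="microarray", seed=0)
    base.update(kwargs)
    with pytest.raises(InvalidParameterError):
        synth.SynthExpressionConfig(**base)


def test_deg_sensitivity_monotone_in_effect_size():
    """Recovery of planted genes never drops as the planted |log2FC| grows."""
    effects = [0.5, 1.5, 3.0]
    sens = []
    for effect in effects:
        hits = total = 0
        for seed in range(30):
            planted = {f"G{i:04d}": effect for i in range(1, 21)}
            cfg = synth.SynthExpressionConfig(
                n_genes=60, n_tumor=10, n_normal=10, technology="microarray",
                planted_deg=planted, baseline_dispersion=1.0, seed=seed)
            table = qc_deg.call_degs_microarray(synth.gen_expression_study(cfg))
            rec = table.records.set_index("gene")
            hits += int((rec.loc[list(planted), "significant"]).sum())
            total += len(planted)
        sens.append(hits / total)
    assert sens[0] <= sens[1] <= sens[2]
    assert sens[2] > 0.9


class TestInteractome:
    def test_no_background_no_hubs_is_empty(self):
        edges = synth.gen_interactome(10, background_edge_prob=0.0, seed=0)
        assert len(edges) == 0

    def test_complete_graph_edge_count(self):
        edges = synth.gen_interactome(4, background_edge_prob=1.0, seed=0)
        assert len(edges) == 6  # C(4,2)

    def test_no_self_loops_or_duplicate_edges(self):
        edges = synth.gen_interactome(
            60, planted_hubs=["P0001", "P0002"], background_edge_prob=0.1,
            hub_degree_boost=15, seed=3)
        assert (edges["node_a"] != edges["node_b"]).all()
        pairs = list(zip(edges["node_a"], edges["node_b"]))
        assert len(pairs) == len(set(pairs))
        assert all(a < b for a, b in pairs)
        assert edges["confidence"].between(0, 1).all()

    def test_bad_probability_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.gen_interactome(10, background_edge_prob=1.5, seed=0)

    def test_planted_hub_is_top_degree(self):
        """A boosted node out-degrees an Erdős–Rényi background nearly always."""
        wins = 0
        for seed in range(100):
            edges = synth.gen_interactome(
                100, planted_hubs=["P0050"], background_edge_prob=0.02,
                hub_degree_boost=20, seed=seed)
            deg = pd.concat([edges["node_a"], edges["node_b"]]).value_counts()
            wins += deg.idxmax() == "P0050"
        assert wins >= 95


class TestRegulons:
    def test_full_density_edge_count(self):
        edges = synth.gen_regulons(["X", "Y"], ["a", "b", "c"], density=1.0, seed=0)
        assert len(edges) == 6

    def test_pure_repression(self):
        edges = synth.gen_regulons(["X"], ["a", "b"], mode_probs=(0, 1, 0), seed=0)
        assert {e.mode for e in edges} == {"repression"}

    def test_empty_tf_list_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.gen_regulons([], ["a"], seed=0)

    def test_mode_frequencies_match_probabilities(self):
        targets = [f"t{i}" for i in range(1000)]
        edges = synth.gen_regulons([f"F{i}" for i in range(10)], targets,
                                   mode_probs=(0.2, 0.5, 0.3), seed=11)
        assert len(edges) == 10_000
        freq = pd.Series([e.mode for e in edges]).value_counts(normalize=True)
        assert abs(freq["activation"] - 0.2) < 0.02
        assert abs(freq["repression"] - 0.5) < 0.02
        assert abs(freq["unknown"] - 0.3) < 0.02


class TestAnnotations:
    def test_planted_only(self):
        ann = synth.gen_annotations(["a", "b", "c"], n_terms=0, term_size_range=(1, 2),
                                    planted_term=("core", ["a", "b"]), seed=0)
        assert list(ann.terms) == ["core"]
        assert ann.terms["core"] == ["a", "b"]

    def test_same_seed_identical(self):
        universe = [f"g{i}" for i in range(50)]
        a = synth.gen_annotations(universe, n_terms=5, term_size_range=(3, 8), seed=2)
        b = synth.gen_annotations(universe, n_terms=5, term_size_range=(3, 8), seed=2)
        assert a.terms == b.terms and a.categories == b.categories

    def test_oversized_term_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.gen_annotations(["a", "b"], n_terms=1, term_size_range=(1, 5), seed=0)

    def test_planted_term_recovered_by_enrichment(self):
        """Querying the planted term's own genes ranks it first by Bonferroni p."""
        universe = [f"g{i:03d}" for i in range(200)]
        planted = universe[:15]
        ann = synth.gen_annotations(universe, n_terms=30, term_size_range=(10, 30),
                                    planted_term=("core", planted), seed=5)
        results = enrichment.enrich(planted, ann.terms, universe)
        best = min(results, key=lambda r: r.p_bonferroni)
        assert best.term == "core"
        others = [r.p_bonferroni for r in results if r.term != "core"]
        assert best.p_bonferroni < min(others)


class TestSurvivalCohort:
    def test_no_censoring_means_all_events(self):
        cohort = synth.gen_survival_cohort(50, beta=0.0, censor_rate=0.0, seed=0)
        assert (cohort.data["event"] == 1).all()

    def test_too_few_patients_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.gen_survival_cohort(7, beta=0.0, seed=0)

    def test_bad_censor_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.gen_survival_cohort(20, beta=0.0, censor_rate=1.0, seed=0)

    def test_censoring_rate_roughly_matches(self):
        cohort = synth.gen_survival_cohort(4000, beta=0.0, censor_rate=0.3, seed=1)
        censored = 1.0 - cohort.data["event"].mean()
        assert abs(censored - 0.3) < 0.04


def test_panel_ids_unique_and_truth_covers_planted():
    panel = synth.gen_study_panel(seed=0)
    ids = [s.dataset_id for s in panel.studies]
    assert len(ids) == len(set(ids))
    assert len(panel.by_technology("microarray")) == 13
    assert len(panel.by_technology("rnaseq")) == 8
    # pan-planted genes are recorded in every cancer type of the vocabulary
    pan_over = [g for g, types in panel.truth["over"].items() if len(types) >= 13]
    assert len(pan_over) >= 12
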