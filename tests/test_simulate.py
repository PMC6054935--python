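"""Synthetic-data generator: planted structure, determinism, realized effects."""

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from psanet.containers import GENE, LNC_GENE, LNC_MIRNA, LNCRNA, MIRNA
from psanet.errors import ConsistencyError, ParameterError
from psanet.simulate import (
    SimulationParams,
    TruthManifest,
    generate_annotations,
    generate_cohort,
    generate_interactions,
    generate_ppi,
)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_case": 1},
            {"n_control": 0},
            {"frac_de_genes": 1.5},
            {"p_in": 0.1, "p_out": 0.5},
            {"effect_fold": 0.5},
            {"n_genes": -1},
            {"n_planted_modules": 50, "module_size": 50},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SimulationParams(**kwargs).validate()

    def test_defaults_valid(self):
        SimulationParams().validate()


class TestCohort:
    def test_shape_and_labels(self, small_params, small_study):
        expr, truth = small_study
        p = small_params
        assert expr.values.shape == (
            p.n_genes + p.n_lncrnas + p.n_mirnas,
            p.n_case + p.n_control,
        )
        assert len(expr.case_samples) == p.n_case
        assert len(expr.control_samples) == p.n_control
        assert (expr.values.to_numpy() > 0).all()

    def test_manifest_consistency(self, small_study):
        expr, truth = small_study
        truth.validate()
        ids = set(expr.values.index)
        referenced = (
            truth.de_genes | truth.de_lncrnas | truth.de_mirnas
            | truth.regulator_lncrnas
            | set().union(*truth.planted_modules)
        )
        assert referenced <= ids
        assert truth.regulator_lncrnas <= truth.de_lncrnas
        module_genes = [g for m in truth.planted_modules for g in m]
        assert len(module_genes) == len(set(module_genes))

    def test_determinism_bit_identical(self, small_params):
        e1, t1 = generate_cohort(small_params)
        e2, t2 = generate_cohort(small_params)
        assert e1.values.equals(e2.values)
        assert t1.to_json() == t2.to_json()

    def test_seed_changes_output(self, small_params):
        e1, _ = generate_cohort(small_params)
        e2, _ = generate_cohort(dataclasses.replace(small_params, seed=99))
        assert not e1.values.equals(e2.values)

    def test_zero_effect_means_equal(self):
        params = SimulationParams(
            n_genes=50, n_lncrnas=10, n_mirnas=5, effect_fold=1.0,
            noise_sigma=0.0, n_regulator_lncrnas=2, n_planted_modules=2,
            module_size=5, seed=4,
        )
        expr, truth = generate_cohort(params)
        assert truth.de_genes  # DE sets still planted
        case = expr.values[expr.case_samples].mean(axis=1)
        ctrl = expr.values[expr.control_samples].mean(axis=1)
        assert np.allclose(case, ctrl)

    def test_realized_fold_change_matches_planted(self):
        """Mean realized |signed FC| of planted transcripts tracks effect_fold."""
        base = SimulationParams(
            n_genes=40, n_lncrnas=10, n_mirnas=5, effect_fold=2.5,
            noise_sigma=0.5, n_planted_modules=1, module_size=5,
            n_regulator_lncrnas=1, seed=0,
        )
        ratios = []
        for seed in range(100):
            expr, truth = generate_cohort(dataclasses.replace(base, seed=seed))
            case = expr.values[expr.case_samples].mean(axis=1)
            ctrl = expr.values[expr.control_samples].mean(axis=1)
            for t, sign in truth.de_sign.items():
                r = case[t] / ctrl[t]
                ratios.append(r if sign > 0 else 1.0 / r)
        assert np.mean(ratios) == pytest.approx(2.5, rel=0.05)

    def test_non_de_transcripts_share_group_means(self):
        params = SimulationParams(
            n_genes=50, n_lncrnas=10, n_mirnas=5, noise_sigma=0.0,
            n_planted_modules=2, module_size=5, n_regulator_lncrnas=1, seed=2,
        )
        expr, truth = generate_cohort(params)
        de = truth.de_genes | truth.de_lncrnas | truth.de_mirnas
        quiet = [t for t in expr.values.index if t not in de]
        case = expr.values.loc[quiet, expr.case_samples].mean(axis=1)
        ctrl = expr.values.loc[quiet, expr.control_samples].mean(axis=1)
        assert np.allclose(case, ctrl)


class TestInteractions:
    def test_regulators_hit_de_mirnas_and_module_genes(self, small_params,
                                                       small_study):
        _, truth = small_study
        cat = generate_interactions(small_params, truth)
        module_genes = set().union(*truth.planted_modules)
        for lnc in truth.regulator_lncrnas:
            mir_edges = [e for e in cat.edges_of_type(LNC_MIRNA)
                         if e.source == lnc]
            gene_edges = [e for e in cat.edges_of_type(LNC_GENE)
                          if e.source == lnc]
            assert mir_edges and gene_edges
            assert all(e.target in truth.de_mirnas for e in mir_edges)
            assert all(e.target in module_genes for e in gene_edges)

    def test_no_lnc_edges_without_regulators_or_background(self):
        params = SimulationParams(
            n_genes=60, n_lncrnas=10, n_mirnas=5, n_regulator_lncrnas=0,
            background_edge_rate=0.0, n_planted_modules=2, module_size=5,
            seed=8,
        )
        _, truth = generate_cohort(params)
        cat = generate_interactions(params, truth)
        assert not cat.edges_of_type(LNC_GENE)
        assert not cat.edges_of_type(LNC_MIRNA)

    def test_deterministic(self, small_params, small_study):
        _, truth = small_study
        c1 = generate_interactions(small_params, truth)
        c2 = generate_interactions(small_params, truth)
        assert c1 == c2

    def test_mismatched_truth_rejected(self, small_params):
        bogus = TruthManifest(
            de_genes=frozenset({"G99999"}), de_sign={"G99999": 1}
        )
        with pytest.raises(ConsistencyError):
            generate_interactions(
                dataclasses.replace(small_params, n_genes=10,
                                    n_planted_modules=0,
                                    n_regulator_lncrnas=0,
                                    frac_de_genes=0.0),
                bogus,
            )


class TestPpi:
    def test_deterministic_k5_components(self):
        params = SimulationParams(
            n_genes=30, n_lncrnas=4, n_mirnas=4, frac_de_genes=0.5,
            n_planted_modules=2, module_size=5, p_in=1.0, p_out=0.0,
            n_regulator_lncrnas=1, seed=5,
        )
        _, truth = generate_cohort(params)
        edges = generate_ppi(params, truth)
        g = nx.Graph(edges)
        comps = sorted(
            (frozenset(c) for c in nx.connected_components(g)),
            key=lambda c: sorted(c),
        )
        assert sorted(map(frozenset, truth.planted_modules),
                      key=lambda c: sorted(c)) == comps
        for mod in truth.planted_modules:
            sub = g.subgraph(mod)
            assert sub.number_of_edges() == 5 * 4 // 2  # K5

    def test_k4_module_core_number(self):
        params = SimulationParams(
            n_genes=20, n_lncrnas=4, n_mirnas=4, frac_de_genes=0.5,
            n_planted_modules=1, module_size=4, p_in=1.0, p_out=0.0,
            n_regulator_lncrnas=1, seed=6,
        )
        _, truth = generate_cohort(params)
        g = nx.Graph(generate_ppi(params, truth))
        cores = nx.core_number(g)
        assert all(cores[v] == 3 for v in truth.planted_modules[0])

    def test_uniform_edge_probability_expected_count(self):
        """At p_in == p_out the graph is Erdos-Renyi with p·N(N-1)/2 edges."""
        base = SimulationParams(
            n_genes=40, n_lncrnas=4, n_mirnas=4, frac_de_genes=0.5,
            n_planted_modules=2, module_size=5, p_in=0.1 + 1e-9, p_out=0.1,
            n_regulator_lncrnas=1,
        )
        counts = [
            len(generate_ppi(dataclasses.replace(base, seed=s),
                             generate_cohort(dataclasses.replace(base, seed=s))[1]))
            for s in range(200)
        ]
        expected = 0.1 * 40 * 39 / 2  # 78
        # Monte-Carlo mean over 200 seeds: SE = sqrt(Np(1-p))/sqrt(200) ~ 0.6
        assert np.mean(counts) == pytest.approx(expected, abs=2.5)

    def test_simple_and_sorted(self, small_params, small_study):
        _, truth = small_study
        edges = generate_ppi(small_params, truth)
        assert all(a < b for a, b in edges)
        assert len(edges) == len(set(edges))


class TestAnnotations:
    def test_closure_over_gene_universe(self, small_params, small_study):
        _, truth = small_study
        terms = generate_annotations(small_params, truth)
        universe = {f"G{i:05d}" for i in range(1, small_params.n_genes + 1)}
        assert all(t <= universe for t in terms.values())
        assert len(terms) == small_params.n_terms

    def test_designated_terms_mostly_within_module(self, small_params,
                                                   small_study):
        _, truth = small_study
        terms = generate_annotations(small_params, truth)
        for term_id, m in truth.enriched_term_per_module.items():
            members = terms[term_id]
            inside = len(members & truth.planted_modules[m])
            assert inside / len(members) >= 0.6

    def test_zero_random_fraction_terms_subset_of_modules(self):
        params = SimulationParams(
            n_genes=60, n_lncrnas=10, n_mirnas=5, frac_de_genes=0.5,
            n_planted_modules=3, module_size=8, n_terms=3,
            term_random_frac=0.0, n_regulator_lncrnas=1, seed=9,
        )
        _, truth = generate_cohort(params)
        terms = generate_annotations(params, truth)
        for term_id, m in truth.enriched_term_per_module.items():
            assert terms[term_id] <= truth.planted_modules[m]

    def test_term_sizes_within_bounds(self, small_params, small_study):
        _, truth = small_study
        terms = generate_annotations(small_params, truth)
        designated = set(truth.enriched_term_per_module)
        for term_id, members in terms.items():
            if term_id in designated:
                continue
            assert (small_params.term_size_min <= len(members)
                    <= small_params.term_size_max)
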