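"""Determinism, truth consistency and parameter recovery of the generator."""

import numpy as np
import pandas as pd
import pytest

from methyltrx.core import ValidationError
from methyltrx.simulate import (
    SimulationConfig,
    plan_truth,
    simulate_annotation,
    simulate_compound_signatures,
    simulate_dataset,
    simulate_expression_counts,
    simulate_methylation_counts,
    simulate_trn,
)

SMALL = dict(n_genes=800, n_compounds=20, n_hit_compounds=2,
             n_tfs=4, n_background_tfs=4, regulon_size=20)


class TestConfig:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValidationError):
            SimulationConfig(frac_de=1.5)

    def test_anti_coupling_requires_dm_within_de_budget(self):
        with pytest.raises(ValidationError, match="anti"):
            SimulationConfig(frac_de=0.01, frac_dm_promoter=0.05, coupling="anti")

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        cfg = SimulationConfig(seed=3, **SMALL)
        p = tmp_path / "c.yaml"
        p.write_text(yaml.safe_dump(cfg.to_dict()))
        assert SimulationConfig.from_yaml(p) == cfg


class TestAnnotation:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=1, **SMALL)
        a1 = simulate_annotation(cfg)
        a2 = simulate_annotation(cfg)
        assert [(g.gene_id, g.tss, g.strand, g.body.start, g.body.end)
                for g in a1] == [(g.gene_id, g.tss, g.strand, g.body.start, g.body.end)
                                 for g in a2]

    def test_tss_spacing_at_least_12kb(self):
        cfg = SimulationConfig(seed=1, **SMALL)
        tss = sorted(g.tss for g in simulate_annotation(cfg))
        assert min(np.diff(tss)) >= 12_000

    def test_single_gene_valid(self):
        cfg = SimulationConfig(seed=1, n_genes=60, n_tfs=1, n_background_tfs=1,
                               regulon_size=5, frac_de=0.2, frac_dm_promoter=0.05,
                               n_compounds=5, n_hit_compounds=1)
        genes = simulate_annotation(cfg)
        assert len(genes) == 60
        for g in genes[:5]:
            assert g.exons and g.body.width >= 2000


class TestTruth:
    def test_planted_set_sizes(self):
        cfg = SimulationConfig(seed=2, **SMALL)
        truth = plan_truth(cfg)
        assert len(truth.de_genes) == round(cfg.frac_de * cfg.n_genes)
        assert len(truth.dm_promoters) == round(cfg.frac_dm_promoter * cfg.n_genes)
        for tf in truth.tf_lfc:
            assert len(truth.tf_altered[tf]) == round(
                cfg.frac_regulon_altered * cfg.regulon_size)

    def test_anti_coupling_nests_dm_in_de_with_negative_lfc(self):
        cfg = SimulationConfig(seed=2, coupling="anti", **SMALL)
        truth = plan_truth(cfg)
        assert set(truth.coupled_pairs) == set(truth.dm_promoters)
        for g in truth.coupled_pairs:
            assert truth.de_genes[g] < 0

    def test_no_coupling_gives_disjoint_sets(self):
        cfg = SimulationConfig(seed=2, coupling="none", **SMALL)
        truth = plan_truth(cfg)
        assert truth.coupled_pairs == []
        assert not set(truth.dm_promoters) & set(truth.de_genes)

    def test_zero_dm_fraction_empty(self):
        cfg = SimulationConfig(seed=2, frac_dm_promoter=0.0, coupling="none", **SMALL)
        assert plan_truth(cfg).dm_promoters == {}

    def test_tf_ids_disjoint_from_targets(self):
        cfg = SimulationConfig(seed=2, **SMALL)
        truth = plan_truth(cfg)
        tfs = set(truth.tf_regulons)
        targets = {g for r in truth.tf_regulons.values() for g in r}
        assert not tfs & targets

    def test_truth_ids_exist_in_matrices(self):
        cfg = SimulationConfig(seed=4, **SMALL)
        ds = simulate_dataset(cfg)
        genes = set(ds["expression"].feature_ids)
        regions = set(ds["methylation"].feature_ids)
        truth = ds["truth"]
        assert set(truth.de_genes) <= genes
        assert {f"{g}|promoter" for g in truth.dm_promoters} <= regions
        assert set(truth.tf_regulons) <= genes


class TestExpressionCounts:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        truth = plan_truth(cfg)
        m1 = simulate_expression_counts(cfg, truth)
        m2 = simulate_expression_counts(cfg, truth)
        assert m1 == m2

    def test_null_config_centers_log_ratios_at_zero(self):
        cfg = SimulationConfig(seed=6, n_genes=2000, frac_de=0.0,
                               frac_dm_promoter=0.0, coupling="none",
                               n_tfs=1, n_background_tfs=0, regulon_size=5,
                               frac_regulon_altered=0.0, tf_lfc=0.0,
                               n_compounds=5, n_hit_compounds=0)
        truth = plan_truth(cfg)
        assert truth.de_genes == {}
        cm = simulate_expression_counts(cfg, truth)
        from methyltrx.diffstats import normalize_counts
        norm, _ = normalize_counts(cm)
        case = norm[cm.samples_in_group("case")].mean(axis=1)
        ctrl = norm[cm.samples_in_group("control")].mean(axis=1)
        ratios = np.log2((case + 0.5) / (ctrl + 0.5))
        assert abs(np.median(ratios)) < 0.1

    def test_planted_lfc_recovered_on_average(self):
        deltas = []
        for seed in range(8):
            cfg = SimulationConfig(seed=seed, n_genes=500, frac_de=0.1,
                                   lfc_de=2.0, baseline_mean_expr=500,
                                   nb_dispersion=0.05, coupling="none",
                                   frac_dm_promoter=0.0, n_tfs=1,
                                   n_background_tfs=0, regulon_size=5,
                                   frac_regulon_altered=0.0,
                                   n_compounds=5, n_hit_compounds=0)
            truth = plan_truth(cfg)
            cm = simulate_expression_counts(cfg, truth)
            from methyltrx.diffstats import normalize_counts
            norm, _ = normalize_counts(cm)
            case = norm[cm.samples_in_group("case")].mean(axis=1)
            ctrl = norm[cm.samples_in_group("control")].mean(axis=1)
            for g, lfc in truth.de_genes.items():
                if g in truth.tf_lfc:
                    continue
                observed = np.log2((case[g] + 0.5) / (ctrl[g] + 0.5))
                deltas.append(observed - lfc)
        assert abs(np.mean(deltas)) < 0.2


class TestMethylationCounts:
    def test_region_id_scheme(self):
        cfg = SimulationConfig(seed=7, **SMALL)
        ds = simulate_dataset(cfg)
        kinds = {rid.split("|")[1] for rid in ds["methylation"].feature_ids}
        assert kinds == {"promoter", "exon", "body"}

    def test_planted_promoter_lfc_recovered(self):
        deltas = []
        for seed in range(8):
            cfg = SimulationConfig(seed=seed, lfc_dm=1.5, **SMALL)
            truth = plan_truth(cfg)
            annotation = simulate_annotation(cfg)
            cm = simulate_methylation_counts(cfg, truth, annotation)
            from methyltrx.diffstats import normalize_counts
            norm, _ = normalize_counts(cm)
            case = norm[cm.samples_in_group("case")].mean(axis=1)
            ctrl = norm[cm.samples_in_group("control")].mean(axis=1)
            for g, lfc in truth.dm_promoters.items():
                rid = f"{g}|promoter"
                deltas.append(np.log2((case[rid] + 0.5) / (ctrl[rid] + 0.5)) - lfc)
        assert abs(np.mean(deltas)) < 0.2


class TestTrnAndSignatures:
    def test_trn_structure(self):
        cfg = SimulationConfig(seed=8, **SMALL)
        truth = plan_truth(cfg)
        net = simulate_trn(cfg, truth)
        assert net.n_edges == (cfg.n_tfs + cfg.n_background_tfs) * cfg.regulon_size
        for tf, regulon in truth.tf_regulons.items():
            assert net.targets_of(tf) == regulon

    def test_hit_compound_tf_at_extreme_rank_every_replicate(self):
        cfg = SimulationConfig(seed=9, compound_effect_size=10.0, **SMALL)
        truth = plan_truth(cfg)
        sigs = simulate_compound_signatures(cfg, truth)
        for hit in truth.compound_hits:
            arr = sigs.scores[(hit["compound"], hit["context"])]
            tf_idx = list(sigs.genes).index(hit["tf"])
            for rep in range(arr.shape[1]):
                rank = (np.argsort(-arr[:, rep]) == tf_idx).argmax() + 1
                if hit["direction"] == "up":
                    assert rank == 1
                else:
                    assert rank == cfg.n_genes

    def test_signature_determinism(self):
        cfg = SimulationConfig(seed=10, **SMALL)
        truth = plan_truth(cfg)
        s1 = simulate_compound_signatures(cfg, truth)
        s2 = simulate_compound_signatures(cfg, truth)
        for key in s1.scores:
            assert np.array_equal(s1.scores[key], s2.scores[key])


class TestWriteDataset:
    def test_bundle_round_trips(self, tmp_path):
        from methyltrx import io as mio
        cfg = SimulationConfig(seed=11, n_genes=100, n_compounds=4,
                               n_hit_compounds=1, n_tfs=2, n_background_tfs=1,
                               regulon_size=8, frac_de=0.3, frac_dm_promoter=0.05)
        from methyltrx.simulate import write_dataset
        ds = simulate_dataset(cfg)
        write_dataset(ds, tmp_path)
        expr = mio.read_count_matrix(tmp_path / "expr_counts.tsv",
                                     tmp_path / "groups.tsv")
        assert expr == ds["expression"]
        genes = mio.read_gene_annotation(tmp_path / "annotation.gtf")
        assert len(genes) == 100
        net = mio.read_network(tmp_path / "trn.tsv")
        assert net.n_edges == ds["network"].n_edges
        sigs = mio.read_signature_dir(tmp_path / "signatures")
        assert set(sigs.scores) == set(ds["signatures"].scores)
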