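"""Generator determinism, planted-truth reachability and schema conformance."""

import numpy as np
import pytest

from herborgan import io_formats
from herborgan.compound_screen import adme_filter, dedup_compounds
from herborgan.errors import PipelineUsageError
from herborgan.ppi_core import build_network, select_core
from herborgan.synthetic_data import (
    TruthBundle,
    gen_atlas,
    gen_catalog_and_list,
    gen_compounds,
    gen_ppi,
    gen_study,
)


class TestGenCompounds:
    def test_exact_planted_active_count(self):
        records, truth = gen_compounds(n=100, frac_active=0.17, seed=1)
        active = adme_filter(dedup_compounds(records))
        assert len(active) == 17
        assert {r.name for r in active} == set(truth.planted_active_compounds)

    def test_zero_active_fraction(self):
        records, _ = gen_compounds(n=50, frac_active=0.0, seed=2)
        assert adme_filter(dedup_compounds(records)) == []

    def test_same_seed_identical(self):
        a, _ = gen_compounds(n=60, seed=9)
        b, _ = gen_compounds(n=60, seed=9)
        assert a == b

    def test_bad_fraction_rejected(self):
        with pytest.raises(PipelineUsageError):
            gen_compounds(frac_active=1.5)


class TestGenPpi:
    def test_core_recovers_planted_hubs(self):
        edges, truth = gen_ppi(n_genes=200, n_hubs=3, hub_p=0.8, spoke_p=0.01, seed=7)
        core = select_core(build_network(edges, min_score=0.9))
        assert set(core) == set(truth.planted_hubs)

    def test_degenerate_probabilities_refused(self):
        with pytest.raises(PipelineUsageError):
            gen_ppi(hub_p=0.01, spoke_p=0.01)
        edges, _ = gen_ppi(hub_p=0.01, spoke_p=0.01, force=True, seed=0)
        assert isinstance(edges, list)

    def test_same_seed_identical(self):
        a, _ = gen_ppi(seed=4)
        b, _ = gen_ppi(seed=4)
        assert a == b

    def test_scores_split_cleanly_at_cutoff(self):
        edges, truth = gen_ppi(seed=3)
        high = {frozenset((a, b)) for a, b, s in edges if s > 0.9}
        low = {frozenset((a, b)) for a, b, s in edges if s <= 0.9}
        assert high and low and not (high & low)

    def test_scores_survive_integer_export(self, tmp_path):
        edges, _ = gen_ppi(seed=2)
        p = tmp_path / "ppi.tsv"
        io_formats.write_edge_list(edges, p, scale=1000)
        assert io_formats.read_edge_list(p) == edges


class TestGenCatalogAndList:
    def test_planted_terms_exist_with_stated_sizes(self):
        catalog, genes, truth = gen_catalog_and_list(seed=0)
        assert catalog.term_count == 150
        assert len(catalog.terms["planted_enriched"]) == 100
        assert len(catalog.terms["planted_depleted"]) == 1500
        assert len(genes) == 50
        assert "planted_enriched" in truth.planted_enriched_terms

    def test_list_avoids_depleted_term(self):
        catalog, genes, _ = gen_catalog_and_list(seed=8)
        assert not set(genes) & catalog.terms["planted_depleted"]

    def test_null_mode_is_uniform(self):
        catalog, genes, truth = gen_catalog_and_list(signal_fraction=None, seed=5)
        assert len(genes) == 50 and truth.planted_enriched_terms == {}

    def test_same_seed_identical(self):
        c1, g1, _ = gen_catalog_and_list(seed=6)
        c2, g2, _ = gen_catalog_and_list(seed=6)
        assert c1.terms == c2.terms and g1 == g2


class TestGenAtlas:
    def test_same_seed_identical(self):
        (a1, b1), _ = gen_atlas(n_genes=20, seed=3)
        (a2, b2), _ = gen_atlas(n_genes=20, seed=3)
        assert a1.frame.equals(a2.frame) and b1.frame.equals(b2.frame)

    def test_pair_shares_truth_but_not_noise(self):
        (a, b), truth = gen_atlas(n_genes=20, seed=4)
        assert not a.frame.equals(b.frame)
        assert set(truth.planted_gene_groups) == set(a.genes) == set(b.genes)

    def test_fold_below_one_rejected(self):
        with pytest.raises(PipelineUsageError):
            gen_atlas(fold=0.5)

    def test_strong_fold_recovers_groups(self):
        from herborgan.expression_linking import assign_top_group, default_organ_grouping

        (atlas, _), truth = gen_atlas(n_genes=200, fold=4.0, cv=0.3, seed=0)
        assigned = assign_top_group(atlas, default_organ_grouping())
        ok = sum(assigned[g] == truth.planted_gene_groups[g] for g in atlas.genes)
        assert ok / len(atlas.genes) >= 0.95


class TestGenStudy:
    def test_bundle_validates_against_all_readers(self, tmp_path):
        paths, truth = gen_study(seed=2, out_dir=tmp_path)
        records = io_formats.read_compound_table(paths["compounds"])
        assert len(records) > 0
        assocs = io_formats.read_association_table(paths["associations"])
        assert len(assocs) > 0
        edges = io_formats.read_edge_list(paths["ppi"])
        assert all(0 <= s <= 1 for _, _, s in edges)
        catalog = io_formats.read_catalog(paths["catalog"])
        assert catalog.term_count == 150
        for key in ("atlas_mean", "atlas_z_a", "atlas_z_b"):
            atlas = io_formats.read_expression_matrix(paths[key])
            assert len(atlas.genes) == truth.union_size
        grouping = io_formats.read_grouping(paths["grouping"])
        assert set(grouping.values()) == set(truth.planted_gene_groups.values())

    def test_truth_round_trips_json(self, tmp_path):
        paths, truth = gen_study(seed=3, out_dir=tmp_path)
        assert TruthBundle.from_json(paths["truth"]) == truth

    def test_different_seeds_same_schema(self, tmp_path):
        p1, _ = gen_study(seed=1, out_dir=tmp_path / "a")
        p2, _ = gen_study(seed=2, out_dir=tmp_path / "b")
        assert set(p1) == set(p2)
        assert (
            (tmp_path / "a" / "compounds.tsv").read_text()
            != (tmp_path / "b" / "compounds.tsv").read_text()
        )
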