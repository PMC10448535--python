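"""Atlas consensus, linking rules, Z-scores and organ-group assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from herborgan.errors import DomainError, PipelineUsageError
from herborgan.expression_linking import (
    ExpressionAtlas,
    assign_top_group,
    consensus_max,
    default_organ_grouping,
    link_above_mean,
    link_positive_z,
    organ_degree_ranking,
    zscore_rows,
)


def _atlas(rows, genes=None, tissues=None):
    arr = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    tissues = tissues or [f"t{j + 1}" for j in range(arr.shape[1])]
    return ExpressionAtlas(pd.DataFrame(arr, index=genes, columns=tissues))


def test_negative_values_rejected():
    with pytest.raises(DomainError):
        _atlas([[1.0, -0.1]])


class TestConsensusMax:
    def test_elementwise_max(self):
        a = _atlas([[5.0]], genes=["g"], tissues=["t"])
        b = _atlas([[7.0]], genes=["g"], tissues=["t"])
        assert consensus_max(a, b).frame.loc["g", "t"] == 7.0

    def test_tissue_only_in_one_source_carried(self):
        a = _atlas([[5.0, 2.0]], genes=["g"], tissues=["t1", "t2"])
        b = _atlas([[9.0]], genes=["g"], tissues=["t1"])
        merged = consensus_max(a, b)
        assert merged.tissues == ["t1", "t2"]
        assert merged.frame.loc["g"].tolist() == [9.0, 2.0]

    def test_genes_are_intersection(self):
        a = _atlas([[1.0], [2.0]], genes=["g1", "g2"], tissues=["t"])
        b = _atlas([[3.0], [4.0]], genes=["g2", "g3"], tissues=["t"])
        assert consensus_max(a, b).genes == ["g2"]

    def test_random_pair_against_brute_force(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(50)]
        tissues = [f"t{j}" for j in range(10)]
        a = _atlas(rng.lognormal(2, 1, (50, 10)), genes, tissues)
        b = _atlas(rng.lognormal(2, 1, (50, 10)), genes, tissues)
        merged = consensus_max(a, b)
        for gi in range(0, 50, 7):
            for tj in range(10):
                assert merged.frame.iloc[gi, tj] == max(
                    a.frame.iloc[gi, tj], b.frame.iloc[gi, tj]
                )


class TestLinkAboveMean:
    def test_boundary_at_the_mean(self):
        links = link_above_mean(_atlas([[1.0, 2.0, 3.0]], genes=["g"]))
        assert links.edges == {("g", "t3")}  # 2 is not > mean 2

    def test_constant_row_produces_no_links(self):
        assert len(link_above_mean(_atlas([[5.0, 5.0, 5.0]]))) == 0

    def test_against_row_scan_oracle(self):
        rng = np.random.default_rng(1)
        atlas = _atlas(rng.lognormal(3, 0.8, (200, 84)))
        links = link_above_mean(atlas)
        oracle = set()
        for g in atlas.genes:
            row = atlas.frame.loc[g]
            for t in atlas.tissues:
                if row[t] > row.mean():
                    oracle.add((g, t))
        assert links.edges == oracle

    def test_non_constant_rows_link_between_1_and_t_minus_1(self):
        rng = np.random.default_rng(2)
        atlas = _atlas(rng.lognormal(0, 1, (100, 12)))
        links = link_above_mean(atlas)
        per_gene = {g: 0 for g in atlas.genes}
        for g, _ in links.edges:
            per_gene[g] += 1
        assert all(1 <= c <= 11 for c in per_gene.values())


class TestZScores:
    def test_unit_spacing_row(self):
        z = zscore_rows(_atlas([[1.0, 2.0, 3.0]], genes=["g"]), ddof=1)
        assert z.frame.loc["g"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_flagged(self):
        z = zscore_rows(_atlas([[4.0, 4.0, 4.0]], genes=["g"]))
        assert z.constant_rows == {"g"}
        assert z.frame.loc["g"].isna().all()

    def test_single_tissue_usage_error(self):
        with pytest.raises(PipelineUsageError):
            zscore_rows(_atlas([[1.0]]))

    @pytest.mark.parametrize("ddof", [0, 1])
    def test_rows_standardized(self, random_atlas, ddof):
        z = zscore_rows(random_atlas, ddof=ddof)
        means = z.frame.mean(axis=1)
        sds = z.frame.std(axis=1, ddof=ddof)
        assert np.allclose(means, 0, atol=1e-9)
        assert np.allclose(sds, 1, atol=1e-9)


class TestLinkPositiveZ:
    def test_strictly_positive_only(self):
        z = zscore_rows(_atlas([[1.0, 2.0, 3.0]], genes=["g"]))
        assert link_positive_z(z).edges == {("g", "t3")}

    def test_identity_with_above_mean_on_non_constant_rows(self, random_atlas):
        assert link_positive_z(zscore_rows(random_atlas)).edges == link_above_mean(
            random_atlas
        ).edges

    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(1, 8), st.integers(2, 10)),
            elements=st.floats(0, 1e6, allow_nan=False),
        )
    )
    def test_identity_property(self, arr):
        atlas = _atlas(arr)
        constant = {g for g in atlas.genes if atlas.frame.loc[g].nunique() == 1}
        above = {(g, t) for g, t in link_above_mean(atlas).edges if g not in constant}
        assert link_positive_z(zscore_rows(atlas)).edges == above


class TestAssignTopGroup:
    def test_cell_type_maps_to_organ_of_origin(self):
        grouping = default_organ_grouping()
        atlas = _atlas(
            [[900.0, 400.0, 100.0]],
            genes=["g"],
            tissues=["CD33+ myeloid cells", "whole blood", "prostate"],
        )
        assert assign_top_group(atlas, grouping) == {"g": "bone marrow"}

    def test_tie_broken_lexicographically(self, caplog):
        grouping = {"t1": "zeta", "t2": "alpha"}
        atlas = _atlas([[7.0, 7.0]], genes=["g"])
        with caplog.at_level("INFO"):
            assert assign_top_group(atlas, grouping) == {"g": "alpha"}
        assert "tie" in caplog.text

    def test_all_zero_gene_unassigned(self, caplog):
        grouping = {"t1": "a", "t2": "b"}
        atlas = _atlas([[0.0, 0.0], [1.0, 2.0]], genes=["dead", "live"])
        with caplog.at_level("INFO"):
            out = assign_top_group(atlas, grouping)
        assert "dead" not in out and out["live"] == "b"

    def test_group_value_is_max_over_member_tissues(self):
        grouping = {"t1": "A", "t2": "A", "t3": "B"}
        # group A max = 10 beats B = 9 even though A also has a low tissue
        atlas = _atlas([[10.0, 1.0, 9.0]], genes=["g"])
        assert assign_top_group(atlas, grouping) == {"g": "A"}

    def test_assigned_group_contains_an_above_mean_tissue(self):
        from herborgan.synthetic_data import gen_atlas

        (atlas, _), truth = gen_atlas(n_genes=50, seed=5)
        grouping = default_organ_grouping()
        links = link_above_mean(atlas)
        for gene, grp in assign_top_group(atlas, grouping).items():
            linked_groups = {
                grouping[t] for g, t in links.edges if g == gene and t in grouping
            }
            assert grp in linked_groups


class TestOrganDegreeRanking:
    def test_tally_and_order(self):
        links = [("g1", "t1"), ("g2", "t1"), ("g1", "t2")]
        assert organ_degree_ranking(links) == [("t1", 2), ("t2", 1)]

    def test_empty(self):
        assert organ_degree_ranking([]) == []

    def test_degree_sum_equals_edge_count(self, random_atlas):
        links = link_above_mean(random_atlas)
        ranking = organ_degree_ranking(links)
        assert sum(d for _, d in ranking) == len(links)
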