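"""Containers, Newick parsing, KEGG BRITE parsing, and the genus filter."""
import math

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from petoscan import (
    FunctionMatrix,
    Hierarchy,
    KegFormatError,
    NewickParseError,
    PhyloTree,
    SpeciesTable,
    ValidationError,
    count_genes_per_category,
    keg_hierarchy,
    parse_newick,
    resolve_polytomies,
    select_representatives,
)
from petoscan.pic import compute_contrasts


def _species_frame(**overrides):
    base = dict(
        species_id=["hsa", "mmu", "cfa"],
        genus=["Homo", "Mus", "Canis"],
        body_mass_g=[7.0e4, 20.0, 1.2e4],
        mass_specific_rate_Wg=[1.2e-3, 1.0e-2, 2.3e-3],
        genome_year=[2003, 2002, 2005],
    )
    base.update(overrides)
    return pd.DataFrame(base)


class TestSpeciesTable:
    def test_roundtrip_and_log_columns(self, tmp_path):
        table = SpeciesTable(_species_frame())
        path = tmp_path / "species.tsv"
        table.to_tsv(path)
        back = SpeciesTable.read_tsv(path)
        pd.testing.assert_frame_equal(table.frame, back.frame)
        np.testing.assert_allclose(back.log10_mass, np.log10([7.0e4, 20.0, 1.2e4]))
        np.testing.assert_allclose(back.log10_bc, np.log10([1.2e-3, 1.0e-2, 2.3e-3]))

    @pytest.mark.parametrize(
        "overrides",
        [
            {"body_mass_g": [7.0e4, -20.0, 1.2e4]},
            {"mass_specific_rate_Wg": [0.0, 1.0e-2, 2.3e-3]},
            {"species_id": ["hsa", "hsa", "cfa"]},
        ],
    )
    def test_invariant_violations_rejected(self, overrides):
        with pytest.raises(ValidationError):
            SpeciesTable(_species_frame(**overrides))

    def test_whole_organism_rate_must_be_consistent(self):
        frame = _species_frame(metabolic_rate_W=[84.0, 0.2, 27.6])
        SpeciesTable(frame)  # B = Bc * M exactly: fine
        frame_bad = _species_frame(metabolic_rate_W=[84.0, 0.3, 27.6])
        with pytest.raises(ValidationError, match="mmu"):
            SpeciesTable(frame_bad)

    def test_subset_preserves_requested_order(self):
        table = SpeciesTable(_species_frame())
        sub = table.subset(["cfa", "hsa"])
        assert sub.species_ids == ["cfa", "hsa"]
        with pytest.raises(KeyError):
            table.subset(["cfa", "xyz"])


class TestFunctionMatrix:
    def test_tsv_roundtrip_both_orientations(self, tmp_path):
        matrix = FunctionMatrix(
            ["s1", "s2"], ["catA", "catB", "catC"], np.arange(6).reshape(2, 3)
        )
        for species_as_columns in (True, False):
            path = tmp_path / f"m_{species_as_columns}.tsv"
            matrix.to_tsv(path, species_as_columns=species_as_columns)
            back = FunctionMatrix.read_tsv(path, species_as_columns=species_as_columns)
            assert back.species_ids == matrix.species_ids
            assert back.category_ids == matrix.category_ids
            np.testing.assert_array_equal(back.counts, matrix.counts)

    @pytest.mark.parametrize(
        "counts",
        [np.array([[1, -1], [0, 2]]), np.array([[1.5, 1.0], [0.0, 2.0]])],
    )
    def test_negative_or_fractional_counts_rejected(self, counts):
        with pytest.raises(ValidationError):
            FunctionMatrix(["s1", "s2"], ["a", "b"], counts)

    def test_integral_floats_accepted(self):
        m = FunctionMatrix(["s1", "s2"], ["a", "b"], np.array([[1.0, 2.0], [3.0, 0.0]]))
        assert m.counts.dtype == np.int64

    def test_subset_species(self):
        matrix = FunctionMatrix(["s1", "s2", "s3"], ["a"], np.array([[1], [2], [3]]))
        sub = matrix.subset_species(["s3", "s1"])
        np.testing.assert_array_equal(sub.counts[:, 0], [3, 1])


class TestNewick:
    def test_minimal_tree_topology(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        assert sorted(tree.leaf_labels) == ["A", "B", "C"]
        assert tree.n_tips == 3
        # C hangs directly off the root at distance 2
        (c,) = [t for t in tree.tips() if t.name == "C"]
        assert c.parent is tree.root and c.branch_length == 2.0

    @pytest.mark.parametrize(
        "text",
        [
            "(A:1,B:1;",          # unbalanced parentheses
            "(A:1,B:1)",          # missing terminator
            "((A:1,A:2):1,C:2);",  # duplicate leaf labels
            "(A:1,B:1); extra",   # trailing characters
            "(A:x,B:1);",         # bad branch length
        ],
    )
    def test_malformed_input_raises_with_offset(self, text):
        with pytest.raises(NewickParseError, match="offset"):
            parse_newick(text)

    def test_roundtrip_preserves_branch_lengths(self):
        text = "((A:1.5,B:0.5):2,(C:1,D:1):2);"
        tree = parse_newick(text)
        assert tree.n_tips == 4
        assert len(tree.internal_nodes()) == 3  # root + 2
        again = parse_newick(tree.to_newick())
        assert again.to_newick() == tree.to_newick()

    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1e6, allow_nan=False),
            min_size=4,
            max_size=16,
        )
    )
    def test_roundtrip_arbitrary_caterpillar(self, lengths):
        """Serialize→parse→serialize is the identity, at full float precision."""
        text = f"(T0:{lengths[0]!r},T1:{lengths[1]!r});"
        for i, bl in enumerate(lengths[2:], start=2):
            text = f"({text[:-1]}:{bl!r},T{i}:{bl!r});"
        tree = parse_newick(text)
        again = parse_newick(tree.to_newick())
        assert tree.to_newick() == again.to_newick()
        tips = {t.name: t.branch_length for t in tree.tips()}
        for i, bl in enumerate(lengths):
            if i >= 2:
                assert tips[f"T{i}"] == bl

    def test_agrees_with_dendropy(self):
        text = "((A:1.25,B:0.5):2.75,(C:1e-3,D:10):2,E:4.5);"
        mine = parse_newick(text)
        ref = dendropy.Tree.get(data=text, schema="newick")
        ref_lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in ref.leaf_node_iter()
        }
        my_lengths = {t.name: t.branch_length for t in mine.tips()}
        assert my_lengths == ref_lengths
        again = dendropy.Tree.get(data=mine.to_newick(), schema="newick")
        assert {l.taxon.label for l in again.leaf_node_iter()} == set(my_lengths)

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValidationError):
            parse_newick("(A:-1,B:1);")

    def test_prune_collapses_and_sums_branches(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        pruned = tree.prune_to(["A", "C"])
        lengths = {t.name: t.branch_length for t in pruned.tips()}
        assert lengths == {"A": 2.0, "C": 2.0}
        assert all(t.parent is pruned.root for t in pruned.tips())

    def test_resolve_polytomies_yields_binary_tree(self):
        tree = parse_newick("(A:1,B:1,C:1,D:1);")
        binary = resolve_polytomies(tree, seed=0)
        assert binary.is_binary()
        assert sorted(binary.leaf_labels) == ["A", "B", "C", "D"]
        # zero-length resolution: root-to-tip distances unchanged
        contrasts = compute_contrasts(binary, {"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0})
        np.testing.assert_allclose(contrasts.contrasts, 0.0)


KEG_SNIPPET = (
    "A<b>Metabolism</b>\n"
    "B  Carbohydrate\n"
    "C    00010 Glycolysis\n"
    "D      gene1\n"
    "D      gene2\n"
)


class TestKegParser:
    def test_basic_counting(self):
        assert count_genes_per_category(KEG_SNIPPET) == {"00010 Glycolysis": 2}

    def test_empty_category_counts_zero(self):
        assert count_genes_per_category("C    00020 TCA\n") == {"00020 TCA": 0}

    def test_duplicate_gene_ids_counted_once(self):
        text = "C  00030 PPP\nD  gene1 desc one\nD  gene1 desc two\nD  gene2\n"
        assert count_genes_per_category(text) == {"00030 PPP": 2}

    def test_gene_before_category_is_format_error(self):
        with pytest.raises(KegFormatError, match="line 2"):
            count_genes_per_category("B  Carbohydrate\nD  gene1\n")

    def test_a_and_b_lines_close_the_current_category(self):
        text = KEG_SNIPPET + "B  Energy\nC    00190 OxPhos\nD      gene3\n"
        counts = count_genes_per_category(text)
        assert counts == {"00010 Glycolysis": 2, "00190 OxPhos": 1}

    def test_html_markup_stripped_from_labels(self):
        text = "A<b>Meta</b>\nB  <i>Lipid</i>\nC    00061 FA <b>biosynthesis</b>\nD g1\n"
        assert count_genes_per_category(text) == {"00061 FA biosynthesis": 1}
        assert keg_hierarchy(text) == {"00061 FA biosynthesis": "Lipid"}

    def test_total_equals_distinct_genes_when_partitioned(self, rng):
        """With each gene in exactly one category, category totals sum to the
        number of distinct gene tokens in the file."""
        lines, all_genes = [], 0
        for b in range(3):
            lines.append(f"B  Block{b}")
            for c in range(4):
                lines.append(f"C  cat_{b}_{c}")
                k = int(rng.integers(0, 6))
                for g in range(k):
                    lines.append(f"D  gene_{b}_{c}_{g} some description")
                all_genes += k
        counts = count_genes_per_category("\n".join(lines))
        assert sum(counts.values()) == all_genes


class TestSelectRepresentatives:
    def _table(self, rows):
        return SpeciesTable(
            pd.DataFrame(
                rows,
                columns=["species_id", "genus", "body_mass_g", "mass_specific_rate_Wg", "genome_year"],
            )
        )

    def test_earliest_year_wins_by_default(self):
        table = self._table(
            [
                ["mm_a", "Mus", 20.0, 1e-2, 2010],
                ["mm_b", "Mus", 25.0, 1e-2, 2005],
            ]
        )
        kept = select_representatives(table)
        assert kept.species_ids == ["mm_b"]
        kept_latest = select_representatives(table, prefer="latest")
        assert kept_latest.species_ids == ["mm_a"]

    def test_single_genus_table_unchanged(self):
        table = self._table([["hsa", "Homo", 7e4, 1.2e-3, 2003]])
        assert select_representatives(table).species_ids == ["hsa"]

    def test_year_tie_broken_lexicographically(self):
        table = self._table(
            [
                ["mm_z", "Mus", 20.0, 1e-2, 2005],
                ["mm_a", "Mus", 25.0, 1e-2, 2005],
            ]
        )
        assert select_representatives(table).species_ids == ["mm_a"]

    def test_missing_year_in_contested_genus_is_an_error(self):
        table = self._table(
            [
                ["mm_a", "Mus", 20.0, 1e-2, pd.NA],
                ["mm_b", "Mus", 25.0, 1e-2, 2005],
                ["hsa", "Homo", 7e4, 1.2e-3, pd.NA],  # singleton: year not needed
            ]
        )
        with pytest.raises(ValidationError, match="Mus"):
            select_representatives(table)

    def test_one_row_per_genus(self, rng):
        genera = [f"G{i}" for i in rng.integers(0, 8, size=30)]
        rows = [
            [f"sp{i:02d}", g, float(rng.uniform(1, 100)), 1e-2, int(rng.integers(2000, 2015))]
            for i, g in enumerate(genera)
        ]
        kept = select_representatives(self._table(rows))
        assert len(kept) == len(set(genera))
        assert sorted(kept.frame["genus"]) == sorted(set(genera))


def test_hierarchy_roundtrip_and_lookup(tmp_path):
    h = Hierarchy({"c1": "U1", "c2": "U1", "c3": "U2"})
    path = tmp_path / "h.tsv"
    h.to_tsv(path)
    back = Hierarchy.read_tsv(path)
    assert back.mapping == h.mapping
    assert back.upper_of("c2") == "U1"
    assert set(back.categories_in("U1")) == {"c1", "c2"}
    assert "c9" not in back
    with pytest.raises(KeyError, match="c9"):
        back.upper_of("c9")
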