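"""Metadata loading, tree construction, propagation, filtering, export."""

import json

import numpy as np
import pytest

from taxomass import (MetadataRecord, aggregate_matches, build_tree,
                      export_tree, filter_tree, load_lineages, load_metadata,
                      tree_from_json, tree_to_dict, validate_tree_dict)
from taxomass.errors import (SchemaError, UnknownFileError, UnknownRankError)
from taxomass.taxonomy import BLANK_ID, QC_ID, UNCLASSIFIED_ID, LineageTable


def _lineages():
    # root(1) -> Bacteria(2) -> phylum(10) -> genus(20) -> species(30,31)
    #   species 30 -> strain(40)
    return LineageTable({
        2: (1, "Bacteria", "domain"),
        10: (2, "Phylum1", "phylum"),
        20: (10, "Genus1", "genus"),
        30: (20, "Genus1 speciesA", "species"),
        31: (20, "Genus1 speciesB", "species"),
        40: (30, "Genus1 speciesA strainX", "strain"),
    })


def _rec(name, ncbi=None, taxon="t", blank=False, qc=False, alt=None):
    return MetadataRecord(file_path=f"D1/peak/{name}.mzML",
                          file_name=f"D1/{name}", dataset_id="D1",
                          taxon_name=taxon, alt_taxon_name=alt, ncbi_id=ncbi,
                          is_blank=blank, is_qc=qc)


def conserved(node) -> bool:
    """Counters at internal nodes are exact sums over counting children."""
    kids = [c for c in node.children.values() if c.counts_in_parent]
    own = len(node.files)
    ok = True
    if node.children:
        ok = (node.n_files == own + sum(c.n_files for c in kids)
              and (own > 0  # files attached here: sums plus own matches
                   or node.n_matched == sum(c.n_matched for c in kids)))
    return ok and all(conserved(c) for c in node.children.values())


class TestMetadata:
    def test_three_row_fixture_flags(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text(
            "file_path\tfile_name\tdataset_id\ttaxon_name\talt_taxon_name\t"
            "ncbi_id\tid_assignment\tredu_available\tis_blank\tis_qc\n"
            "D1/a.mzML\tD1/a\tD1\tGenus1 speciesA\t\t30\tcurated\tTrue\tFalse\tFalse\n"
            "D1/b.mzML\tD1/b\tD1\tblank\t\t\tautomatic\tFalse\tTrue\tFalse\n"
            "D1/c.mzML\tD1/c\tD1\tQC\t\t\tautomatic\tFalse\tFalse\tTrue\n")
        recs = load_metadata(p)
        assert [r.is_blank for r in recs] == [False, True, False]
        assert [r.is_qc for r in recs] == [False, False, True]
        assert recs[0].ncbi_id == 30 and recs[1].ncbi_id is None

    def test_duplicate_file_name_rejected(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text(
            "file_path\tfile_name\tdataset_id\ttaxon_name\tncbi_id\t"
            "is_blank\tis_qc\n"
            "a\tD1/a\tD1\tt\t30\tFalse\tFalse\n"
            "b\tD1/a\tD1\tt\t30\tFalse\tFalse\n")
        with pytest.raises(SchemaError, match="duplicated"):
            load_metadata(p)

    def test_missing_mandatory_column_listed(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text("file_path\tfile_name\n a\tb\n")
        with pytest.raises(SchemaError) as err:
            load_metadata(p)
        assert "dataset_id" in str(err.value)

    def test_blank_and_qc_mutually_exclusive(self):
        with pytest.raises(SchemaError):
            _rec("x", blank=True, qc=True)

    def test_generated_table_loads_fully(self, repo_dir, manifest):
        recs = load_metadata(repo_dir / "metadata.tsv")
        assert len(recs) == len(manifest["files"])


class TestBuildTree:
    def test_two_files_same_species_count_along_lineage(self):
        recs = [_rec("f1", ncbi=30), _rec("f2", ncbi=30)]
        root = build_tree(recs, _lineages())
        species = root.children[2].children[10].children[20].children[30]
        assert species.n_files == 2
        assert root.children[2].n_files == 2
        assert root.n_files == 2

    def test_blank_and_qc_go_to_pseudo_children_excluded_from_totals(self):
        recs = [_rec("f1", ncbi=30), _rec("b1", blank=True),
                _rec("q1", qc=True)]
        root = build_tree(recs, _lineages())
        assert root.children[BLANK_ID].n_files == 1
        assert root.children[QC_ID].n_files == 1
        assert root.n_files == 1  # biological only

    def test_closest_taxon_fallback_attaches_at_resolvable_ancestor(self):
        # unknown NCBI id, name resolvable at species level via alt name
        recs = [_rec("f1", ncbi=99999, taxon="Genus1 speciesA CM05",
                     alt="Genus1 speciesA")]
        root = build_tree(recs, _lineages())
        species = root.children[2].children[10].children[20].children[30]
        assert species.n_files == 1

    def test_fallback_at_internal_node_keeps_strict_conservation(self):
        recs = [_rec("f1", ncbi=40),   # strain under species 30
                _rec("f2", ncbi=99999, taxon="Genus1 speciesA")]
        root = build_tree(recs, _lineages())
        species = root.children[2].children[10].children[20].children[30]
        assert species.n_files == 2
        assert not species.files  # file hangs off a synthetic child
        assert conserved(root)

    def test_unresolvable_record_routed_to_unclassified(self):
        recs = [_rec("f1", ncbi=None, taxon="Unheard-of organism")]
        root = build_tree(recs, _lineages())
        assert root.children[UNCLASSIFIED_ID].n_files == 1
        assert root.n_files == 1  # unclassified is still a biological sample

    def test_build_is_input_order_invariant(self):
        recs = [_rec("f1", ncbi=30), _rec("f2", ncbi=31), _rec("f3", ncbi=40),
                _rec("b1", blank=True)]
        t1 = build_tree(recs, _lineages())
        t2 = build_tree(list(reversed(recs)), _lineages())
        assert tree_to_dict(t1) == tree_to_dict(t2)

    def test_fixture_repository_tree_matches_generator_truth(self, repo,
                                                             manifest):
        n_bio = manifest["n_biological_files"]
        assert repo.tree.n_files == n_bio
        assert repo.tree.children[BLANK_ID].n_files == \
            manifest["spec"]["n_blanks"]
        assert conserved(repo.tree)


class TestAggregateMatches:
    def test_single_match_propagates_to_every_ancestor(self):
        recs = [_rec("f1", ncbi=40), _rec("f2", ncbi=31)]
        root = build_tree(recs, _lineages())
        aggregate_matches(root, {"D1/f1"})
        node = root
        for nid in (2, 10, 20, 30, 40):
            node = node.children[nid]
            assert node.n_matched == 1
        assert root.n_matched == 1
        assert root.children[2].children[10].children[20].children[31].n_matched == 0

    def test_empty_matched_set_zeroes_all(self):
        recs = [_rec("f1", ncbi=40)]
        root = build_tree(recs, _lineages())
        aggregate_matches(root, {"D1/f1"})
        aggregate_matches(root, set())
        assert all(n.n_matched == 0 for n in root.walk())

    def test_blank_match_stays_on_pseudo_node(self):
        recs = [_rec("f1", ncbi=40), _rec("b1", blank=True)]
        root = build_tree(recs, _lineages())
        aggregate_matches(root, {"D1/b1"})
        assert root.children[BLANK_ID].n_matched == 1
        assert root.n_matched == 0

    def test_unknown_file_errors_by_name(self):
        root = build_tree([_rec("f1", ncbi=40)], _lineages())
        with pytest.raises(UnknownFileError, match="D1/ghost"):
            aggregate_matches(root, {"D1/ghost"})

    def test_random_subsets_conserve_counts(self, repo, manifest):
        rng = np.random.default_rng(43)
        bio = [f for f, info in manifest["files"].items()
               if info["group"] not in ("blank", "qc")]
        import copy
        for _ in range(25):
            k = int(rng.integers(0, len(bio) + 1))
            chosen = set(rng.choice(bio, size=k, replace=False))
            tree = copy.deepcopy(repo.tree)
            aggregate_matches(tree, chosen)
            assert tree.n_matched == len(chosen)
            assert conserved(tree)
            prop = tree.proportion
            assert prop == pytest.approx(len(chosen) / tree.n_files)
            for node in tree.walk():
                assert node.n_matched <= node.n_files
                if node.proportion is not None:
                    assert 0.0 <= node.proportion <= 1.0


class TestFilterTree:
    def _matched_tree(self):
        recs = [_rec("f1", ncbi=40), _rec("f2", ncbi=31), _rec("f3", ncbi=31)]
        root = build_tree(recs, _lineages())
        aggregate_matches(root, {"D1/f1"})
        return root

    def test_min_matches_keeps_exactly_matched_lineage(self):
        root = self._matched_tree()
        out = filter_tree(root, min_matches=1)
        ids = {n.ncbi_id for n in out.walk()}
        assert ids == {1, 2, 10, 20, 30, 40}

    def test_rank_collapse_preserves_counts(self):
        root = self._matched_tree()
        out = filter_tree(root, max_rank="genus")
        genus = out.children[2].children[10].children[20]
        assert not genus.children
        assert genus.n_files == 3 and genus.n_matched == 1

    def test_pruning_never_changes_surviving_counts(self):
        root = self._matched_tree()
        before = {n.ncbi_id: (n.n_files, n.n_matched) for n in root.walk()}
        out = filter_tree(root, min_matches=1)
        for node in out.walk():
            assert before[node.ncbi_id] == (node.n_files, node.n_matched)

    def test_unknown_rank_rejected_with_valid_list(self):
        with pytest.raises(UnknownRankError, match="genus"):
            filter_tree(self._matched_tree(), max_rank="tribe")

    def test_root_always_retained(self):
        out = filter_tree(self._matched_tree(), min_matches=99)
        assert out.ncbi_id == 1
        assert not out.children


class TestExport:
    def test_json_depth_equals_lineage_length_plus_root(self, tmp_path):
        root = build_tree([_rec("f1", ncbi=40)], _lineages())
        path = export_tree(root, "json", tmp_path / "t.json")
        data = json.loads(path.read_text())
        validate_tree_dict(data)
        depth = 0
        node = data
        while node["children"]:
            taxon_children = [c for c in node["children"] if c["ncbi_id"] > 0]
            if not taxon_children:
                break
            node = taxon_children[0]
            depth += 1
        assert depth == 5  # domain, phylum, genus, species, strain

    def test_json_roundtrip_reproduces_counts(self, tmp_path, repo):
        import copy
        tree = copy.deepcopy(repo.tree)
        aggregate_matches(tree, {repo.records[0].file_name})
        path = export_tree(tree, "json", tmp_path / "t.json")
        back = tree_from_json(json.loads(path.read_text()))
        orig = {(n.ncbi_id, n.n_files, n.n_matched) for n in tree.walk()}
        new = {(n.ncbi_id, n.n_files, n.n_matched) for n in back.walk()}
        assert orig == new

    def test_newick_leaf_count_matches_terminal_nodes(self, tmp_path, repo):
        dendropy = pytest.importorskip("dendropy")
        path = export_tree(repo.tree, "newick", tmp_path / "t.nwk")
        n_leaves_expected = sum(1 for n in repo.tree.walk() if not n.children)
        tree = dendropy.Tree.get(data=path.read_text(), schema="newick",
                                 suppress_internal_node_taxa=False)
        assert len(tree.leaf_nodes()) == n_leaves_expected

    def test_html_is_self_contained_with_embedded_json(self, tmp_path, repo):
        path = export_tree(repo.tree, "html", tmp_path / "t.html")
        text = path.read_text()
        assert text.startswith("<!DOCTYPE html>")
        assert "http" not in text.split("</title>")[1]  # no external assets
        assert "tree-data" in text

    def test_unknown_format_rejected(self, tmp_path, repo):
        with pytest.raises(ValueError):
            export_tree(repo.tree, "svg", tmp_path / "t.svg")
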