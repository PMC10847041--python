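"""End-to-end search orchestration, result tables and their reconciliation."""

import numpy as np
import pandas as pd
import pytest

from taxomass import (SearchConfig, Spectrum, library_match, search_batch,
                      search_one, serialize_usi, write_mgf)
from taxomass.errors import InvalidSpectrumError


class TestSearchOne:
    def test_self_query_yields_perfect_match(self, repo):
        query = repo.spectra[0].copy(spectrum_id="q_self")
        job = search_one(query, repo.index, repo)
        assert job.matches[0].cosine == pytest.approx(1.0, abs=1e-9)
        perfect = {m.reference_id for m in job.matches
                   if m.cosine > 1 - 1e-9}
        assert repo.spectra[0].spectrum_id in perfect
        assert repo.spectra[0].source_file in job.matched_files
        assert job.tree.n_matched >= 1

    def test_query_outside_precursor_range_matches_nothing(self, repo):
        query = Spectrum("q_far", 2000.0, [100.0, 110.0, 120.0],
                         [1.0, 1.0, 1.0])
        job = search_one(query, repo.index, repo)
        assert job.matches == []
        assert job.tree.n_matched == 0
        assert len(job.tables["taxa_matches"]) == 0

    def test_unsearchable_query_rejected(self, repo):
        with pytest.raises(InvalidSpectrumError):
            search_one(Spectrum("q", None, [100.0], [1.0]), repo.index, repo)

    def test_planted_analogue_found_only_in_analogue_mode(self, repo,
                                                          manifest):
        pair = manifest["analogue_pairs"][0]
        base = manifest["patterns"][pair["base"]]
        query = Spectrum("q_ana", base["precursor_mz"],
                         np.array(base["mz"]), np.array(base["intensities"]))
        off = search_one(query, repo.index, repo, SearchConfig(analogue=False))
        assert off.matches == []
        on = search_one(query, repo.index, repo, SearchConfig(analogue=True))
        assert len(on.matches) >= 1
        matched_taxa = set(on.tables["taxa_matches"]["ncbi_id"])
        assert pair["taxon_ncbi"] in matched_taxa

    def test_blank_match_flagged_and_kept_out_of_taxa_table(self, repo,
                                                            manifest):
        cont = manifest["patterns"][manifest["contaminant_patterns"][0]]
        query = Spectrum("q_cont", cont["precursor_mz"],
                         np.array(cont["mz"]), np.array(cont["intensities"]))
        job = search_one(query, repo.index, repo)
        ds = job.tables["dataset_matches"]
        assert ds["is_blank"].any() and ds["is_qc"].any()
        # contaminants live only in blanks/QCs: no taxon may claim them
        assert len(job.tables["taxa_matches"]) == 0
        assert job.tree.n_matched == 0


class TestTables:
    def test_dataset_table_row_per_matching_scan_sorted(self, repo):
        query = repo.spectra[0].copy(spectrum_id="q")
        job = search_one(query, repo.index, repo)
        ds = job.tables["dataset_matches"]
        assert len(ds) == len(job.matches)
        assert list(ds["cosine"]) == sorted(ds["cosine"], reverse=True)

    def test_taxa_table_rows_equal_tree_nodes(self, repo):
        query = repo.spectra[0].copy(spectrum_id="q")
        job = search_one(query, repo.index, repo)
        taxa = job.tables["taxa_matches"].set_index("ncbi_id")
        nodes = {n.ncbi_id: n for n in job.tree.walk()
                 if n.n_matched > 0 and n.ncbi_id not in (-1, -2)}
        assert set(taxa.index) == set(nodes)
        for nid, node in nodes.items():
            row = taxa.loc[nid]
            assert row["n_matched"] == node.n_matched
            assert row["n_files"] == node.n_files

    def test_matched_strain_reports_every_ancestor(self, repo, manifest):
        query = repo.spectra[0].copy(spectrum_id="q")
        job = search_one(query, repo.index, repo)
        ranks = set(job.tables["taxa_matches"]["rank"])
        assert {"strain", "species", "genus", "family", "order", "class",
                "phylum", "domain", "root"} <= ranks

    def test_tables_reconcile_distinct_matched_files(self, repo, queries):
        specs, _ = queries
        for q in specs[:8]:
            job = search_one(q, repo.index, repo)
            ds = job.tables["dataset_matches"]
            bio = ds[~(ds["is_blank"] | ds["is_qc"])]
            n_files = bio["file_name"].nunique()
            assert job.tree.n_matched == n_files
            taxa = job.tables["taxa_matches"]
            if n_files:
                root_row = taxa[taxa["rank"] == "root"].iloc[0]
                assert root_row["n_matched"] == n_files


class TestLibraryMatch:
    def test_library_containing_query_tops_table(self, repo):
        q = repo.spectra[0].copy(spectrum_id="q")
        lib = [repo.spectra[0].copy(spectrum_id="LIB0001|compound X")]
        table = library_match(q, lib)
        assert table.iloc[0]["annotation"] == "compound X"
        assert table.iloc[0]["cosine"] == pytest.approx(1.0, abs=1e-9)

    def test_empty_library_gives_empty_table(self, repo):
        q = repo.spectra[0].copy(spectrum_id="q")
        assert len(library_match(q, [])) == 0

    def test_near_duplicates_both_pass_ordered_by_cosine(self, repo):
        q = repo.spectra[0].copy(spectrum_id="q")
        exact = q.copy(spectrum_id="LIB1|exact")
        damped = q.copy(spectrum_id="LIB2|damped",
                        intensities=q.intensities * np.linspace(1, 3,
                                                                q.n_peaks))
        table = library_match(q, [damped, exact])
        assert list(table["library_id"]) == ["LIB1", "LIB2"]
        assert table["cosine"].iloc[0] >= table["cosine"].iloc[1]


class TestBatch:
    def test_batch_with_malformed_usi_records_error_row(self, repo, tmp_path):
        good = [s for s in repo.spectra[:2]]
        tsv = tmp_path / "batch.tsv"
        tsv.write_text("\n".join([serialize_usi(
            __import__("taxomass").parse_usi(s.spectrum_id)) for s in good]
            + ["mzspec:only:two"]) + "\n")
        jobs, summary = search_batch(tsv, repo.index, repo)
        assert len(jobs) == 2
        assert len(summary) == 3
        assert (summary["status"] == "error").sum() == 1

    def test_batch_of_fixture_self_queries_all_match(self, repo, tmp_path):
        specs = [s.copy(spectrum_id=f"q{i}") for i, s in
                 enumerate(repo.spectra[:5])]
        mgf = tmp_path / "batch.mgf"
        write_mgf(specs, mgf)
        jobs, summary = search_batch(mgf, repo.index, repo)
        assert len(jobs) == 5
        assert (summary["n_matches"] >= 1).all()
        assert (summary["top_cosine"] >= 0.999999).all()

    def test_empty_mgf_batch_warns_and_succeeds(self, repo, tmp_path):
        mgf = tmp_path / "empty.mgf"
        mgf.write_text("")
        with pytest.warns(UserWarning):
            jobs, summary = search_batch(mgf, repo.index, repo)
        assert jobs == [] and len(summary) == 0

    def test_batch_of_one_equals_single_search(self, repo, tmp_path):
        q = repo.spectra[0].copy(spectrum_id="q1")
        mgf = tmp_path / "one.mgf"
        write_mgf([q], mgf)
        jobs, _ = search_batch(mgf, repo.index, repo)
        single = search_one(jobs[0].query_spectrum, repo.index, repo)
        assert [m for m in jobs[0].matches] == [m for m in single.matches]
        for name in ("dataset_matches", "taxa_matches", "library_matches"):
            pd.testing.assert_frame_equal(jobs[0].tables[name],
                                          single.tables[name])


class TestThresholdMonotonicity:
    def test_tighter_thresholds_give_subset_matches(self, repo, queries):
        specs, _ = queries
        configs = [SearchConfig(min_cosine=0.8, min_matched_ions=4),
                   SearchConfig(min_cosine=0.7, min_matched_ions=3),
                   SearchConfig(min_cosine=0.6, min_matched_ions=2)]
        for q in specs[:10]:
            sets = []
            for cfg in configs:
                job = search_one(q, repo.index, repo, cfg)
                sets.append({m.reference_id for m in job.matches})
            assert sets[0] <= sets[1] <= sets[2]

    def test_smaller_tolerance_gives_subset(self, repo, queries):
        specs, _ = queries
        tight = SearchConfig(precursor_tol=0.01, fragment_tol=0.01)
        loose = SearchConfig()
        for q in specs[:6]:
            a = {m.reference_id for m in
                 search_one(q, repo.index, repo, tight).matches}
            b = {m.reference_id for m in
                 search_one(q, repo.index, repo, loose).matches}
            assert a <= b
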