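"""End-to-end repository search: candidates -> scoring -> taxonomic tree.

:class:`Repository` bundles the reference spectra, the file-to-taxon
metadata, the lineage table, the base taxonomic tree and the precursor
index, all built from the on-disk layout the fixture generator emits
(``metadata.tsv``, ``lineages.tsv``, ``spectra/<dataset>/*.mgf``).

A query runs as: precursor-index candidate retrieval, modified-cosine
scoring, inclusive thresholding, then aggregation of the distinct matched
files onto a per-query copy of the tree. Three result tables mirror the
usual repository-search outputs: per-scan dataset matches, per-taxon
matches (consistent with the tree counters), and annotated library
matches.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import InvalidSpectrumError, TaxomassError, UsiParseError
from .index import SpectrumIndex, build_index, query_candidates
from .similarity import MatchResult, SearchConfig, modified_cosine, passes_thresholds
from .spectra import Spectrum, read_mgf
from .taxonomy import (MetadataRecord, TaxonNode, aggregate_matches,
                       build_tree, load_lineages, load_metadata)
from .usi import parse_usi, resolve_usi

__all__ = ["Repository", "QueryJob", "search_one", "search_batch",
           "library_match", "dataset_matches_table", "taxa_matches_table"]


class Repository:
    """A loaded reference repository: spectra + metadata + tree + index."""

    def __init__(self, records: list[MetadataRecord], lineages,
                 spectra: list[Spectrum]):
        self.records = records
        self.by_file = {r.file_name: r for r in records}
        self.lineages = lineages
        self.spectra = spectra
        self.tree = build_tree(records, lineages)
        self.index = build_index(spectra)
        self._datasets: dict | None = None

    @classmethod
    def load(cls, repo_dir: str | Path) -> "Repository":
        """Load a repository directory (metadata.tsv, lineages.tsv, spectra/)."""
        repo_dir = Path(repo_dir)
        records = load_metadata(repo_dir / "metadata.tsv")
        lineages = load_lineages(repo_dir / "lineages.tsv")
        spectra: list[Spectrum] = []
        for rec in records:
            base = rec.file_name.split("/", 1)[-1]
            mgf = repo_dir / "spectra" / rec.dataset_id / f"{base}.mgf"
            if not mgf.exists():
                warnings.warn(f"no spectra file for {rec.file_name}",
                              stacklevel=2)
                continue
            for s in read_mgf(mgf):
                s.source_file = rec.file_name
                s.dataset_id = rec.dataset_id
                spectra.append(s)
        return cls(records, lineages, spectra)

    def spectra_by_dataset(self) -> dict[str, dict[str, list[Spectrum]]]:
        if self._datasets is None:
            out: dict[str, dict[str, list[Spectrum]]] = {}
            for s in self.spectra:
                base = (s.source_file or "").split("/", 1)[-1]
                out.setdefault(s.dataset_id or "", {}).setdefault(base, []).append(s)
            self._datasets = out
        return self._datasets

    @property
    def fingerprint(self) -> str:
        return self.index.build_fingerprint


@dataclass
class QueryJob:
    """Result bundle of one query: accepted matches, tree, result tables."""

    query_id: str
    query_spectrum: Spectrum
    config: SearchConfig
    matches: list[MatchResult]
    tree: TaxonNode
    #: distinct reference file names (metadata-qualified) with >=1 match
    matched_files: set[str] = field(default_factory=set)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _reference_file(repo: Repository, match: MatchResult) -> str:
    """Map a reference spectrum ID back to its qualified file name."""
    for s in repo.spectra:
        if s.spectrum_id == match.reference_id:
            return s.source_file
    raise TaxomassError(f"reference {match.reference_id!r} not in repository")


def search_one(query: Spectrum, ix: SpectrumIndex, repo: Repository,
               cfg: SearchConfig | None = None,
               library: list[Spectrum] | None = None) -> QueryJob:
    """Search a single query spectrum against the repository.

    Raises :class:`InvalidSpectrumError` for unsearchable queries. The
    index must belong to the repository (fingerprint check).
    """
    cfg = cfg or SearchConfig()
    if not query.is_searchable:
        raise InvalidSpectrumError(
            f"query {query.spectrum_id!r} lacks precursor m/z or peaks")
    if ix.build_fingerprint != repo.fingerprint:
        raise TaxomassError("index fingerprint does not match repository; "
                            "rebuild the index from the loaded spectra")
    matches: list[MatchResult] = []
    for cand in query_candidates(ix, query.precursor_mz, cfg):
        m = modified_cosine(query, cand, cfg)
        if passes_thresholds(m, cfg):
            matches.append(m)
    matches.sort(key=lambda m: (-m.cosine, m.reference_id))

    # one credit per distinct matched file, scans notwithstanding
    matched_files = set()
    spec_to_file = {s.spectrum_id: s.source_file for s in repo.spectra}
    for m in matches:
        matched_files.add(spec_to_file[m.reference_id])
    tree = copy.deepcopy(repo.tree)
    aggregate_matches(tree, matched_files)

    job = QueryJob(query_id=query.spectrum_id, query_spectrum=query,
                   config=cfg, matches=matches, tree=tree,
                   matched_files=matched_files)
    job.tables["dataset_matches"] = dataset_matches_table(job, repo)
    job.tables["taxa_matches"] = taxa_matches_table(job)
    job.tables["library_matches"] = library_match(query, library or [], cfg)
    return job


def dataset_matches_table(job: QueryJob, repo: Repository) -> pd.DataFrame:
    """One row per matching scan, sorted by cosine desc then file name."""
    rows = []
    spec_to_file = {s.spectrum_id: s.source_file for s in repo.spectra}
    for m in job.matches:
        fname = spec_to_file[m.reference_id]
        rec = repo.by_file[fname]
        lin = None
        if rec.ncbi_id is not None:
            lin = repo.lineages.lineage(rec.ncbi_id)
        rank = lin.ranked_path[-1][2] if lin else None
        rows.append({
            "reference_id": m.reference_id,
            "file_name": fname,
            "dataset_id": rec.dataset_id,
            "taxon_name": rec.taxon_name,
            "ncbi_id": rec.ncbi_id,
            "rank": rank,
            "n_matched_ions": m.n_matched_ions,
            "cosine": m.cosine,
            "precursor_delta": m.precursor_delta,
            "is_blank": rec.is_blank,
            "is_qc": rec.is_qc,
        })
    cols = ["reference_id", "file_name", "dataset_id", "taxon_name",
            "ncbi_id", "rank", "n_matched_ions", "cosine",
            "precursor_delta", "is_blank", "is_qc"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["cosine", "file_name", "reference_id"],
                          ascending=[False, True, True]).reset_index(drop=True)


def taxa_matches_table(job: QueryJob) -> pd.DataFrame:
    """One row per taxon node with at least one match (blank/QC excluded)."""
    rows = []
    for node in job.tree.walk():
        if node.ncbi_id in (-1, -2):  # blank/QC pseudo-nodes are not taxa
            continue
        if node.n_matched > 0:
            rows.append({
                "name": node.name, "ncbi_id": node.ncbi_id,
                "rank": node.rank, "n_matched": node.n_matched,
                "n_files": node.n_files, "proportion": node.proportion,
            })
    cols = ["name", "ncbi_id", "rank", "n_matched", "n_files", "proportion"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["n_matched", "name"],
                          ascending=[False, True]).reset_index(drop=True)


def library_match(query: Spectrum, library: list[Spectrum],
                  cfg: SearchConfig | None = None) -> pd.DataFrame:
    """Search a query against an annotated spectral library.

    Same scoring and thresholds as the repository search. Annotation names
    (taken from the library spectrum IDs, ``<library_id>|<compound name>``
    or plain IDs) are candidate-level annotations, not identifications.
    """
    cfg = cfg or SearchConfig()
    rows = []
    for ref in library:
        if not ref.is_searchable:
            continue
        if abs(query.precursor_mz - ref.precursor_mz) > cfg.precursor_window:
            continue
        m = modified_cosine(query, ref, cfg)
        if not passes_thresholds(m, cfg):
            continue
        lib_id, _, name = ref.spectrum_id.partition("|")
        rows.append({"library_id": lib_id, "annotation": name or lib_id,
                     "cosine": m.cosine, "n_matched_ions": m.n_matched_ions,
                     "precursor_delta": m.precursor_delta})
    cols = ["library_id", "annotation", "cosine", "n_matched_ions",
            "precursor_delta"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["cosine", "library_id"],
                          ascending=[False, True]).reset_index(drop=True)


def search_batch(inputs: str | Path | list[Spectrum], ix: SpectrumIndex,
                 repo: Repository, cfg: SearchConfig | None = None,
                 library: list[Spectrum] | None = None
                 ) -> tuple[list[QueryJob], pd.DataFrame]:
    """Batch search from an .mgf file, a .tsv of USIs, or spectra in memory.

    Per-query failures are recorded in the summary without aborting the
    batch. Returns (jobs, summary table) with one summary row per input.
    """
    cfg = cfg or SearchConfig()
    queries: list[tuple[str, Spectrum | None, str | None]] = []
    if isinstance(inputs, (str, Path)):
        path = Path(inputs)
        if path.suffix.lower() == ".mgf":
            specs = read_mgf(path)
            if not specs:
                warnings.warn(f"batch input {path} is empty", stacklevel=2)
            queries = [(s.spectrum_id, s, None) for s in specs]
        elif path.suffix.lower() in (".tsv", ".txt"):
            for line in path.read_text().splitlines():
                line = line.strip()
                if not line or line.lower() == "usi":
                    continue
                try:
                    spec = resolve_usi(parse_usi(line), repo)
                    queries.append((line, spec, None))
                except (UsiParseError, TaxomassError) as exc:
                    queries.append((line, None, str(exc)))
        else:
            raise ValueError(f"unsupported batch input {path.suffix!r}; "
                             "use .mgf or .tsv of USIs")
    else:
        queries = [(s.spectrum_id, s, None) for s in inputs]

    jobs: list[QueryJob] = []
    summary_rows = []
    for qid, spec, err in queries:
        if err is None and spec is not None:
            try:
                job = search_one(spec, ix, repo, cfg, library=library)
            except TaxomassError as exc:
                err = str(exc)
        if err is not None or spec is None:
            summary_rows.append({"query_id": qid, "status": "error",
                                 "error": err, "n_matches": 0,
                                 "top_taxon": None, "top_cosine": None})
            continue
        jobs.append(job)
        taxa = job.tables["taxa_matches"]
        deepest = None
        if len(taxa):
            from .taxonomy import rank_depth
            ranked = taxa.assign(
                _d=[(rank_depth(r) if rank_depth(r) is not None else -1)
                    for r in taxa["rank"]])
            deepest = ranked.sort_values(["_d", "n_matched"],
                                         ascending=[False, False]).iloc[0]["name"]
        summary_rows.append({
            "query_id": qid, "status": "ok", "error": None,
            "n_matches": len(job.matches),
            "top_taxon": deepest,
            "top_cosine": job.matches[0].cosine if job.matches else None,
        })
    cols = ["query_id", "status", "error", "n_matches", "top_taxon",
            "top_cosine"]
    return jobs, pd.DataFrame(summary_rows, columns=cols)
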