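"""Cohort spectral subtraction and producer-domain partitioning.

Mines candidate microbial spectra from a colonized (e.g. SPF mouse) cohort
by removing everything attributable to the host: first any spectrum whose
ID also appears in the germ-free cohort (the two cohorts share a
clustering, so IDs are comparable), then any spectrum linked to a
germ-free spectrum by a spectral-network-style edge — cosine similarity
strictly above ``edge_cosine`` at a precursor mass difference within
``edge_delta`` Th. Survivors are then repository-searched and partitioned
by the taxonomic domain of their matches.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd

from .search import QueryJob, Repository
from .similarity import SearchConfig, modified_cosine
from .spectra import Spectrum

__all__ = ["subtract_cohort", "partition_by_domain"]

#: guard so a pair engineered exactly at the threshold is never removed by
#: float rounding; removal requires cosine > edge_cosine + this
_STRICT_EPS = 1e-9


def subtract_cohort(spf_spectra: list[Spectrum], gf_spectra: list[Spectrum],
                    edge_cosine: float = 0.7, edge_delta: float = 0.02,
                    fragment_tol: float = 0.05) -> list[Spectrum]:
    """Spectra of the colonized cohort not explained by the germ-free one.

    Removes (1) spectra whose IDs occur in both cohorts, then (2) spectra
    with at least one germ-free counterpart at cosine strictly greater than
    ``edge_cosine`` and absolute precursor delta at most ``edge_delta`` Th.
    The boundary (cosine exactly at the threshold) is retained.
    """
    if not spf_spectra or not gf_spectra:
        raise ValueError("both cohorts must be non-empty")
    gf_ids = {s.spectrum_id for s in gf_spectra}
    candidates = [s for s in spf_spectra if s.spectrum_id not in gf_ids]

    gf_sorted = sorted((s for s in gf_spectra if s.is_searchable),
                       key=lambda s: s.precursor_mz)
    gf_prec = np.array([s.precursor_mz for s in gf_sorted])
    cfg = SearchConfig(fragment_tol=fragment_tol)

    retained = []
    for s in candidates:
        if not s.is_searchable:
            retained.append(s)
            continue
        lo = np.searchsorted(gf_prec, s.precursor_mz - edge_delta, "left")
        hi = np.searchsorted(gf_prec, s.precursor_mz + edge_delta, "right")
        removed = False
        for g in gf_sorted[lo:hi]:
            m = modified_cosine(s, g, cfg)
            if m.cosine > edge_cosine + _STRICT_EPS:
                removed = True
                break
        if not removed:
            retained.append(s)
    return retained


def _producer_group(lineage) -> str:
    """bacteria / fungi / host_cell / other from a ranked lineage path."""
    names = {(rank.lower(), name) for _, name, rank in lineage.ranked_path}
    if any(name == "Homo sapiens" for _, name in names):
        return "host_cell"
    if ("domain", "Bacteria") in names or ("superkingdom", "Bacteria") in names:
        return "bacteria"
    if ("kingdom", "Fungi") in names:
        return "fungi"
    return "other"


def partition_by_domain(jobs: list[QueryJob], repo: Repository
                        ) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Partition queries by the producer domain of their matched files.

    Any match to a host-cell-line file sends the query to ``host_cell``
    (host molecules take precedence and are discarded from microbial
    candidates); otherwise the query lands in ``bacteria_only``,
    ``fungi_only`` or ``both`` by the domains of its matched biological
    files, in ``ambiguous`` if a matched taxon's domain cannot be derived,
    and in ``unmatched`` with no biological matches. Bins are disjoint and
    exhaustive.
    """
    bins: dict[str, list[str]] = {k: [] for k in
                                  ("host_cell", "bacteria_only", "fungi_only",
                                   "both", "ambiguous", "unmatched")}
    rows = []
    for job in jobs:
        counts = defaultdict(int)
        for fname in sorted(job.matched_files):
            rec = repo.by_file.get(fname)
            if rec is None or not rec.is_biological:
                continue
            lin = None
            if rec.ncbi_id is not None:
                lin = repo.lineages.lineage(rec.ncbi_id)
            if lin is None:
                nid = repo.lineages.id_for_name(rec.alt_taxon_name) \
                    or repo.lineages.id_for_name(rec.taxon_name)
                lin = repo.lineages.lineage(nid) if nid is not None else None
            counts[_producer_group(lin) if lin is not None else "other"] += 1
        if counts.get("host_cell"):
            bin_ = "host_cell"
        elif counts.get("other"):
            bin_ = "ambiguous"
        elif counts.get("bacteria") and counts.get("fungi"):
            bin_ = "both"
        elif counts.get("bacteria"):
            bin_ = "bacteria_only"
        elif counts.get("fungi"):
            bin_ = "fungi_only"
        else:
            bin_ = "unmatched"
        bins[bin_].append(job.query_id)
        rows.append({"query_id": job.query_id, "bin": bin_,
                     "n_bacteria_files": counts.get("bacteria", 0),
                     "n_fungi_files": counts.get("fungi", 0),
                     "n_hostcell_files": counts.get("host_cell", 0)})
    table = pd.DataFrame(rows, columns=["query_id", "bin", "n_bacteria_files",
                                        "n_fungi_files", "n_hostcell_files"])
    return bins, table
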