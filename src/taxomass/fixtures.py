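"""Deterministic synthetic repository, query and cohort generator.

Emulates a miniature curated monoculture repository: a synthetic taxonomy
(bacterial and fungal lineages plus a human host-cell lineage), per-taxon
"producer" fragment patterns, data files carrying those patterns, shared
contaminant spectra in blanks/QCs, and host-cell files that share some
patterns with bacteria (to exercise host-molecule removal). Everything is
driven by a single integer seed and a :class:`FixtureSpec`; the manifest
records the ground truth for every generated spectrum.

Fragment patterns are sampled on a 0.01 Th grid in [80, 1500] Th with
8-40 peaks and log-normal intensities — realistic sparsity for
tolerance-based matching without real data. Reference precursors stay
below 1050 Th; negative-control queries are placed above 1100 Th so they
can never fall inside any exact-mode precursor window.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum, write_mgf

__all__ = ["FixtureSpec", "make_repository", "make_queries", "make_cohorts"]

_GRID = 0.01


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 1
    n_taxa: int = 50
    ranks_depth: int = 8
    files_per_taxon: tuple[int, int] = (1, 3)
    peaks_per_spectrum: tuple[int, int] = (8, 40)
    patterns_per_taxon: tuple[int, int] = (2, 4)
    n_blanks: int = 3
    n_qcs: int = 3
    n_hostcell: int = 4
    noise_mz_sd: float = 0.005
    noise_intensity_cv: float = 0.10
    n_planted_analogues: int = 5
    analogue_shift: float = 42.01
    fungi_fraction: float = 0.2

    def __post_init__(self):
        for name in ("n_taxa",):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("n_blanks", "n_qcs", "n_hostcell", "n_planted_analogues"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for lo, hi in (self.files_per_taxon, self.peaks_per_spectrum,
                       self.patterns_per_taxon):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must satisfy 1 <= lo <= hi")
        if self.noise_mz_sd < 0 or self.noise_intensity_cv < 0:
            raise ValueError("noise levels must be non-negative")


# -- synthetic taxonomy -------------------------------------------------------

_HOST_LINEAGE = [
    (2759, "Eukaryota", "domain"), (33208, "Metazoa", "kingdom"),
    (7711, "Chordata", "phylum"), (40674, "Mammalia", "class"),
    (9443, "Primates", "order"), (9604, "Hominidae", "family"),
    (9605, "Homo", "genus"), (9606, "Homo sapiens", "species"),
]


def _build_taxonomy(spec: FixtureSpec):
    """Return (lineage rows, terminal taxa) for a balanced synthetic tree.

    Terminal taxa are strains nested genus -> species -> strain under
    synthetic families/orders/classes/phyla, split between Bacteria and
    Fungi by ``fungi_fraction``.
    """
    rows: list[tuple[int, int, str, str]] = []  # id, parent, name, rank
    next_id = [1000]

    def new_id() -> int:
        next_id[0] += 1
        return next_id[0]

    def add(parent: int, name: str, rank: str) -> int:
        nid = new_id()
        rows.append((nid, parent, name, rank))
        return nid

    rows.append((2, 1, "Bacteria", "domain"))
    for nid, name, rank in _HOST_LINEAGE:
        parent = 1 if rank == "domain" else _HOST_LINEAGE[
            [r for _, _, r in _HOST_LINEAGE].index(rank) - 1][0]
        rows.append((nid, parent, name, rank))
    fungi_kingdom = 4751
    rows.append((fungi_kingdom, 2759, "Fungi", "kingdom"))

    n_fungi = max(1, int(round(spec.n_taxa * spec.fungi_fraction))) \
        if spec.n_taxa >= 5 else 0
    n_bact = spec.n_taxa - n_fungi
    terminals: list[dict] = []

    def grow(domain_parent: int, prefix: str, group: str, n_terminals: int):
        # chain: phylum > class > order > family > genus > species > strain
        made = 0
        p_i = 0
        while made < n_terminals:
            p_i += 1
            phylum = add(domain_parent, f"{prefix}phylum{p_i}", "phylum")
            klass = add(phylum, f"{prefix}class{p_i}", "class")
            order = add(klass, f"{prefix}order{p_i}", "order")
            for f_i in range(1, 3):
                if made >= n_terminals:
                    break
                family = add(order, f"{prefix}family{p_i}.{f_i}", "family")
                for g_i in range(1, 3):
                    if made >= n_terminals:
                        break
                    gname = f"{prefix.capitalize()}genus{p_i}.{f_i}.{g_i}"
                    genus = add(family, gname, "genus")
                    for s_i in range(1, 3):
                        if made >= n_terminals:
                            break
                        sname = f"{gname} species{s_i}"
                        species = add(genus, sname, "species")
                        strain = add(species, f"{sname} strain1", "strain")
                        terminals.append({
                            "ncbi_id": strain,
                            "name": f"{sname} strain1",
                            "genus_id": genus, "genus_name": gname,
                            "species_id": species, "species_name": sname,
                            "group": group,
                        })
                        made += 1

    grow(2, "bac", "bacteria", n_bact)
    if n_fungi:
        grow(fungi_kingdom, "fun", "fungi", n_fungi)
    return rows, terminals


# -- fragment patterns --------------------------------------------------------

def _sample_pattern(rng: np.random.Generator, spec: FixtureSpec,
                    precursor_lo: float = 150.0,
                    precursor_hi: float = 1000.0) -> dict:
    precursor = round(float(rng.integers(int(precursor_lo / _GRID),
                                         int(precursor_hi / _GRID))) * _GRID, 2)
    lo_p, hi_p = spec.peaks_per_spectrum
    n_peaks = int(rng.integers(lo_p, hi_p + 1))
    hi_mz = min(1500.0, precursor)
    grid_points = rng.choice(np.arange(int(80 / _GRID), int(hi_mz / _GRID)),
                             size=n_peaks, replace=False)
    mz = np.sort(grid_points) * _GRID
    intensities = rng.lognormal(mean=0.0, sigma=1.0, size=n_peaks)
    return {"precursor_mz": precursor,
            "mz": [round(float(m), 2) for m in mz],
            "intensities": [round(float(i), 6) for i in intensities]}


def _pattern_spectrum(pattern: dict, spectrum_id: str, scan: int | None = None,
                      source_file: str | None = None,
                      dataset_id: str | None = None) -> Spectrum:
    return Spectrum(spectrum_id=spectrum_id,
                    precursor_mz=pattern["precursor_mz"],
                    mz=np.array(pattern["mz"]),
                    intensities=np.array(pattern["intensities"]),
                    scan=scan, source_file=source_file, dataset_id=dataset_id)


# -- repository ---------------------------------------------------------------

def make_repository(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Generate a miniature reference repository on disk.

    Writes ``metadata.tsv``, ``lineages.tsv``, ``manifest.json`` and one MGF
    per data file under ``spectra/<dataset>/``. Returns the manifest dict.
    Identical spec -> byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    lineage_rows, terminals = _build_taxonomy(spec)

    patterns: dict[str, dict] = {}

    def register(prefix: str, k: int, **truth) -> str:
        pid = f"{prefix}{k:04d}"
        patterns[pid] = {**_sample_pattern(rng, spec), **truth, "id": pid}
        return pid

    # producer patterns per terminal taxon
    lo_pat, hi_pat = spec.patterns_per_taxon
    pat_counter = 0
    for t in terminals:
        n_pat = int(rng.integers(lo_pat, hi_pat + 1))
        t["patterns"] = []
        for _ in range(n_pat):
            pat_counter += 1
            t["patterns"].append(register(
                "P", pat_counter, taxon_ncbi=t["ncbi_id"],
                taxon_name=t["name"], genus_name=t["genus_name"],
                group=t["group"]))

    contaminants = [register("C", i + 1, taxon_ncbi=None, taxon_name=None,
                             genus_name=None, group="contaminant")
                    for i in range(3)]
    host_patterns = [register("H", i + 1, taxon_ncbi=9606,
                              taxon_name="Homo sapiens", genus_name="Homo",
                              group="host")
                     for i in range(3)] if spec.n_hostcell else []
    # host/bacteria shared molecules: a bacterial pattern also in host files
    shared_host = []
    bact = [t for t in terminals if t["group"] == "bacteria"]
    if spec.n_hostcell and len(bact) >= 2:
        shared_host = [bact[0]["patterns"][0], bact[1]["patterns"][0]]

    # planted analogues: base pattern never deposited; shifted copy deposited
    analogue_pairs = []
    for i in range(spec.n_planted_analogues):
        base = register("A", i + 1, taxon_ncbi=None, taxon_name=None,
                        genus_name=None, group="analogue_base")
        host_taxon = bact[i % len(bact)] if bact else terminals[i % len(terminals)]
        shifted = {
            "id": f"A{i + 1:04d}s",
            "precursor_mz": round(patterns[base]["precursor_mz"]
                                  + spec.analogue_shift, 4),
            "mz": [round(m + spec.analogue_shift, 4)
                   for m in patterns[base]["mz"]],
            "intensities": patterns[base]["intensities"],
            "taxon_ncbi": host_taxon["ncbi_id"],
            "taxon_name": host_taxon["name"],
            "genus_name": host_taxon["genus_name"],
            "group": "analogue_shifted",
        }
        patterns[shifted["id"]] = shifted
        analogue_pairs.append({"base": base, "shifted": shifted["id"],
                               "taxon_ncbi": host_taxon["ncbi_id"]})

    # data files
    meta_rows = []
    files: dict[str, dict] = {}
    datasets = ["SYN000001", "SYN000002", "SYN000003"]
    file_counter = 0

    def add_file(dataset: str, base: str, taxon_name: str,
                 ncbi_id: int | None, pattern_ids: Sequence[str],
                 is_blank=False, is_qc=False, group="biological",
                 alt_taxon_name: str | None = None):
        nonlocal file_counter
        file_counter += 1
        fname = f"{dataset}/{base}"
        meta_rows.append({
            "file_path": f"{dataset}/peak/{base}.mzML",
            "file_name": fname, "dataset_id": dataset,
            "taxon_name": taxon_name, "alt_taxon_name": alt_taxon_name or "",
            "ncbi_id": "" if ncbi_id is None else ncbi_id,
            "id_assignment": "automatic", "redu_available": "True",
            "is_blank": str(is_blank), "is_qc": str(is_qc),
        })
        specs = []
        for scan, pid in enumerate(pattern_ids, start=1):
            sid = f"mzspec:{dataset}:{base}:scan:{scan}"
            specs.append(_pattern_spectrum(patterns[pid], sid, scan=scan,
                                           source_file=fname,
                                           dataset_id=dataset))
        files[fname] = {"dataset_id": dataset, "taxon_ncbi": ncbi_id,
                        "taxon_name": taxon_name, "group": group,
                        "scans": {str(i + 1): pattern_ids[i]
                                  for i in range(len(pattern_ids))}}
        mgf_path = outdir / "spectra" / dataset / f"{base}.mgf"
        write_mgf(specs, mgf_path)

    lo_f, hi_f = spec.files_per_taxon
    shifted_assigned = {p["shifted"]: p["taxon_ncbi"] for p in analogue_pairs}
    for idx, t in enumerate(terminals):
        dataset = datasets[idx % len(datasets)]
        n_files = int(rng.integers(lo_f, hi_f + 1))
        extra = [sid for sid, ncbi in shifted_assigned.items()
                 if ncbi == t["ncbi_id"]]
        for f_i in range(n_files):
            base = f"taxon{t['ncbi_id']}_file{f_i + 1}"
            pats = list(t["patterns"]) + (extra if f_i == 0 else [])
            add_file(dataset, base, t["name"], t["ncbi_id"], pats,
                     group=t["group"])

    # one file exercising the closest-taxon fallback: NCBI ID unknown to the
    # lineage table, name resolvable at genus level
    fallback_file = None
    if terminals:
        t0 = terminals[0]
        fallback_file = f"{datasets[0]}/fallback_file1"
        add_file(datasets[0], "fallback_file1",
                 f"{t0['genus_name']} novel-isolate", None,
                 [t0["patterns"][0]], group=t0["group"],
                 alt_taxon_name=t0["genus_name"])

    for b in range(spec.n_blanks):
        add_file(datasets[0], f"blank{b + 1}", "blank", None, contaminants,
                 is_blank=True, group="blank")
    for q in range(spec.n_qcs):
        add_file(datasets[0], f"qc{q + 1}", "QC", None, contaminants,
                 is_qc=True, group="qc")
    for h in range(spec.n_hostcell):
        add_file(datasets[1 % len(datasets)], f"hostcell{h + 1}",
                 "Homo sapiens", 9606, host_patterns + shared_host,
                 group="host")

    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.tsv", sep="\t",
                                   index=False)
    pd.DataFrame(lineage_rows,
                 columns=["ncbi_id", "parent_ncbi_id", "name", "rank"]
                 ).to_csv(outdir / "lineages.tsv", sep="\t", index=False)

    manifest = {
        "spec": asdict(spec),
        "patterns": patterns,
        "terminals": terminals,
        "files": files,
        "analogue_pairs": analogue_pairs,
        "contaminant_patterns": contaminants,
        "host_patterns": host_patterns,
        "host_shared_patterns": shared_host,
        "fallback_file": fallback_file,
        "negative_precursor_range": [1100.0, 1400.0],
        "n_biological_files": sum(1 for f in files.values()
                                  if f["group"] not in ("blank", "qc")),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


# -- queries ------------------------------------------------------------------

def _noisy(pattern: dict, rng: np.random.Generator, mz_sd: float,
           cv: float, spectrum_id: str) -> Spectrum:
    mz = np.array(pattern["mz"], dtype=float)
    inten = np.array(pattern["intensities"], dtype=float)
    if mz_sd > 0:
        mz = mz + rng.normal(0.0, mz_sd, size=mz.size)
    if cv > 0:
        inten = inten * np.clip(1.0 + rng.normal(0.0, cv, size=inten.size),
                                0.05, None)
    precursor = pattern["precursor_mz"]
    if mz_sd > 0:
        precursor = precursor + float(rng.normal(0.0, mz_sd))
    # Spectrum sorts and pairs peaks itself
    return Spectrum(spectrum_id=spectrum_id, precursor_mz=precursor,
                    mz=mz, intensities=inten)


def make_queries(manifest: dict, n_queries: int = 200, n_negative: int = 50,
                 n_analogue: int | None = None, seed: int | None = None,
                 outdir: str | Path | None = None
                 ) -> tuple[list[Spectrum], pd.DataFrame]:
    """Generate query spectra with known ground truth.

    Positives are noisy copies of deposited producer patterns (noise per the
    repository spec); negatives are random spectra whose precursor lies in a
    reserved window above every reference precursor; analogue queries are the
    undeposited base patterns whose shifted copies sit in the repository.
    Returns the spectra and a truth table; optionally writes ``queries.mgf``
    and ``query_truth.tsv``.
    """
    spec = FixtureSpec(**manifest["spec"])
    rng = np.random.default_rng(spec.seed + 7919 if seed is None else seed)
    producer = [p for p in manifest["patterns"].values()
                if p["group"] in ("bacteria", "fungi")]
    producer.sort(key=lambda p: p["id"])
    queries: list[Spectrum] = []
    truth_rows = []

    for i in range(n_queries):
        pat = producer[int(rng.integers(len(producer)))]
        qid = f"query_pos_{i + 1:04d}"
        queries.append(_noisy(pat, rng, spec.noise_mz_sd,
                              spec.noise_intensity_cv, qid))
        truth_rows.append({"query_id": qid, "kind": "positive",
                           "pattern_id": pat["id"],
                           "true_taxon_ncbi": pat["taxon_ncbi"],
                           "true_taxon_name": pat["taxon_name"],
                           "true_genus": pat["genus_name"]})

    lo, hi = manifest["negative_precursor_range"]
    for i in range(n_negative):
        pat = _sample_pattern(rng, spec, precursor_lo=lo, precursor_hi=hi)
        qid = f"query_neg_{i + 1:04d}"
        queries.append(_pattern_spectrum(pat, qid))
        truth_rows.append({"query_id": qid, "kind": "negative",
                           "pattern_id": "", "true_taxon_ncbi": None,
                           "true_taxon_name": None, "true_genus": None})

    pairs = manifest["analogue_pairs"]
    n_ana = len(pairs) if n_analogue is None else min(n_analogue, len(pairs))
    for i in range(n_ana):
        base = manifest["patterns"][pairs[i]["base"]]
        qid = f"query_ana_{i + 1:04d}"
        queries.append(_noisy(base, rng, spec.noise_mz_sd,
                              spec.noise_intensity_cv, qid))
        truth_rows.append({"query_id": qid, "kind": "analogue",
                           "pattern_id": base["id"],
                           "true_taxon_ncbi": pairs[i]["taxon_ncbi"],
                           "true_taxon_name": None, "true_genus": None})

    truth = pd.DataFrame(truth_rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_mgf(queries, outdir / "queries.mgf")
        truth.to_csv(outdir / "query_truth.tsv", sep="\t", index=False)
    return queries, truth


# -- cohorts ------------------------------------------------------------------

def make_cohorts(spec: FixtureSpec, n_private: int = 20, n_shared_id: int = 5,
                 n_edge_linked: int = 5, n_gf_only: int = 10
                 ) -> tuple[list[Spectrum], list[Spectrum], dict]:
    """Colonized (SPF) vs germ-free (GF) cohort pair with planted overlap.

    The SPF cohort contains ``n_private`` spectra found nowhere in GF (the
    ground-truth microbial candidates), ``n_shared_id`` spectra whose IDs
    also appear in GF, and ``n_edge_linked`` spectra that are near-duplicates
    of GF spectra (cosine > 0.7 at delta precursor within 0.02 Th). Returns
    (spf, gf, truth) where truth lists the IDs that survive subtraction.
    """
    rng = np.random.default_rng(spec.seed + 104729)
    spf: list[Spectrum] = []
    gf: list[Spectrum] = []

    for i in range(n_gf_only):
        pat = _sample_pattern(rng, spec)
        gf.append(_pattern_spectrum(pat, f"gf_{i + 1:03d}"))
    for i in range(n_private):
        pat = _sample_pattern(rng, spec)
        spf.append(_pattern_spectrum(pat, f"spf_private_{i + 1:03d}"))
    for i in range(n_shared_id):
        pat = _sample_pattern(rng, spec)
        sid = f"shared_{i + 1:03d}"
        spf.append(_pattern_spectrum(pat, sid))
        gf.append(_pattern_spectrum(pat, sid))
    for i in range(n_edge_linked):
        pat = _sample_pattern(rng, spec)
        gf_id = f"gf_edge_{i + 1:03d}"
        gf.append(_pattern_spectrum(pat, gf_id))
        # near-duplicate: tiny precursor offset, same fragments
        dup = dict(pat, precursor_mz=round(pat["precursor_mz"] + 0.01, 4))
        spf.append(_pattern_spectrum(dup, f"spf_edge_{i + 1:03d}"))

    truth = {
        "retained_ids": sorted(s.spectrum_id for s in spf
                               if s.spectrum_id.startswith("spf_private")),
        "removed_shared_ids": sorted(s.spectrum_id for s in spf
                                     if s.spectrum_id.startswith("shared_")),
        "removed_edge_ids": sorted(s.spectrum_id for s in spf
                                   if s.spectrum_id.startswith("spf_edge")),
    }
    return spf, gf, truth
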