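# Methods

## Problem setting

A reference repository of microbial-monoculture LC–MS/MS data consists of
peak-list files, a metadata table assigning every file to a taxon (or
flagging it as a blank or QC injection), and a lineage table giving each
taxon's ranked path through an NCBI-style taxonomy. A query MS/MS spectrum
is matched against the repository; the set of files containing a match is
then summarised per taxon. Because a monoculture file belongs to exactly
one organism, a match is direct evidence that the organism can produce (or
take up and modify) the queried molecule — subject to the usual caveats of
spectral matching: isomers are indistinguishable, absence of a match is
not evidence of absence, and acquisition conditions limit coverage.

## Modified cosine

Peaks may match directly (|Δm/z| ≤ fragment tolerance) or after shifting
one spectrum's fragments by the precursor mass difference; each peak is
used at most once. Intensities are square-root transformed by default
(configurable to `none`) and L2-normalised per spectrum, so the optimal
assignment's total pair-weight is a cosine in [0, 1] by Cauchy–Schwarz.

The assignment is solved **exactly** as a maximum-weight bipartite
matching on the candidate-pair graph using the Hungarian algorithm
(`scipy.optimize.linear_sum_assignment`) restricted to peaks that appear
in at least one candidate pair. A 1e-12 bonus on candidate cells makes
zero-weight candidate pairs preferred over non-edges in ties; the bonus is
excluded from the reported score, and is three orders of magnitude below
every tolerance used anywhere in the package. A greedy assignment
(descending pair weight, ties by index) is available via
`modified_cosine(..., method="greedy")` for compatibility experiments; the
exact method is the default because it is deterministic, symmetric and at
least as large as any greedy score. `n_matched_ions` counts all assigned
pairs, direct and shifted alike, since one matched-ion count is reported
per match.

Acceptance thresholds are inclusive (cosine ≥ min_cosine, ions ≥
min_matched_ions), reading "minimum" as attainable. Defaults: precursor
and fragment tolerance 0.05 Th (absolute, not ppm), minimum cosine 0.7,
minimum matched ions 3, analogue search off with a ±130 Th window when
enabled.

## Precursor index

Reference spectra are sorted by precursor m/z; candidates are retrieved by
binary search over the inclusive window (`precursor_tol` in exact mode,
`analogue_max_delta` in analogue mode). Retrieval is provably identical to
a linear scan — the index changes cost, not results — and the tests assert
exactly that. Unsearchable spectra (no precursor, no peaks) are excluded
and counted. The index carries a fingerprint (digest of spectrum IDs,
precursors, peak counts) that `search_one` checks against the repository
so an index cannot be used with mismatched metadata. The index is always
rebuilt from the loaded spectra; at the collection sizes this package
targets a rebuild takes well under a second, so no on-disk cache is kept.

## Taxonomic tree

The tree is built from the supplied lineage table (no live taxonomy
lookups; hermetic by construction). Supported ranks, shallow to deep:
domain/superkingdom, kingdom, phylum, class, order, family, genus,
subgenus, species, subspecies, varietas, strain. Each biological file
contributes +1 to `n_files` along its full lineage. Counters obey strict
conservation: an internal node's `(n_files, n_matched)` equals the sum
over its counting children, which is achieved by attaching files only at
childless nodes:

* A record whose NCBI ID is missing from the lineage table falls back to
  the closest resolvable taxon by name (curated alternative name first,
  then the reported name). If that ancestor has taxonomic children, the
  file attaches to a synthetic child (`<name> (unresolved descendants)`,
  negative ID) so the ancestor's counter remains an exact sum while still
  including the file.
* Records resolvable to nothing land on an `unclassified` pseudo-node
  under the root; they are biological samples and count in root totals.
* Blanks and QCs attach to dedicated pseudo-children of the root
  (IDs −1/−2). They keep their own counters for contaminant inspection
  but are excluded from every taxon total including the root, so the root
  proportion is exactly (matched biological files)/(biological files).

Pseudo-node IDs are negative and cannot collide with NCBI IDs. Child
ordering is canonical (rank depth, then name, then ID), making tree build
input-order invariant. Match aggregation recomputes counters from zero
for a given matched-file set (idempotent); a file with several matching
scans counts once in node counters, with per-scan detail available in the
dataset-matches table.

Filtering: `max_rank` truncates below the given rank — counts are
aggregate sums, so the surviving ancestor retains its subtree totals;
`min_matches` prunes nodes below the threshold unless an ancestor of a
retained node; the root always survives, keeping the tree connected.

Exports: nested JSON (schema-checked by an explicit validator), Newick
with `name|ncbi_id` labels and counters in `[&...]` comment blocks, and a
dependency-free static HTML page (collapsible `<details>` lists with the
JSON embedded).

## Search orchestration

`search_one` = candidate retrieval → modified cosine → thresholding →
aggregation onto a per-query copy of the tree, then three tables: dataset
matches (one row per matching scan, sorted by cosine descending with file
name as tiebreak — the sort order is this package's choice), taxa matches
(one row per matched taxon node, cross-checked against the tree), and
library matches (same scoring against an annotated library; annotations
are candidate-level, never asserted identifications). Batch search
accepts an `.mgf` or a `.tsv` of USIs; per-query failures become error
rows without aborting the batch, and a batch of one is byte-identical to
a single search. USIs are resolved locally by exact dataset/file/scan
lookup. Nothing in the search path uses randomness.

## Cohort subtraction and domain partition

Colonized-cohort (e.g. SPF) spectra are filtered in two passes: removal
of IDs present in both cohorts (the cohorts are assumed to share a
clustering, so IDs are comparable), then removal of spectra with at least
one germ-free counterpart at cosine **strictly** greater than the edge
threshold (default 0.7) and |Δ precursor| ≤ 0.02 Da. Strictness is
enforced with a 1e-9 guard so a pair engineered to sit exactly at the
threshold is retained regardless of floating-point rounding direction.
The fragment tolerance for these pairwise cosines defaults to the search
default (0.05 Th) and is exposed as a parameter.

Surviving spectra are repository-searched and partitioned by the domains
of their matched biological files: any host-cell-line match sends the
query to `host_cell` (precedence, since such molecules cannot be claimed
as exclusively microbial); otherwise `bacteria_only` / `fungi_only` /
`both`; taxa whose domain cannot be derived from the lineage route the
query to `ambiguous` rather than being dropped; queries without
biological matches are `unmatched`. Bacteria are identified by the
domain/superkingdom name, fungi by the kingdom name, host cells by *Homo
sapiens* in the lineage.

## Synthetic data generator

The generator emulates the study conditions at desk scale: a balanced
synthetic taxonomy (80% bacterial / 20% fungal terminal strains by
default, plus a human lineage for host cell lines), 2–4 characteristic
producer patterns per taxon, 1–3 files per taxon, 3 blanks and 3 QCs
sharing contaminant spectra, 4 host-cell files that also carry two
bacterial patterns (exercising host-molecule precedence), one file whose
NCBI ID is deliberately unknown to the lineage table (exercising the
closest-taxon fallback), and planted analogue pairs: a base pattern never
deposited whose +42.01 Th-shifted copy (precursor and fragments) is
deposited, so it is findable only in analogue mode.

Fragment patterns are drawn on a 0.01 Th grid in [80, 1500] Th with 8–40
peaks and log-normal intensities; reference precursors lie in [150, 1000]
Th. Negative-control queries get precursors in [1100, 1400] Th, which
guarantees zero exact-mode candidates by construction. Query noise
defaults to m/z jitter of sd 0.005 Th and 10% intensity CV — an order of
magnitude inside the matching tolerance, representing well-calibrated
high-resolution instruments. Everything derives from one seed;
regeneration is byte-identical.

What the generator does **not** model: chromatography, isotope envelopes,
adducts, chimeric spectra, peak dropout, or correlated noise. Passing the
recovery tests therefore demonstrates the correctness of the machinery
(indexing, scoring, thresholding, aggregation) under clean conditions,
not expected recovery rates on real data, where dropout and chimeras
dominate failure modes. Likewise the cohort generator produces unrelated
random patterns — it exercises the subtraction logic and its ground-truth
bookkeeping, not realistic mouse-tissue chemistry.

## Numerical and degenerate-input choices

* Peaks closer than 1e-5 Th merge on construction (summed intensity at
  the intensity-weighted mean m/z) so a fragment never matches twice.
* Peak lists are strictly ascending after load; MGF keys are handled
  case-insensitively; the PEPMASS second token (precursor intensity) is
  ignored; spectra without a precursor are loaded but flagged
  unsearchable, never silently dropped.
* Scan numbers follow the source file verbatim so USIs round-trip.
* Empty inputs are valid where a sensible empty result exists (empty MGF,
  empty index, empty library, empty matched set) and warn rather than
  fail; genuinely unusable inputs (query without precursor, malformed
  USI, duplicated file names, missing metadata columns) raise typed
  errors.
* The score is clamped to ≤ 1 to absorb float accumulation at
  self-similarity.

## Problem sizes

The test suite and acceptance script run at sizes chosen to exercise every
code path with comfortable margins on a single CPU: 1,000 spectrum pairs
for the assignment-oracle comparison, 1,000 queries × 5,000 references
for index/linear-scan equality, 100 random match subsets on a 40-taxon
tree for conservation, and a 50-taxon repository with 200 positive +
50 negative queries for planted-genus recovery. The full suite completes
in well under a minute on one core.

## Known limitations

* Tolerances are absolute Th only; no ppm mode.
* No mzML/mzXML parsing — convert upstream to MGF.
* Analogue candidate windows are symmetric; no neutral-loss-only scoring
  or spectral-entropy alternatives.
* USI resolution is strictly local; there is no network resolver.
* The HTML tree export is a static collapsible list, not an interactive
  visualisation.
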