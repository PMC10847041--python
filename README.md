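# taxomass

Taxonomically informed MS/MS repository search for microbial metabolomics.

Untargeted metabolomics produces tandem mass spectra (MS/MS) whose
molecular producers are usually unknown. When a reference collection of
spectra from *microbial monocultures* exists — each data file unambiguously
attributable to one cultured taxon — a spectral match links an
uncharacterized spectrum to the organisms that can produce the molecule.
`taxomass` is a self-contained, local engine for exactly that workflow:

1. **Index** a reference repository (MGF peak lists + a file-to-taxon
   metadata table + an NCBI-style lineage table) by precursor m/z.
2. **Search** query spectra (a peak list, a USI, an `.mgf`, or a `.tsv` of
   USIs) against it with the **modified cosine** score, in exact mode
   (precursor within tolerance) or analogue mode (precursor free to differ
   by up to a large mass window, so modified analogues still match).
3. **Aggregate** the matched files onto a taxonomic tree: every match is
   propagated upstream through the taxon's lineage, each node reporting
   `n_matched / n_files` — the fraction of that taxon's data files
   containing the molecule. Blank and QC injections are kept as separate
   pseudo-nodes so contaminants are visible but never counted as biology.
4. **Export** dataset/taxa/library match tables (TSV) and the tree
   (JSON / Newick / static HTML).

It also implements the germ-free-vs-colonized **cohort subtraction**
workflow (remove every colonized-cohort spectrum with a spectral-network
edge — cosine > 0.7 at |Δ precursor| ≤ 0.02 Da — to a germ-free spectrum)
and partitions the surviving candidate microbial spectra by producer
domain (bacteria / fungi / both / host cell lines).

## The score

For spectra $A, B$ with precursor difference $\delta = p_A - p_B$, peaks
$i \in A$ and $j \in B$ form a candidate pair if
$|m_i - m_j| \le \tau_f$ (direct) **or** $|m_i - (m_j + \delta)| \le \tau_f$
(shifted). With per-spectrum L2-normalised (optionally square-rooted)
intensities $\hat a_i, \hat b_j$, the modified cosine is

$$\mathrm{cos}(A,B) \;=\; \max_{M} \sum_{(i,j) \in M} \hat a_i\, \hat b_j,$$

the maximum over one-to-one assignments $M$ of candidate pairs — solved
exactly as a maximum-weight bipartite matching, so the score is
deterministic, symmetric, and lies in $[0,1]$. A match is accepted when
cosine ≥ 0.7 **and** at least 3 fragment ions are matched (both
inclusive); default precursor/fragment tolerances are 0.05 Th.

## Worked example

No downloads are needed: the fixture module generates a miniature
repository with known ground truth.

```python
from taxomass import (FixtureSpec, Repository, SearchConfig,
                      make_repository, make_queries, search_one)

spec = FixtureSpec(seed=1, n_taxa=10)
manifest = make_repository(spec, "demo_repo")
repo = Repository.load("demo_repo")
queries, truth = make_queries(manifest, n_queries=1, n_negative=0, n_analogue=0)
job = search_one(queries[0], repo.index, repo, SearchConfig())
print(job.tables["taxa_matches"].to_string(index=False))
```

prints

```
                          name  ncbi_id    rank  n_matched  n_files  proportion
                 Bacgenus1.1.1     1005   genus          1        3    0.333333
        Bacgenus1.1.1 species2     1008 species          1        1    1.000000
Bacgenus1.1.1 species2 strain1     1009  strain          1        1    1.000000
                      Bacteria        2  domain          1       12    0.083333
                     bacclass1     1002   class          1       12    0.083333
                  bacfamily1.1     1004  family          1        5    0.200000
                     bacorder1     1003   order          1       12    0.083333
                    bacphylum1     1001  phylum          1       12    0.083333
                          root        1    root          1       21    0.047619
```

The noisy query recovered its true producer strain; the single matched
file is credited to the strain and to every ancestor up to the root, and
each row's `proportion` is `n_matched / n_files` for that taxon (1/3 of
the genus's files contain the molecule, 1/21 of all biological files).

The same is available from the shell:

```bash
taxomass fixtures make demo --n-taxa 10
taxomass index build demo
taxomass search batch demo demo/queries/queries.mgf --out results
taxomass mine cohort demo demo/cohorts/spf.mgf demo/cohorts/gf.mgf
```

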