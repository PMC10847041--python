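"""File metadata, lineages, and the taxonomic result tree.

Every reference data file maps to a taxon (an NCBI-style integer ID with a
ranked lineage) or is flagged as a blank or QC injection. Files hang off
the taxonomic tree at their terminal taxon; a match observed in a file is
credited to that taxon and propagated upstream through every ancestor, so
each node carries (n_files, n_matched) counters and their ratio, the
per-taxon match proportion.

Conventions:

* Blanks and QCs attach to two dedicated pseudo-children of the root. They
  keep their own counters but are excluded from every taxon total,
  including the root's, so contaminant matches never inflate biology.
* A biological file whose taxon cannot be resolved to a lineage falls back
  to the deepest resolvable ancestor (closest-taxon rule); if that ancestor
  has taxonomic children the file attaches to a synthetic child node so
  that internal-node counters remain exact sums over children. Files with
  no resolvable taxon at all land on an "unclassified" pseudo-node.
* Pseudo-node IDs are negative and can never collide with NCBI IDs.
"""

from __future__ import annotations

import copy
import html as _html
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, UnknownFileError, UnknownRankError

__all__ = [
    "RANKS", "MetadataRecord", "Lineage", "LineageTable", "TaxonNode",
    "load_metadata", "load_lineages", "build_tree", "aggregate_matches",
    "filter_tree", "export_tree", "tree_to_dict", "tree_from_json",
    "validate_tree_dict",
]

#: supported ranks, shallowest to deepest; 'domain' and 'superkingdom' are
#: synonyms for the top division
RANKS = ["domain", "kingdom", "phylum", "class", "order", "family",
         "genus", "subgenus", "species", "subspecies", "varietas", "strain"]

_RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}
_RANK_DEPTH["superkingdom"] = _RANK_DEPTH["domain"]

BLANK_ID = -1
QC_ID = -2
UNCLASSIFIED_ID = -3
ROOT_ID = 1


def rank_depth(rank: str | None) -> int | None:
    if rank is None:
        return None
    return _RANK_DEPTH.get(rank.lower())


@dataclass
class MetadataRecord:
    file_path: str
    file_name: str            # qualified as dataset_id/file_name
    dataset_id: str
    taxon_name: str
    alt_taxon_name: str | None = None
    ncbi_id: int | None = None
    id_assignment: str = "automatic"   # or "curated"
    redu_available: bool = False
    is_blank: bool = False
    is_qc: bool = False

    def __post_init__(self):
        if self.is_blank and self.is_qc:
            raise SchemaError(
                f"record {self.file_name!r} flagged as both blank and QC")

    @property
    def is_biological(self) -> bool:
        return not (self.is_blank or self.is_qc)


@dataclass(frozen=True)
class Lineage:
    ncbi_id: int
    #: (ncbi_id, scientific_name, rank) from root-most to terminal
    ranked_path: tuple[tuple[int, str, str], ...]


class LineageTable:
    """Lineages reconstructed from an (id, parent, name, rank) edge table."""

    def __init__(self, nodes: Mapping[int, tuple[int, str, str]]):
        # nodes: ncbi_id -> (parent_id, name, rank)
        self._nodes = dict(nodes)
        self._by_name = {}
        for nid, (_, name, _) in self._nodes.items():
            self._by_name.setdefault(name.strip().lower(), nid)

    def __contains__(self, ncbi_id: int) -> bool:
        return ncbi_id in self._nodes

    def id_for_name(self, name: str | None) -> int | None:
        if not name:
            return None
        return self._by_name.get(name.strip().lower())

    def lineage(self, ncbi_id: int) -> Lineage | None:
        if ncbi_id not in self._nodes:
            return None
        path = []
        seen = set()
        nid = ncbi_id
        while nid in self._nodes and nid not in seen:
            seen.add(nid)
            parent, name, rank = self._nodes[nid]
            path.append((nid, name, rank))
            if parent == nid or parent in (0, ROOT_ID):
                break
            nid = parent
        return Lineage(ncbi_id=ncbi_id, ranked_path=tuple(reversed(path)))


_COLUMN_SYNONYMS = {
    "filepath": "file_path", "full_path": "file_path", "path": "file_path",
    "filename": "file_name", "sample_name": "file_name",
    "massive_id": "dataset_id", "dataset": "dataset_id",
    "taxaname_file": "taxon_name", "taxa_name": "taxon_name",
    "taxonname": "taxon_name",
    "alternative_taxon_name": "alt_taxon_name", "alt_name": "alt_taxon_name",
    "taxa_ncbi": "ncbi_id", "ncbi": "ncbi_id", "taxid": "ncbi_id",
    "ncbi_assignment": "id_assignment", "assignment": "id_assignment",
    "redu": "redu_available",
    "blank": "is_blank", "qc": "is_qc",
}

_MANDATORY = ["file_path", "file_name", "dataset_id", "taxon_name",
              "ncbi_id", "is_blank", "is_qc"]
_OPTIONAL_DEFAULTS = {"alt_taxon_name": None, "id_assignment": "automatic",
                      "redu_available": False}

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", "", "nan", "none"}


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise SchemaError(f"cannot interpret {value!r} as boolean")


def load_metadata(path: str | Path) -> list[MetadataRecord]:
    """Read and validate the 10-column file-to-taxon metadata table.

    Accepts TSV or CSV (sniffed from the extension); header names are
    matched case-insensitively with a synonym map. Raises
    :class:`SchemaError` listing missing mandatory columns, on duplicated
    file names, or on uninterpretable flags.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    rename = {}
    for col in df.columns:
        key = col.strip().lower().replace(" ", "_")
        rename[col] = _COLUMN_SYNONYMS.get(key, key)
    df = df.rename(columns=rename)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata table missing mandatory columns: {missing}")
    for col, default in _OPTIONAL_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    records = []
    for _, row in df.iterrows():
        ncbi = row["ncbi_id"]
        ncbi = None if pd.isna(ncbi) or str(ncbi).strip() == "" else int(float(ncbi))
        alt = row["alt_taxon_name"]
        alt = None if pd.isna(alt) or str(alt).strip() == "" else str(alt)
        records.append(MetadataRecord(
            file_path=str(row["file_path"]),
            file_name=str(row["file_name"]),
            dataset_id=str(row["dataset_id"]),
            taxon_name=str(row["taxon_name"]),
            alt_taxon_name=alt,
            ncbi_id=ncbi,
            id_assignment=str(row["id_assignment"] or "automatic"),
            redu_available=_as_bool(row["redu_available"]),
            is_blank=_as_bool(row["is_blank"]),
            is_qc=_as_bool(row["is_qc"]),
        ))
    names = [r.file_name for r in records]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise SchemaError(f"duplicated file_name values in metadata: {dupes}")
    return records


def load_lineages(path: str | Path) -> LineageTable:
    """Read a lineage edge table (TSV: ncbi_id, parent_ncbi_id, name, rank)."""
    df = pd.read_csv(path, sep="\t", dtype={"ncbi_id": int,
                                            "parent_ncbi_id": int,
                                            "name": str, "rank": str})
    needed = {"ncbi_id", "parent_ncbi_id", "name", "rank"}
    missing = sorted(needed - set(df.columns))
    if missing:
        raise SchemaError(f"lineage table missing columns: {missing}")
    nodes = {int(r.ncbi_id): (int(r.parent_ncbi_id), str(r.name), str(r.rank))
             for r in df.itertuples()}
    return LineageTable(nodes)


class TaxonNode:
    """Node of the result tree with file/match counters."""

    __slots__ = ("ncbi_id", "name", "rank", "children", "parent",
                 "n_files", "n_matched", "counts_in_parent", "files",
                 "file_nodes")

    def __init__(self, ncbi_id: int, name: str, rank: str,
                 counts_in_parent: bool = True):
        self.ncbi_id = ncbi_id
        self.name = name
        self.rank = rank
        self.children: dict[int, TaxonNode] = {}
        self.parent: TaxonNode | None = None
        self.n_files = 0
        self.n_matched = 0
        self.counts_in_parent = counts_in_parent
        self.files: list[str] = []
        self.file_nodes: dict[str, TaxonNode] | None = None  # set on root

    @property
    def proportion(self) -> float | None:
        return self.n_matched / self.n_files if self.n_files > 0 else None

    @property
    def is_pseudo(self) -> bool:
        return self.ncbi_id < 0

    def child(self, ncbi_id: int, name: str, rank: str,
              counts_in_parent: bool = True) -> "TaxonNode":
        node = self.children.get(ncbi_id)
        if node is None:
            node = TaxonNode(ncbi_id, name, rank, counts_in_parent)
            node.parent = self
            self.children[ncbi_id] = node
        return node

    def sorted_children(self) -> list["TaxonNode"]:
        """Canonical child order: rank depth, then name, then id."""
        def key(n: TaxonNode):
            d = rank_depth(n.rank)
            return (0 if not n.is_pseudo else 1,
                    d if d is not None else len(RANKS), n.name, n.ncbi_id)
        return sorted(self.children.values(), key=key)

    def walk(self):
        yield self
        for c in self.sorted_children():
            yield from c.walk()

    def __repr__(self):
        return (f"TaxonNode({self.ncbi_id}, {self.name!r}, {self.rank!r}, "
                f"files={self.n_files}, matched={self.n_matched})")


def _resolve_lineage(record: MetadataRecord,
                     lineages: LineageTable) -> Lineage | None:
    if record.ncbi_id is not None and record.ncbi_id in lineages:
        return lineages.lineage(record.ncbi_id)
    # closest-taxon fallback by name: the curated alternative name first
    for name in (record.alt_taxon_name, record.taxon_name):
        nid = lineages.id_for_name(name)
        if nid is not None:
            return lineages.lineage(nid)
    return None


def build_tree(records: Sequence[MetadataRecord],
               lineages: LineageTable) -> TaxonNode:
    """Build the taxonomic tree and attach every file.

    Each biological file adds +1 to ``n_files`` along its full lineage;
    blanks and QCs go to pseudo-children of the root. Deterministic and
    input-order invariant.
    """
    root = TaxonNode(ROOT_ID, "root", "root")
    blank_node = root.child(BLANK_ID, "blanks", "pseudo", counts_in_parent=False)
    qc_node = root.child(QC_ID, "QCs", "pseudo", counts_in_parent=False)
    file_nodes: dict[str, TaxonNode] = {}

    resolved: list[tuple[MetadataRecord, Lineage | None]] = []
    for rec in sorted(records, key=lambda r: r.file_name):
        if rec.is_biological:
            resolved.append((rec, _resolve_lineage(rec, lineages)))

    # pass 1: topology from all resolved lineages
    for _, lin in resolved:
        if lin is None:
            continue
        node = root
        for nid, name, rank in lin.ranked_path:
            node = node.child(nid, name, rank)

    # pass 2: attach files (synthetic child when the target is internal,
    # keeping internal counters exact sums over children)
    for rec, lin in resolved:
        if lin is None:
            target = root.child(UNCLASSIFIED_ID, "unclassified", "pseudo")
        else:
            target = root
            for nid, name, rank in lin.ranked_path:
                target = target.children[nid]
            if any(not c.is_pseudo for c in target.children.values()):
                target = target.child(-(100000 + target.ncbi_id),
                                      f"{target.name} (unresolved descendants)",
                                      "no rank")
        target.files.append(rec.file_name)
        file_nodes[rec.file_name] = target

    for rec in records:
        if rec.is_blank:
            blank_node.files.append(rec.file_name)
            file_nodes[rec.file_name] = blank_node
        elif rec.is_qc:
            qc_node.files.append(rec.file_name)
            file_nodes[rec.file_name] = qc_node

    _recount_files(root)
    root.file_nodes = file_nodes
    return root


def _recount_files(node: TaxonNode) -> None:
    for c in node.children.values():
        _recount_files(c)
    node.n_files = len(node.files) + sum(
        c.n_files for c in node.children.values() if c.counts_in_parent)


def aggregate_matches(root: TaxonNode, matched_files: Iterable[str]) -> TaxonNode:
    """Recompute match counters from zero for a set of matched file names.

    Each matched biological file adds +1 to ``n_matched`` at its terminal
    node and every ancestor; blank/QC matches stay on their pseudo-node.
    Idempotent for a fixed matched set. Raises :class:`UnknownFileError`
    for a file name absent from the metadata.
    """
    if root.file_nodes is None:
        raise ValueError("tree was not built by build_tree (no file mapping)")
    for node in root.walk():
        node.n_matched = 0
    for fname in sorted(set(matched_files)):
        node = root.file_nodes.get(fname)
        if node is None:
            raise UnknownFileError(f"matched file {fname!r} not in metadata")
        node.n_matched += 1
        while node.parent is not None and node.counts_in_parent:
            node = node.parent
            node.n_matched += 1
    return root


def filter_tree(root: TaxonNode, max_rank: str | None = None,
                min_matches: int = 0) -> TaxonNode:
    """Return a filtered copy of the tree.

    ``max_rank`` collapses everything deeper than the given rank into its
    ancestor at that rank (counts are already aggregate sums, so the
    surviving node keeps the subtree totals). ``min_matches`` prunes nodes
    with fewer matches unless they are ancestors of retained nodes. The
    root (and its blank/QC pseudo-children, if retained by the match
    filter) always stays connected.
    """
    if max_rank is not None:
        depth = rank_depth(max_rank)
        if depth is None:
            raise UnknownRankError(
                f"unknown rank {max_rank!r}; valid ranks: {RANKS}")
    out = copy.deepcopy(root)

    if max_rank is not None:
        def collapse(node: TaxonNode):
            keep = {}
            for nid, c in node.children.items():
                d = rank_depth(c.rank)
                if c.parent is out and c.is_pseudo:
                    keep[nid] = c          # root-level pseudo-nodes survive
                elif d is None and c.is_pseudo:
                    continue               # attached synthetic child: fold up
                elif d is not None and d > depth:
                    continue
                else:
                    keep[nid] = c
            node.children = keep
            for c in node.children.values():
                collapse(c)
        collapse(out)

    if min_matches > 0:
        def prune(node: TaxonNode) -> bool:
            kept = {}
            for nid, c in node.children.items():
                if prune(c):
                    kept[nid] = c
            node.children = kept
            return bool(kept) or node.n_matched >= min_matches
        for nid in list(out.children):
            if not prune(out.children[nid]):
                del out.children[nid]

    # the copy's file map may reference dropped nodes; invalidate it
    out.file_nodes = None
    return out


def tree_to_dict(node: TaxonNode) -> dict:
    return {
        "ncbi_id": node.ncbi_id,
        "name": node.name,
        "rank": node.rank,
        "n_files": node.n_files,
        "n_matched": node.n_matched,
        "proportion": node.proportion,
        "children": [tree_to_dict(c) for c in node.sorted_children()],
    }


def tree_from_json(data: dict) -> TaxonNode:
    """Rebuild a counter tree from its JSON dict form (topology + counts)."""
    node = TaxonNode(int(data["ncbi_id"]), data["name"], data["rank"])
    node.n_files = int(data["n_files"])
    node.n_matched = int(data["n_matched"])
    for child_data in data.get("children", []):
        child = tree_from_json(child_data)
        child.parent = node
        node.children[child.ncbi_id] = child
    return node


def validate_tree_dict(data: dict) -> None:
    """Structural validation of the exported tree JSON (raises SchemaError)."""
    required = {"ncbi_id": int, "name": str, "rank": str,
                "n_files": int, "n_matched": int}
    for key, typ in required.items():
        if key not in data:
            raise SchemaError(f"tree JSON node missing key {key!r}")
        if not isinstance(data[key], typ):
            raise SchemaError(f"tree JSON key {key!r} has type "
                              f"{type(data[key]).__name__}, expected {typ.__name__}")
    prop = data.get("proportion")
    if prop is not None and not (0.0 <= prop <= 1.0):
        raise SchemaError(f"proportion {prop} outside [0, 1]")
    if not isinstance(data.get("children", []), list):
        raise SchemaError("tree JSON 'children' must be a list")
    for child in data.get("children", []):
        validate_tree_dict(child)


def _newick_label(node: TaxonNode) -> str:
    label = f"{node.name}|{node.ncbi_id}"
    label = label.replace("'", "_")
    comment = f"[&rank={node.rank},n_files={node.n_files},n_matched={node.n_matched}]"
    return f"'{label}'{comment}"


def _to_newick(node: TaxonNode) -> str:
    kids = node.sorted_children()
    if not kids:
        return _newick_label(node)
    inner = ",".join(_to_newick(c) for c in kids)
    return f"({inner}){_newick_label(node)}"


def _to_html(node: TaxonNode) -> str:
    def render(n: TaxonNode) -> str:
        prop = f", {n.proportion:.3f}" if n.proportion is not None else ""
        label = (f"{_html.escape(n.name)} [{n.rank}] "
                 f"({n.n_matched}/{n.n_files}{prop})")
        kids = n.sorted_children()
        if not kids:
            return f"<li>{label}</li>"
        sub = "".join(render(c) for c in kids)
        return (f"<li><details open><summary>{label}</summary>"
                f"<ul>{sub}</ul></details></li>")
    payload = json.dumps(tree_to_dict(node))
    return ("<!DOCTYPE html><html><head><meta charset='utf-8'>"
            "<title>taxomass tree</title>"
            "<style>body{font-family:sans-serif}ul{list-style:none}</style>"
            "</head><body><h1>Taxonomic match tree</h1>"
            f"<ul>{render(node)}</ul>"
            f"<script type='application/json' id='tree-data'>{payload}</script>"
            "</body></html>")


def export_tree(root: TaxonNode, format: str, path: str | Path) -> Path:
    """Write the tree as nested JSON, Newick (labels ``name|ncbi_id`` with
    counters in comment blocks) or a static self-contained HTML page."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        data = tree_to_dict(root)
        validate_tree_dict(data)
        path.write_text(json.dumps(data, indent=1) + "\n")
    elif format == "newick":
        path.write_text(_to_newick(root) + ";\n")
    elif format == "html":
        path.write_text(_to_html(root))
    else:
        raise ValueError(f"unknown tree export format {format!r}; "
                         "use json, newick or html")
    return path
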