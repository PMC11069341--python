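"""Phylogenetic-placement ingestion and query classification.

Reads jplace v3 files (the EPA-ng output format: a JSON container holding
the reference newick with ``{N}`` edge numbers and per-query placements
with like_weight_ratio, LWR), assigns each query a functional cluster and
a consensus taxonomy by a best-hit rule — the cluster collecting the
largest summed LWR wins — filters poor-quality placements by that summed
LWR, and aggregates kept queries into (taxon, implementation, context)
sequence groups with summed TPM abundance and observed richness.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import dendropy
import numpy as np
import pandas as pd

from ._trees import ensure_node_ids, leaf_ids_under, node_id
from .tree_annotation import AnnotatedTree

__all__ = [
    "PlacementSet",
    "read_jplace",
    "write_jplace",
    "parse_jplace_tree",
    "jplace_tree_text",
    "consensus_taxonomy",
    "assign_queries",
    "filter_low_quality",
    "build_groups",
]

KNOWN_FIELDS = {
    "edge_num",
    "likelihood",
    "like_weight_ratio",
    "distal_length",
    "pendant_length",
}

ASSIGNMENT_COLUMNS = (
    "query",
    "cluster",
    "u",
    "taxonomy",
    "confidence",
    "best_edge",
    "n_placements",
)

_EDGE_TOKEN = re.compile(r"([^,():{}\[\]\s]*)((?::[0-9eE&+\-.]+)?)\{(\d+)\}")
_EDGE_LABEL = re.compile(r"^(.*)__EDGE_(\d+)__$")


@dataclass
class PlacementSet:
    """Parsed jplace content: reference tree text plus per-query placements."""

    tree_text: str
    fields: List[str]
    placements: List[dict]  # each: {"name": str, "p": [[...], ...]}
    version: int = 3
    metadata: dict = field(default_factory=dict)

    def edge_numbers(self) -> set:
        i = self.fields.index("edge_num")
        return {int(p[i]) for q in self.placements for p in q["p"]}


def parse_jplace_tree(tree_text: str) -> Tuple[dendropy.Tree, Dict[int, dendropy.Node]]:
    """Parse a newick with jplace ``{N}`` edge tokens.

    Returns the tree (edge tokens stripped) and the edge number -> child
    node map. The token is rewritten onto the node label before parsing so
    a standard newick reader can carry it through.
    """
    rewritten = _EDGE_TOKEN.sub(r"\1__EDGE_\3__\2", tree_text)
    if "{" in rewritten:
        raise ValueError("malformed jplace tree: unparsed {N} edge tokens remain")
    tree = dendropy.Tree.get(data=rewritten, schema="newick", preserve_underscores=True)
    edge_map: Dict[int, dendropy.Node] = {}
    for nd in tree.preorder_node_iter():
        label = nd.taxon.label if nd.is_leaf() and nd.taxon else nd.label
        if label is None:
            continue
        m = _EDGE_LABEL.match(label)
        if not m:
            continue
        stripped = m.group(1) or None
        if nd.is_leaf() and nd.taxon:
            nd.taxon.label = stripped
        else:
            nd.label = stripped
        edge_map[int(m.group(2))] = nd
    ensure_node_ids(tree)
    return tree, edge_map


def jplace_tree_text(tree: dendropy.Tree, edge_map: Mapping[int, dendropy.Node]) -> str:
    """Render a tree back to newick with ``{N}`` edge tokens."""
    node_to_edge = {id(nd): num for num, nd in edge_map.items()}
    for nd in tree.preorder_node_iter():
        num = node_to_edge.get(id(nd))
        if num is None:
            continue
        if nd.is_leaf() and nd.taxon:
            nd.taxon.label = f"{nd.taxon.label}__EDGE_{num}__"
        else:
            nd.label = f"{nd.label or ''}__EDGE_{num}__"
    text = tree.as_string(schema="newick", unquoted_underscores=True, suppress_rooting=True)
    # restore labels
    for nd in tree.preorder_node_iter():
        label = nd.taxon.label if nd.is_leaf() and nd.taxon else nd.label
        if label is None:
            continue
        m = _EDGE_LABEL.match(label)
        if not m:
            continue
        if nd.is_leaf() and nd.taxon:
            nd.taxon.label = m.group(1) or None
        else:
            nd.label = m.group(1) or None
    def put_token(m):
        return f"{m.group(1)}{m.group(3) or ''}{{{m.group(2)}}}"
    return re.sub(r"([^,():\s]*?)__EDGE_(\d+)__((?::[0-9eE+\-.]+)?)", put_token, text).strip() + "\n"


def read_jplace(path, lwr_tolerance: float = 1e-6) -> PlacementSet:
    """Read and validate a jplace v3 file."""
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("tree", "placements", "fields"):
        if key not in doc:
            raise ValueError(f"jplace file lacks required key: {key!r}")
    fields = list(doc["fields"])
    for fname in ("edge_num", "like_weight_ratio"):
        if fname not in fields:
            raise ValueError(f"jplace 'fields' lacks {fname!r}")
    unknown = [f for f in fields if f not in KNOWN_FIELDS]
    if unknown:
        warnings.warn(f"ignoring unknown jplace fields: {unknown}")
    version = int(doc.get("version", 3))
    if version != 3:
        warnings.warn(f"jplace version {version} is not 3; attempting to read anyway")
    _, edge_map = parse_jplace_tree(doc["tree"])
    i_edge = fields.index("edge_num")
    i_lwr = fields.index("like_weight_ratio")
    placements = []
    for entry in doc["placements"]:
        if "n" in entry:
            names = list(entry["n"])
        elif "nm" in entry:
            names = [nm[0] for nm in entry["nm"]]
        else:
            raise ValueError("placement entry lacks 'n'/'nm' query names")
        p = [list(row) for row in entry["p"]]
        lwr_sum = sum(row[i_lwr] for row in p)
        for name in names:
            if lwr_sum > 1 + lwr_tolerance:
                raise ValueError(
                    f"query {name!r}: like_weight_ratio sums to {lwr_sum} > 1"
                )
            bad = [int(row[i_edge]) for row in p if int(row[i_edge]) not in edge_map]
            if bad:
                raise ValueError(f"query {name!r} placed on unknown edges: {bad}")
            placements.append({"name": name, "p": p})
    return PlacementSet(
        tree_text=doc["tree"],
        fields=fields,
        placements=placements,
        version=version,
        metadata=doc.get("metadata", {}),
    )


def write_jplace(pset: PlacementSet, path) -> None:
    """Write a PlacementSet back to jplace v3 (order-normalized, deterministic)."""
    i_lwr = pset.fields.index("like_weight_ratio")
    placements = [
        {
            "p": sorted(q["p"], key=lambda row: (-row[i_lwr], row)),
            "n": [q["name"]],
        }
        for q in sorted(pset.placements, key=lambda q: q["name"])
    ]
    doc = {
        "tree": pset.tree_text,
        "placements": placements,
        "fields": pset.fields,
        "version": pset.version,
        "metadata": pset.metadata,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def consensus_taxonomy(
    tree: dendropy.Tree, leaf_taxonomies: Mapping[str, str]
) -> Dict[str, str]:
    """Longest-common-prefix taxonomy (semicolon-ranked) for every node."""
    ensure_node_ids(tree)
    paths: Dict[int, List[str]] = {}
    out: Dict[str, str] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            nid = node_id(nd)
            if nid not in leaf_taxonomies:
                raise KeyError(f"leaf {nid!r} has no taxonomy path")
            raw = leaf_taxonomies[nid]
            if not isinstance(raw, str) or raw == "":
                raise ValueError(f"malformed taxonomy path for leaf {nid!r}: {raw!r}")
            parts = [p.strip() for p in raw.split(";")]
            if any(p == "" for p in parts):
                raise ValueError(f"malformed taxonomy path for leaf {nid!r}: {raw!r}")
        else:
            child_paths = [paths[id(ch)] for ch in nd.child_nodes()]
            parts = list(child_paths[0])
            for cp in child_paths[1:]:
                k = 0
                while k < min(len(parts), len(cp)) and parts[k] == cp[k]:
                    k += 1
                parts = parts[:k]
        paths[id(nd)] = parts
        out[node_id(nd)] = ";".join(parts)
    return out


def _edge_to_annotated_node(
    placement_tree: dendropy.Tree,
    edge_map: Mapping[int, dendropy.Node],
    atree: AnnotatedTree,
) -> Dict[int, str]:
    """Map jplace edge numbers to annotated-tree node ids via child leaf sets."""
    n_edges_placement = sum(
        1 for nd in placement_tree.preorder_node_iter() if nd.parent_node is not None
    )
    n_edges_annot = sum(
        1 for nd in atree.tree.preorder_node_iter() if nd.parent_node is not None
    )
    if n_edges_placement != n_edges_annot:
        raise ValueError(
            f"edge count mismatch: placement tree has {n_edges_placement}, "
            f"annotated tree has {n_edges_annot}"
        )
    by_leafset = {leaf_ids_under(nd): node_id(nd) for nd in atree.tree.preorder_node_iter()}
    out = {}
    for num, nd in edge_map.items():
        ls = leaf_ids_under(nd)
        nid = by_leafset.get(ls)
        if nid is None:
            raise ValueError(
                f"edge {num}: no annotated-tree node with matching leaf set"
            )
        out[num] = nid
    return out


def assign_queries(pset: PlacementSet, atree: AnnotatedTree) -> pd.DataFrame:
    """Best-hit cluster and taxonomy assignment for every placed query.

    Per query, LWR mass is summed per cluster (an edge belongs to the
    cluster of its child node; edges above every cluster root are
    *incertae*) and the argmax cluster wins. Ties break toward the cluster
    holding the single best-supported edge, then lexicographically.
    Taxonomy is the consensus at the best edge of the winning cluster.
    Queries landing in u = 0 clusters are kept and flagged non-functional;
    queries whose best cluster is *incertae* keep that label.
    """
    ptree, edge_map = parse_jplace_tree(pset.tree_text)
    edge_node = _edge_to_annotated_node(ptree, edge_map, atree)
    taxonomy = (
        consensus_taxonomy(atree.tree, atree.leaf_taxonomy)
        if atree.leaf_taxonomy
        else None
    )
    i_edge = pset.fields.index("edge_num")
    i_lwr = pset.fields.index("like_weight_ratio")
    rows = []
    for q in pset.placements:
        mass: Dict[str, float] = {}
        best_in_cluster: Dict[str, Tuple[float, int]] = {}
        cluster_u: Dict[str, Optional[float]] = {}
        for row in q["p"]:
            edge = int(row[i_edge])
            lwr = float(row[i_lwr])
            label, u = atree.cluster_of(edge_node[edge])
            mass[label] = mass.get(label, 0.0) + lwr
            cluster_u[label] = u
            cur = best_in_cluster.get(label)
            if cur is None or lwr > cur[0]:
                best_in_cluster[label] = (lwr, edge)
        top = max(mass.values())
        tied = [lab for lab, m in mass.items() if m == top]
        if len(tied) > 1:
            best_lwr = max(best_in_cluster[lab][0] for lab in tied)
            tied2 = sorted(
                lab for lab in tied if best_in_cluster[lab][0] == best_lwr
            )
            if len(tied2) > 1:
                warnings.warn(
                    f"query {q['name']!r}: cluster tie among {tied2}, "
                    "breaking lexicographically"
                )
            winner = tied2[0]
        else:
            winner = tied[0]
        best_edge = best_in_cluster[winner][1]
        tax = taxonomy[edge_node[best_edge]] if taxonomy is not None else ""
        rows.append(
            (
                q["name"],
                winner,
                cluster_u[winner],
                tax,
                min(top, 1.0),
                best_edge,
                len(q["p"]),
            )
        )
    return pd.DataFrame(rows, columns=list(ASSIGNMENT_COLUMNS))


def filter_low_quality(
    assignments: pd.DataFrame, min_confidence: float
) -> Tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Split assignments at the confidence threshold.

    Confidence is the winning cluster's summed LWR (the weighted likelihood
    robustness of the classification). Returns (kept, discarded, report);
    the report carries counts, the discard percentage, and the mean
    confidence of kept queries.
    """
    if not (0.0 <= min_confidence <= 1.0):
        raise ValueError(f"min_confidence must lie in [0, 1], got {min_confidence}")
    keep = assignments["confidence"] >= min_confidence
    kept, discarded = assignments[keep], assignments[~keep]
    n = len(assignments)
    report = {
        "n_total": n,
        "n_kept": int(keep.sum()),
        "n_discarded": int((~keep).sum()),
        "pct_discarded": float(100.0 * (~keep).sum() / n) if n else 0.0,
        "mean_confidence_kept": float(kept["confidence"].mean()) if len(kept) else float("nan"),
    }
    return kept, discarded, report


def _truncate_rank(path: str, rank: Optional[int]) -> str:
    if not path:
        return "unresolved"
    parts = path.split(";")
    if rank is None or rank >= len(parts):
        return path  # deepest resolved rank
    return ";".join(parts[:rank])


def build_groups(
    assignments: pd.DataFrame,
    abundance: pd.DataFrame,
    rank: Optional[int] = None,
    on_missing_abundance: str = "error",
) -> pd.DataFrame:
    """Aggregate kept queries into (taxon, implementation, context) groups.

    ``abundance`` columns: query_id, context, tpm. Group abundance is the
    summed TPM of member queries in that context; d_obs counts distinct
    member queries. ``rank`` truncates the taxonomy path to its first
    ``rank`` levels (None keeps the deepest resolved path). Queries in the
    abundance table that were never placed raise a warning; placed queries
    missing from the abundance table raise by default (``"drop"`` discards
    them with a warning instead).
    """
    required = {"query_id", "context", "tpm"}
    if not required <= set(abundance.columns):
        raise ValueError(f"abundance table must have columns {sorted(required)}")
    dup = abundance.duplicated(subset=["query_id", "context"])
    if dup.any():
        offenders = abundance.loc[dup, ["query_id", "context"]].values.tolist()
        raise ValueError(f"duplicated (query, context) abundance rows: {offenders[:5]}")
    placed = set(assignments["query"])
    unplaced = sorted(set(abundance["query_id"]) - placed)
    if unplaced:
        warnings.warn(f"{len(unplaced)} abundance queries were never placed: {unplaced[:5]}")
    missing = sorted(placed - set(abundance["query_id"]))
    if missing:
        if on_missing_abundance == "error":
            raise ValueError(
                f"{len(missing)} placed queries lack abundance rows: {missing[:5]}"
            )
        elif on_missing_abundance == "drop":
            warnings.warn(f"dropping {len(missing)} placed queries without abundance")
        else:
            raise ValueError(f"unknown on_missing_abundance: {on_missing_abundance!r}")
    merged = abundance.merge(
        assignments[["query", "cluster", "taxonomy"]],
        left_on="query_id",
        right_on="query",
        how="inner",
    )
    merged["taxon"] = [_truncate_rank(p, rank) for p in merged["taxonomy"]]
    grouped = (
        merged.groupby(["taxon", "cluster", "context"])
        .agg(abundance_tpm=("tpm", "sum"), d_obs=("query_id", "nunique"))
        .reset_index()
        .rename(columns={"cluster": "implementation"})
    )
    return grouped[["taxon", "implementation", "context", "abundance_tpm", "d_obs"]]
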