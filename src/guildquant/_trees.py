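"""Shared helpers for dendropy trees: stable node ids and newick IO.

Node id convention: leaves are identified by their taxon label; internal
nodes keep the label present in the newick if any, otherwise they are
assigned ``n<i>`` in preorder. Ids are written back when trees are saved,
so downstream tables (clusters, enrichment results, divergence points)
stay joinable across runs.
"""

from __future__ import annotations

from typing import Dict

import dendropy


def read_tree(path_or_text, schema: str = "newick") -> dendropy.Tree:
    if "\n" in str(path_or_text) or str(path_or_text).rstrip().endswith(";"):
        tree = dendropy.Tree.get(data=str(path_or_text), schema=schema, preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(path=str(path_or_text), schema=schema, preserve_underscores=True)
    ensure_node_ids(tree)
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree))


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )


def node_id(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label if node.taxon else node.label
    return node.label


def ensure_node_ids(tree: dendropy.Tree) -> Dict[str, dendropy.Node]:
    """Assign ids to unlabeled internal nodes and return the id -> node map."""
    taken = set()
    for nd in tree.preorder_node_iter():
        nid = node_id(nd)
        if nid is not None:
            taken.add(nid)
    i = 0
    index: Dict[str, dendropy.Node] = {}
    for nd in tree.preorder_node_iter():
        if node_id(nd) is None:
            while f"n{i}" in taken:
                i += 1
            nd.label = f"n{i}"
            taken.add(nd.label)
        nid = node_id(nd)
        if nid in index:
            raise ValueError(f"duplicate node id in tree: {nid!r}")
        index[nid] = nd
    return index


def leaf_ids_under(node: dendropy.Node) -> frozenset:
    return frozenset(node_id(lf) for lf in node.leaf_iter())


def parent_map(tree: dendropy.Tree) -> Dict[str, str]:
    """node id -> parent node id (root absent)."""
    out = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            out[node_id(nd)] = node_id(nd.parent_node)
    return out
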