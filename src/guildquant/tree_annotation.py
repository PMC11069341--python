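"""Annotation of reference gene trees with functional clusters.

Two routes produce clusters:

* :func:`assign_univocity` propagates experimental functional / non-functional
  evidence from leaves to the largest monophyletic regions whose evidenced
  leaves are unanimous, yielding clusters with univocity u = 1 or u = 0;
  mixed or unevidenced regions stay *incertae*.

* :func:`node_trait_enrichment` + :func:`select_general_nodes` +
  :func:`define_implementations` discover "implementations" — sequence
  spaces putatively adapted to shared environmental conditions — as internal
  nodes whose leaf-trait mean is extreme against a tree-wide leaf-label
  randomization null (20 000 shuffles by default, |z| >= 3, one-tailed
  permutation P < 0.003), keeping only the most general such nodes (those
  significant while their parent is not).
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Tuple

import dendropy
import numpy as np
import pandas as pd

from ._trees import ensure_node_ids, leaf_ids_under, node_id, parent_map, read_tree

__all__ = [
    "AnnotatedTree",
    "assign_univocity",
    "node_trait_enrichment",
    "select_general_nodes",
    "define_implementations",
    "read_trait_table",
    "write_trait_table",
]

INCERTAE = "incertae"

ENRICHMENT_COLUMNS = (
    "node_id",
    "trait",
    "n_leaves_with_data",
    "observed_mean",
    "null_mean",
    "null_sd",
    "z",
    "p_one_tailed",
    "significant",
    "most_general",
)


class AnnotatedTree:
    """A reference tree whose regions carry cluster labels and univocity.

    ``cluster_map`` maps a cluster-root node id to ``(label, u)``. Cluster
    regions must be disjoint: no cluster root may be an ancestor of another.
    Every leaf belongs to the cluster of its nearest cluster-root ancestor
    (or itself), or is *incertae*.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        cluster_map: Optional[Mapping[str, Tuple[str, float]]] = None,
        leaf_taxonomy: Optional[Mapping[str, str]] = None,
    ):
        self.tree = tree
        self.nodes = ensure_node_ids(tree)
        self.cluster_map: Dict[str, Tuple[str, float]] = {
            k: (str(v[0]), None if v[1] is None else float(v[1]))
            for k, v in (cluster_map or {}).items()
        }
        self.leaf_taxonomy = dict(leaf_taxonomy or {})
        unknown = [nid for nid in self.cluster_map if nid not in self.nodes]
        if unknown:
            raise KeyError(f"cluster map references unknown node ids: {unknown}")
        self._check_disjoint()

    def _check_disjoint(self):
        roots = set(self.cluster_map)
        for nid in roots:
            nd = self.nodes[nid].parent_node
            while nd is not None:
                if node_id(nd) in roots:
                    raise ValueError(
                        f"cluster regions overlap: {nid!r} lies under {node_id(nd)!r}"
                    )
                nd = nd.parent_node

    def leaf_ids(self):
        return [node_id(lf) for lf in self.tree.leaf_node_iter()]

    def cluster_of(self, nid: str) -> Tuple[str, Optional[float]]:
        """(cluster label, u) of the nearest cluster-root ancestor-or-self."""
        nd = self.nodes[nid]
        while nd is not None:
            hit = self.cluster_map.get(node_id(nd))
            if hit is not None:
                return hit
            nd = nd.parent_node
        return (INCERTAE, None)

    def leaf_clusters(self) -> Dict[str, str]:
        return {lid: self.cluster_of(lid)[0] for lid in self.leaf_ids()}

    def univocity_table(self) -> Dict[str, float]:
        """cluster label -> u (labels sharing a u must agree)."""
        out: Dict[str, float] = {}
        for label, u in self.cluster_map.values():
            if label in out and out[label] != u:
                raise ValueError(f"cluster label {label!r} carries conflicting u values")
            out[label] = u
        return out

    def write_clusters(self, path) -> None:
        df = pd.DataFrame(
            [(nid, lab, u) for nid, (lab, u) in sorted(self.cluster_map.items())],
            columns=["node_id", "cluster", "u"],
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_files(cls, tree_path, clusters_path=None, taxonomy_path=None) -> "AnnotatedTree":
        tree = read_tree(tree_path)
        cluster_map = {}
        if clusters_path is not None:
            cdf = pd.read_csv(clusters_path, sep="\t", dtype={"node_id": str, "cluster": str})
            for row in cdf.itertuples(index=False):
                u = None if pd.isna(row.u) else float(row.u)
                cluster_map[str(row.node_id)] = (str(row.cluster), u)
        taxonomy = None
        if taxonomy_path is not None:
            tdf = pd.read_csv(taxonomy_path, sep="\t", dtype=str)
            taxonomy = dict(zip(tdf["leaf_id"], tdf["taxonomy"]))
        return cls(tree, cluster_map, taxonomy)


def assign_univocity(tree: dendropy.Tree, evidence: Mapping[str, str]) -> AnnotatedTree:
    """Propagate leaf-level functional evidence to maximal unanimous clades.

    ``evidence`` maps leaf id -> one of ``functional`` / ``non-functional``
    / ``ambiguous``. A node is unanimous when it has evidenced leaves, all
    functional or all non-functional, with no ambiguous evidence below it.
    The maximal unanimous nodes become cluster roots with u = 1 or u = 0;
    everything else stays *incertae* — the conservative propagation: a
    cluster never contains contradictory evidence.
    """
    if not evidence:
        raise ValueError("evidence must cover at least one leaf")
    index = ensure_node_ids(tree)
    leaves = {node_id(lf) for lf in tree.leaf_node_iter()}
    unknown = sorted(set(evidence) - leaves)
    if unknown:
        raise KeyError(f"evidence references unknown leaves: {unknown}")
    valid = {"functional", "non-functional", "ambiguous"}
    bad = sorted({v for v in evidence.values() if v not in valid})
    if bad:
        raise ValueError(f"unknown evidence labels: {bad} (expected {sorted(valid)})")

    counts: Dict[int, np.ndarray] = {}  # id(node) -> [n_func, n_nonfunc, n_ambig]
    for nd in tree.postorder_node_iter():
        c = np.zeros(3, int)
        if nd.is_leaf():
            ev = evidence.get(node_id(nd))
            if ev == "functional":
                c[0] = 1
            elif ev == "non-functional":
                c[1] = 1
            elif ev == "ambiguous":
                c[2] = 1
        else:
            for ch in nd.child_nodes():
                c += counts[id(ch)]
        counts[id(nd)] = c

    def unanimous(nd):
        f, n, a = counts[id(nd)]
        if a > 0 or (f > 0 and n > 0):
            return None
        if f > 0:
            return 1.0
        if n > 0:
            return 0.0
        return None

    cluster_map: Dict[str, Tuple[str, float]] = {}
    n_f = n_nf = 0
    for nd in tree.preorder_node_iter():
        u = unanimous(nd)
        if u is None:
            continue
        parent = nd.parent_node
        if parent is not None and unanimous(parent) is not None:
            continue  # not maximal
        if u == 1.0:
            n_f += 1
            label = f"F{n_f}"
        else:
            n_nf += 1
            label = f"NF{n_nf}"
        cluster_map[node_id(nd)] = (label, u)
    return AnnotatedTree(tree, cluster_map)


def read_trait_table(path) -> pd.DataFrame:
    """Long TSV (leaf_id, trait, value) -> wide leaf x trait DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype={"leaf_id": str, "trait": str})
    return df.pivot_table(index="leaf_id", columns="trait", values="value", aggfunc="first")


def write_trait_table(traits: pd.DataFrame, path) -> None:
    long = traits.stack().rename("value").reset_index()
    long.columns = ["leaf_id", "trait", "value"]
    long.to_csv(path, sep="\t", index=False)


def node_trait_enrichment(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    n_rand: int = 20_000,
    min_leaves: int = 4,
    seed: Optional[int] = None,
    z_threshold: float = 3.0,
) -> pd.DataFrame:
    """Randomization test of leaf-trait means at every internal node.

    For each internal node and trait, the observed mean over the node's
    data-bearing leaves is compared against the null distribution obtained
    by shuffling the trait values among *all* data-bearing leaves tree-wide
    and recomputing the node mean per shuffle. Reports z scores, one-tailed
    permutation p values with the (b+1)/(B+1) correction, and significance
    at |z| >= z_threshold for nodes with at least ``min_leaves`` data
    leaves. A constant trait (null sd = 0) yields z = 0, never significant.
    Deterministic given ``seed``.
    """
    if n_rand < 1000:
        raise ValueError(f"n_rand must be >= 1000 for a usable null, got {n_rand}")
    if traits.shape[1] == 0:
        raise ValueError("trait table has no trait columns")
    index = ensure_node_ids(tree)
    leaves = [node_id(lf) for lf in tree.leaf_node_iter()]
    leaf_set = set(leaves)
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    internal_leafsets = {node_id(nd): leaf_ids_under(nd) for nd in internal}

    rng = np.random.default_rng(seed)
    rows = []
    for trait in traits.columns:
        col = traits[trait].dropna()
        col = col[col.index.isin(leaf_set)]
        # sort for leaf-input-order invariance
        col = col.sort_index()
        if col.empty:
            raise ValueError(f"trait {trait!r} has no data-bearing leaves in the tree")
        data_leaves = list(col.index)
        v = col.to_numpy(float)
        pos = {lid: i for i, lid in enumerate(data_leaves)}
        mask = np.zeros((len(internal), len(v)), bool)
        for r, nd in enumerate(internal):
            for lid in internal_leafsets[node_id(nd)]:
                i = pos.get(lid)
                if i is not None:
                    mask[r, i] = True
        counts = mask.sum(axis=1)
        keep = counts >= 1
        perms = rng.permuted(np.tile(v, (n_rand, 1)), axis=1)
        null = (mask[keep].astype(float) @ perms.T) / counts[keep, None]
        obs = (mask[keep].astype(float) @ v) / counts[keep]
        null_mean = null.mean(axis=1)
        null_sd = null.std(axis=1, ddof=1)
        upper = obs >= null_mean
        # ties count as at-least-as-extreme; tolerance absorbs float
        # summation-order noise when a shuffle reproduces the observed subset
        tol = 1e-9 * (np.abs(obs) + np.abs(null_mean) + null_sd + 1.0)
        b = np.where(
            upper,
            (null >= (obs - tol)[:, None]).sum(axis=1),
            (null <= (obs + tol)[:, None]).sum(axis=1),
        )
        p = (b + 1) / (n_rand + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(null_sd > 0, (obs - null_mean) / null_sd, 0.0)
        p = np.where(null_sd > 0, p, 1.0)
        node_ids = [node_id(nd) for nd, k in zip(internal, keep) if k]
        sig = (np.abs(z) >= z_threshold) & (counts[keep] >= min_leaves) & (null_sd > 0)
        for i, nid in enumerate(node_ids):
            rows.append(
                (
                    nid,
                    trait,
                    int(counts[keep][i]),
                    float(obs[i]),
                    float(null_mean[i]),
                    float(null_sd[i]),
                    float(z[i]),
                    float(p[i]),
                    bool(sig[i]),
                    False,
                )
            )
    return pd.DataFrame(rows, columns=list(ENRICHMENT_COLUMNS))


def select_general_nodes(results: pd.DataFrame, tree: dendropy.Tree) -> pd.DataFrame:
    """Mark, per trait, significant nodes whose parent is not significant.

    Returns a copy of ``results`` with ``most_general`` set; the root
    qualifies whenever it is significant. The selected nodes are the most
    general (largest) tree regions supporting each trait association.
    """
    parents = parent_map(tree)
    out = results.copy()
    out["most_general"] = False
    for trait, sub in results.groupby("trait"):
        sig = set(sub.loc[sub["significant"], "node_id"])
        general = {nid for nid in sig if parents.get(nid) not in sig}
        sel = (out["trait"] == trait) & out["node_id"].isin(general)
        out.loc[sel, "most_general"] = True
    return out


def general_nodes_per_trait(results: pd.DataFrame) -> Dict[str, set]:
    marked = results[results["most_general"]]
    return {t: set(s["node_id"]) for t, s in marked.groupby("trait")}


def define_implementations(
    tree: dendropy.Tree,
    selected: Mapping[str, Iterable[str]],
    labels: Optional[Mapping[str, str]] = None,
    trait_order: Optional[Iterable[str]] = None,
    default_u: float = 1.0,
) -> AnnotatedTree:
    """Turn selected (most-general) nodes into implementation clusters.

    ``selected`` maps trait -> node ids. When selections from different
    traits overlap (in a tree: nested or identical), the node covering more
    leaves wins; ties break by trait order (given or alphabetical).
    Identical nodes chosen by several traits merge into one cluster. Leaves
    under no selected node remain *incertae*.
    """
    index = ensure_node_ids(tree)
    order = list(trait_order) if trait_order is not None else sorted(selected)
    cand = []  # (n_leaves, trait_rank, node_id, trait)
    for trait, nids in selected.items():
        rank = order.index(trait) if trait in order else len(order)
        for nid in nids:
            if nid not in index:
                raise KeyError(f"selected node {nid!r} not in tree")
            cand.append((len(leaf_ids_under(index[nid])), rank, nid, trait))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))

    kept: Dict[str, set] = {}  # node_id -> traits
    kept_leafsets: Dict[str, frozenset] = {}
    for n_leaves, rank, nid, trait in cand:
        if nid in kept:
            kept[nid].add(trait)
            continue
        ls = leaf_ids_under(index[nid])
        overlapping = [k for k, kls in kept_leafsets.items() if ls & kls]
        if overlapping:
            # precedence: the larger node was kept first; drop this one
            for k in overlapping:
                if not (ls <= kept_leafsets[k]):
                    raise ValueError(
                        f"selections {nid!r} and {k!r} overlap without nesting"
                    )
            continue
        kept[nid] = {trait}
        kept_leafsets[nid] = ls

    cluster_map = {}
    for nid, trts in kept.items():
        if labels is not None and nid in labels:
            label = labels[nid]
        else:
            label = nid
        cluster_map[nid] = (label, default_u)
    return AnnotatedTree(tree, cluster_map)
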