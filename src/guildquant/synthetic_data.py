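"""Synthetic inputs with planted ground truth.

Everything the pipeline consumes — reference trees, leaf trait tables,
jplace placements, per-context abundance tables, cluster annotations — can
be generated here with known answers: which internal nodes carry a trait
shift, which cluster each query belongs to, and the impact coefficient k
each (taxon, implementation, context) group should receive.

Generation laws (recorded in each scenario's metadata):

* Trees: Yule (pure-birth) topology, exponential inter-event waiting times
  as branch lengths.
* Traits: Gaussian baseline; leaves under a planted clade are shifted by a
  fixed effect; values missing completely at random.
* Placements: each query draws a home cluster, spreads its LWR mass over a
  few edges inside that cluster with a Dirichlet-concentrated profile, and
  draws a lognormal TPM per context — lognormal because metagenomic
  per-group abundances span orders of magnitude.
* Marker/target tree triples: per-branch lognormal rate jitter around a
  shared base tree; convergence is planted in the target by regrafting a
  distant leaf next to another, so the pair's ancestor shows a much
  smaller target distance than either phylomarker predicts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from ._trees import ensure_node_ids, leaf_ids_under, node_id, tree_to_newick
from .guild_model import RichnessModel, expected_richness, impact_coefficient
from .placement_io import PlacementSet, jplace_tree_text
from .tree_annotation import AnnotatedTree

__all__ = [
    "simulate_tree",
    "plant_traits",
    "simulate_placements",
    "simulate_marker_pair",
    "SimulatedPlacements",
    "MarkerTriple",
]

JPLACE_FIELDS = ["edge_num", "likelihood", "like_weight_ratio"]


def simulate_tree(n_leaves: int, seed: Optional[int] = None, birth_rate: float = 1.0) -> dendropy.Tree:
    """Yule pure-birth tree with exponential branch lengths.

    Leaves are named ``L000..`` in birth order and internal nodes ``n0..``
    in preorder; identical seeds reproduce identical newick strings.
    """
    if n_leaves < 3:
        raise ValueError(f"need at least 3 leaves, got {n_leaves}")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    first, second = root.new_child(), root.new_child()
    active = [first, second]
    pending = {id(first): 0.0, id(second): 0.0}
    while len(active) < n_leaves:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for nd in active:
            pending[id(nd)] += wait
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        parent.edge.length = pending.pop(id(parent))
        a, b = parent.new_child(), parent.new_child()
        active.extend([a, b])
        pending[id(a)] = 0.0
        pending[id(b)] = 0.0
    wait = rng.exponential(1.0 / (birth_rate * len(active)))
    for i, nd in enumerate(active):
        nd.edge.length = pending[id(nd)] + wait
    root.edge.length = None
    for i, nd in enumerate(tree.leaf_node_iter()):
        nd.taxon = tns.new_taxon(label=f"L{i:03d}")
    ensure_node_ids(tree)
    return tree


def plant_traits(
    tree: dendropy.Tree,
    clade_shifts: Mapping[str, float],
    noise_sd: float = 1.0,
    missing_frac: float = 0.0,
    baseline: float = 0.0,
    trait_name: str = "trait",
    n_null_traits: int = 0,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, List[str]]:
    """Plant trait shifts on disjoint clades over a Gaussian baseline.

    Returns the wide leaf x trait table (shifted trait first, then
    ``n_null_traits`` i.i.d. no-signal traits) and the ground-truth list of
    shifted clade node ids (those with a nonzero shift).
    """
    index = ensure_node_ids(tree)
    rng = np.random.default_rng(seed)
    leaves = [node_id(lf) for lf in tree.leaf_node_iter()]
    clade_leaves: Dict[str, frozenset] = {}
    for nid in clade_shifts:
        if nid not in index:
            raise KeyError(f"clade node {nid!r} not in tree")
        clade_leaves[nid] = leaf_ids_under(index[nid])
    ids = list(clade_shifts)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if clade_leaves[ids[i]] & clade_leaves[ids[j]]:
                raise ValueError(f"clades {ids[i]!r} and {ids[j]!r} overlap")
    if missing_frac >= 1.0:
        raise ValueError("missing_frac = 1 leaves no data-bearing leaves")

    values = baseline + rng.normal(0.0, noise_sd, size=len(leaves))
    for nid, shift in clade_shifts.items():
        members = clade_leaves[nid]
        for i, lid in enumerate(leaves):
            if lid in members:
                values[i] += shift
    data = {trait_name: values}
    for t in range(n_null_traits):
        data[f"null_{t}"] = baseline + rng.normal(0.0, noise_sd, size=len(leaves))
    df = pd.DataFrame(data, index=pd.Index(leaves, name="leaf_id"))
    if missing_frac > 0:
        miss = rng.random(df.shape) < missing_frac
        df = df.mask(miss)
    truth = [nid for nid, s in clade_shifts.items() if s != 0]
    return df, truth


@dataclass
class SimulatedPlacements:
    """A placement scenario with planted ground truth."""

    annotated_tree: AnnotatedTree
    placement_set: PlacementSet
    abundance: pd.DataFrame  # query_id, context, tpm
    truth_assignments: pd.DataFrame  # query, cluster
    truth_groups: pd.DataFrame  # taxon, implementation, context, abundance_tpm, d_obs, u, d_exp, k
    richness_model: RichnessModel
    params: dict = field(default_factory=dict)


def _edge_numbering(tree: dendropy.Tree) -> Dict[int, dendropy.Node]:
    """Number every non-root node's edge in preorder, jplace style."""
    return {
        i: nd
        for i, nd in enumerate(
            nd for nd in tree.preorder_node_iter() if nd.parent_node is not None
        )
    }


def simulate_placements(
    tree: dendropy.Tree,
    clusters: Mapping[str, Tuple[str, float]],
    n_queries: int = 300,
    cluster_weights: Optional[Mapping[str, float]] = None,
    lwr_concentration: float = 20.0,
    contexts: Sequence[str] = ("epi", "meso", "bathy"),
    tpm_law: Optional[Mapping[str, Tuple[float, float]]] = None,
    richness_constants: Tuple[float, float] = (2.0, 0.5),
    shared_queries: bool = True,
    max_edges_per_query: int = 3,
    seed: Optional[int] = None,
) -> SimulatedPlacements:
    """Generate jplace placements, abundances, and the ground-truth k table.

    ``clusters`` maps cluster label -> (cluster-root node id, u). Each
    query draws a home cluster from ``cluster_weights`` (uniform default),
    places its LWR mass on up to ``max_edges_per_query`` edges inside that
    cluster with Dirichlet(concentration) weights (an infinite
    concentration puts all mass on one edge), and draws a lognormal TPM in
    each context (``tpm_law``: context -> (mean_log, sd_log), default
    (1.0, 1.0) everywhere). With ``shared_queries`` every query is observed
    in every context (same observed richness per layer); otherwise each
    query is observed in one random context.

    Ground-truth k uses Eq.-style bookkeeping with the supplied
    ``richness_constants`` (c, gamma): k = A * d_obs / (c * A**gamma) * u.
    """
    index = ensure_node_ids(tree)
    labels = sorted(clusters)
    if not labels:
        raise ValueError("need at least one cluster")
    for lab in labels:
        nid, u = clusters[lab]
        if nid not in index:
            raise KeyError(f"cluster root {nid!r} not in tree")
    rng = np.random.default_rng(seed)
    edge_map = _edge_numbering(tree)
    node_to_edge = {id(nd): num for num, nd in edge_map.items()}

    cluster_edges: Dict[str, List[int]] = {}
    leaf_tax: Dict[str, str] = {}
    for lab in labels:
        nid, u = clusters[lab]
        root = index[nid]
        nums = [node_to_edge[id(nd)] for nd in root.preorder_iter()]
        if not nums:
            raise ValueError(f"cluster {lab!r} has no edges")
        cluster_edges[lab] = sorted(nums)
        for lf in root.leaf_iter():
            leaf_tax[node_id(lf)] = f"Bacteria;P_{lab};S_{lab}"
    for lf in tree.leaf_node_iter():
        lid = node_id(lf)
        if lid not in leaf_tax:
            leaf_tax[lid] = f"Bacteria;P_out;S_{lid}"

    if cluster_weights is None:
        weights = np.full(len(labels), 1.0 / len(labels))
    else:
        weights = np.array([cluster_weights[lab] for lab in labels], float)
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"cluster weights must sum to 1, got {weights.sum()}")
    tpm_law = dict(tpm_law or {})
    for ctx in contexts:
        tpm_law.setdefault(ctx, (1.0, 1.0))

    placements = []
    tax_rows = []
    truth_assign = []
    ab_rows = []
    for qi in range(n_queries):
        lab = labels[int(rng.choice(len(labels), p=weights))]
        name = f"Q{qi:05d}"
        edges = cluster_edges[lab]
        if math.isinf(lwr_concentration):
            chosen = [edges[int(rng.integers(len(edges)))]]
            lwrs = np.array([1.0])
        else:
            ne = min(max_edges_per_query, len(edges))
            chosen = list(rng.choice(edges, size=ne, replace=False))
            lwrs = rng.dirichlet(np.full(ne, lwr_concentration))
        p = [
            [int(e), float(-10.0 - rng.exponential(2.0)), float(w)]
            for e, w in sorted(zip(chosen, lwrs), key=lambda t: -t[1])
        ]
        placements.append({"name": name, "p": p})
        truth_assign.append((name, lab))
        q_contexts = contexts if shared_queries else [contexts[int(rng.integers(len(contexts)))]]
        for ctx in q_contexts:
            mu, sd = tpm_law[ctx]
            ab_rows.append((name, ctx, float(rng.lognormal(mu, sd))))

    atree = AnnotatedTree(
        tree,
        cluster_map={clusters[lab][0]: (lab, clusters[lab][1]) for lab in labels},
        leaf_taxonomy=leaf_tax,
    )
    pset = PlacementSet(
        tree_text=jplace_tree_text(tree, edge_map),
        fields=list(JPLACE_FIELDS),
        placements=placements,
        version=3,
        metadata={"invocation": "guildquant.synthetic_data.simulate_placements"},
    )
    abundance = pd.DataFrame(ab_rows, columns=["query_id", "context", "tpm"])
    truth_assignments = pd.DataFrame(truth_assign, columns=["query", "cluster"])

    c, gamma = richness_constants
    model = RichnessModel(c=c, gamma=gamma, r_squared=1.0, n_points=0)
    merged = abundance.merge(truth_assignments, left_on="query_id", right_on="query")
    rows = []
    for (lab, ctx), sub in merged.groupby(["cluster", "context"]):
        a = float(sub["tpm"].sum())
        d_obs = int(sub["query_id"].nunique())
        u = clusters[lab][1]
        d_exp = expected_richness(model, a)
        rows.append(
            (
                f"Bacteria;P_{lab};S_{lab}",
                lab,
                ctx,
                a,
                d_obs,
                u,
                d_exp,
                impact_coefficient(a, d_obs, d_exp, u),
            )
        )
    truth_groups = pd.DataFrame(
        rows,
        columns=["taxon", "implementation", "context", "abundance_tpm", "d_obs", "u", "d_exp", "k"],
    )
    params = dict(
        n_queries=n_queries,
        lwr_concentration=lwr_concentration,
        contexts=list(contexts),
        tpm_law={k: list(v) for k, v in tpm_law.items()},
        richness_constants=[c, gamma],
        shared_queries=shared_queries,
        seed=seed,
        tree_law="yule_exponential",
        tpm_distribution="lognormal",
    )
    return SimulatedPlacements(
        annotated_tree=atree,
        placement_set=pset,
        abundance=abundance,
        truth_assignments=truth_assignments,
        truth_groups=truth_groups,
        richness_model=model,
        params=params,
    )


@dataclass
class MarkerTriple:
    """Two phylomarker trees plus a target tree with planted convergence."""

    marker1: dendropy.Tree
    marker2: dendropy.Tree
    target: dendropy.Tree
    organism_map: Dict[str, str]  # leaf -> organism (identical names here)
    truth_nodes: List[str]  # target-tree node ids of planted convergence pairs
    moved_pairs: List[Tuple[str, str]]
    #: Every target node containing a moved pair (the cherries and all their
    #: ancestors). A tree metric cannot shrink one pairwise distance in
    #: isolation, so planted convergence is inherited upward: flags inside
    #: this set are planted signal, flags outside it are false positives.
    affected_nodes: List[str] = field(default_factory=list)


def _jitter_tree(tree: dendropy.Tree, rate_jitter_sd: float, rng) -> dendropy.Tree:
    clone = tree.clone(depth=1)
    if rate_jitter_sd > 0:
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = float(edge.length * rng.lognormal(0.0, rate_jitter_sd))
    ensure_node_ids(clone)
    return clone


def simulate_marker_pair(
    base_tree: dendropy.Tree,
    rate_jitter_sd: float = 0.1,
    n_convergence_events: int = 0,
    seed: Optional[int] = None,
    distance_quantile: float = 0.6,
) -> MarkerTriple:
    """Marker trees = rate-jittered copies of the base; target = jittered
    copy with ``n_convergence_events`` prune-regraft moves, each taking a
    leaf far (patristic distance above ``distance_quantile``) from a second
    leaf and regrafting it as that leaf's sister with short branches. The
    new cherry nodes are the ground-truth outliers.
    """
    n = sum(1 for _ in base_tree.leaf_node_iter())
    if n < 10:
        raise ValueError(f"base tree must have >= 10 leaves, got {n}")
    rng = np.random.default_rng(seed)
    marker1 = _jitter_tree(base_tree, rate_jitter_sd, rng)
    marker2 = _jitter_tree(base_tree, rate_jitter_sd, rng)
    target = _jitter_tree(base_tree, rate_jitter_sd, rng)

    from .divergence_null import patristic_matrix  # local import avoids a cycle

    truth_nodes: List[str] = []
    moved_pairs: List[Tuple[str, str]] = []
    if n_convergence_events > 0:
        d = patristic_matrix(target, normalize=True)
        labels = list(d.index)
        thresh = np.quantile(d.to_numpy()[np.triu_indices(len(labels), k=1)], distance_quantile)
        # Regrafting a next to b perturbs every ancestor of the new cherry by
        # ~2*Delta/m (m = organisms under the ancestor): attach at leaves whose
        # ancestors grow large quickly so the planted signal stays local to
        # the cherry instead of bleeding into small ancestral nodes.
        def small_ancestors(leaf_node, cap=15):
            k = 0
            nd = leaf_node.parent_node
            while nd is not None:
                if sum(1 for _ in nd.leaf_iter()) < cap:
                    k += 1
                nd = nd.parent_node
            return k

        leaf_nodes = {nd.taxon.label: nd for nd in target.leaf_node_iter()}
        locality = {lab: small_ancestors(nd) for lab, nd in leaf_nodes.items()}
        pairs = [
            (a, b)
            for i, a in enumerate(labels)
            for b in labels[i + 1 :]
            if d.loc[a, b] > thresh
        ]
        rng.shuffle(pairs)
        # orient each pair so the regraft target (second element) is the
        # better-anchored leaf, then try best-anchored pairs first
        pairs = [
            (a, b) if locality[b] <= locality[a] else (b, a) for a, b in pairs
        ]
        pairs.sort(key=lambda ab: locality[ab[1]])
        used: set = set()
        chosen = []
        for a, b in pairs:
            if a in used or b in used:
                continue
            chosen.append((a, b))
            used.update((a, b))
            if len(chosen) == n_convergence_events:
                break
        if len(chosen) < n_convergence_events:
            raise ValueError(
                f"cannot plant {n_convergence_events} events: only {len(chosen)} "
                "disjoint distant pairs available"
            )
        mean_edge = float(
            np.mean([e.length for e in target.preorder_edge_iter() if e.length])
        )
        leaf_by_label = {
            nd.taxon.label: nd for nd in target.leaf_node_iter()
        }
        for ev, (a, b) in enumerate(chosen):
            nd_a = leaf_by_label[a]
            nd_b = leaf_by_label[b]
            # prune a
            parent = nd_a.parent_node
            parent.remove_child(nd_a)
            if parent.num_child_nodes() == 1:
                only = parent.child_nodes()[0]
                grand = parent.parent_node
                if grand is None:
                    # parent is root; promote the only child as new root
                    only.parent_node = None
                    target.seed_node = only
                    only.edge.length = None
                else:
                    extra = parent.edge.length or 0.0
                    grand.remove_child(parent)
                    grand.add_child(only)
                    only.edge.length = (only.edge.length or 0.0) + extra
            # regraft as sister of b
            b_parent = nd_b.parent_node
            b_len = nd_b.edge.length or 0.0
            cherry = dendropy.Node()
            b_parent.remove_child(nd_b)
            b_parent.add_child(cherry)
            cherry.edge.length = max(b_len - 0.05 * mean_edge, 0.5 * b_len)
            short = max(b_len - cherry.edge.length, 0.05 * mean_edge)
            cherry.add_child(nd_b)
            nd_b.edge.length = short
            cherry.add_child(nd_a)
            nd_a.edge.length = short
            cherry.label = f"conv{ev}"
            truth_nodes.append(cherry.label)
            moved_pairs.append((a, b))
        ensure_node_ids(target)
    organism_map = {nd.taxon.label: nd.taxon.label for nd in base_tree.leaf_node_iter()}
    affected: List[str] = []
    index = ensure_node_ids(target)
    for label in truth_nodes:
        nd = index[label]
        while nd is not None:
            if node_id(nd) not in affected:
                affected.append(node_id(nd))
            nd = nd.parent_node
    return MarkerTriple(
        marker1=marker1,
        marker2=marker2,
        target=target,
        organism_map=organism_map,
        truth_nodes=truth_nodes,
        moved_pairs=moved_pairs,
        affected_nodes=affected,
    )
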