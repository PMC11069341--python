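"""Taxonomy-based null model for functional-gene divergence.

Whether a functional gene diverges as its carriers' phylogeny predicts is
tested by comparing, for the groups of organisms under each internal node
of the target gene tree, mean normalized patristic distances in two
phylomarker trees (e.g. 16S rRNA and rplB) and in the target tree. The two
phylomarkers track organismal phylogeny and fall on a straight line; the
line plus a +-3 sigma residual band (bivariate OLS of marker 2 on marker 1)
is the null envelope. Target-tree nodes falling outside the band mark
convergence (below) or excess divergence (above) not explained by taxonomy.

Distances are normalized by each tree's diameter (maximum pairwise
patristic distance), bounding them to [0, 1] and making every statistic
invariant to a global rescaling of branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Mapping, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from ._trees import ensure_node_ids, node_id

__all__ = [
    "NullEnvelope",
    "patristic_matrix",
    "node_group_distances",
    "fit_null",
    "flag_divergent",
    "read_organism_map",
]

POINT_COLUMNS = (
    "node_id",
    "n_organisms",
    "dist_marker1",
    "dist_marker2",
    "dist_target",
)


@dataclass(frozen=True)
class NullEnvelope:
    """OLS line of marker2 on marker1 with residual standard deviation."""

    slope: float
    intercept: float
    sigma: float
    n_points: int

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def predict(self, x):
        return self.slope * np.asarray(x, float) + self.intercept


def patristic_matrix(tree: dendropy.Tree, normalize: bool = False) -> pd.DataFrame:
    """All leaf-to-leaf path-length distances, optionally diameter-normalized."""
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length: {edge.length}")
    pdm = tree.phylogenetic_distance_matrix()
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    labels = [lf.taxon.label for lf in leaves]
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
    if normalize:
        diam = d.max()
        if diam > 0:
            d = d / diam
    return pd.DataFrame(d, index=labels, columns=labels)


def read_organism_map(path) -> Dict[str, Dict[str, str]]:
    """TSV (leaf_id, tree_id, organism) -> {tree_id: {leaf_id: organism}}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: Dict[str, Dict[str, str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.tree_id, {})[row.leaf_id] = row.organism
    return out


def _organism_distance(tree, org_map, multi_copy: str) -> pd.DataFrame:
    """Collapse a normalized leaf distance matrix to organism level.

    Organisms with several leaves (paralogs / multiple gene copies) are
    summarized by the minimum leaf-pair distance by default — the most
    convergent copy — or by the mean.
    """
    if multi_copy not in ("min", "mean"):
        raise ValueError(f"multi_copy must be 'min' or 'mean', got {multi_copy!r}")
    d = patristic_matrix(tree, normalize=True)
    members: Dict[str, list] = {}
    for leaf in d.index:
        org = org_map.get(leaf)
        if org is not None:
            members.setdefault(org, []).append(leaf)
    orgs = sorted(members)
    n = len(orgs)
    out = np.zeros((n, n))
    arr = d.to_numpy()
    pos = {leaf: i for i, leaf in enumerate(d.index)}
    for i, j in combinations(range(n), 2):
        li = [pos[x] for x in members[orgs[i]]]
        lj = [pos[x] for x in members[orgs[j]]]
        block = arr[np.ix_(li, lj)]
        val = block.min() if multi_copy == "min" else block.mean()
        out[i, j] = out[j, i] = val
    return pd.DataFrame(out, index=orgs, columns=orgs)


def node_group_distances(
    target_tree: dendropy.Tree,
    marker_trees: Tuple[dendropy.Tree, dendropy.Tree],
    organism_map,
    multi_copy: str = "min",
    min_organisms: int = 2,
) -> pd.DataFrame:
    """Per internal node of the target tree, mean pairwise normalized
    patristic distance among its organisms in each marker and in the target.

    ``organism_map`` is either a single leaf -> organism mapping applied to
    all three trees, or a dict with keys ``target``, ``marker1``,
    ``marker2``. Only organisms present in all three trees enter; nodes
    with fewer than ``min_organisms`` mapped organisms are skipped.
    """
    marker1, marker2 = marker_trees
    if isinstance(organism_map, Mapping) and {"target", "marker1", "marker2"} <= set(
        organism_map
    ):
        maps = organism_map
    else:
        maps = {"target": organism_map, "marker1": organism_map, "marker2": organism_map}

    od_t = _organism_distance(target_tree, maps["target"], multi_copy)
    od_1 = _organism_distance(marker1, maps["marker1"], multi_copy)
    od_2 = _organism_distance(marker2, maps["marker2"], multi_copy)
    common = sorted(set(od_t.index) & set(od_1.index) & set(od_2.index))
    if len(common) < 2:
        raise ValueError("fewer than 2 organisms shared by the three trees")
    a_t = od_t.loc[common, common].to_numpy()
    a_1 = od_1.loc[common, common].to_numpy()
    a_2 = od_2.loc[common, common].to_numpy()
    pos = {o: i for i, o in enumerate(common)}
    tmap = maps["target"]

    ensure_node_ids(target_tree)
    rows = []
    for nd in target_tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        orgs = sorted(
            {
                tmap[node_id(lf)]
                for lf in nd.leaf_iter()
                if tmap.get(node_id(lf)) in pos
            }
        )
        if len(orgs) < min_organisms:
            continue
        idx = np.array([pos[o] for o in orgs])
        iu = np.triu_indices(len(idx), k=1)
        rows.append(
            (
                node_id(nd),
                len(orgs),
                float(a_1[np.ix_(idx, idx)][iu].mean()),
                float(a_2[np.ix_(idx, idx)][iu].mean()),
                float(a_t[np.ix_(idx, idx)][iu].mean()),
            )
        )
    return pd.DataFrame(rows, columns=list(POINT_COLUMNS))


def fit_null(points: pd.DataFrame) -> NullEnvelope:
    """Bivariate OLS of dist_marker2 on dist_marker1; sigma = residual SD (ddof 2)."""
    x = points["dist_marker1"].to_numpy(float)
    y = points["dist_marker2"].to_numpy(float)
    if np.unique(x).size < 3:
        raise ValueError(
            f"need >= 3 points with distinct marker1 distances, got {np.unique(x).size}"
        )
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    sigma = float(np.sqrt((resid**2).sum() / (x.size - 2)))
    return NullEnvelope(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        sigma=sigma,
        n_points=int(x.size),
    )


def flag_divergent(
    points: pd.DataFrame,
    envelope: NullEnvelope,
    n_sigma: float = 3.0,
    zero_sigma_tol: float = 1e-12,
) -> pd.DataFrame:
    """Flag target points outside the +-n_sigma band around the null line.

    Two-sided: convergence (target distance below the line) and excess
    divergence (above) both count. A degenerate envelope (sigma = 0) flags
    any nonzero residual.
    """
    out = points.copy()
    resid = out["dist_target"].to_numpy(float) - envelope.predict(
        out["dist_marker1"].to_numpy(float)
    )
    out["residual"] = resid
    if envelope.sigma > 0:
        out["outlier"] = np.abs(resid) > n_sigma * envelope.sigma
    else:
        out["outlier"] = np.abs(resid) > zero_sigma_tol
    return out
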