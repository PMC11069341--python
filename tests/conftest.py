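import dendropy
import numpy as np
import pandas as pd
import pytest

from guildquant import synthetic_data as syn
from guildquant._trees import leaf_ids_under, node_id


@pytest.fixture
def balanced8():
    """Fixed 8-leaf balanced tree with labeled internal nodes."""
    newick = (
        "(((a:1,b:1)n3:1,(c:1,d:1)n4:1)n1:1,"
        "((e:1,f:1)n5:1,(g:1,h:1)n6:1)n2:1)n0;"
    )
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


@pytest.fixture
def yule64():
    return syn.simulate_tree(64, seed=42)


def pick_clade(tree, lo, hi, skip=0):
    """First internal non-root node subtending between lo and hi leaves."""
    found = 0
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        n = len(leaf_ids_under(nd))
        if lo <= n <= hi:
            if found == skip:
                return node_id(nd)
            found += 1
    raise AssertionError("no clade of requested size")


def disjoint_clades(tree, lo, hi, count):
    """node ids of `count` disjoint internal clades of size in [lo, hi]."""
    taken = set()
    out = []
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        ls = leaf_ids_under(nd)
        if lo <= len(ls) <= hi and not (ls & taken):
            out.append(node_id(nd))
            taken |= ls
        if len(out) == count:
            return out
    raise AssertionError(f"only {len(out)} disjoint clades of size [{lo},{hi}]")
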