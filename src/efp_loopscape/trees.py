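"""Phylogenetic tree handling: Newick I/O, midpoint rooting, ultrametric leveling.

Trees are represented as :class:`dendropy.Tree` objects throughout the package.
All trees carried between stages are rooted and have branch lengths; the helpers
here enforce those contracts and implement the two transformations the ancestral
reconstruction expects — midpoint rooting and conversion to an ultrametric tree
by top-down proportional leveling.
"""

from __future__ import annotations

import dendropy

__all__ = [
    "parse_newick",
    "serialize_newick",
    "read_newick",
    "write_newick",
    "midpoint_root",
    "make_ultrametric",
    "rescale_to_height",
    "leaf_depths",
    "tree_height",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or duplicate leaf labels."""


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted dendropy tree.

    Internal node labels (e.g. bootstrap supports) are preserved on
    ``node.label``; leaf labels must be unique.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickError(f"duplicate leaf labels: {dupes}")
    tree.is_rooted = True
    return tree


def serialize_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a single-line Newick string with branch lengths."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(serialize_newick(tree))


def _require_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has a branch without a length")


def _longest_leaf_path(tree):
    """(length, leafA, leafB) of the longest leaf-to-leaf path; among equal
    longest paths the lexicographically smallest (leafA, leafB) pair wins."""
    best_down = {}
    best = None  # (-length, leafA, leafB)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            best_down[id(node)] = (0.0, node.taxon.label)
            continue
        entries = []
        for child in node.child_nodes():
            d, leaf = best_down[id(child)]
            entries.append((d + (child.edge.length or 0.0), leaf))
        entries.sort(key=lambda e: (-e[0], e[1]))
        best_down[id(node)] = entries[0]
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                length = entries[i][0] + entries[j][0]
                pair = tuple(sorted((entries[i][1], entries[j][1])))
                cand = (-length, pair[0], pair[1])
                if best is None or cand < best:
                    best = cand
    return -best[0], best[1], best[2]


def _path_between(tree, label_a, label_b):
    """Node path [a, ..., b] and the edge lengths between consecutive nodes."""
    nodes = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    a, b = nodes[label_a], nodes[label_b]
    anc_a = []
    node = a
    while node is not None:
        anc_a.append(node)
        node = node.parent_node
    seen = {id(n): i for i, n in enumerate(anc_a)}
    path_b = []
    node = b
    while id(node) not in seen:
        path_b.append(node)
        node = node.parent_node
    lca_index = seen[id(node)]
    path = anc_a[: lca_index + 1] + list(reversed(path_b))
    lengths = []
    for u, v in zip(path, path[1:]):
        child = v if v.parent_node is u else u
        lengths.append(float(child.edge.length or 0.0))
    return path, lengths


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    Returns a new tree; the input is not modified. The two edges incident to
    the new root sum to the length of the edge the midpoint falls on, and all
    pairwise leaf path lengths are preserved. Among equally long paths the
    lexicographically smallest leaf pair is chosen; a midpoint falling
    exactly on an existing node makes that node the root.
    """
    if sum(1 for _ in tree.leaf_node_iter()) < 2:
        raise ValueError("midpoint rooting requires at least 2 leaves")
    work = tree.clone(depth=1)
    _require_branch_lengths(work)
    work.is_rooted = True

    total, leaf_a, leaf_b = _longest_leaf_path(work)
    path, lengths = _path_between(work, leaf_a, leaf_b)
    half = total / 2.0

    cum = 0.0
    for i, seg in enumerate(lengths):
        if cum + seg >= half - 1e-12:
            u, v = path[i], path[i + 1]
            into = half - cum  # distance walked into this edge from u
            break
        cum += seg
    else:  # numerical slack: midpoint at the far end
        u, v = path[-2], path[-1]
        into = lengths[-1]

    child = v if v.parent_node is u else u
    x_from_child = into if child is u else lengths[i] - into
    eps = 1e-12
    if x_from_child <= eps:
        new_root = child
    elif x_from_child >= lengths[i] - eps:
        new_root = child.parent_node
    else:
        parent = child.parent_node
        length = float(child.edge.length)
        parent.remove_child(child)
        mid = dendropy.Node()
        parent.add_child(mid)
        mid.edge.length = length - x_from_child
        mid.add_child(child)
        child.edge.length = x_from_child
        new_root = mid
    if new_root is not work.seed_node:
        work.reroot_at_node(new_root, update_bipartitions=False)
    work.suppress_unifurcations()
    return work


def leaf_depths(tree: dendropy.Tree) -> dict:
    """Root-to-leaf path length for every leaf, keyed by leaf label."""
    depths = {}
    for node in tree.preorder_node_iter():
        parent_depth = 0.0 if node.parent_node is None else node.parent_node._depth_tmp
        node._depth_tmp = parent_depth + (node.edge.length or 0.0)
        if node.is_leaf():
            depths[node.taxon.label] = node._depth_tmp
    for node in tree.preorder_node_iter():
        del node._depth_tmp
    return depths


def tree_height(tree: dendropy.Tree) -> float:
    d = leaf_depths(tree)
    return max(d.values()) if d else 0.0


def rescale_to_height(tree: dendropy.Tree, height: float = 1.0) -> dendropy.Tree:
    """Return a copy with all branch lengths scaled so the max depth is ``height``."""
    out = tree.clone(depth=1)
    h = tree_height(out)
    if h <= 0:
        raise ValueError("tree has zero height")
    factor = height / h
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return out


def make_ultrametric(tree: dendropy.Tree) -> dendropy.Tree:
    """Level all root-to-leaf depths to the input tree's maximum depth.

    Topology is unchanged. Each child subtree is rescaled proportionally
    (top-down): for a node with ``allotted`` remaining depth, every child path
    of current total length p is stretched by ``allotted / p``. Subtrees of
    total length zero receive the full allotment on the child edge.
    """
    if tree.seed_node is None or not tree.is_rooted:
        raise ValueError("ultrametric conversion requires a rooted tree")
    out = tree.clone(depth=1)
    _require_branch_lengths(out)

    # max depth below each node, in current branch lengths
    below = {}
    for node in out.postorder_node_iter():
        if node.is_leaf():
            below[node] = 0.0
        else:
            below[node] = max(
                (c.edge.length or 0.0) + below[c] for c in node.child_nodes()
            )

    target = below[out.seed_node]

    def level(node, allotted: float) -> None:
        for child in node.child_nodes():
            path = (child.edge.length or 0.0) + below[child]
            if path <= 0.0:
                child.edge.length = allotted if child.is_leaf() else 0.0
                level(child, allotted)
            else:
                scale = allotted / path
                child.edge.length = (child.edge.length or 0.0) * scale
                level(child, allotted - child.edge.length)

    level(out.seed_node, target)
    return out
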