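"""Newick tree I/O for UniFrac computations (thin wrapper over scikit-bio)."""

from __future__ import annotations

import io
import warnings

from skbio import TreeNode

__all__ = ["read_tree", "read_tree_string", "write_tree", "total_branch_length",
           "check_tips"]


def _clean(tree: TreeNode) -> TreeNode:
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValueError(f"negative branch length on node {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        warnings.warn(f"{n_missing} branch(es) without length treated as 0", UserWarning)
    return tree


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree; missing branch lengths become 0 (with warning)."""
    tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    return _clean(tree)


def read_tree_string(newick: str) -> TreeNode:
    tree = TreeNode.read(io.StringIO(newick), format="newick", convert_underscores=False)
    return _clean(tree)


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def total_branch_length(tree: TreeNode) -> float:
    return sum(n.length or 0.0 for n in tree.traverse(include_self=False))


def check_tips(tree: TreeNode, otu_ids) -> list:
    """Return tree tips not present among ``otu_ids`` (warning listed orphans)."""
    tips = {t.name for t in tree.tips()}
    orphans = sorted(tips - set(otu_ids))
    if orphans:
        warnings.warn(f"tree tips not matching any OTU: {orphans[:10]}", UserWarning)
    return orphans
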