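"""Thin newick/tree layer over dendropy.

All pipeline stages (simulation, parsimony, footprinting, NJ) operate on
``dendropy.Tree`` objects; this module owns parsing, serialization and the
deterministic internal-node labelling shared by ancestral reconstruction and
codon simulation.
"""

from __future__ import annotations

import logging

import dendropy

logger = logging.getLogger("globinevo")


def _check_parens(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced parentheses at character {i}")
    if depth != 0:
        raise ValueError(f"unbalanced parentheses at character {len(text)} (end of input)")


def read_newick(source) -> dendropy.Tree:
    """Read a single newick tree from a path or a newick string.

    Leaf names must be unique; missing branch lengths are set to 0 with a
    warning.
    """
    if isinstance(source, str) and ";" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    _check_parens(text)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "Duplicate" in msg or "duplicate" in msg:
            raise ValueError(f"duplicate leaf in newick input: {msg}") from exc
        raise ValueError(f"newick parse error: {msg}") from exc
    names = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leaf {dupes[0]!r}")
    missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            missing += 1
    if missing:
        logger.warning("%d branch(es) without length set to 0", missing)
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def node_name(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "anc") -> dendropy.Tree:
    """Give unlabelled internal nodes deterministic names anc1, anc2, ... (preorder)."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            i += 1
            node.label = f"{prefix}{i}"
    return tree
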