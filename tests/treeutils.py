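"""Random-topology helpers and the bipartition-enumeration monophyly oracle
shared by the tree tests (kept independent of the package's tree code)."""

from __future__ import annotations


def random_topology(rng, leaves):
    """Random binary tree as nested tuples over leaf labels."""
    nodes = list(leaves)
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        nodes.append((a, b))
    return nodes[0]


def to_newick(node):
    if isinstance(node, str):
        return node
    return f"({to_newick(node[0])},{to_newick(node[1])})"


def _clades(node, out):
    if isinstance(node, str):
        out.append(frozenset([node]))
        return frozenset([node])
    clade = _clades(node[0], out) | _clades(node[1], out)
    out.append(clade)
    return clade


def oracle_monophyletic(topology, leaves, taxa):
    """Exhaustive bipartition enumeration: taxa form one side of some split."""
    clades: list[frozenset] = []
    _clades(topology, clades)
    splits = set(clades) | {frozenset(leaves) - c for c in clades}
    return frozenset(taxa) in splits
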