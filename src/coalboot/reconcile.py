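"""Minimum deep coalescences of a gene tree fitted to a species tree.

The statistic is Maddison's (1997) minimum number of extra lineages: the
smallest number of gene lineages, summed over species-tree branches, that
fail to coalesce within the branch on which their species coexist,
minimized over all embeddings of the gene tree into the species tree.

Two implementations are provided.  :func:`count_deep_coalescences` uses
the per-edge cluster formula: for the species cluster ``C`` below each
species-tree edge, let ``k(C)`` be the number of maximal gene-tree clades
whose tip sets map entirely into ``C``; the count is the sum over edges
of ``max(0, k(C) - 1)``.  Tip edges are included, so multiple alleles of
one species contribute extra lineages.  :func:`brute_force_deep_coalescences`
minimizes over an exhaustive enumeration of embeddings and serves as an
independent oracle on small instances.

Gene trees may be this package's simulated :class:`~coalboot.coalsim.GeneTree`
objects or any rooted ``dendropy.Tree`` (e.g. read from newick consensus
trees); polytomies are handled as given, without resolution.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from coalboot.coalsim import GeneTree

__all__ = [
    "SpeciesTree",
    "count_deep_coalescences",
    "brute_force_deep_coalescences",
    "read_gene_trees",
    "read_taxon_map",
    "root_with_outgroup",
]


class SpeciesTree:
    """Rooted species-tree topology over deme names; branch lengths ignored.

    Construct from a newick string (``SpeciesTree("((A,B),C);")``), a
    ``dendropy.Tree``, or nested tuples of names.  May be nonbinary.
    """

    def __init__(self, source):
        if isinstance(source, SpeciesTree):
            nested = source.to_nested()
        elif isinstance(source, dendropy.Tree):
            nested = _dendropy_to_nested(source)
        elif isinstance(source, str):
            tree = dendropy.Tree.get(
                data=source, schema="newick", preserve_underscores=True
            )
            nested = _dendropy_to_nested(tree)
        else:
            nested = source
        self._nested = nested
        # flatten to postorder arrays
        children: list[tuple[int, ...]] = []
        names: list[str | None] = []

        def build(node) -> int:
            if isinstance(node, str):
                children.append(())
                names.append(node)
            else:
                kids = tuple(build(c) for c in node)
                children.append(kids)
                names.append(None)
            return len(children) - 1

        self.root = build(nested)
        self.children = children
        self.names = names
        self.parent = [-1] * len(children)
        for i, kids in enumerate(children):
            for c in kids:
                self.parent[c] = i
        self.leaf_names = [n for n in names if n is not None]
        if len(self.leaf_names) < 2:
            raise ValueError("species tree needs at least 2 leaves")
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ValueError("species tree leaves must be distinct demes")
        # bit index per species; cluster masks per node
        self.bit = {name: i for i, name in enumerate(sorted(self.leaf_names))}
        self.cluster_mask = [0] * len(children)
        for i in range(len(children)):  # children precede parents? build() is postorder
            if not children[i]:
                self.cluster_mask[i] = 1 << self.bit[names[i]]
        for i in range(len(children)):
            for c in children[i]:
                self.cluster_mask[i] |= self.cluster_mask[c]

    def to_nested(self):
        return self._nested

    def to_newick(self) -> str:
        def render(node) -> str:
            if isinstance(node, str):
                return node
            return "(" + ",".join(render(c) for c in node) + ")"

        return render(self._nested) + ";"

    def clusters(self) -> list[frozenset[str]]:
        """Species clusters below each non-root edge (tip edges included)."""
        inv = {i: name for name, i in self.bit.items()}
        out = []
        for node in range(len(self.children)):
            if node == self.root:
                continue
            mask = self.cluster_mask[node]
            out.append(frozenset(inv[b] for b in range(len(inv)) if mask >> b & 1))
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpeciesTree):
            return NotImplemented
        return _canonical(self._nested) == _canonical(other._nested)

    def __hash__(self) -> int:
        return hash(_canonical(self._nested))

    def __repr__(self) -> str:
        return f"SpeciesTree({self.to_newick()!r})"


def _canonical(nested):
    if isinstance(nested, str):
        return nested
    return tuple(sorted(_canonical(c) for c in nested))


def _dendropy_to_nested(tree: dendropy.Tree):
    def conv(node):
        if node.is_leaf():
            if node.taxon is None or node.taxon.label is None:
                raise ValueError("species tree leaf without a label")
            return node.taxon.label
        return tuple(conv(c) for c in node.child_nodes())

    return conv(tree.seed_node)


# ---------------------------------------------------------------------------
# gene-tree normalization

def _gene_tree_arrays(gene_tree, taxon_map: Mapping[str, str] | None):
    """Return (children, parent, tip_deme_per_node) for either tree type."""
    if isinstance(gene_tree, GeneTree):
        children = gene_tree.children
        parent = gene_tree.parent_array()
        if taxon_map is None:
            demes = gene_tree.tip_demes
        else:
            demes = [
                _resolve(taxon_map, lab) if not kids else None
                for lab, kids in zip(gene_tree.labels, children)
            ]
        return children, parent, demes
    if isinstance(gene_tree, dendropy.Tree):
        nodes = list(gene_tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        children = [
            tuple(index[id(c)] for c in n.child_nodes()) for n in nodes
        ]
        parent = [-1] * len(nodes)
        for i, kids in enumerate(children):
            for c in kids:
                parent[c] = i
        demes: list[str | None] = []
        for n in nodes:
            if n.is_leaf():
                label = n.taxon.label if n.taxon is not None else None
                if label is None:
                    raise ValueError("gene tree tip without a label")
                demes.append(_resolve(taxon_map, label))
            else:
                demes.append(None)
        return children, parent, demes
    raise TypeError(f"unsupported gene tree type: {type(gene_tree)!r}")


def _resolve(taxon_map: Mapping[str, str] | None, label: str) -> str:
    if taxon_map is not None:
        try:
            return taxon_map[label]
        except KeyError:
            raise KeyError(f"gene-tree tip {label!r} missing from taxon map") from None
    # default convention: tips labeled "deme|allele"
    return label.split("|", 1)[0]


# ---------------------------------------------------------------------------
# fast per-edge cluster count

def count_deep_coalescences(
    gene_tree,
    species_tree: SpeciesTree,
    taxon_map: Mapping[str, str] | None = None,
) -> int:
    """Minimum number of deep coalescences of one gene tree on one species tree.

    For every species-tree edge with species cluster ``C``, counts the
    maximal gene-tree clades whose tips all map into ``C`` and adds
    ``max(0, k(C) - 1)``.  Gene trees may have multiple alleles per
    species, missing species, and polytomies (treated as hard).
    """
    if not isinstance(species_tree, SpeciesTree):
        species_tree = SpeciesTree(species_tree)
    children, parent, demes = _gene_tree_arrays(gene_tree, taxon_map)
    n = len(children)
    masks = np.zeros(n + 1, dtype=np.int64)
    bit = species_tree.bit
    for i in range(n):  # postorder: children precede parents
        kids = children[i]
        if not kids:
            deme = demes[i]
            if deme not in bit:
                raise ValueError(
                    f"gene-tree tip maps to deme {deme!r} absent from the species tree"
                )
            masks[i] = 1 << bit[deme]
        else:
            m = 0
            for c in kids:
                m |= masks[c]
            masks[i] = m
    parent_arr = np.asarray(parent, dtype=np.int64)
    parent_arr[parent_arr < 0] = n  # virtual parent slot, never "inside"
    node_masks = masks[:n]

    total = 0
    for node in range(len(species_tree.children)):
        if node == species_tree.root:
            continue
        c = species_tree.cluster_mask[node]
        inside = np.empty(n + 1, dtype=bool)
        inside[:n] = (node_masks & ~c) == 0
        inside[n] = False
        k = int(np.count_nonzero(inside[:n] & ~inside[parent_arr]))
        if k > 1:
            total += k - 1
    return total


# ---------------------------------------------------------------------------
# brute-force oracle

def brute_force_deep_coalescences(
    gene_tree,
    species_tree: SpeciesTree,
    taxon_map: Mapping[str, str] | None = None,
    max_tips: int = 8,
) -> int:
    """Minimize extra lineages over exhaustive enumeration of embeddings.

    Every gene-tree coalescence is assigned to a species-tree node at or
    above the species-MRCA of its descendant tips, consistently with its
    parent's assignment; for each assignment the lineages crossing every
    species edge are counted and ``sum(max(0, crossing - 1))`` taken; the
    minimum over assignments is returned.  Only for small instances
    (``<= max_tips`` gene tips); exponential time.
    """
    if not isinstance(species_tree, SpeciesTree):
        species_tree = SpeciesTree(species_tree)
    children, parent, demes = _gene_tree_arrays(gene_tree, taxon_map)
    n = len(children)
    n_tips = sum(1 for k in children if not k)
    if n_tips > max_tips:
        raise ValueError(f"instance too large for brute force ({n_tips} tips)")

    sp_parent = species_tree.parent
    sp_n = len(species_tree.children)
    leaf_node = {
        species_tree.names[i]: i
        for i in range(sp_n)
        if species_tree.names[i] is not None
    }

    depth = [0] * sp_n
    for i in range(sp_n):
        d = 0
        j = sp_parent[i]
        while j != -1:
            d += 1
            j = sp_parent[j]
        depth[i] = d

    def sp_lca(a: int, b: int) -> int:
        while a != b:
            if depth[a] >= depth[b]:
                a = sp_parent[a]
            else:
                b = sp_parent[b]
        return a

    # gene-node order: postorder indices of internal nodes
    internal = [i for i in range(n) if children[i]]
    assign = [0] * n  # species node per gene node
    for i in range(n):
        if not children[i]:
            deme = demes[i]
            if deme not in leaf_node:
                raise ValueError(
                    f"gene-tree tip maps to deme {deme!r} absent from the species tree"
                )
            assign[i] = leaf_node[deme]

    def cost_of(assign: Sequence[int]) -> int:
        crossing = [0] * sp_n
        for u in range(n):
            p = parent[u]
            top = assign[p] if p != -1 else -1  # root lineage runs to species root
            w = assign[u]
            while w != top:
                crossing[w] += 1
                w = sp_parent[w]
        return sum(c - 1 for c in crossing if c > 1)

    best_val = np.inf

    # internal nodes in postorder, so children are always assigned first;
    # the candidate walk from the children's species-LCA to the root makes
    # every partial assignment ancestor-consistent by construction
    def recurse2(idx: int) -> None:
        nonlocal best_val
        if idx == len(internal):
            best_val = min(best_val, cost_of(assign))
            return
        v = internal[idx]
        lca = assign[children[v][0]]
        for c in children[v][1:]:
            lca = sp_lca(lca, assign[c])
        w = lca
        while True:
            assign[v] = w
            recurse2(idx + 1)
            if sp_parent[w] == -1:
                break
            w = sp_parent[w]

    recurse2(0)
    return int(best_val)


# ---------------------------------------------------------------------------
# I/O helpers

def read_gene_trees(path: str | Path) -> list[dendropy.Tree]:
    """Read one or more rooted newick trees (one per line or concatenated)."""
    trees = dendropy.TreeList.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    if not trees:
        raise ValueError(f"no trees found in {path}")
    for t in trees:
        t.is_rooted = True
    return list(trees)


def read_taxon_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``tip_label<TAB>deme``; duplicate tips error."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        tip, deme = parts
        if tip in mapping:
            raise ValueError(f"{path}:{lineno}: duplicate tip label {tip!r}")
        mapping[tip] = deme
    if not mapping:
        raise ValueError(f"empty taxon map: {path}")
    return mapping


def root_with_outgroup(tree: dendropy.Tree, outgroup: Iterable[str]) -> dendropy.Tree:
    """Root a tree on the edge separating the outgroup tips from the rest.

    The outgroup must be separable: after rerooting, the outgroup tips
    must form a clade (for a single tip this is always possible).
    """
    tree = tree.clone(depth=1)
    outgroup = list(outgroup)
    if not outgroup:
        raise ValueError("outgroup must contain at least one tip label")
    labels = {t.label for t in tree.taxon_namespace}
    missing = [o for o in outgroup if o not in labels]
    if missing:
        raise ValueError(f"outgroup tips not in tree: {missing}")
    taxa = [t for t in tree.taxon_namespace if t.label in set(outgroup)]
    if len(taxa) == 1:
        node = tree.find_node_with_taxon_label(taxa[0].label)
    else:
        tree.is_rooted = False
        tree.update_bipartitions(suppress_unifurcations=True)
        node = tree.mrca(taxa=taxa)
        if node is None or node is tree.seed_node:
            # try the complement: outgroup may surround the current root
            ingroup = [t for t in tree.taxon_namespace if t.label not in set(outgroup)]
            node = tree.mrca(taxa=ingroup)
            if node is None or node is tree.seed_node:
                raise ValueError("outgroup is not separable from the ingroup")
    tree.is_rooted = True
    edge = node.edge
    if edge.length is not None:
        tree.reroot_at_edge(edge, length1=edge.length / 2.0, length2=edge.length / 2.0)
    else:
        tree.reroot_at_edge(edge)
    tree.update_bipartitions(suppress_unifurcations=True)
    # verify separation
    out_set = set(outgroup)
    for child in tree.seed_node.child_nodes():
        tip_labels = {lf.taxon.label for lf in child.leaf_iter()}
        if tip_labels == out_set:
            return tree
    if len(outgroup) == 1:
        return tree
    raise ValueError("outgroup is not monophyletic after rooting")
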