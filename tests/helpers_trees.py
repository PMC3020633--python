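"""Shared test helpers: exhaustive and random gene-tree instance generators.

Gene trees are represented as nested tuples of species labels (leaves may
repeat: multiple alleles).  Enumeration is over distinct species-labeled
shapes, i.e. up to permutations of same-species tips and child order, so
the exhaustive checks cover every distinct reconciliation instance once.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from coalboot.coalsim import GeneTree


def nested_to_genetree(nested) -> GeneTree:
    """Build a (topology-only) GeneTree from nested species-label tuples."""
    children: list[tuple[int, ...]] = []
    times: list[float] = []
    labels: list[str | None] = []
    demes: list[str | None] = []
    counter: dict[str, int] = {}

    def rec(node) -> int:
        if isinstance(node, str):
            counter[node] = counter.get(node, 0) + 1
            children.append(())
            times.append(0.0)
            labels.append(f"{node}|{counter[node]}")
            demes.append(node)
        else:
            kids = tuple(rec(c) for c in node)
            children.append(kids)
            times.append(float(len(children)))
            labels.append(None)
            demes.append(None)
        return len(children) - 1

    root = rec(nested)
    return GeneTree(children, times, labels, demes, root)


@lru_cache(maxsize=None)
def enum_trees(multiset: tuple[str, ...]) -> frozenset:
    """All distinct rooted binary trees whose leaves carry ``multiset``."""
    if len(multiset) == 1:
        return frozenset({multiset[0]})
    out = set()
    n = len(multiset)
    seen_splits = set()
    for r in range(1, n // 2 + 1):
        for left_idx in itertools.combinations(range(n), r):
            left_set = set(left_idx)
            left = tuple(sorted(multiset[i] for i in left_idx))
            right = tuple(sorted(multiset[i] for i in range(n) if i not in left_set))
            key = (left, right) if (len(left), left) <= (len(right), right) else (right, left)
            if key in seen_splits:
                continue
            seen_splits.add(key)
            for lt in enum_trees(key[0]):
                for rt in enum_trees(key[1]):
                    out.add(tuple(sorted((lt, rt), key=repr)))
    return frozenset(out)


def all_multisets(species: tuple[str, ...], total: int):
    """All leaf multisets of size ``total`` over ``species`` (zeros allowed)."""
    for combo in itertools.combinations_with_replacement(species, total):
        yield combo


def species_trees_over(species: tuple[str, ...]):
    """All rooted species-tree shapes over a small species set (incl. star)."""
    if len(species) == 2:
        return [tuple(species)]
    if len(species) == 3:
        a, b, c = species
        return [((a, b), c), ((a, c), b), ((b, c), a), (a, b, c)]
    raise ValueError("only 2 or 3 species supported here")


def random_instance(rng: np.random.Generator, n_tips: int, species: tuple[str, ...]):
    """One random binary gene tree (nested tuples) + random binary species tree."""
    tips = [str(rng.choice(species)) for _ in range(n_tips)]
    nodes: list = list(tips)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    sp_nodes: list = list(species)
    while len(sp_nodes) > 1:
        i, j = sorted(rng.choice(len(sp_nodes), size=2, replace=False))
        b = sp_nodes.pop(j)
        a = sp_nodes.pop(i)
        sp_nodes.append((a, b))
    return nodes[0], sp_nodes[0]
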