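"""Pseudo-observed datasets: simulated stand-ins for the empirical input.

The observed input to the analysis is a set of per-locus rooted gene
trees (newick) plus a tip-label-to-lineage map (TSV).  This module
generates datasets in exactly that format by simulating one multi-locus
replicate under a chosen demographic model, so the whole pipeline can be
exercised, and parameter-recovery experiments run, without any external
sequence data.  Files written here are synthetic by construction and say
so in their manifest.

:func:`degrade_to_consensus` additionally mimics the loss of resolution
of consensus trees by collapsing a fraction of the shortest internal
branches into polytomies.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

import coalboot
from coalboot.coalsim import GeneTree, RandomSource, simulate_replicate
from coalboot.demography import (
    DemographicModel,
    SamplingScheme,
    get_model,
    limenitis_sampling,
    model_to_dict,
    to_coalescent_scale,
)

__all__ = ["PseudoObservedSet", "generate_pseudo_observed", "degrade_to_consensus"]


@dataclass
class PseudoObservedSet:
    """One simulated multi-locus dataset on disk, regenerable from its seed."""

    model_id: str
    seed: int
    tree_paths: dict[str, Path]
    taxon_map_path: Path
    manifest_path: Path
    trees: list[GeneTree]

    @property
    def loci(self) -> list[str]:
        return list(self.tree_paths)


def generate_pseudo_observed(
    model: str | DemographicModel,
    sampling: SamplingScheme | None = None,
    seed: int = 0,
    out_dir: str | Path = ".",
) -> PseudoObservedSet:
    """Simulate one replicate under ``model`` and write it as observed-format input.

    Writes one newick file per locus (tips ``deme|allele``), a two-column
    taxon map TSV, and a JSON manifest recording the generating model,
    seed, and a parameter hash.  Identical arguments produce bitwise
    identical files.
    """
    if isinstance(model, str):
        model = get_model(model)
    if sampling is None:
        sampling = limenitis_sampling()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    scaled = to_coalescent_scale(model)
    trees = simulate_replicate(scaled, sampling, RandomSource(seed))

    tree_paths: dict[str, Path] = {}
    tip_map: dict[str, str] = {}
    for locus, tree in zip(sampling, trees):
        path = out_dir / f"{locus}.nwk"
        path.write_text(tree.to_newick() + "\n")
        tree_paths[locus] = path
        for label, deme in zip(tree.labels, tree.tip_demes):
            if deme is not None:
                tip_map[label] = deme

    map_path = out_dir / "taxon_map.tsv"
    map_path.write_text(
        "".join(f"{tip}\t{deme}\n" for tip, deme in sorted(tip_map.items()))
    )

    param_hash = hashlib.sha256(
        json.dumps(model_to_dict(model), sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "kind": "synthetic pseudo-observed dataset",
        "model_id": model.model_id,
        "seed": int(seed),
        "package": "coalboot",
        "version": coalboot.__version__,
        "parameter_hash": param_hash,
        "loci": {locus: p.name for locus, p in tree_paths.items()},
        "taxon_map": map_path.name,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PseudoObservedSet(
        model_id=model.model_id,
        seed=int(seed),
        tree_paths=tree_paths,
        taxon_map_path=map_path,
        manifest_path=manifest_path,
        trees=trees,
    )


def degrade_to_consensus(
    tree: dendropy.Tree | GeneTree,
    collapse_fraction: float,
    rng: np.random.Generator | int = 0,
) -> dendropy.Tree:
    """Collapse the shortest internal branches into polytomies.

    Mimics the partial resolution of consensus summaries of tree
    posteriors, where poorly supported (typically short) internal branches
    appear as polytomies.  ``collapse_fraction`` of the internal (non-root)
    branches, rounded up, are collapsed, shortest first; ties are broken
    by a seeded shuffle.  Returns a new ``dendropy.Tree``.
    """
    if not (0.0 <= collapse_fraction <= 1.0):
        raise ValueError("collapse_fraction must be in [0, 1]")
    if isinstance(tree, GeneTree):
        tree = dendropy.Tree.get(
            data=tree.to_newick(), schema="newick", preserve_underscores=True
        )
        tree.is_rooted = True
    else:
        tree = tree.clone(depth=1)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    internal_edges = [
        node.edge
        for node in tree.preorder_node_iter()
        if node.parent_node is not None and not node.is_leaf()
    ]
    if not internal_edges or collapse_fraction == 0.0:
        return tree
    n_collapse = math.ceil(collapse_fraction * len(internal_edges))
    order = gen.permutation(len(internal_edges))
    ranked = sorted(
        (internal_edges[i] for i in order),
        key=lambda e: e.length if e.length is not None else 0.0,
    )
    for edge in ranked[:n_collapse]:
        edge.collapse()
    return tree
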