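"""Event-driven structured-coalescent simulation of gene trees.

The simulator runs backward in time on a :class:`~coalboot.demography.ScaledDemography`.
Within a deme of relative size ``x`` holding ``k`` lineages, coalescences
occur at total rate ``k (k - 1) / x`` (each pair at rate ``2 / x``, the
standard rate when time is measured in units of ``4 N_ref`` generations).
Lineages migrate backward along the active migration phases at their
scaled per-lineage rates, and at each population-split time every lineage
of the derived deme transfers to the ancestral deme.  The race between
exponential waiting times is piecewise constant between demographic
events; at equal event times splits are processed before migration-phase
toggles.  Simulation ends at the grand most recent common ancestor.

Randomness comes from numpy's PCG64 generator.  A replicate seed spawns
one independent substream per locus (keyed by locus index), so a
replicate is bitwise reproducible and loci are exchangeable across runs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from coalboot.demography import SamplingScheme, ScaledDemography

__all__ = [
    "RandomSource",
    "GeneTree",
    "simulate_gene_tree",
    "simulate_replicate",
    "write_gene_trees",
]


class RandomSource:
    """Seeded source of per-locus random substreams.

    The seed may be an integer or a tuple of integers (e.g.
    ``(suite_seed, model_index, replicate)``); per-locus generators append
    the locus index to the key, so every locus of every replicate has an
    independent, reproducible PCG64 stream.
    """

    def __init__(self, seed):
        if isinstance(seed, tuple):
            self.seed: tuple[int, ...] = tuple(_flatten_key(seed))
        else:
            self.seed = (int(seed),)

    def generator(self) -> np.random.Generator:
        return np.random.Generator(np.random.PCG64(np.random.SeedSequence(self.seed)))

    def locus_generator(self, locus_index: int) -> np.random.Generator:
        """Independent substream for one locus, derived from the seed."""
        return np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(self.seed + (int(locus_index),)))
        )


def _flatten_key(key) -> list[int]:
    out: list[int] = []
    for part in key:
        if isinstance(part, tuple):
            out.extend(_flatten_key(part))
        else:
            out.append(int(part))
    return out


def _as_generator(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if isinstance(rng, RandomSource):
        return rng.generator()
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(rng))))


class GeneTree:
    """A rooted, binary, ultrametric gene tree in scaled coalescent units.

    Nodes are stored as flat arrays: ``children[i]`` is a tuple of child
    ids (empty for tips), ``times[i]`` the node age (tips at 0), and
    ``labels[i]`` the tip label ``"deme|allele"`` (``None`` internally).
    """

    __slots__ = ("children", "times", "labels", "tip_demes", "root")

    def __init__(
        self,
        children: list[tuple[int, ...]],
        times: list[float],
        labels: list[str | None],
        tip_demes: list[str | None],
        root: int,
    ):
        self.children = children
        self.times = times
        self.labels = labels
        self.tip_demes = tip_demes
        self.root = root

    @property
    def n_tips(self) -> int:
        return sum(1 for c in self.children if not c)

    def tip_labels(self) -> list[str]:
        return [lab for lab, c in zip(self.labels, self.children) if not c]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    def parent_array(self) -> list[int]:
        parent = [-1] * len(self.children)
        for i, kids in enumerate(self.children):
            for c in kids:
                parent[c] = i
        return parent

    def to_newick(self, scaled: ScaledDemography | None = None, precision: int = 10) -> str:
        """Serialize to newick.  Branch lengths are in scaled coalescent
        units unless ``scaled`` is given, in which case they are converted
        to years for reporting."""
        factor = 1.0
        if scaled is not None:
            factor = 4.0 * scaled.reference_size / scaled.generations_per_year
        fmt = f"%.{precision}g"
        parent = self.parent_array()
        out: dict[int, str] = {}
        for node in self.postorder():
            kids = self.children[node]
            if not kids:
                s = self.labels[node]
            else:
                s = "(" + ",".join(out.pop(c) for c in kids) + ")"
            if parent[node] >= 0:
                blen = (self.times[parent[node]] - self.times[node]) * factor
                s += ":" + (fmt % blen)
            out[node] = s
        return out[self.root] + ";"


def simulate_gene_tree(
    scaled: ScaledDemography,
    counts_per_deme: Mapping[str, int],
    rng,
) -> GeneTree:
    """Simulate one gene tree under the structured coalescent.

    Parameters
    ----------
    scaled
        Demography on the coalescent scale (see
        :func:`coalboot.demography.to_coalescent_scale`).
    counts_per_deme
        Sampled allele count per contemporary deme; zero-count demes are
        omitted from the tree.  At least two alleles in total.
    rng
        A :class:`RandomSource`, integer seed, or numpy ``Generator``.
    """
    gen = _as_generator(rng)
    counts = {d: int(n) for d, n in counts_per_deme.items() if n > 0}
    if sum(counts.values()) < 2:
        raise ValueError("need at least 2 sampled alleles in total")
    ancestral = {s.ancestral for s in scaled.splits}
    for d in counts:
        if d not in scaled.relative_sizes:
            raise ValueError(f"samples requested in unknown deme {d!r}")
        if d in ancestral:
            raise ValueError(f"samples requested in non-contemporary deme {d!r}")

    inv_size = {d: 1.0 / x for d, x in scaled.relative_sizes.items()}

    # node arrays
    children: list[tuple[int, ...]] = []
    times: list[float] = []
    labels: list[str | None] = []
    tip_demes: list[str | None] = []

    lineages: dict[str, list[int]] = {}
    for deme in sorted(counts):
        ids = []
        for allele in range(1, counts[deme] + 1):
            ids.append(len(children))
            children.append(())
            times.append(0.0)
            labels.append(f"{deme}|{allele}")
            tip_demes.append(deme)
        lineages[deme] = ids

    # demographic timeline: (time, priority, kind, payload); splits first on ties
    events: list[tuple[float, int, str, object]] = []
    for s in scaled.splits:
        events.append((s.time, 0, "split", s))
    for m in scaled.migrations:
        events.append((m.start, 1, "mig", None))
        events.append((m.end, 1, "mig", None))
    events.sort(key=lambda e: (e[0], e[1]))

    def active_routes(t: float):
        return [
            (m.dest, m.source, m.rate)
            for m in scaled.migrations
            if m.start <= t < m.end and m.dest in lineages
        ]

    t = 0.0
    routes = active_routes(t)
    ev_idx = 0
    n_live = sum(len(v) for v in lineages.values())

    while n_live > 1:
        coal_rates = [
            (deme, len(ids) * (len(ids) - 1) * inv_size[deme])
            for deme, ids in lineages.items()
            if len(ids) > 1
        ]
        mig_rates = [
            (dest, source, rate * len(lineages[dest]))
            for dest, source, rate in routes
            if lineages.get(dest)
        ]
        total = sum(r for _, r in coal_rates) + sum(r for *_, r in mig_rates)

        next_ev = events[ev_idx][0] if ev_idx < len(events) else np.inf
        if total <= 0.0:
            if not np.isfinite(next_ev):
                raise ValueError(
                    "coalescence unreachable: multiple lineages remain in "
                    "disconnected demes with no further events"
                )
            wait = np.inf
        else:
            wait = gen.exponential(1.0 / total)

        if t + wait >= next_ev:
            # advance to the demographic event(s) at next_ev
            t = next_ev
            while ev_idx < len(events) and events[ev_idx][0] == next_ev:
                _, _, kind, payload = events[ev_idx]
                if kind == "split":
                    s = payload
                    moved = lineages.pop(s.derived, [])
                    lineages.setdefault(s.ancestral, []).extend(moved)
                ev_idx += 1
            routes = active_routes(t)
            continue

        t += wait
        u = gen.random() * total
        chosen = None
        for deme, r in coal_rates:
            if u < r:
                chosen = ("coal", deme)
                break
            u -= r
        if chosen is None:
            for dest, source, r in mig_rates:
                if u < r:
                    chosen = ("mig", dest, source)
                    break
                u -= r
        if chosen is None:  # numerical edge: attribute to the last category
            if mig_rates:
                chosen = ("mig", mig_rates[-1][0], mig_rates[-1][1])
            else:
                chosen = ("coal", coal_rates[-1][0])

        if chosen[0] == "coal":
            deme = chosen[1]
            ids = lineages[deme]
            i = int(gen.integers(len(ids)))
            j = int(gen.integers(len(ids) - 1))
            if j >= i:
                j += 1
            a, b = ids[i], ids[j]
            node = len(children)
            children.append((a, b))
            times.append(t)
            labels.append(None)
            tip_demes.append(None)
            # remove higher index first
            for k in sorted((i, j), reverse=True):
                ids.pop(k)
            ids.append(node)
            n_live -= 1
        else:
            _, dest, source = chosen
            ids = lineages[dest]
            i = int(gen.integers(len(ids)))
            lineage = ids.pop(i)
            lineages.setdefault(source, []).append(lineage)

    root = len(children) - 1
    return GeneTree(children, times, labels, tip_demes, root)


def simulate_replicate(
    scaled: ScaledDemography,
    sampling: SamplingScheme,
    rng: RandomSource | int,
) -> list[GeneTree]:
    """Simulate one multi-locus replicate: one independent gene tree per
    locus, each with that locus's allele counts.  Loci are simulated from
    independent substreams of the replicate seed, in scheme order."""
    source = rng if isinstance(rng, RandomSource) else RandomSource(int(rng))
    trees = []
    for idx, locus in enumerate(sampling):
        counts = sampling[locus]
        if sum(counts.values()) < 2:
            raise ValueError(f"locus {locus!r} has fewer than 2 sampled alleles")
        trees.append(simulate_gene_tree(scaled, counts, source.locus_generator(idx)))
    return trees


def write_gene_trees(
    trees: Iterable[GeneTree],
    path: str | Path,
    scaled: ScaledDemography | None = None,
) -> None:
    """Write trees as plain newick, one per line (optionally in years)."""
    Path(path).write_text(
        "".join(t.to_newick(scaled=scaled) + "\n" for t in trees)
    )
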