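"""The δ statistic and the two-criterion parametric-bootstrap model test.

For a set of per-locus gene trees and a pair of rival species trees
(``tree_R``: *arthemis* + *astyanax* sister; ``tree_MM``: *arizonensis* +
*astyanax* sister), the relative-fit statistic is

    δ = Σ_loci dc(gene tree, tree_R) − Σ_loci dc(gene tree, tree_MM)

with ``dc`` the minimum number of deep coalescences; negative δ favors
``tree_R``.  The absolute-fit statistic is the summed deep-coalescence
count on the species tree of the model under test.  Each demographic
model is evaluated by simulating many multi-locus replicates, computing
both statistics per replicate, and locating the observed values within
the simulated distributions.  A model is supported only when both
observed statistics lie within their simulated distributions.  "Within"
is operationalized per statistic: δ, the directional relative-fit
statistic, is judged by its nearer empirical tail at the 5% level
(rejected when the min tail is ≤ 0.05), while the absolute
deep-coalescence count uses the central 95% interval (rejected when its
nearer tail is < 0.025).  Both thresholds are configurable per result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from coalboot.coalsim import RandomSource, simulate_replicate
from coalboot.demography import (
    DemographicModel,
    SamplingScheme,
    to_coalescent_scale,
)
from coalboot.reconcile import SpeciesTree, count_deep_coalescences

__all__ = [
    "HypothesisPair",
    "ReplicateStats",
    "ModelTestResult",
    "limenitis_hypothesis_pair",
    "delta_statistic",
    "summed_dc",
    "empirical_tails",
    "evaluate_model",
    "run_model_suite",
    "suite_report_frame",
    "format_p",
]

ALPHA = 0.05

#: Fixed outgroup arrangement shared by both hypotheses.
_R_NEWICK = "(archippus,(weidemeyerii,(lorquini,(arizonensis,(arthemis,astyanax)))));"
_MM_NEWICK = "(archippus,(weidemeyerii,(lorquini,(arthemis,(arizonensis,astyanax)))));"


@dataclass(frozen=True)
class HypothesisPair:
    """The two rival species trees; identical leaf sets and outgroup."""

    tree_R: SpeciesTree
    tree_MM: SpeciesTree

    def __post_init__(self) -> None:
        if set(self.tree_R.leaf_names) != set(self.tree_MM.leaf_names):
            raise ValueError("hypothesis trees must share one leaf set")

    def tree_for(self, hypothesis: str) -> SpeciesTree:
        """Species tree matching a model's own topology (``"MM"`` or ``"R"``)."""
        if hypothesis == "MM":
            return self.tree_MM
        if hypothesis == "R":
            return self.tree_R
        raise ValueError(f"unknown hypothesis label {hypothesis!r}")

    def swapped(self) -> "HypothesisPair":
        return HypothesisPair(tree_R=self.tree_MM, tree_MM=self.tree_R)


def limenitis_hypothesis_pair(
    tree_R: str | SpeciesTree | None = None,
    tree_MM: str | SpeciesTree | None = None,
) -> HypothesisPair:
    """The default six-taxon hypothesis pair for the *Limenitis* analysis."""
    return HypothesisPair(
        tree_R=SpeciesTree(tree_R if tree_R is not None else _R_NEWICK),
        tree_MM=SpeciesTree(tree_MM if tree_MM is not None else _MM_NEWICK),
    )


@dataclass(frozen=True)
class ReplicateStats:
    """Summed deep-coalescence counts of one multi-locus dataset."""

    dc_R: int
    dc_MM: int

    @property
    def delta(self) -> int:
        return self.dc_R - self.dc_MM

    def dc_for(self, hypothesis: str) -> int:
        return self.dc_MM if hypothesis == "MM" else self.dc_R


@dataclass
class ModelTestResult:
    """Observed vs simulated statistics and the support decision for one model."""

    model_id: str
    hypothesis: str
    observed_delta: int
    observed_dc: int
    sim_deltas: np.ndarray
    sim_dcs: np.ndarray
    nreps: int
    #: δ is judged outside its simulated distribution when the nearer
    #: empirical tail is <= this level (one-sided 5%).
    delta_tail_alpha: float = ALPHA
    #: the absolute count is judged outside when the nearer tail is
    #: < this level (central 95% interval).
    dc_tail_alpha: float = ALPHA / 2.0

    @property
    def mean_delta(self) -> float:
        return float(np.mean(self.sim_deltas))

    @property
    def mean_dc(self) -> float:
        return float(np.mean(self.sim_dcs))

    @property
    def delta_tails(self) -> tuple[float, float]:
        return empirical_tails(self.observed_delta, self.sim_deltas)

    @property
    def dc_tails(self) -> tuple[float, float]:
        return empirical_tails(self.observed_dc, self.sim_dcs)

    @property
    def delta_p(self) -> float:
        return min(self.delta_tails)

    @property
    def dc_p(self) -> float:
        return min(self.dc_tails)

    @property
    def delta_within(self) -> bool:
        return self.delta_p > self.delta_tail_alpha

    @property
    def dc_within(self) -> bool:
        return self.dc_p >= self.dc_tail_alpha

    @property
    def supported(self) -> bool:
        return self.delta_within and self.dc_within


def summed_dc(
    gene_trees: Sequence,
    taxon_map: Mapping[str, str] | None,
    species_tree: SpeciesTree,
) -> int:
    """Sum of per-locus minimum deep-coalescence counts on one species tree."""
    gene_trees = list(gene_trees)
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    return sum(count_deep_coalescences(t, species_tree, taxon_map) for t in gene_trees)


def delta_statistic(
    gene_trees: Sequence,
    taxon_map: Mapping[str, str] | None,
    pair: HypothesisPair,
) -> int:
    """δ for a multi-locus dataset: summed dc on ``tree_R`` minus on ``tree_MM``."""
    return summed_dc(gene_trees, taxon_map, pair.tree_R) - summed_dc(
        gene_trees, taxon_map, pair.tree_MM
    )


def replicate_stats(
    gene_trees: Sequence,
    taxon_map: Mapping[str, str] | None,
    pair: HypothesisPair,
) -> ReplicateStats:
    """Both summed counts for one multi-locus dataset."""
    return ReplicateStats(
        dc_R=summed_dc(gene_trees, taxon_map, pair.tree_R),
        dc_MM=summed_dc(gene_trees, taxon_map, pair.tree_MM),
    )


def empirical_tails(observed: float, simulated: Sequence[float]) -> tuple[float, float]:
    """Empirical tail proportions of an observed value in a simulated sample.

    Returns ``(p_low, p_high)`` with ``p_low = #{sim <= obs} / n`` and
    ``p_high = #{sim >= obs} / n``; ties count in both tails, so
    ``p_low + p_high = 1 + ties/n``.  No continuity correction is applied.
    """
    sims = np.asarray(list(simulated), dtype=float)
    if sims.size == 0:
        raise ValueError("need at least one simulated value")
    p_low = float(np.count_nonzero(sims <= observed)) / sims.size
    p_high = float(np.count_nonzero(sims >= observed)) / sims.size
    return p_low, p_high


def format_p(p: float, n: int) -> str:
    """Render an empirical tail probability; zero counts become ``"<1/n"``."""
    if p <= 0.0:
        return f"<{1.0 / n:g}"
    return f"{p:g}"


def simulate_null_distribution(
    model: DemographicModel,
    pair: HypothesisPair,
    sampling: SamplingScheme,
    nreps: int,
    seed,
) -> list[ReplicateStats]:
    """Simulate ``nreps`` multi-locus replicates under one model and score each.

    Replicate ``r`` draws its per-locus substreams from the seed key
    ``(seed, r)``, so distributions are reproducible and replicates
    independent.
    """
    if nreps < 1:
        raise ValueError("nreps must be >= 1")
    scaled = to_coalescent_scale(model)
    out = []
    for r in range(nreps):
        trees = simulate_replicate(scaled, sampling, RandomSource((seed, r)))
        out.append(replicate_stats(trees, None, pair))
    return out


def evaluate_model(
    model: DemographicModel,
    observed_stats: ReplicateStats,
    pair: HypothesisPair,
    sampling: SamplingScheme,
    nreps: int = 2000,
    seed=0,
) -> ModelTestResult:
    """Parametric-bootstrap evaluation of one demographic model.

    Simulates ``nreps`` eight-locus replicates under ``model``, computes δ
    and the summed deep-coalescence count on the model's own species tree
    for each, and locates the observed statistics in the two simulated
    distributions.  The model is supported when both observed statistics
    lie within the central 95% simulated intervals.
    """
    stats = simulate_null_distribution(model, pair, sampling, nreps, seed)
    sim_deltas = np.array([s.delta for s in stats])
    sim_dcs = np.array([s.dc_for(model.hypothesis) for s in stats])
    return ModelTestResult(
        model_id=model.model_id,
        hypothesis=model.hypothesis,
        observed_delta=observed_stats.delta,
        observed_dc=observed_stats.dc_for(model.hypothesis),
        sim_deltas=sim_deltas,
        sim_dcs=sim_dcs,
        nreps=nreps,
    )


def run_model_suite(
    models: Sequence[DemographicModel],
    observed_stats: ReplicateStats,
    pair: HypothesisPair,
    sampling: SamplingScheme,
    nreps: int = 2000,
    seed: int = 0,
) -> list[ModelTestResult]:
    """Evaluate several models with independent substreams per model."""
    return [
        evaluate_model(m, observed_stats, pair, sampling, nreps, seed=(seed, i))
        for i, m in enumerate(models)
    ]


def suite_report_frame(results: Sequence[ModelTestResult]) -> pd.DataFrame:
    """Tabular report: one row per model with means, tails, and decision."""
    rows = []
    for r in results:
        d_lo, d_hi = r.delta_tails
        c_lo, c_hi = r.dc_tails
        rows.append(
            {
                "model": r.model_id,
                "hypothesis": r.hypothesis,
                "mean_delta": round(r.mean_delta, 4),
                "delta_p_low": d_lo,
                "delta_p_high": d_hi,
                "delta_p": format_p(r.delta_p, r.nreps),
                "mean_dc": round(r.mean_dc, 4),
                "dc_p_low": c_lo,
                "dc_p_high": c_hi,
                "dc_p": format_p(r.dc_p, r.nreps),
                "supported": r.supported,
            }
        )
    return pd.DataFrame(rows)
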