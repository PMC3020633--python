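"""Orchestration: configuration, full-analysis runs, and report files.

A :class:`RunConfig` fully determines an analysis: which models to
evaluate, the sampling design, the hypothesis pair, the observed input
(either literal statistics or gene-tree files plus a taxon map), the
replicate count and the seed.  :func:`run_full_analysis` produces a
report table (TSV + JSON) shaped like the model-support summary of the
study, the raw simulated distributions per model, and enough provenance
(config hash, seed, parameter values) to regenerate every output
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import coalboot
from coalboot.demography import (
    DEFAULT_OUTGROUP_TIMES,
    build_limenitis_models,
    limenitis_sampling,
)
from coalboot.hyptest import (
    HypothesisPair,
    ReplicateStats,
    limenitis_hypothesis_pair,
    replicate_stats,
    run_model_suite,
    suite_report_frame,
)
from coalboot.reconcile import read_gene_trees, read_taxon_map, root_with_outgroup

__all__ = ["RunConfig", "run_full_analysis", "load_config"]

log = logging.getLogger("coalboot")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one full analysis."""

    models: list[str] | str = "all"
    nreps: int = 2000
    seed: int = 0
    out_dir: str = "coalboot_out"
    # observed input, mode 1: literal statistics
    observed_dc_R: int | None = None
    observed_dc_MM: int | None = None
    # observed input, mode 2: tree files
    gene_tree_files: list[str] = field(default_factory=list)
    taxon_map_file: str | None = None
    outgroup: list[str] = field(default_factory=list)  # optional rooting tips
    # hypothesis pair and demography overrides
    tree_R: str | None = None
    tree_MM: str | None = None
    outgroup_times: dict = field(default_factory=dict)
    migration_scale: float = 1.0
    migration_rate_unit: str = "4Nm"
    write_distributions: bool = True

    def validate(self) -> None:
        literal = self.observed_dc_R is not None or self.observed_dc_MM is not None
        files = bool(self.gene_tree_files)
        if literal == files:
            raise ConfigError(
                "exactly one observed-input mode required: either both "
                "observed_dc_R/observed_dc_MM or gene_tree_files + taxon_map_file"
            )
        if literal and (self.observed_dc_R is None or self.observed_dc_MM is None):
            raise ConfigError("literal mode needs both observed_dc_R and observed_dc_MM")
        if files and not self.taxon_map_file:
            raise ConfigError("gene_tree_files given but no taxon_map_file")
        if self.nreps < 1:
            raise ConfigError("nreps must be >= 1")

    def to_dict(self) -> dict:
        return {
            "models": self.models,
            "nreps": self.nreps,
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "observed_dc_R": self.observed_dc_R,
            "observed_dc_MM": self.observed_dc_MM,
            "gene_tree_files": [str(p) for p in self.gene_tree_files],
            "taxon_map_file": self.taxon_map_file and str(self.taxon_map_file),
            "outgroup": list(self.outgroup),
            "tree_R": self.tree_R,
            "tree_MM": self.tree_MM,
            "outgroup_times": dict(self.outgroup_times),
            "migration_scale": self.migration_scale,
            "migration_rate_unit": self.migration_rate_unit,
        }

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _select_models(config: RunConfig):
    models = build_limenitis_models(
        outgroup_times=config.outgroup_times or None,
        migration_scale=config.migration_scale,
        migration_rate_unit=config.migration_rate_unit,
    )
    if config.models in ("all", ["all"]):
        return models
    wanted = list(config.models)
    by_id = {m.model_id: m for m in models}
    missing = [w for w in wanted if w not in by_id]
    if missing:
        raise ConfigError(f"unknown model ids: {missing}")
    return [by_id[w] for w in wanted]


def _observed_stats(config: RunConfig, pair: HypothesisPair) -> ReplicateStats:
    if config.observed_dc_R is not None:
        return ReplicateStats(
            dc_R=int(config.observed_dc_R), dc_MM=int(config.observed_dc_MM)
        )
    taxon_map = read_taxon_map(config.taxon_map_file)
    trees = []
    for f in config.gene_tree_files:
        trees.extend(read_gene_trees(f))
    if config.outgroup:
        log.info("rooting %d gene trees on outgroup %s", len(trees), config.outgroup)
        trees = [root_with_outgroup(t, config.outgroup) for t in trees]
    return replicate_stats(trees, taxon_map, pair)


def run_full_analysis(config: RunConfig) -> dict:
    """Run the complete parametric-bootstrap analysis described by ``config``.

    Returns the report payload (also written to ``out_dir/report.json``,
    with the table in ``out_dir/report.tsv`` and per-model simulated
    distributions under ``out_dir/distributions/``).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pair = limenitis_hypothesis_pair(config.tree_R, config.tree_MM)
    models = _select_models(config)
    observed = _observed_stats(config, pair)
    log.info(
        "observed statistics: dc_R=%d dc_MM=%d delta=%d",
        observed.dc_R,
        observed.dc_MM,
        observed.delta,
    )

    sampling = limenitis_sampling()
    results = run_model_suite(
        models, observed, pair, sampling, nreps=config.nreps, seed=config.seed
    )
    for r in results:
        log.info(
            "model %-5s mean_delta=%8.2f mean_dc=%8.2f supported=%s",
            r.model_id,
            r.mean_delta,
            r.mean_dc,
            r.supported,
        )

    frame = suite_report_frame(results)
    frame.to_csv(out_dir / "report.tsv", sep="\t", index=False)

    if config.write_distributions:
        dist_dir = out_dir / "distributions"
        dist_dir.mkdir(exist_ok=True)
        for r in results:
            lines = ["delta\tdc"]
            lines += [f"{d}\t{c}" for d, c in zip(r.sim_deltas, r.sim_dcs)]
            (dist_dir / f"{r.model_id}.tsv").write_text("\n".join(lines) + "\n")

    outgroup_times = dict(DEFAULT_OUTGROUP_TIMES)
    outgroup_times.update(config.outgroup_times)
    payload = {
        "package": "coalboot",
        "version": coalboot.__version__,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "outgroup_times_used": outgroup_times,
        "observed": {
            "dc_R": observed.dc_R,
            "dc_MM": observed.dc_MM,
            "delta": observed.delta,
        },
        "results": frame.to_dict(orient="records"),
        "supported_models": [r.model_id for r in results if r.supported],
    }
    (out_dir / "report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    return payload
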