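"""Demographic models as data, and conversion to coalescent scale.

A :class:`DemographicModel` describes a rooted species history in natural
units: demes with diploid effective sizes and generations per year, split
events in years before present, and piecewise-constant migration phases
expressed as expected migrants per generation (``Nm``) in forward-time
direction.  :func:`to_coalescent_scale` converts such a model into the
dimensionless units used by standard coalescent simulators: time in units
of ``4 * reference_size`` generations, deme sizes as ratios to the
reference size, and migration as backward per-lineage rates.

The builtin suite (:func:`build_limenitis_models`) encodes fifteen models
of North American *Limenitis* history: twelve "monophyletic mimic" (MM)
models in which the mimetic *L. a. astyanax* and *L. a. arizonensis* are
sister taxa, and three "reversion" (R) models in which *L. a. astyanax*
is sister to the non-mimetic *L. a. arthemis*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "LINEAGES",
    "LOCI",
    "Deme",
    "SplitEvent",
    "MigrationPhase",
    "DemographicModel",
    "SamplingScheme",
    "ScaledDemography",
    "build_limenitis_models",
    "limenitis_sampling",
    "to_coalescent_scale",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

#: The six contemporary North American *Limenitis* lineages, in the column
#: order of the sampling table.
LINEAGES = (
    "archippus",
    "arizonensis",
    "arthemis",
    "astyanax",
    "lorquini",
    "weidemeyerii",
)

#: The eight nuclear loci of the study design.
LOCI = ("Anon06", "Anon10", "Anon15", "Anon17", "EF1a", "kettin", "Ldh", "wg")

# Per-locus allele counts per lineage (same column order as LINEAGES).
_SAMPLING_TABLE = {
    "Anon06": (1, 2, 11, 7, 1, 1),
    "Anon10": (1, 2, 11, 8, 1, 1),
    "Anon15": (1, 1, 11, 9, 0, 1),
    "Anon17": (0, 2, 13, 8, 1, 1),
    "EF1a": (22, 12, 14, 16, 17, 15),
    "kettin": (1, 4, 11, 9, 1, 1),
    "Ldh": (1, 3, 11, 9, 1, 1),
    "wg": (7, 2, 16, 4, 1, 4),
}

# (T1, T2) in years before present for each builtin model.
_MODEL_TIMES = {
    "MM1": (117_500, 235_000),
    "MM2": (211_500, 235_000),
    "MM3": (327_500, 655_000),
    "MM4": (589_500, 655_000),
    "MM5": (537_000, 1_075_000),
    "MM6": (966_600, 1_075_000),
    "MM7": (117_500, 235_000),
    "MM8": (211_500, 235_000),
    "MM9": (327_500, 655_000),
    "MM10": (589_500, 655_000),
    "MM11": (537_000, 1_075_000),
    "MM12": (966_600, 1_075_000),
    "R1": (235_000, 1_095_000),
    "R2": (655_000, 1_095_000),
    "R3": (1_075_000, 1_095_000),
}

#: Maximum-likelihood ("moderate") migration estimates, migrants/generation.
MODERATE_MIGRATION = {"astyanax->arthemis": 3.2, "arthemis->astyanax": 0.14}
#: Upper 90% posterior-density bounds ("high").
HIGH_MIGRATION = {"astyanax->arthemis": 17.71, "arthemis->astyanax": 15.53}

#: Hybridization between *arthemis* and *astyanax* begins at the recession
#: of the Laurentide ice sheet, 12,000 years before present.
HYBRIDIZATION_ONSET_YBP = 12_000.0

CONTEMPORARY_NE = 2.5e6
ARTHEMIS_STEM_NE = 350_000.0
GENERATIONS_PER_YEAR = 2.0

#: Divergence times of the three outgroup species (years before present).
#: These are configurable model parameters; the defaults place the
#: outgroup splits outside the range of the ingroup split times under test.
DEFAULT_OUTGROUP_TIMES = {
    "lorquini": 1.5e6,
    "weidemeyerii": 2.5e6,
    "archippus": 3.5e6,
}


@dataclass(frozen=True)
class Deme:
    """A population: a lineage label with an effective size.

    Parameters
    ----------
    name
        Lineage label, unique within a model.
    effective_size
        Diploid effective population size, individuals.
    generations_per_year
        Generation turnover used when converting years to generations.
    """

    name: str
    effective_size: float
    generations_per_year: float = GENERATIONS_PER_YEAR

    def __post_init__(self) -> None:
        if self.effective_size <= 0:
            raise ValueError(f"deme {self.name!r}: effective_size must be > 0")
        if self.generations_per_year <= 0:
            raise ValueError(f"deme {self.name!r}: generations_per_year must be > 0")


@dataclass(frozen=True)
class SplitEvent:
    """Backward in time, all lineages of ``derived`` join ``ancestral``."""

    time_years: float
    derived: str
    ancestral: str

    def __post_init__(self) -> None:
        if self.time_years <= 0:
            raise ValueError("split time must be > 0")
        if self.derived == self.ancestral:
            raise ValueError("derived and ancestral demes must differ")


@dataclass(frozen=True)
class MigrationPhase:
    """Forward-time migration from ``source`` into ``dest`` over an interval.

    The interval ``[start_years, end_years)`` is half-open in years before
    present.  ``rate_migrants_per_gen`` is the expected number of migrant
    individuals per generation (``Nm``); backward in time a lineage sampled
    in ``dest`` traces its ancestry to ``source`` at per-generation rate
    ``Nm / N_dest``.
    """

    start_years: float
    end_years: float
    source: str
    dest: str
    rate_migrants_per_gen: float
    #: Unit in which ``rate_migrants_per_gen`` is expressed.  ``"Nm"``:
    #: literal expected migrants per generation.  ``"2Nm"`` / ``"4Nm"``:
    #: the published number is a scaled population rate (the MS simulator's
    #: migration parameter is 4Nm), so the effective migrant count is the
    #: stated value divided by 2 or 4.
    rate_unit: str = "Nm"

    _UNIT_FACTOR = {"Nm": 1.0, "2Nm": 2.0, "4Nm": 4.0}

    def __post_init__(self) -> None:
        if not (0 <= self.start_years < self.end_years):
            raise ValueError("require 0 <= start_years < end_years")
        if self.rate_migrants_per_gen < 0:
            raise ValueError("migration rate must be >= 0")
        if self.source == self.dest:
            raise ValueError("source and dest demes must differ")
        if self.rate_unit not in self._UNIT_FACTOR:
            raise ValueError(f"unknown rate_unit {self.rate_unit!r}")

    @property
    def effective_migrants_per_gen(self) -> float:
        """Expected migrant individuals per generation after unit conversion."""
        return self.rate_migrants_per_gen / self._UNIT_FACTOR[self.rate_unit]


@dataclass
class DemographicModel:
    """One rooted species history with sizes, splits, and migration."""

    model_id: str
    hypothesis: str  # "MM", "R", or user-defined label
    demes: list[Deme]
    splits: list[SplitEvent]
    migrations: list[MigrationPhase] = field(default_factory=list)
    reference_size: float = CONTEMPORARY_NE

    def __post_init__(self) -> None:
        self.validate()

    def deme(self, name: str) -> Deme:
        for d in self.demes:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def deme_names(self) -> list[str]:
        return [d.name for d in self.demes]

    @property
    def root_deme(self) -> str:
        derived = {s.derived for s in self.splits}
        roots = [d.name for d in self.demes if d.name not in derived]
        if len(roots) != 1:  # validate() guarantees this
            raise ValueError(f"model {self.model_id}: expected one root, got {roots}")
        return roots[0]

    def contemporary_demes(self) -> list[str]:
        """Demes extant at present: those never acting as an ancestor."""
        ancestral = {s.ancestral for s in self.splits}
        return [d.name for d in self.demes if d.name not in ancestral]

    def split_time(self, deme_name: str) -> float:
        """Time at which ``deme_name`` merges into its ancestor (inf for root)."""
        for s in self.splits:
            if s.derived == deme_name:
                return s.time_years
        return float("inf")

    def validate(self) -> None:
        names = [d.name for d in self.demes]
        if len(names) != len(set(names)):
            raise ValueError(f"model {self.model_id}: duplicate deme names")
        if self.reference_size <= 0:
            raise ValueError(f"model {self.model_id}: reference_size must be > 0")
        known = set(names)
        derived_seen = set()
        for s in self.splits:
            if s.derived not in known or s.ancestral not in known:
                raise ValueError(
                    f"model {self.model_id}: split references unknown deme "
                    f"({s.derived!r} -> {s.ancestral!r})"
                )
            if s.derived in derived_seen:
                raise ValueError(
                    f"model {self.model_id}: deme {s.derived!r} splits twice"
                )
            derived_seen.add(s.derived)
        roots = known - derived_seen
        if len(roots) != 1:
            raise ValueError(
                f"model {self.model_id}: species history must have exactly one "
                f"root deme, found {sorted(roots)}"
            )
        # splits must form a single rooted history: every deme reaches the root
        ancestor_of = {s.derived: s.ancestral for s in self.splits}
        (root,) = roots
        for name in known:
            seen: set[str] = set()
            cur = name
            while cur != root:
                if cur in seen:
                    raise ValueError(f"model {self.model_id}: cycle in splits at {cur!r}")
                seen.add(cur)
                cur = ancestor_of[cur]
        # ancestral deme must outlive (backward) its derived deme's join time
        for s in self.splits:
            if self.split_time(s.ancestral) <= s.time_years:
                raise ValueError(
                    f"model {self.model_id}: {s.ancestral!r} ends before "
                    f"{s.derived!r} joins it"
                )
        # migration only between demes extant throughout the phase
        for m in self.migrations:
            for deme_name in (m.source, m.dest):
                if deme_name not in known:
                    raise ValueError(
                        f"model {self.model_id}: migration references unknown "
                        f"deme {deme_name!r}"
                    )
                if self.split_time(deme_name) < m.end_years:
                    raise ValueError(
                        f"model {self.model_id}: deme {deme_name!r} not extant "
                        f"through migration phase ending {m.end_years}"
                    )


class SamplingScheme(dict):
    """Mapping ``locus -> {deme -> allele count}`` for a multi-locus design."""

    def __init__(self, table: Mapping[str, Mapping[str, int]]):
        super().__init__({loc: dict(counts) for loc, counts in table.items()})
        self.validate()

    def validate(self) -> None:
        if not self:
            raise ValueError("sampling scheme has no loci")
        any_pair = False
        for locus, counts in self.items():
            for deme_name, n in counts.items():
                if not (isinstance(n, (int,)) and n >= 0):
                    raise ValueError(
                        f"locus {locus!r}, deme {deme_name!r}: counts must be "
                        f"non-negative integers, got {n!r}"
                    )
            if sum(counts.values()) >= 2:
                any_pair = True
        if not any_pair:
            raise ValueError("no locus has at least 2 sampled alleles")

    def total_tips(self, locus: str) -> int:
        return sum(self[locus].values())


@dataclass(frozen=True)
class ScaledMigration:
    """Backward per-lineage migration: a lineage in ``dest`` jumps to
    ``source`` at ``rate`` per unit of scaled time over ``[start, end)``."""

    start: float
    end: float
    source: str
    dest: str
    rate: float


@dataclass(frozen=True)
class ScaledSplit:
    time: float
    derived: str
    ancestral: str


@dataclass
class ScaledDemography:
    """A demographic model on the coalescent scale.

    Times are in units of ``4 * reference_size`` generations, deme sizes
    are ratios to the reference size, and migration rates are backward
    per-lineage rates per scaled time unit.
    """

    model_id: str
    relative_sizes: dict[str, float]
    splits: list[ScaledSplit]
    migrations: list[ScaledMigration]
    reference_size: float
    generations_per_year: float

    @property
    def root_deme(self) -> str:
        derived = {s.derived for s in self.splits}
        (root,) = [d for d in self.relative_sizes if d not in derived]
        return root

    def years_to_scaled(self, t_years: float) -> float:
        return t_years * self.generations_per_year / (4.0 * self.reference_size)

    def scaled_to_years(self, t: float) -> float:
        return t * 4.0 * self.reference_size / self.generations_per_year


def to_coalescent_scale(model: DemographicModel) -> ScaledDemography:
    """Convert a model in natural units to coalescent (simulator) units.

    A time of ``t`` years becomes ``t * g / (4 * N_ref)`` with ``g``
    generations per year; a forward flow of ``M`` migrants/generation from
    ``source`` into ``dest`` becomes a backward per-lineage rate of
    ``4 * N_ref * M / N_dest`` per scaled unit for lineages in ``dest``;
    a deme of size ``N`` gets relative size ``N / N_ref``.
    """
    if model.reference_size <= 0:
        raise ValueError("reference_size must be > 0")
    n_ref = model.reference_size
    gpy = {d.generations_per_year for d in model.demes}
    if len(gpy) != 1:
        raise ValueError("all demes must share one generations_per_year for scaling")
    (g,) = gpy

    def t_scale(t_years: float) -> float:
        return t_years * g / (4.0 * n_ref)

    sizes = {d.name: d.effective_size / n_ref for d in model.demes}
    splits = sorted(
        (ScaledSplit(t_scale(s.time_years), s.derived, s.ancestral) for s in model.splits),
        key=lambda s: s.time,
    )
    migrations = [
        ScaledMigration(
            start=t_scale(m.start_years),
            end=t_scale(m.end_years),
            source=m.source,
            dest=m.dest,
            rate=4.0 * n_ref * m.effective_migrants_per_gen / model.deme(m.dest).effective_size,
        )
        for m in model.migrations
    ]
    return ScaledDemography(
        model_id=model.model_id,
        relative_sizes=sizes,
        splits=splits,
        migrations=migrations,
        reference_size=n_ref,
        generations_per_year=g,
    )


def limenitis_sampling() -> SamplingScheme:
    """The eight-locus *Limenitis* sampling design (alleles per lineage)."""
    return SamplingScheme(
        {
            locus: dict(zip(LINEAGES, counts))
            for locus, counts in _SAMPLING_TABLE.items()
        }
    )


def _ingroup_structure(model_id: str) -> tuple[str, list[tuple[str, str]]]:
    """Hypothesis label and the (derived, ancestral) pairs at T1 for a model."""
    if model_id.startswith("MM"):
        # mimetic clade: astyanax + arizonensis coalesce first
        return "MM", [("astyanax", "anc_T1"), ("arizonensis", "anc_T1")]
    return "R", [("astyanax", "anc_T1"), ("arthemis", "anc_T1")]


def build_limenitis_models(
    outgroup_times: Mapping[str, float] | None = None,
    migration_scale: float = 1.0,
    migration_rate_unit: str = "4Nm",
) -> list[DemographicModel]:
    """Build the fifteen builtin models of *Limenitis* history.

    Models MM1-MM6 and the R models carry the maximum-likelihood
    ("moderate") migration between *astyanax* and *arthemis*; MM7-MM12
    carry the upper posterior-density ("high") rates.  All migration is
    active over the last 12,000 years.  Contemporary demes have an
    effective size of 2.5 million with two generations per year; the
    ancestral stem of the *arthemis* complex (above T2) has size 350,000.

    Parameters
    ----------
    outgroup_times
        Optional overrides for the divergence times (years) of the three
        outgroup species, keyed ``"lorquini"``, ``"weidemeyerii"``,
        ``"archippus"``.  Each must exceed every ingroup split time.
    migration_scale
        Extra multiplier applied to all migration rates, for sensitivity
        analyses.
    migration_rate_unit
        How the published migration numbers are interpreted (see
        :class:`MigrationPhase`).  The default ``"4Nm"`` treats them as
        MS-convention population rates (effective migrant count = value/4);
        this is the interpretation under which the simulated δ
        distributions reproduce the study's reported per-model means for
        both migration tiers.  Set ``"Nm"`` to read them as literal
        migrants per generation.
    """
    og = dict(DEFAULT_OUTGROUP_TIMES)
    if outgroup_times:
        og.update(outgroup_times)
    if not (og["lorquini"] < og["weidemeyerii"] < og["archippus"]):
        raise ValueError("outgroup times must be ordered lorquini < weidemeyerii < archippus")

    models = []
    for model_id, (t1, t2) in _MODEL_TIMES.items():
        if og["lorquini"] <= t2:
            raise ValueError(
                f"outgroup (lorquini) split {og['lorquini']} must exceed T2={t2}"
            )
        hypothesis, t1_joins = _ingroup_structure(model_id)
        third = {"MM": "arthemis", "R": "arizonensis"}[hypothesis]
        demes = [
            Deme(name, CONTEMPORARY_NE) for name in LINEAGES
        ] + [
            Deme("anc_T1", CONTEMPORARY_NE),
            Deme("arthemis_stem", ARTHEMIS_STEM_NE),
            Deme("anc_lorquini", CONTEMPORARY_NE),
            Deme("anc_weidemeyerii", CONTEMPORARY_NE),
            Deme("anc_root", CONTEMPORARY_NE),
        ]
        splits = [SplitEvent(t1, derived, anc) for derived, anc in t1_joins]
        splits += [
            SplitEvent(t2, "anc_T1", "arthemis_stem"),
            SplitEvent(t2, third, "arthemis_stem"),
            SplitEvent(og["lorquini"], "arthemis_stem", "anc_lorquini"),
            SplitEvent(og["lorquini"], "lorquini", "anc_lorquini"),
            SplitEvent(og["weidemeyerii"], "anc_lorquini", "anc_weidemeyerii"),
            SplitEvent(og["weidemeyerii"], "weidemeyerii", "anc_weidemeyerii"),
            SplitEvent(og["archippus"], "anc_weidemeyerii", "anc_root"),
            SplitEvent(og["archippus"], "archippus", "anc_root"),
        ]
        tier = HIGH_MIGRATION if model_id in {f"MM{i}" for i in range(7, 13)} else MODERATE_MIGRATION
        migrations = [
            MigrationPhase(
                0.0,
                HYBRIDIZATION_ONSET_YBP,
                source="astyanax",
                dest="arthemis",
                rate_migrants_per_gen=tier["astyanax->arthemis"] * migration_scale,
                rate_unit=migration_rate_unit,
            ),
            MigrationPhase(
                0.0,
                HYBRIDIZATION_ONSET_YBP,
                source="arthemis",
                dest="astyanax",
                rate_migrants_per_gen=tier["arthemis->astyanax"] * migration_scale,
                rate_unit=migration_rate_unit,
            ),
        ]
        models.append(
            DemographicModel(
                model_id=model_id,
                hypothesis=hypothesis,
                demes=demes,
                splits=splits,
                migrations=migrations,
                reference_size=CONTEMPORARY_NE,
            )
        )
    return models


def get_model(model_id: str, **kwargs) -> DemographicModel:
    """Fetch one builtin model by id (e.g. ``"R2"``)."""
    for m in build_limenitis_models(**kwargs):
        if m.model_id == model_id:
            return m
    raise KeyError(f"unknown builtin model {model_id!r}")


# ---------------------------------------------------------------------------
# serialization

def model_to_dict(model: DemographicModel) -> dict:
    return {
        "model_id": model.model_id,
        "hypothesis": model.hypothesis,
        "reference_size": model.reference_size,
        "demes": [asdict(d) for d in model.demes],
        "splits": [asdict(s) for s in model.splits],
        "migrations": [asdict(m) for m in model.migrations],
    }


def model_from_dict(data: Mapping) -> DemographicModel:
    return DemographicModel(
        model_id=data["model_id"],
        hypothesis=data.get("hypothesis", "user"),
        demes=[Deme(**d) for d in data["demes"]],
        splits=[SplitEvent(**s) for s in data["splits"]],
        migrations=[MigrationPhase(**m) for m in data.get("migrations", [])],
        reference_size=data["reference_size"],
    )


def save_model(model: DemographicModel, path: str | Path) -> None:
    path = Path(path)
    payload = model_to_dict(model)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path) -> DemographicModel:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    return model_from_dict(data)


def sampling_to_tsv(sampling: SamplingScheme) -> str:
    """Render a sampling scheme as a TSV table (loci as rows)."""
    demes = sorted({d for counts in sampling.values() for d in counts})
    lines = ["\t".join(["locus"] + demes)]
    for locus in sampling:
        lines.append("\t".join([locus] + [str(sampling[locus].get(d, 0)) for d in demes]))
    return "\n".join(lines) + "\n"
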