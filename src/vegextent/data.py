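"""Survey data model, validation, CSV I/O, species filtering and survey designs.

A belt-transect vegetation survey is stored in long format: one row per
(plot, species) observation carrying a stalk count and a percent cover.
The transect layout (zone, distance from the construction corridor,
number of plots) travels in a separate table.  Percent cover is kept on
the 0-100 scale throughout; computations convert internally.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Zone",
    "Transect",
    "PlotRecord",
    "CommunityDataset",
    "IVTable",
    "FormatError",
    "IntegrityError",
    "ValidationError",
    "read_community_csv",
    "write_community_csv",
    "build_design",
    "filter_species",
    "table1_fixture",
    "TABLE1_CLUSTERS",
]

SURVEY_COLUMNS = ("plot_id", "transect_id", "species", "count", "cover_pct")
LAYOUT_COLUMNS = ("transect_id", "zone", "distance_m", "n_plots")

#: Half-width, in percent cover, tolerated when per-species covers are
#: compared with the plot total (visual estimates are rounded in the field).
COVER_SLACK_PCT = 1.0


class FormatError(ValueError):
    """A file does not match the expected column layout."""


class IntegrityError(ValueError):
    """Cross-references between survey and layout are inconsistent."""


class ValidationError(ValueError):
    """A value violates a domain invariant (negative count, cover > 100, ...)."""


class Zone(str, enum.Enum):
    """Position of a belt transect relative to the construction corridor."""

    PIPELINE_AREA = "pipeline_area"
    INTER_PIPELINE = "inter_pipeline"
    DISTANCE = "distance"
    CONTROL = "control"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Transect:
    """One belt transect: identifier, zone and distance from the corridor edge.

    ``distance_m`` is measured from the edge of the outermost pipeline
    working area; transects inside or between working areas carry 0 and
    the far-field control carries its actual distance (2000 m in the
    reference design).
    """

    transect_id: str
    zone: Zone
    distance_m: float
    n_plots: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "zone", Zone(self.zone))
        if self.distance_m < 0:
            raise ValidationError(f"transect {self.transect_id}: negative distance")
        if self.n_plots <= 0:
            raise ValidationError(f"transect {self.transect_id}: n_plots must be positive")
        if self.zone is Zone.DISTANCE and self.distance_m <= 0:
            raise ValidationError(
                f"transect {self.transect_id}: distance-zone transects need distance_m > 0"
            )


@dataclass
class PlotRecord:
    """A single 2 x 2 m sampling plot.

    ``counts`` maps species name -> stalk count; ``covers`` maps species
    name -> percent cover (0-100).  ``total_cover`` is the visually
    estimated percent cover of all vegetation in the plot; species covers
    may overlap, so their sum is only required to stay within a small
    slack of the total.
    """

    plot_id: str
    transect_id: str
    counts: dict[str, int] = field(default_factory=dict)
    covers: dict[str, float] = field(default_factory=dict)
    total_cover: float = 0.0

    def validate(self, permissive_cover_only: bool = False) -> None:
        for sp, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValidationError(
                    f"plot {self.plot_id}: count for {sp!r} must be a non-negative integer"
                )
        for sp, cv in self.covers.items():
            if not (0.0 <= cv <= 100.0):
                raise ValidationError(
                    f"plot {self.plot_id}: cover for {sp!r} outside [0, 100]"
                )
        if not (0.0 <= self.total_cover <= 100.0):
            raise ValidationError(f"plot {self.plot_id}: total_cover outside [0, 100]")
        if sum(self.covers.values()) > self.total_cover + COVER_SLACK_PCT:
            raise ValidationError(
                f"plot {self.plot_id}: species covers sum to more than total_cover"
            )
        if not permissive_cover_only:
            orphans = [
                sp for sp, cv in self.covers.items()
                if cv > 0 and self.counts.get(sp, 0) == 0
            ]
            if orphans:
                raise ValidationError(
                    f"plot {self.plot_id}: cover without counted stalks for {orphans}; "
                    "pass permissive_cover_only=True to keep such records"
                )

    @property
    def species(self) -> list[str]:
        return sorted(set(self.counts) | set(self.covers))

    @property
    def total_stalks(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class CommunityDataset:
    """A full survey: plots bound to a transect layout.

    ``species_registry`` preserves first-appearance order and is the
    canonical species axis for every downstream matrix.
    """

    plots: list[PlotRecord]
    layout: list[Transect]
    species_registry: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species_registry:
            self.species_registry = _registry_from_plots(self.plots)

    # -- lookups ---------------------------------------------------------
    def transect(self, transect_id: str) -> Transect:
        for t in self.layout:
            if t.transect_id == transect_id:
                return t
        raise KeyError(transect_id)

    def plots_for(self, transect_id: str) -> list[PlotRecord]:
        return [p for p in self.plots if p.transect_id == transect_id]

    def transect_ids(self, include_control: bool = False) -> list[str]:
        return [
            t.transect_id
            for t in self.layout
            if include_control or t.zone is not Zone.CONTROL
        ]

    # -- validation ------------------------------------------------------
    def validate(self, permissive_cover_only: bool = False) -> None:
        known = {t.transect_id for t in self.layout}
        if len(known) != len(self.layout):
            raise IntegrityError("duplicate transect_id in layout")
        for p in self.plots:
            if p.transect_id not in known:
                raise IntegrityError(
                    f"plot {p.plot_id} references unknown transect {p.transect_id!r}"
                )
            p.validate(permissive_cover_only=permissive_cover_only)
        counts = pd.Series([p.transect_id for p in self.plots]).value_counts()
        for t in self.layout:
            observed = int(counts.get(t.transect_id, 0))
            if observed and observed != t.n_plots:
                raise IntegrityError(
                    f"transect {t.transect_id}: layout declares {t.n_plots} plots, "
                    f"survey has {observed}"
                )
        seen = set(self.species_registry)
        for p in self.plots:
            missing = set(p.species) - seen
            if missing:
                raise IntegrityError(f"species {missing} missing from registry")
        dists = sorted(
            t.distance_m for t in self.layout if t.zone is Zone.DISTANCE
        )
        if len(dists) != len(set(dists)):
            raise ValidationError("distance transects must have distinct distances")

    # -- conversion ------------------------------------------------------
    def survey_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.plots:
            for sp in p.species:
                rows.append(
                    (p.plot_id, p.transect_id, sp,
                     p.counts.get(sp, 0), p.covers.get(sp, 0.0))
                )
        return pd.DataFrame(rows, columns=list(SURVEY_COLUMNS))

    def layout_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.transect_id, t.zone.value, t.distance_m, t.n_plots) for t in self.layout],
            columns=list(LAYOUT_COLUMNS),
        )


def _registry_from_plots(plots: Iterable[PlotRecord]) -> list[str]:
    registry: list[str] = []
    seen: set[str] = set()
    for p in plots:
        for sp in list(p.counts) + list(p.covers):
            if sp not in seen:
                seen.add(sp)
                registry.append(sp)
    return registry


def _normalize_name(name: str) -> str:
    return " ".join(str(name).split())


# ---------------------------------------------------------------------------
# CSV I/O


def read_community_csv(
    survey_path: str | Path,
    layout_path: str | Path,
    permissive_cover_only: bool = False,
) -> CommunityDataset:
    """Read a long-format survey CSV and its layout CSV into a validated dataset.

    The survey file needs columns ``plot_id,transect_id,species,count,cover_pct``
    (one row per plot x species) and the layout file
    ``transect_id,zone,distance_m,n_plots``.  Total plot cover is
    reconstructed as the sum of per-species covers; a ``__total__``
    pseudo-species row, when present, overrides it.
    """
    survey = pd.read_csv(survey_path, dtype={"plot_id": str, "transect_id": str},
                         float_precision="round_trip")
    layout = pd.read_csv(layout_path, dtype={"transect_id": str},
                         float_precision="round_trip")
    for col in SURVEY_COLUMNS:
        if col not in survey.columns:
            raise FormatError(f"survey file missing column {col!r}")
    for col in LAYOUT_COLUMNS:
        if col not in layout.columns:
            raise FormatError(f"layout file missing column {col!r}")

    transects = [
        Transect(str(r.transect_id), Zone(r.zone), float(r.distance_m), int(r.n_plots))
        for r in layout.itertuples()
    ]

    plots: dict[str, PlotRecord] = {}
    for r in survey.itertuples():
        pid = str(r.plot_id)
        rec = plots.get(pid)
        if rec is None:
            rec = plots[pid] = PlotRecord(pid, str(r.transect_id))
        elif rec.transect_id != str(r.transect_id):
            raise IntegrityError(f"plot {pid} assigned to two transects")
        sp = _normalize_name(r.species)
        if sp == "__total__":
            rec.total_cover = float(r.cover_pct)
            continue
        if float(r.count) < 0 or float(r.cover_pct) < 0:
            raise ValidationError(f"plot {pid}, species {sp!r}: negative count or cover")
        rec.counts[sp] = rec.counts.get(sp, 0) + int(r.count)
        rec.covers[sp] = rec.covers.get(sp, 0.0) + float(r.cover_pct)
    for rec in plots.values():
        if rec.total_cover == 0.0:
            rec.total_cover = min(100.0, sum(rec.covers.values()))

    ds = CommunityDataset(list(plots.values()), transects)
    ds.validate(permissive_cover_only=permissive_cover_only)
    return ds


def write_community_csv(
    dataset: CommunityDataset,
    survey_path: str | Path,
    layout_path: str | Path,
    write_total_rows: bool = True,
) -> None:
    """Write a dataset back to the survey/layout CSV pair.

    ``__total__`` rows preserve each plot's visually estimated total cover
    so that a read/write round-trip is lossless.
    """
    frame = dataset.survey_frame()
    if write_total_rows:
        totals = pd.DataFrame(
            [
                (p.plot_id, p.transect_id, "__total__", 0, p.total_cover)
                for p in dataset.plots
            ],
            columns=list(SURVEY_COLUMNS),
        )
        frame = pd.concat([frame, totals], ignore_index=True)
    frame.to_csv(survey_path, index=False)
    dataset.layout_frame().to_csv(layout_path, index=False)


# ---------------------------------------------------------------------------
# Survey designs

_S1_DISTANCES = (10.0, 30.0, 50.0, 100.0, 300.0, 500.0, 800.0, 1000.0)


def build_design(preset: str, include_control: bool = False) -> list[Transect]:
    """Standard belt-transect layouts.

    ``S1`` mirrors a three-pipeline corridor: three working-area transects
    (I, Oil, II), two inter-pipeline transects (I-O, O-II) and eight
    distance transects at 10-1000 m, six plots each (13 transects, 78
    plots).  ``S2`` is the single-pipeline variant: one working-area
    transect plus the eight distance transects (9 transects, 54 plots).
    ``include_control`` appends a far-field CK transect at 2000 m.
    """
    preset = preset.upper()
    if preset == "S1":
        transects = [
            Transect("I", Zone.PIPELINE_AREA, 0.0, 6),
            Transect("I-O", Zone.INTER_PIPELINE, 0.0, 6),
            Transect("Oil", Zone.PIPELINE_AREA, 0.0, 6),
            Transect("O-II", Zone.INTER_PIPELINE, 0.0, 6),
            Transect("II", Zone.PIPELINE_AREA, 0.0, 6),
        ]
    elif preset == "S2":
        transects = [Transect("II", Zone.PIPELINE_AREA, 0.0, 6)]
    else:
        raise ValueError(f"unknown design preset {preset!r} (expected 'S1' or 'S2')")
    transects += [
        Transect(f"{int(d)}m", Zone.DISTANCE, d, 6) for d in _S1_DISTANCES
    ]
    if include_control:
        transects.append(Transect("CK", Zone.CONTROL, 2000.0, 6))
    return transects


# ---------------------------------------------------------------------------
# Species filtering


def filter_species(
    dataset: CommunityDataset,
    exclude: Sequence[str] = (),
    min_plot_occurrence: int = 0,
) -> CommunityDataset:
    """Drop named species and rare ('accidental') species.

    A species is kept when it is not in ``exclude`` and occurs (count > 0
    or cover > 0) in at least ``min_plot_occurrence`` plots.  Use the
    name filter for taxa that would distort importance values (e.g. the
    large-crowned shrub *Tamarix chinensis*) and the occurrence filter
    for accidental singletons.
    """
    if min_plot_occurrence < 0:
        raise ValueError("min_plot_occurrence must be >= 0")
    excluded = {_normalize_name(s) for s in exclude}
    occurrence: dict[str, int] = {sp: 0 for sp in dataset.species_registry}
    for p in dataset.plots:
        for sp in p.species:
            if p.counts.get(sp, 0) > 0 or p.covers.get(sp, 0.0) > 0:
                occurrence[sp] = occurrence.get(sp, 0) + 1
    keep = [
        sp
        for sp in dataset.species_registry
        if sp not in excluded and occurrence.get(sp, 0) >= min_plot_occurrence
    ]
    if not keep:
        raise ValidationError("species filter removed every species")
    keep_set = set(keep)
    plots = [
        PlotRecord(
            p.plot_id,
            p.transect_id,
            {sp: c for sp, c in p.counts.items() if sp in keep_set},
            {sp: cv for sp, cv in p.covers.items() if sp in keep_set},
            p.total_cover,
        )
        for p in dataset.plots
    ]
    return CommunityDataset(plots, list(dataset.layout), keep)


# ---------------------------------------------------------------------------
# IV tables and the packaged reference matrix


@dataclass
class IVTable:
    """Species x transect importance values with their three components.

    ``Rd``, ``Rf``, ``Rc`` and ``IV`` are DataFrames indexed by species
    with transect ids as columns; each component column sums to 1 over
    the species present in that transect, and IV is their mean, so IV
    columns sum to 1 as well.
    """

    Rd: pd.DataFrame
    Rf: pd.DataFrame
    Rc: pd.DataFrame
    IV: pd.DataFrame
    clusters: dict[str, list[str]] | None = None

    @property
    def species(self) -> list[str]:
        return list(self.IV.index)

    @property
    def transects(self) -> list[str]:
        return list(self.IV.columns)

    def rounded(self, decimals: int = 3) -> pd.DataFrame:
        """IV matrix rounded half-up to ``decimals`` (display convention)."""
        return round_half_up(self.IV, decimals)

    def write_csv(self, path: str | Path, precision: int | None = None) -> None:
        out = self.IV if precision is None else self.rounded(precision)
        out.rename_axis("species").to_csv(path)


def round_half_up(values, decimals: int = 3):
    """Round half away from zero (the convention of printed ecological tables).

    numpy and Python 3 round half to even; printed tables almost always
    round 0.0775 -> 0.078, so we shift by a hair above half before floor.
    """
    arr = np.asarray(values, dtype=float)
    factor = 10.0 ** decimals
    out = np.floor(np.abs(arr) * factor + 0.5) / factor * np.sign(arr)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    if np.isscalar(values):
        return float(out)
    return out


#: Cluster memberships of the reference eight-species matrix.
TABLE1_CLUSTERS: dict[str, list[str]] = {
    "Cluster 1": ["Kalidium gracile", "Leymus secalinus", "Phragmites australis"],
    "Cluster 2": ["Kalidium foliatum", "Scorzonera sinensis"],
    "Cluster 3": ["Achnatherum splendens", "Galium verum", "Nitraria sibirica"],
}


def table1_fixture() -> IVTable:
    """The packaged reference IV matrix: 8 desert-steppe species x 13 transects.

    This is the published survey of a three-pipeline corridor in arid
    desert steppe (Guazhou, Gansu), with working-area transects I, Oil
    and II, inter-pipeline transects I-O and O-II, and distance transects
    at 10-1000 m.  Component matrices (Rd/Rf/Rc) were not published, so
    they are returned as NaN; cluster memberships of the published
    classification ride along in ``clusters``.
    """
    path = resources.files("vegextent") / "tables" / "table1_iv.csv"
    with resources.as_file(path) as p:
        frame = pd.read_csv(p, index_col="species")
    frame = frame.drop(columns=["cluster"])
    nan = frame * np.nan
    return IVTable(Rd=nan, Rf=nan.copy(), Rc=nan.copy(), IV=frame,
                   clusters={k: list(v) for k, v in TABLE1_CLUSTERS.items()})


def table1_layout() -> list[Transect]:
    """The S1 layout matching the reference matrix's column order."""
    return build_design("S1")
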