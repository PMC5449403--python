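"""Importance values and integrated importance values.

The importance value (IV) of a species in a belt transect is the mean of
its relative density, relative frequency and relative cover::

    IV = (Rd + Rf + Rc) / 3
    Rd = d / D     stalks of the species / all stalks in the transect
    Rf = f / F     plots containing the species / sum of f over species
    Rc = c / C     cover of the species / total vegetation cover

All three components are normalised within a transect, so each sums to 1
over the species present, and so does IV.  The integrated importance
value (IIV) of a cluster of species is the arithmetic mean of its
members' IVs (absent members contribute 0); the IIV of a response group
is the sum of its member clusters' IIVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .data import CommunityDataset, IVTable, Zone, round_half_up

__all__ = ["IIVTable", "importance_values", "integrated_iv", "group_iiv",
           "DegenerateTransectError"]

logger = logging.getLogger(__name__)


class DegenerateTransectError(ValueError):
    """A transect has no individuals or no cover, so ratios are undefined."""


@dataclass
class IIVTable:
    """Cluster x transect integrated importance values.

    ``clusters`` maps cluster label -> member species (the order of the
    mapping fixes the row order of ``IIV``).
    """

    clusters: dict[str, list[str]]
    IIV: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.IIV.index)

    @property
    def transects(self) -> list[str]:
        return list(self.IIV.columns)

    def rounded(self, decimals: int = 3) -> pd.DataFrame:
        return round_half_up(self.IIV, decimals)

    def write_csv(self, path: str | Path, precision: int | None = None) -> None:
        out = self.IIV if precision is None else self.rounded(precision)
        out.rename_axis("cluster").to_csv(path)


def importance_values(
    dataset: CommunityDataset,
    include_control: bool = False,
    pooled_cover_denominator: bool = False,
) -> IVTable:
    """Compute the species x transect IV table from plot records.

    Counts, plot occurrences and covers are summed across a transect's
    plots before ratio-taking (per-plot ratios averaged afterwards would
    not sum to 1 over species).  By default relative cover uses the
    per-plot total vegetation cover as denominator; with
    ``pooled_cover_denominator`` the summed per-species covers are used
    instead.  Control (CK) transects are excluded unless requested.
    """
    dataset.validate(permissive_cover_only=True)
    transect_ids = dataset.transect_ids(include_control=include_control)
    species = list(dataset.species_registry)
    if not transect_ids:
        raise ValueError("dataset has no non-control transects")

    Rd = pd.DataFrame(0.0, index=species, columns=transect_ids)
    Rf = pd.DataFrame(0.0, index=species, columns=transect_ids)
    Rc = pd.DataFrame(0.0, index=species, columns=transect_ids)

    for tid in transect_ids:
        plots = dataset.plots_for(tid)
        if not plots:
            raise DegenerateTransectError(f"transect {tid}: no plots surveyed")
        counts = pd.Series(0, index=species, dtype=float)
        occur = pd.Series(0, index=species, dtype=float)
        cover = pd.Series(0.0, index=species, dtype=float)
        total_cover = 0.0
        for p in plots:
            for sp, c in p.counts.items():
                counts[sp] += c
            for sp in p.species:
                if p.counts.get(sp, 0) > 0 or p.covers.get(sp, 0.0) > 0:
                    occur[sp] += 1
            for sp, cv in p.covers.items():
                cover[sp] += cv
            total_cover += p.total_cover

        D = counts.sum()
        if D <= 0:
            raise DegenerateTransectError(f"transect {tid}: zero total individuals")
        F = occur.sum()
        C = cover.sum() if pooled_cover_denominator else total_cover
        if C <= 0:
            raise DegenerateTransectError(
                f"transect {tid}: zero total cover with nonzero counts"
            )
        Rd[tid] = counts / D
        Rf[tid] = occur / F
        # Rc sums to 1 only when the total equals the species-cover sum
        # (no canopy overlap); with overlapping covers it falls short.
        Rc[tid] = cover / C

    IV = (Rd + Rf + Rc) / 3.0
    return IVTable(Rd=Rd, Rf=Rf, Rc=Rc, IV=IV)


def drop_all_zero_species(iv: IVTable) -> IVTable:
    """Remove species whose IV is 0 in every transect (unplaceable by clustering)."""
    mask = (iv.IV != 0).any(axis=1)
    dropped = list(iv.IV.index[~mask])
    if dropped:
        logger.warning("dropping %d all-zero species before clustering: %s",
                       len(dropped), dropped)
    return IVTable(Rd=iv.Rd.loc[mask], Rf=iv.Rf.loc[mask],
                   Rc=iv.Rc.loc[mask], IV=iv.IV.loc[mask], clusters=iv.clusters)


def _cluster_map(clustering) -> dict[str, list[str]]:
    if isinstance(clustering, Mapping):
        return {str(k): list(v) for k, v in clustering.items()}
    # SpeciesClustering-like object
    return {str(k): list(v) for k, v in clustering.cluster_members().items()}


def integrated_iv(iv: IVTable, clustering) -> IIVTable:
    """IIV per cluster and transect: the mean IV of member species.

    ``clustering`` is either a mapping ``label -> member species`` or a
    ``SpeciesClustering``.  Members absent from a transect contribute an
    IV of 0 (they are part of the cluster's potential composition), which
    is why the mean is taken over all members, not only those present.
    """
    clusters = _cluster_map(clustering)
    rows = {}
    for label, members in clusters.items():
        if not members:
            raise ValueError(f"cluster {label!r} is empty")
        missing = [m for m in members if m not in iv.IV.index]
        if missing:
            raise KeyError(f"cluster {label!r} members not in IV table: {missing}")
        rows[label] = iv.IV.loc[members].mean(axis=0)
    return IIVTable(clusters=clusters, IIV=pd.DataFrame(rows).T[iv.IV.columns])


def group_iiv(iiv: IIVTable, groups) -> pd.DataFrame:
    """Group x transect IIV: the sum of member clusters' IIVs.

    ``groups`` is a mapping ``cluster label -> group label`` (e.g. a
    ``GroupAssignment.mapping``); every cluster must be assigned.
    """
    mapping = getattr(groups, "mapping", groups)
    unassigned = [c for c in iiv.labels if c not in mapping]
    if unassigned:
        raise ValueError(f"clusters not assigned to any group: {unassigned}")
    by_group = pd.Series({c: mapping[c] for c in iiv.labels}, name="group")
    out = iiv.IIV.groupby(by_group).sum()
    return out.sort_index()
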