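"""Response groups and effect-extent inference.

Species clusters are mapped onto three disturbance-response groups:

* **G1** — disturbance-promoted pioneers: rare in the intact community,
  dominant near the construction corridor, IIV decreasing outward.
* **G2** — disturbance-suppressed original dominants (the *indicator
  group*): IIV low near the corridor, recovering outward.
* **G3** — accompanying species: everything else.

On the G2 trajectory the distance at which the IIV settles into a band
around its far-field level is **K2**, the headline effect extent; the
same statistic on G1 gives **K1**.  **K3** is the half-open interval
between the last transect where G1 still dominates G2 and the first
where G2 overtakes it — the edge-effect transition zone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import Transect, Zone
from .importance import IIVTable, group_iiv

__all__ = [
    "GroupParams",
    "StabilizationParams",
    "GroupAssignment",
    "CrossingInterval",
    "StabilizationResult",
    "ExtentEstimate",
    "assign_groups",
    "detect_stabilization",
    "crossing_interval",
    "effect_extent",
    "indicator_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class GroupParams:
    """Thresholds of the G1/G2/G3 classification rule.

    ``near_max_distance_m`` bounds the near zone (working-area,
    inter-pipeline and distance transects up to this distance);
    ``far_window`` counts the outermost distance transects averaged as
    the far field (CK replaces them when surveyed).  ``ratio`` is the
    dominance ratio between zone means, ``trend_rho`` the minimum
    absolute Spearman rank correlation of IIV against distance, and
    ``dominance_floor`` the minimum *share* of the zone's summed
    cluster IIVs a cluster must carry to count as dominant there
    (a share rather than an absolute level keeps the rule scale-free;
    it keeps sparse accompanying species out of G2).
    """

    near_max_distance_m: float = 50.0
    far_window: int = 3
    ratio: float = 1.5
    trend_rho: float = 0.5
    dominance_floor: float = 0.2
    metric_distance: bool = False  # Pearson on metres instead of rank trend


@dataclass
class StabilizationParams:
    """Plateau rule: K = first distance from which the trajectory stays
    within ``tolerance`` x reference of the far-field reference (mean of
    the ``far_window`` outermost values, or CK)."""

    far_window: int = 3
    tolerance: float = 0.15


@dataclass
class GroupAssignment:
    """Cluster -> group mapping plus the diagnostics that produced it."""

    mapping: dict[str, str]
    diagnostics: pd.DataFrame
    params: GroupParams

    def clusters_in(self, group: str) -> list[str]:
        return [c for c, g in self.mapping.items() if g == group]


@dataclass
class StabilizationResult:
    K: float | None
    resolved: bool
    reference: float
    band: tuple[float, float]
    params: StabilizationParams


@dataclass
class CrossingInterval:
    """Half-open interval (lower, upper] bracketing the dominance change."""

    lower: float | None
    upper: float | None
    empty: bool = False
    dominant: str | None = None  # when empty: which series dominates throughout
    warnings: list[str] = field(default_factory=list)

    def as_tuple(self) -> tuple[float | None, float | None]:
        return (self.lower, self.upper)


@dataclass
class ExtentEstimate:
    K1: StabilizationResult | None
    K2: StabilizationResult
    K3: CrossingInterval
    groups: GroupAssignment
    params: StabilizationParams
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers


def _distance_transects(layout: Sequence[Transect]) -> list[Transect]:
    return sorted((t for t in layout if t.zone is Zone.DISTANCE),
                  key=lambda t: t.distance_m)


def _near_ids(layout: Sequence[Transect], near_max: float) -> list[str]:
    return [
        t.transect_id
        for t in layout
        if t.zone in (Zone.PIPELINE_AREA, Zone.INTER_PIPELINE)
        or (t.zone is Zone.DISTANCE and t.distance_m <= near_max)
    ]


def _far_reference_ids(layout: Sequence[Transect], far_window: int,
                       available: Sequence[str]) -> list[str]:
    ck = [t.transect_id for t in layout
          if t.zone is Zone.CONTROL and t.transect_id in available]
    if ck:
        return ck
    dist = [t.transect_id for t in _distance_transects(layout)
            if t.transect_id in available]
    return dist[-far_window:]


# ---------------------------------------------------------------------------
# Group assignment


def assign_groups(
    iiv: IIVTable,
    layout: Sequence[Transect],
    params: GroupParams | None = None,
) -> GroupAssignment:
    """Classify each cluster as G1, G2 or G3 from its IIV trajectory.

    A cluster is G1 when its near-zone mean IIV dominates the far zone
    (ratio and floor) and its trend along the distance transects falls;
    G2 when the far zone dominates and the trend rises; otherwise G3.
    The rule is scale-free: multiplying every IIV by a positive constant
    changes nothing.
    """
    params = params or GroupParams()
    dist = [t for t in _distance_transects(layout) if t.transect_id in iiv.transects]
    if len(dist) < 2:
        raise ValueError("need at least 2 distance transects to assign groups")
    near_ids = [t for t in _near_ids(layout, params.near_max_distance_m)
                if t in iiv.transects]
    far_ids = _far_reference_ids(layout, params.far_window, iiv.transects)
    if not near_ids or not far_ids:
        raise ValueError("IIV table does not span near and far zones")

    distances = np.array([t.distance_m for t in dist])
    near_total = float(iiv.IIV[near_ids].mean(axis=1).sum())
    far_total = float(iiv.IIV[far_ids].mean(axis=1).sum())
    rows, mapping = [], {}
    for label in iiv.labels:
        series = iiv.IIV.loc[label]
        near = float(series[near_ids].mean())
        far = float(series[far_ids].mean())
        near_share = near / near_total if near_total > 0 else 0.0
        far_share = far / far_total if far_total > 0 else 0.0
        y = series[[t.transect_id for t in dist]].to_numpy(float)
        if np.ptp(y) == 0:
            rho = 0.0
        elif params.metric_distance:
            rho = float(stats.pearsonr(distances, y)[0])
        else:
            rho = float(stats.spearmanr(distances, y)[0])
        is_g1 = (near >= params.ratio * far
                 and near_share >= params.dominance_floor
                 and rho <= -params.trend_rho)
        is_g2 = (far >= params.ratio * near
                 and far_share >= params.dominance_floor
                 and rho >= params.trend_rho)
        group = "G1" if is_g1 else "G2" if is_g2 else "G3"
        mapping[label] = group
        rows.append({"cluster": label, "group": group, "near_mean": near,
                     "far_mean": far, "near_share": near_share,
                     "far_share": far_share, "trend_rho": rho,
                     "near_dominant": is_g1, "far_dominant": is_g2})
    diagnostics = pd.DataFrame(rows).set_index("cluster")
    return GroupAssignment(mapping=mapping, diagnostics=diagnostics, params=params)


# ---------------------------------------------------------------------------
# K points


def detect_stabilization(
    series: Sequence[float],
    distances: Sequence[float],
    params: StabilizationParams | None = None,
    reference: float | None = None,
) -> StabilizationResult:
    """Smallest distance from which the trajectory stays in the far-field band.

    The reference level is the mean of the ``far_window`` outermost
    values (or an externally supplied far-field value, e.g. from CK
    plots); the band is ``reference * (1 +/- tolerance)``.  K is the
    smallest surveyed distance d* such that every value at distance >=
    d* lies inside the band; a constant series gives the nearest
    distance, and a trajectory that never settles is flagged unresolved.
    """
    params = params or StabilizationParams()
    y = np.asarray(series, float)
    d = np.asarray(distances, float)
    if y.shape != d.shape or y.ndim != 1:
        raise ValueError("series and distances must be 1-d and equally long")
    if len(y) < params.far_window + 1:
        raise ValueError(
            f"need at least far_window + 1 = {params.far_window + 1} transects"
        )
    if np.any(np.diff(d) <= 0):
        raise ValueError("distances must be strictly increasing")
    if reference is None:
        reference = float(y[-params.far_window:].mean())
    if reference == 0:
        if np.any(y != 0):
            raise ValueError("far-field reference is 0 but the series is not")
        band = (0.0, 0.0)
        return StabilizationResult(float(d[0]), True, 0.0, band, params)
    half = params.tolerance * abs(reference)
    band = (reference - half, reference + half)
    inside = (y >= band[0]) & (y <= band[1])
    # suffix scan: first index from which everything stays inside
    ok_from = None
    for i in range(len(y) - 1, -1, -1):
        if not inside[i]:
            break
        ok_from = i
    if ok_from is None:
        return StabilizationResult(None, False, reference, band, params)
    return StabilizationResult(float(d[ok_from]), True, reference, band, params)


def crossing_interval(
    g1_series: Sequence[float],
    g2_series: Sequence[float],
    distances: Sequence[float] | Sequence[str],
) -> CrossingInterval:
    """Locate where the suppressed dominants (G2) overtake the pioneers (G1).

    Scanning outward, the first position with G2 strictly above G1 closes
    the half-open interval ``(previous position, that position]``.  With
    no sign change an empty interval is returned together with which
    series dominates throughout; multiple sign changes return the first
    with a warning.
    """
    a = np.asarray(g1_series, float)
    b = np.asarray(g2_series, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-d and equally long")
    if len(distances) != len(a):
        raise ValueError("distances must match the series length")
    above = b > a
    if above.all():
        return CrossingInterval(None, None, empty=True, dominant="G2")
    if not above.any():
        return CrossingInterval(None, None, empty=True, dominant="G1")
    rising = [i for i in range(1, len(above)) if above[i] and not above[i - 1]]
    warns = []
    if above[0]:
        warns.append("series starts G2-dominant before the corridor-side scan")
    if not rising:
        # G2 dominates only an initial stretch: no outward takeover
        return CrossingInterval(None, None, empty=True, dominant="G1",
                                warnings=warns)
    if len(rising) > 1 or above[0]:
        flips = int(np.count_nonzero(np.diff(above.astype(int))))
        warns.append(f"dominance changes {flips} times; reporting the first "
                     "outward crossing")
    first = rising[0]
    return CrossingInterval(_pos(distances, first - 1), _pos(distances, first),
                            warnings=warns)


def _pos(distances, i):
    v = distances[i]
    return float(v) if isinstance(v, (int, float, np.floating, np.integer)) else v


def effect_extent(
    iiv: IIVTable,
    groups: GroupAssignment,
    layout: Sequence[Transect],
    params: StabilizationParams | None = None,
) -> ExtentEstimate:
    """K1, K2 and K3 from the grouped IIV trajectories.

    Group trajectories are the *sums* of member-cluster IIVs.  K2, the
    stabilization distance of the indicator group G2, is the headline
    effect extent; a note is attached when it disagrees with the K3
    crossover by one transect (a transition zone worth reporting, since
    plateau detection and dominance change need not coincide).
    """
    params = params or StabilizationParams()
    if not groups.clusters_in("G2"):
        raise ValueError("no indicator group: no cluster was assigned to G2")
    gm = group_iiv(iiv, groups)
    dist = [t for t in _distance_transects(layout) if t.transect_id in iiv.transects]
    if len(dist) < params.far_window + 1:
        raise ValueError("not enough distance transects for stabilization")
    ids = [t.transect_id for t in dist]
    d = [t.distance_m for t in dist]

    def series(group: str) -> np.ndarray:
        if group in gm.index:
            return gm.loc[group, ids].to_numpy(float)
        return np.zeros(len(ids))

    g1, g2 = series("G1"), series("G2")
    K2 = detect_stabilization(g2, d, params)
    K1 = detect_stabilization(g1, d, params) if groups.clusters_in("G1") else None

    ordered = [t.transect_id for t in layout if t.transect_id in iiv.transects
               and t.zone is not Zone.CONTROL]
    full_g1 = (gm.loc["G1", ordered].to_numpy(float) if "G1" in gm.index
               else np.zeros(len(ordered)))
    full_g2 = gm.loc["G2", ordered].to_numpy(float)
    labels = [_transect_position(t) for t in layout
              if t.transect_id in ordered]
    K3 = crossing_interval(full_g1, full_g2, labels)

    notes = []
    if K2.resolved and not K3.empty and K3.upper is not None:
        k3_upper = K3.upper if isinstance(K3.upper, float) else None
        if k3_upper is not None and K2.K != k3_upper:
            notes.append(
                "transition zone: the G2 stabilization distance "
                f"({K2.K:g} m) and the G1/G2 crossover ({k3_upper:g} m) "
                "disagree; the belt between them deserves attention"
            )
    if not K2.resolved:
        notes.append("K2 unresolved: the G2 trajectory never settles inside "
                     "the survey; the effect extends beyond the outermost transect")
    return ExtentEstimate(K1=K1, K2=K2, K3=K3, groups=groups, params=params,
                          notes=notes)


def _transect_position(t: Transect) -> float:
    # corridor transects sit at distance 0; distance transects at their metre mark
    return float(t.distance_m)


# ---------------------------------------------------------------------------
# Indicator validation


def indicator_correlation(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Pearson r between two series with a two-sided permutation p-value.

    One series is shuffled ``n_perm`` times; the p-value is the add-one
    corrected share of permutations with ``|r| >= |r_observed|``.  Used
    to validate that the indicator group's IIV tracks community indices
    (cover, richness) across plots or transects.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("series must be 1-d, equal length, n >= 3")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a series; correlation undefined")
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    n = len(x)
    r_obs = float(np.dot(xc, yc) / n)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(yc, (n_perm, 1)), axis=1)
    r_perm = perms @ xc / n
    exceed = int(np.count_nonzero(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    p = (1 + exceed) / (n_perm + 1)
    return r_obs, p
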