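"""Divisive classification by a modified TWINSPAN.

Classical two-way indicator species analysis (Hill 1979) classifies the
rows of an abundance matrix hierarchically: quantitative abundances are
expanded into binary *pseudospecies* at ascending cut levels, the rows
are ordered on the first correspondence-analysis (CA) axis obtained by
reciprocal averaging, the axis is split near its middle, and the split
is polished with indicator pseudospecies preferential to one side.  The
modification of Roleček et al. (2009) changes only the order of
divisions: instead of dividing every cluster level by level, the
currently most heterogeneous cluster is divided next, which yields flat
partitions at any requested cluster count.

Here the items being classified are *species*, described by their
importance-value profiles across belt transects, which is the form
needed to recognise disturbance-response groups; the code is agnostic
and classifies whatever the rows of the profile matrix are.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "TwinspanParams",
    "PseudospeciesMatrix",
    "Division",
    "SpeciesClustering",
    "DegenerateMatrixError",
    "ConvergenceError",
    "to_pseudospecies",
    "ca_first_axis",
    "divide",
    "modified_twinspan",
    "DEFAULT_CUT_LEVELS",
]

logger = logging.getLogger(__name__)

#: Hill's classic percent cut levels 0/2/5/10/20 rescaled to the 0-1
#: range of importance values, extended with a dominance level at 0.30.
#: IVs are compositional (a transect's values sum to 1), so an IV above
#: 0.3 marks a species carrying about a third of the community's
#: importance; without a cut in that range the binary representation
#: cannot see dominance shifts, which are exactly the signal that
#: separates disturbance-promoted from disturbance-suppressed species.
DEFAULT_CUT_LEVELS: tuple[float, ...] = (0.0, 0.02, 0.05, 0.10, 0.20, 0.30)


class DegenerateMatrixError(ValueError):
    """The matrix carries no usable gradient (identical or empty rows)."""


class ConvergenceError(RuntimeError):
    """Reciprocal averaging failed to converge."""


@dataclass
class TwinspanParams:
    """Tuning knobs of the divisive classification.

    ``cut_levels`` are the pseudospecies thresholds (ascending, starting
    at 0).  ``max_indicators`` caps how many preferential pseudospecies
    vote during refinement; ``refine_passes`` bounds the polishing
    rounds; ``min_group_size`` is the smallest admissible side of a
    split (1 allows singleton leaves, needed when a lone species forms
    its own branch).  ``heterogeneity`` selects the statistic that picks
    the next cluster to divide: mean pairwise Bray-Curtis dissimilarity
    of the raw profiles (default) or total CA inertia of the
    pseudospecies submatrix.
    """

    cut_levels: tuple[float, ...] = DEFAULT_CUT_LEVELS
    max_indicators: int = 7
    refine_passes: int = 2
    min_group_size: int = 1
    misclassification_threshold: int = 0
    heterogeneity: str = "braycurtis"


@dataclass
class PseudospeciesMatrix:
    """Binary expansion of a profile matrix at ascending cut levels."""

    X: np.ndarray  # items x pseudospecies, values in {0, 1}
    row_labels: list[str]
    col_labels: list[tuple[str, float]]  # (attribute, cut level)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


@dataclass
class Division:
    """One dichotomy of a cluster."""

    parent: list[str]
    left: list[str]
    right: list[str]
    scores: dict[str, float]
    indicators: list[tuple[tuple[str, float], int]]  # (pseudospecies, sign)
    eigenvalue: float
    heterogeneity: float


@dataclass
class SpeciesClustering:
    """Dendrogram of divisions plus the flat partition at the stop point.

    ``clusters`` lists terminal clusters in dendrogram order; labels are
    "1", "2", ... in that order.
    """

    divisions: list[Division]
    clusters: list[list[str]]
    requested: int

    def cluster_members(self) -> dict[str, list[str]]:
        return {str(i + 1): list(c) for i, c in enumerate(self.clusters)}

    def assignments(self) -> dict[str, str]:
        return {sp: lab for lab, mem in self.cluster_members().items() for sp in mem}

    def partition(self) -> set[frozenset[str]]:
        """Order-free view of the flat partition, for comparisons."""
        return {frozenset(c) for c in self.clusters}

    def dendrogram_text(self) -> str:
        lines = []
        for i, d in enumerate(self.divisions, 1):
            lines.append(f"division {i} (eigenvalue {d.eigenvalue:.3f}, "
                         f"heterogeneity {d.heterogeneity:.3f})")
            lines.append("  left : " + ", ".join(d.left))
            lines.append("  right: " + ", ".join(d.right))
        lines.append("terminal clusters:")
        for lab, mem in self.cluster_members().items():
            lines.append(f"  {lab}: " + ", ".join(mem))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Pseudospecies


def to_pseudospecies(
    profiles: pd.DataFrame,
    cut_levels: Sequence[float] = DEFAULT_CUT_LEVELS,
) -> PseudospeciesMatrix:
    """Expand a quantitative item x attribute matrix into binary pseudospecies.

    One column per (attribute, cut level); a cell is 1 iff the value
    strictly exceeds the level, so presence at a level implies presence
    at all lower levels (the nested property classical TWINSPAN relies
    on).
    """
    levels = list(cut_levels)
    if not levels or levels[0] != 0:
        raise ValueError("cut_levels must start at 0")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("cut_levels must be strictly ascending")
    values = profiles.to_numpy(dtype=float)
    cols, labels = [], []
    for j, attr in enumerate(profiles.columns):
        for lev in levels:
            cols.append((values[:, j] > lev).astype(float))
            labels.append((str(attr), float(lev)))
    X = np.column_stack(cols) if cols else np.zeros((len(profiles), 0))
    return PseudospeciesMatrix(X=X, row_labels=[str(r) for r in profiles.index],
                               col_labels=labels)


# ---------------------------------------------------------------------------
# Correspondence analysis by reciprocal averaging


def ca_first_axis(
    matrix: PseudospeciesMatrix | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> tuple[np.ndarray, np.ndarray, float]:
    """First non-trivial CA axis of a non-negative matrix.

    Reciprocal averaging: column scores are weighted means of row
    scores and vice versa; each pass the row scores are centred (which
    removes the trivial constant axis) and rescaled to unit weighted
    variance.  The shrinkage factor of the un-rescaled scores converges
    to the axis eigenvalue.  Row scores are returned centred with unit
    weighted variance; the sign is fixed so the first row with nonzero
    weight scores >= 0.

    All-zero columns are ignored; an all-zero row or a rank-deficient
    (e.g. all-rows-identical) matrix raises ``DegenerateMatrixError``.
    """
    X = matrix.X if isinstance(matrix, PseudospeciesMatrix) else np.asarray(matrix, float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise DegenerateMatrixError("matrix must be at least 2 x 2")
    if (X < 0).any():
        raise ValueError("matrix must be non-negative")
    col_keep = X.sum(axis=0) > 0
    Xt = X[:, col_keep]
    r = Xt.sum(axis=1)
    if (r == 0).any():
        raise DegenerateMatrixError("all-zero row after trimming empty columns")
    if Xt.shape[1] < 2 or np.all(Xt == Xt[0], axis=None):
        raise DegenerateMatrixError("no gradient: identical rows")
    c = Xt.sum(axis=0)
    total = Xt.sum()
    w = r / total

    # deterministic start from a fixed seed: a structured start (e.g. an
    # index ramp) can be exactly orthogonal to the leading axis on
    # symmetric matrices and trap the iteration on a minor axis
    u = np.random.default_rng(1979).standard_normal(Xt.shape[0])
    u = _standardize(u, w)
    eig = np.nan
    for _ in range(max_iter):
        v = Xt.T @ u / c
        u_new = Xt @ v / r
        u_new = u_new - np.sum(w * u_new)  # deflate trivial axis
        norm = np.sqrt(np.sum(w * u_new**2))
        if norm < 1e-14:
            raise DegenerateMatrixError("no gradient: axis collapsed to zero")
        eig = norm
        u_new = u_new / norm
        delta = np.max(np.abs(u_new - u))
        u = u_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"reciprocal averaging did not converge (residual {delta:.2e})"
        )

    first = int(np.argmax(r > 0))
    if u[first] < 0:
        u, v = -u, -v
    v = Xt.T @ u / c  # final column scores consistent with returned u

    row_scores = u
    col_scores = np.full(X.shape[1], np.nan)
    col_scores[col_keep] = v
    return row_scores, col_scores, float(eig)


def _standardize(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    u = u - np.sum(w * u)
    sd = np.sqrt(np.sum(w * u**2))
    if sd < 1e-14:
        raise DegenerateMatrixError("no gradient: identical rows")
    return u / sd


# ---------------------------------------------------------------------------
# One dichotomy


def divide(
    items: Sequence[int],
    matrix: PseudospeciesMatrix,
    params: TwinspanParams | None = None,
    heterogeneity: float = float("nan"),
) -> Division | None:
    """Split one cluster (row indices into ``matrix``) into two.

    Rows are ordered on the first CA axis of the cluster's pseudospecies
    submatrix and cut at the axis centroid (score zero - the scores are
    centred, so this is the literal middle); the cut is then refined:
    pseudospecies at least twice as frequent on one side as the other
    are *preferential*, the strongest ``max_indicators`` of them vote on
    each row, and rows whose net indicator score contradicts their side
    are moved.  Returns ``None`` (no-division signal) when the cluster
    is too small or carries no gradient.
    """
    params = params or TwinspanParams()
    items = list(items)
    if len(items) < 2 * params.min_group_size or len(items) < 2:
        return None
    sub = matrix.X[items, :]
    try:
        scores, _, eig = ca_first_axis(sub)
    except DegenerateMatrixError:
        return None

    # crude dichotomy at the centroid: scores are centred to weighted
    # mean zero, so the sign splits the axis at its middle; the boundary
    # slides along the score order only if a side falls below
    # min_group_size
    order = sorted(range(len(items)), key=lambda i: (scores[i], i))
    k = sum(1 for i in range(len(items)) if scores[i] < 0)
    k = min(max(k, params.min_group_size), len(items) - params.min_group_size)
    left = {items[i] for i in order[:k]}
    right = {items[i] for i in order[k:]}

    indicators: list[tuple[tuple[str, float], int]] = []
    for _ in range(params.refine_passes):
        indicators = _preferential(matrix, left, right, params.max_indicators)
        if not indicators:
            break
        moved = False
        new_left, new_right = set(left), set(right)
        for i in items:
            s = sum(sign * matrix.X[i, j] for (j, sign) in _indicator_cols(matrix, indicators))
            if s > params.misclassification_threshold and i in new_left:
                new_left.discard(i); new_right.add(i); moved = True
            elif s < -params.misclassification_threshold and i in new_right:
                new_right.discard(i); new_left.add(i); moved = True
        if (len(new_left) < params.min_group_size
                or len(new_right) < params.min_group_size):
            break  # refinement would empty a side; keep the current split
        left, right = new_left, new_right
        if not moved:
            break

    name = matrix.row_labels
    return Division(
        parent=[name[i] for i in items],
        left=[name[i] for i in items if i in left],
        right=[name[i] for i in items if i in right],
        scores={name[items[i]]: float(scores[i]) for i in range(len(items))},
        indicators=indicators,
        eigenvalue=eig,
        heterogeneity=heterogeneity,
    )


def _indicator_cols(matrix: PseudospeciesMatrix, indicators):
    index = {lab: j for j, lab in enumerate(matrix.col_labels)}
    return [(index[lab], sign) for lab, sign in indicators]


def _preferential(
    matrix: PseudospeciesMatrix,
    left: set[int],
    right: set[int],
    max_indicators: int,
) -> list[tuple[tuple[str, float], int]]:
    """Pseudospecies preferential to one side (frequency ratio >= 2).

    Sign +1 marks right-preferential columns, -1 left-preferential; the
    ``max_indicators`` strongest (largest frequency difference, ties by
    column order) are kept.
    """
    li, ri = sorted(left), sorted(right)
    fl = matrix.X[li, :].mean(axis=0)
    fr = matrix.X[ri, :].mean(axis=0)
    cands: list[tuple[float, int, int]] = []  # (-strength, col, sign)
    for j in range(matrix.X.shape[1]):
        if fl[j] == 0 and fr[j] == 0:
            continue
        if fl[j] >= 2 * fr[j] and fl[j] > 0:
            cands.append((-(fl[j] - fr[j]), j, -1))
        elif fr[j] >= 2 * fl[j] and fr[j] > 0:
            cands.append((-(fr[j] - fl[j]), j, +1))
    cands.sort()
    return [(matrix.col_labels[j], sign) for _, j, sign in cands[:max_indicators]]


# ---------------------------------------------------------------------------
# Division ordering (Roleček modification)


def cluster_heterogeneity(
    profiles: pd.DataFrame,
    members: Sequence[int],
    method: str = "braycurtis",
    pseudo: PseudospeciesMatrix | None = None,
) -> float:
    """Heterogeneity of a cluster of profile rows.

    ``braycurtis`` is the mean pairwise Bray-Curtis dissimilarity of the
    raw profiles; ``ca_inertia`` is the total inertia (sum of chi-square
    distances to the centroid) of the pseudospecies submatrix.
    """
    members = list(members)
    if len(members) < 2:
        return 0.0
    if method == "braycurtis":
        d = pdist(profiles.to_numpy(float)[members, :], metric="braycurtis")
        return float(np.mean(d))
    if method == "ca_inertia":
        if pseudo is None:
            raise ValueError("ca_inertia heterogeneity needs the pseudospecies matrix")
        X = pseudo.X[members, :]
        X = X[:, X.sum(axis=0) > 0]
        if X.size == 0 or X.sum() == 0:
            return 0.0
        P = X / X.sum()
        r = P.sum(axis=1, keepdims=True)
        c = P.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi = (P - r @ c) ** 2 / (r @ c)
        return float(np.nansum(chi))
    raise ValueError(f"unknown heterogeneity method {method!r}")


def modified_twinspan(
    profiles: pd.DataFrame,
    n_clusters: int = 3,
    params: TwinspanParams | None = None,
) -> SpeciesClustering:
    """Divisive classification of profile rows, most heterogeneous cluster first.

    Starting from one cluster holding every row, the cluster with the
    greatest heterogeneity is repeatedly divided until ``n_clusters``
    terminal clusters exist or nothing remains divisible (then a warning
    is emitted and the best-effort partition returned).  Fully
    deterministic: ties break by dendrogram order.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    params = params or TwinspanParams()
    if profiles.index.has_duplicates:
        raise ValueError("profile rows must have unique labels")
    matrix = to_pseudospecies(profiles, params.cut_levels)
    zero_rows = [matrix.row_labels[i] for i in range(len(profiles))
                 if matrix.X[i].sum() == 0]
    if zero_rows:
        raise DegenerateMatrixError(
            f"rows with no pseudospecies presence cannot be classified: {zero_rows}"
        )

    clusters: list[list[int]] = [list(range(len(profiles)))]
    blocked: set[int] = set()  # positions that returned no-division
    divisions: list[Division] = []
    while len(clusters) < n_clusters:
        hets = [
            cluster_heterogeneity(profiles, c, params.heterogeneity, matrix)
            if pos not in blocked and len(c) >= 2 * params.min_group_size
            else -np.inf
            for pos, c in enumerate(clusters)
        ]
        pos = int(np.argmax(hets))
        if not np.isfinite(hets[pos]) or hets[pos] <= 0:
            warnings.warn(
                f"requested {n_clusters} clusters but only {len(clusters)} are "
                "reachable; returning best-effort partition",
                stacklevel=2,
            )
            break
        div = divide(clusters[pos], matrix, params, heterogeneity=hets[pos])
        if div is None:
            blocked.add(pos)
            continue
        divisions.append(div)
        index = {name: i for i, name in enumerate(matrix.row_labels)}
        clusters[pos:pos + 1] = [
            [index[n] for n in div.left],
            [index[n] for n in div.right],
        ]
        blocked = set()  # positions shifted; recompute eligibility

    names = matrix.row_labels
    return SpeciesClustering(
        divisions=divisions,
        clusters=[[names[i] for i in c] for c in clusters],
        requested=n_clusters,
    )
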