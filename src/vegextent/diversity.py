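"""Community indices per plot and per transect.

Shannon-Wiener diversity H, Pielou's evenness, Margalef's richness and
percent cover of vegetation.  The field convention followed here prints
H with base-10 logarithms while evenness divides that same H by the
*natural* log of species number::

    H        = -sum (n_i/N) lg (n_i/N)
    Evenness = H / ln S
    Richness = (S - 1) / ln N

The mixed bases mean Evenness can exceed neither its classical bound nor
interpretation; ``log_base="e"`` restores the classical Pielou index
(H_e / ln S, bounded by 1).
"""

from __future__ import annotations

import math
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .data import CommunityDataset

__all__ = ["shannon", "evenness", "richness", "percent_cover", "diversity_table"]

LogBase = Literal["10", "e", 10]


def _log(x: np.ndarray, log_base: LogBase) -> np.ndarray:
    if str(log_base) == "10":
        return np.log10(x)
    if str(log_base) == "e":
        return np.log(x)
    raise ValueError(f"log_base must be '10' or 'e', got {log_base!r}")


def shannon(abundances: Sequence[float], log_base: LogBase = "10") -> float:
    """Shannon-Wiener H of an abundance vector (zeros ignored).

    Base 10 by default, matching the common 'lg' form of printed surveys;
    pass ``log_base='e'`` for nats.
    """
    n = np.asarray(abundances, dtype=float)
    if (n < 0).any():
        raise ValueError("abundances must be non-negative")
    n = n[n > 0]
    if n.size == 0:
        raise ValueError("at least one abundance must be positive")
    p = n / n.sum()
    return float(-(p * _log(p, log_base)).sum())


def evenness(abundances: Sequence[float], log_base: LogBase = "10") -> float:
    """Pielou's evenness: H divided by ln S (S = 1 returns 0 by convention).

    With the default base-10 H the quotient mixes bases, exactly as the
    index is usually printed; with ``log_base='e'`` it is the classical
    Pielou J bounded by 1.
    """
    n = np.asarray(abundances, dtype=float)
    S = int((n > 0).sum())
    if S <= 1:
        shannon(abundances, log_base)  # raise on all-zero input
        return 0.0
    return shannon(abundances, log_base) / math.log(S)


def richness(S: int, N: int) -> float:
    """Margalef's richness (S - 1)/ln N; 0 when only one species or individual."""
    if S < 1 or N < 1:
        raise ValueError("S and N must be >= 1")
    if S > N:
        raise ValueError(f"S={S} species cannot exceed N={N} individuals")
    if S == 1 or N == 1:
        return 0.0
    return (S - 1) / math.log(N)


def percent_cover(dataset: CommunityDataset, transect_id: str) -> float:
    """Mean total vegetation cover (percent) over a transect's plots."""
    plots = dataset.plots_for(transect_id)
    if not plots:
        raise ValueError(f"transect {transect_id!r} has no plots")
    return float(np.mean([p.total_cover for p in plots]))


def diversity_table(
    dataset: CommunityDataset,
    log_base: LogBase = "10",
    per_plot: bool = False,
    include_control: bool = True,
) -> pd.DataFrame:
    """Indices per transect (pooled over plots) or per plot.

    Pooled mode sums abundances over a transect's plots before computing
    the indices; per-plot mode computes them on each plot separately
    (the sampling unit of plot-level correlation analyses) and reports
    one row per plot.
    """
    rows = []
    if per_plot:
        for p in dataset.plots:
            counts = [c for c in p.counts.values() if c > 0]
            if not counts:
                continue
            S, N = len(counts), int(sum(counts))
            rows.append({
                "plot_id": p.plot_id,
                "transect_id": p.transect_id,
                "H": shannon(counts, log_base),
                "evenness": evenness(counts, log_base),
                "richness": richness(S, N),
                "percent_cover": p.total_cover,
            })
        return pd.DataFrame(rows)

    for tid in dataset.transect_ids(include_control=include_control):
        pooled: dict[str, float] = {}
        for p in dataset.plots_for(tid):
            for sp, c in p.counts.items():
                pooled[sp] = pooled.get(sp, 0) + c
        counts = [c for c in pooled.values() if c > 0]
        if not counts:
            raise ValueError(f"transect {tid!r} has no individuals")
        S, N = len(counts), int(sum(counts))
        rows.append({
            "transect_id": tid,
            "H": shannon(counts, log_base),
            "evenness": evenness(counts, log_base),
            "richness": richness(S, N),
            "percent_cover": percent_cover(dataset, tid),
        })
    return pd.DataFrame(rows).set_index("transect_id")
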