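"""Occurrence-record cleaning.

Presence records from opportunistic databases are spatially redundant and
autocorrelated.  The cleaning chain is: (1) keep a single record per raster
pixel; (2) profile spatial autocorrelation of the local climate at the
records with Moran's I over a ladder of distance lags; (3) thin the records
so no retained pair is closer than the lag that minimizes |I|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .grids import GridSpec

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_world import ClimateStack

__all__ = [
    "OccurrenceSet",
    "MoranProfile",
    "deduplicate_per_pixel",
    "morans_i",
    "moran_profile",
    "thin",
]


@dataclass
class OccurrenceSet:
    """Presence coordinates for one taxon, with per-record provenance."""

    taxon_id: str
    points: np.ndarray
    source: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not self.source:
            self.source = ["unknown"] * len(self.points)
        if len(self.source) != len(self.points):
            raise ValueError("source list length must match the number of points")

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, idx: Sequence[int]) -> "OccurrenceSet":
        idx = list(idx)
        return OccurrenceSet(
            taxon_id=self.taxon_id,
            points=self.points[idx],
            source=[self.source[i] for i in idx],
        )


@dataclass
class MoranProfile:
    """Moran's I against distance lag; NaN marks lags with no qualifying pairs."""

    lags: np.ndarray
    moran_i: np.ndarray
    chosen_lag: float

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.moran_i = np.asarray(self.moran_i, dtype=float)
        if not np.all(np.diff(self.lags) > 0):
            raise ValueError("lags must be strictly increasing")


def deduplicate_per_pixel(occ: OccurrenceSet, spec: GridSpec) -> OccurrenceSet:
    """Keep the first record (input order) in each occupied grid cell."""
    cells = spec.cells_of(occ.points)
    seen: set[tuple[int, int]] = set()
    keep: list[int] = []
    for i, rc in enumerate(map(tuple, cells)):
        if rc not in seen:
            seen.add(rc)
            keep.append(i)
    return occ.subset(keep)


def morans_i(values: np.ndarray, points: np.ndarray, lag: float) -> float:
    """Moran's I with binary weights: w_ij = 1 iff 0 < dist(i, j) <= lag.

    Returns NaN when no pair qualifies; raises on zero variance.
    """
    z = np.asarray(values, dtype=float)
    pts = np.asarray(points, dtype=float)
    n = z.size
    d = squareform(pdist(pts))
    w = (d <= lag) & ~np.eye(n, dtype=bool)
    W = w.sum()
    if W == 0:
        return float("nan")
    zc = z - z.mean()
    denom = (zc**2).sum()
    if denom == 0:
        raise ValueError("Moran's I is undefined for zero-variance values")
    return float((n / W) * (w * np.outer(zc, zc)).sum() / denom)


def _pc1_scores(X: np.ndarray) -> np.ndarray:
    """First principal-component scores of column-standardized predictors."""
    sd = X.std(axis=0)
    ok = sd > 0
    if not ok.any():
        raise ValueError("all predictor values are constant across occurrence points")
    Z = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    return Z @ vt[0]


def moran_profile(
    occ: OccurrenceSet,
    stack: "ClimateStack",
    lags: Optional[Sequence[float]] = None,
) -> MoranProfile:
    """Moran's I of the first climate principal component at the records.

    ``chosen_lag`` is the smallest lag minimizing |I| among lags with at
    least one qualifying pair — the thinning distance at which climate
    autocorrelation among records is weakest.  The default lag ladder spans
    ten equal steps from the cell size to a quarter of the domain diagonal.
    """
    if len(occ) < 5:
        raise ValueError("moran_profile needs at least 5 records")
    spec = stack.spec
    if lags is None:
        lags = np.linspace(spec.cell_size, spec.diagonal / 4.0, 10)
    lags = np.asarray(sorted(lags), dtype=float)
    if lags.size < 2:
        raise ValueError("need at least 2 lags")

    cells = spec.cells_of(occ.points)
    X = np.column_stack(
        [stack.layers[v][cells[:, 0], cells[:, 1]] for v in stack.layer_names]
    )
    z = _pc1_scores(X)
    if z.std() == 0:
        raise ValueError("first principal component has zero variance")

    values = np.array([morans_i(z, occ.points, lag) for lag in lags])
    defined = ~np.isnan(values)
    if not defined.any():
        raise ValueError("no lag has qualifying point pairs")
    abs_i = np.where(defined, np.abs(values), np.inf)
    chosen = float(lags[int(np.argmin(abs_i))])  # argmin takes the smallest lag on ties
    return MoranProfile(lags=lags, moran_i=values, chosen_lag=chosen)


def thin(
    occ: OccurrenceSet,
    min_distance: float,
    n_restarts: int = 10,
    seed: int = 0,
) -> OccurrenceSet:
    """Spatial thinning: retain a large subset with no pair closer than
    ``min_distance``.

    Randomized greedy with restarts (the spThin strategy): repeatedly discard
    a record from the currently most-crowded neighborhood, breaking ties
    uniformly at random; over ``n_restarts`` runs the one retaining the most
    records wins (first such run on ties).  Deterministic under a fixed seed.
    """
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    n = len(occ)
    if min_distance == 0 or n <= 1:
        return occ
    d = squareform(pdist(occ.points))
    conflict = (d < min_distance) & ~np.eye(n, dtype=bool)
    if not conflict.any():
        return occ

    rng = np.random.default_rng([seed, 71])
    best: Optional[np.ndarray] = None
    for _ in range(max(1, n_restarts)):
        alive = np.ones(n, dtype=bool)
        adj = conflict.copy()
        while True:
            degree = adj.sum(axis=1)
            dmax = degree.max()
            if dmax == 0:
                break
            ties = np.flatnonzero(degree == dmax)
            drop = ties[rng.integers(len(ties))]
            alive[drop] = False
            adj[drop, :] = False
            adj[:, drop] = False
        if best is None or alive.sum() > best.sum():
            best = alive
    return occ.subset(np.flatnonzero(best))
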