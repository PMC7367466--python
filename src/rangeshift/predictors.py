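"""Predictor collinearity screening.

Bioclimatic layers are strongly collinear; models are fitted on a subset in
which no retained pair exceeds a pairwise Pearson threshold (|r| > 0.8 drops
a member of the pair).  Which member survives is set by a caller-supplied
priority order, so a published selection can be reproduced exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_world import ClimateStack

__all__ = [
    "CorrelationMatrix",
    "pearson_matrix",
    "select_uncorrelated",
    "load_synthetic_bioclim19",
]


@dataclass
class CorrelationMatrix:
    """Labeled symmetric matrix of pairwise Pearson coefficients.

    Undefined entries (zero-variance layers) are NaN.
    """

    variable_names: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variable_names)
        if self.r.shape != (k, k):
            raise ValueError("correlation matrix shape does not match labels")
        finite = ~np.isnan(self.r)
        if not np.allclose(self.r[finite.T & finite], self.r.T[finite.T & finite]):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-9:
            raise ValueError("|r| must not exceed 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variable_names, columns=self.variable_names)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrelationMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(variable_names=list(df.columns), r=df.to_numpy(dtype=float))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def pearson_matrix(
    stack: "ClimateStack",
    sample_cells: Optional[int] = None,
    seed: int = 0,
) -> CorrelationMatrix:
    """Pairwise Pearson correlations between stack layers over valid cells.

    ``sample_cells`` caps the number of cells used (uniform random subsample,
    seeded); by default all jointly valid cells enter.  A zero-variance layer
    gets NaN correlations and a warning.
    """
    names = stack.layer_names
    if len(names) < 2:
        raise ValueError("need at least 2 layers")
    X = stack.as_matrix(names)
    valid = ~np.isnan(X).any(axis=1)
    X = X[valid]
    if X.shape[0] < 3:
        raise ValueError("need at least 3 jointly valid cells")
    if sample_cells is not None and sample_cells < X.shape[0]:
        rng = np.random.default_rng([seed, 83])
        X = X[rng.choice(X.shape[0], size=sample_cells, replace=False)]

    sd = X.std(axis=0)
    degenerate = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    if degenerate.size:
        bad = [names[i] for i in degenerate]
        warnings.warn(f"zero-variance layer(s) {bad}: correlations undefined", stacklevel=2)
        r[degenerate, :] = np.nan
        r[:, degenerate] = np.nan
    return CorrelationMatrix(variable_names=names, r=r)


def select_uncorrelated(
    cm: CorrelationMatrix,
    threshold: float = 0.8,
    priority: Optional[Sequence[str]] = None,
) -> list[str]:
    """Greedy low-collinearity subset in priority order.

    A variable is kept iff |r| <= threshold against every already-kept
    variable (|r| exactly at the threshold survives — only strictly higher
    correlation drops a variable).  Undefined (NaN) correlations are treated
    as violations.  The returned list preserves priority order.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    names = cm.variable_names
    if priority is None:
        priority = list(names)
    if sorted(priority) != sorted(names):
        raise ValueError("priority must be a permutation of the variable names")
    idx = {v: i for i, v in enumerate(names)}
    kept: list[str] = []
    for v in priority:
        ok = True
        for u in kept:
            rij = cm.r[idx[v], idx[u]]
            if np.isnan(rij) or abs(rij) > threshold:
                ok = False
                break
        if ok:
            kept.append(v)
    return kept


def load_synthetic_bioclim19() -> CorrelationMatrix:
    """Packaged synthetic 19-variable bioclim correlation matrix.

    A stand-in (not observed data) built from a seeded 5-factor latent model:
    screening it at |r| > 0.8 with the five canonical roles first retains
    exactly bio1, bio3, bio4, bio12, bio13.
    """
    with resources.files("rangeshift.data").joinpath(
        "synthetic_bioclim19_correlation.csv"
    ).open() as fh:
        df = pd.read_csv(fh, index_col=0)
    return CorrelationMatrix(variable_names=list(df.columns), r=df.to_numpy(dtype=float))
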