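"""Suitability, range, dispersal and richness map carriers.

These are thin typed wrappers over :class:`~rangeshift.grids.Grid` that record
the provenance every downstream accounting step needs: which taxon, which
scenario, which threshold, which members were averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grids import Grid, GridSpec

__all__ = [
    "ScenarioSpec",
    "SuitabilityMap",
    "DispersalLayer",
    "BinaryRangeMap",
    "RichnessMap",
]

_CLIMATES = {"current", "rcp45", "rcp85"}
_DEFOREST = {"current", "GOV", "BAU"}
_DISPERSAL = {"unlimited", "limited", "none"}

# the two future pairings the study design allows
_PAIRING = {"rcp45": "GOV", "rcp85": "BAU"}


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the scenario matrix.

    Future climates pair strictly: the mitigation scenario is (rcp45, GOV),
    the business-as-usual scenario is (rcp85, BAU).  The present pairs only
    with current forest cover.
    """

    climate: str = "current"
    deforestation: str = "current"
    dispersal: str = "unlimited"
    horizon_label: str = "present"

    def __post_init__(self) -> None:
        if self.climate not in _CLIMATES:
            raise ValueError(f"unknown climate {self.climate!r}")
        if self.deforestation not in _DEFOREST:
            raise ValueError(f"unknown deforestation scenario {self.deforestation!r}")
        if self.dispersal not in _DISPERSAL:
            raise ValueError(f"unknown dispersal mode {self.dispersal!r}")
        if self.climate == "current":
            if self.deforestation != "current" or self.horizon_label != "present":
                raise ValueError("current climate pairs only with current forest, present horizon")
        else:
            if self.deforestation != _PAIRING[self.climate]:
                raise ValueError(
                    f"climate {self.climate} pairs with deforestation "
                    f"{_PAIRING[self.climate]}, got {self.deforestation}"
                )
            if self.horizon_label != "2050":
                raise ValueError("future climates use the 2050 horizon")

    @property
    def label(self) -> str:
        if self.climate == "current":
            return "present"
        name = "mitigation" if self.climate == "rcp45" else "bau"
        return f"{name}_{self.dispersal}"


@dataclass
class SuitabilityMap:
    """Continuous habitat suitability in [0, 1] on a grid."""

    grid: Grid
    taxon_id: str = ""
    scenario_tag: str = "current"
    provenance: list = field(default_factory=list)

    @property
    def spec(self) -> GridSpec:
        return self.grid.spec

    def __post_init__(self) -> None:
        vals = self.grid.values()
        if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")


@dataclass
class DispersalLayer:
    """Min-max normalized cumulative distance to all occurrences.

    Low values mark the occupied core; 1 marks the farthest valid cell.  Used
    as an extra predictor to express dispersal limitation inside the model.
    """

    grid: Grid
    kind: str = "cumulative-distance"
    normalization: str = "minmax"

    @property
    def spec(self) -> GridSpec:
        return self.grid.spec


@dataclass
class BinaryRangeMap:
    """Thresholded (boolean) range map with its accounting metadata."""

    grid: Grid
    taxon_id: str = ""
    scenario: Optional[ScenarioSpec] = None
    threshold: float = 0.5
    from_dispersal_fit: bool = False

    def __post_init__(self) -> None:
        if self.grid.data.dtype != bool:
            self.grid = Grid(self.grid.spec, self.grid.data.astype(bool))

    @property
    def spec(self) -> GridSpec:
        return self.grid.spec

    @property
    def suitable_cell_count(self) -> int:
        return int(self.grid.data.sum())

    def replace_grid(self, data: np.ndarray, scenario: Optional[ScenarioSpec] = None) -> "BinaryRangeMap":
        return BinaryRangeMap(
            grid=Grid(self.spec, data.astype(bool)),
            taxon_id=self.taxon_id,
            scenario=scenario if scenario is not None else self.scenario,
            threshold=self.threshold,
            from_dispersal_fit=self.from_dispersal_fit,
        )


@dataclass
class RichnessMap:
    """Stacked-SDM species richness: cellwise count of predicted presences."""

    grid: Grid
    scenario: Optional[ScenarioSpec]
    n_taxa: int

    def __post_init__(self) -> None:
        data = self.grid.data
        if data.min() < 0 or data.max() > self.n_taxa:
            raise ValueError("richness must lie in [0, n_taxa]")
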