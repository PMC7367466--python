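"""Habitat-change accounting and richness stacking.

Turns per-taxon binary range maps into the taxa × scenario table of percent
area change (loss negative, bounded below by −100), computes the summary
statistics and threshold counts reported from such tables, and stacks binary
maps into species-richness surfaces.  Area is the suitable-cell count on the
uniform grid, so percentages are resolution-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .grids import Grid
from .maps import BinaryRangeMap, RichnessMap, ScenarioSpec

__all__ = [
    "SCENARIO_COLUMNS",
    "ChangeTable",
    "area_change_percent",
    "build_change_table",
    "SummaryMean",
    "summarize_mean",
    "count_rows_where",
    "stack_richness",
    "load_table2_transcription",
    "round_half_up",
]

# column order of the six future scenarios: mitigation = (rcp45, GOV),
# business-as-usual = (rcp85, BAU), each under three dispersal frameworks
SCENARIO_COLUMNS = [
    "mitigation_unlimited",
    "mitigation_limited",
    "mitigation_none",
    "bau_unlimited",
    "bau_limited",
    "bau_none",
]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), matching printed tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ChangeTable:
    """Taxa × scenario matrix of percent area change (negative = loss)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy(dtype=float)
        if np.nanmin(vals) < -100 - 1e-9:
            raise ValueError("percent change cannot fall below -100")

    @property
    def taxa(self) -> list[str]:
        return list(self.frame.index)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChangeTable":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path)


def area_change_percent(current: BinaryRangeMap, future: BinaryRangeMap) -> float:
    """Percent change of suitable area, ``100·(A_future − A_current)/A_current``,
    reported to two decimals (half-up).  Undefined for empty current ranges."""
    if current.spec != future.spec:
        raise ValueError("current and future maps must share a grid geometry")
    a_cur = current.suitable_cell_count
    if a_cur == 0:
        raise ValueError(
            f"taxon {current.taxon_id!r} has zero current area; percent change undefined"
        )
    a_fut = future.suitable_cell_count
    return round_half_up(100.0 * (a_fut - a_cur) / a_cur, 2)


CurrentMaps = Mapping[str, Union[BinaryRangeMap, Mapping[str, BinaryRangeMap]]]


def build_change_table(
    current_maps: CurrentMaps,
    future_maps: Mapping[str, Mapping[str, BinaryRangeMap]],
    columns: Sequence[str] = SCENARIO_COLUMNS,
) -> ChangeTable:
    """Assemble the change table from per-taxon range maps.

    ``current_maps[taxon]`` is either one baseline map or a per-column
    mapping (a dispersal-constrained fit carries its own current baseline).
    Missing maps raise an error naming taxon and scenario.
    """
    rows = {}
    for taxon, futures in future_maps.items():
        if taxon not in current_maps:
            raise KeyError(f"missing current map for taxon {taxon!r}")
        row = {}
        for col in columns:
            if col not in futures:
                raise KeyError(f"missing scenario map {col!r} for taxon {taxon!r}")
            cur = current_maps[taxon]
            if isinstance(cur, Mapping):
                if col not in cur:
                    raise KeyError(f"missing current baseline {col!r} for taxon {taxon!r}")
                cur = cur[col]
            row[col] = area_change_percent(cur, futures[col])
        rows[taxon] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")[list(columns)]
    return ChangeTable(frame)


@dataclass
class SummaryMean:
    """Mean percent change over a table block, signed and as a printed loss."""

    signed: float
    loss_magnitude: float
    n_cells: int


def summarize_mean(
    table: ChangeTable,
    rows: Optional[Sequence[str]] = None,
    cols: Optional[Sequence[str]] = None,
    rounding: int = 2,
) -> SummaryMean:
    """Arithmetic mean of the selected cells.

    Returns the unrounded signed mean plus the loss magnitude (its negation)
    rounded half-up to ``rounding`` decimals, the convention of prose like
    "an average loss of 73.80%".
    """
    sub = table.frame
    if rows is not None:
        if len(rows) == 0:
            raise ValueError("empty row selection")
        sub = sub.loc[list(rows)]
    if cols is not None:
        if len(cols) == 0:
            raise ValueError("empty column selection")
        sub = sub[list(cols)]
    vals = sub.to_numpy(dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("empty selection")
    signed = float(vals.mean())
    return SummaryMean(
        signed=signed,
        loss_magnitude=round_half_up(-signed, rounding),
        n_cells=vals.size,
    )


def count_rows_where(
    table: ChangeTable,
    cols: Sequence[str],
    predicate: str,
    x: float = 0.0,
) -> int:
    """Number of taxa whose selected cells all satisfy the predicate.

    * ``"loss_gt"``   — change < −x (lost more than x percent);
    * ``"gain_gt"``   — change > x (gained area);
    * ``"loss_ge_all"`` — change ≤ −x in every selected column (alias kept
      for readability when several columns are scanned).
    """
    if len(cols) == 0:
        raise ValueError("empty column selection")
    sub = table.frame[list(cols)].to_numpy(dtype=float)
    if predicate == "loss_gt":
        hit = (sub < -x).all(axis=1)
    elif predicate == "gain_gt":
        hit = (sub > x).all(axis=1)
    elif predicate == "loss_ge_all":
        hit = (sub <= -x).all(axis=1)
    else:
        raise ValueError(f"unknown predicate {predicate!r}")
    return int(hit.sum())


def stack_richness(ranges: Sequence[BinaryRangeMap]) -> RichnessMap:
    """Stacked-SDM richness: cellwise integer sum of one scenario's binary
    range maps."""
    if len(ranges) == 0:
        raise ValueError("richness stack needs at least one range map")
    spec = ranges[0].spec
    scen = ranges[0].scenario
    for r in ranges[1:]:
        if r.spec != spec:
            raise ValueError("range maps must share a grid geometry")
        if r.scenario != scen:
            raise ValueError("richness stacks one scenario at a time")
    total = np.sum([r.grid.data.astype(int) for r in ranges], axis=0)
    return RichnessMap(grid=Grid(spec, total), scenario=scen, n_taxa=len(ranges))


def load_table2_transcription() -> ChangeTable:
    """Packaged transcription of the published 15-taxa × 6-scenario table of
    percent habitat change (the worked-example input)."""
    with resources.files("rangeshift.data").joinpath("table2_transcription.csv").open() as fh:
        return ChangeTable(pd.read_csv(fh, index_col=0))
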