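"""Scenario projection.

Projects a fitted ensemble onto climate stacks, averages emulated-GCM
realizations into a consensus surface, binarizes at the taxon's
current-scenario threshold, applies a dispersal framework, and overlays a
forest-cover mask.  The pipeline always averages continuous projections
before thresholding (consensus-then-binarize).
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

from .grids import Grid
from .maps import BinaryRangeMap, DispersalLayer, ScenarioSpec, SuitabilityMap
from .sdm import EnsembleModel, ModelFit
from .synthetic_world import ClimateStack

__all__ = [
    "project",
    "gcm_consensus",
    "binarize",
    "apply_dispersal",
    "apply_forest_mask",
]


def project(
    model: Union[ModelFit, EnsembleModel],
    stack: ClimateStack,
    dispersal_layer: Optional[DispersalLayer] = None,
) -> SuitabilityMap:
    """Cellwise suitability of a fitted model or ensemble on a climate stack.

    A model fitted with the cumulative-distance predictor requires
    ``dispersal_layer``; when projecting to the future the caller passes the
    layer built from *current* occurrences (species cannot re-seed it).
    NaN cells propagate.
    """
    uses_dispersal = getattr(model, "uses_dispersal", False)
    climate_features = [f for f in model.feature_names if f != "cumdist"]
    X = stack.as_matrix(climate_features)  # raises KeyError naming missing layers
    if uses_dispersal:
        if dispersal_layer is None:
            raise ValueError("model was fitted with a dispersal layer; none supplied")
        if dispersal_layer.spec != stack.spec:
            raise ValueError("dispersal layer geometry does not match the climate stack")
        cum = dispersal_layer.grid.data.ravel()
        cols = {f: X[:, i] for i, f in enumerate(climate_features)}
        cols["cumdist"] = cum
        X = np.column_stack([cols[f] for f in model.feature_names])
    elif dispersal_layer is not None and "cumdist" not in model.feature_names:
        raise ValueError("model was fitted without a dispersal layer")

    valid = ~np.isnan(X).any(axis=1)
    out = np.full(stack.spec.n_cells, np.nan)
    if valid.any():
        out[valid] = model.predict(X[valid])
    return SuitabilityMap(
        grid=Grid(stack.spec, out.reshape(stack.spec.shape)),
        taxon_id=getattr(model, "taxon_id", ""),
        scenario_tag=stack.scenario_tag,
        provenance=[(stack.rcp_tag, stack.realization_id, 1.0)],
    )


def gcm_consensus(maps: Sequence[SuitabilityMap]) -> SuitabilityMap:
    """Unweighted cellwise mean across GCM-realization projections."""
    if len(maps) == 0:
        raise ValueError("consensus needs at least one map")
    spec = maps[0].spec
    for m in maps[1:]:
        if m.spec != spec:
            raise ValueError("realization maps must share a grid geometry")
    data = np.mean([m.grid.data for m in maps], axis=0)
    prov = [p for m in maps for p in m.provenance]
    return SuitabilityMap(
        grid=Grid(spec, data),
        taxon_id=maps[0].taxon_id,
        scenario_tag=maps[0].scenario_tag,
        provenance=prov,
    )


def binarize(
    smap: SuitabilityMap,
    threshold: float,
    scenario: Optional[ScenarioSpec] = None,
    from_dispersal_fit: bool = False,
) -> BinaryRangeMap:
    """Boolean range: cell suitable iff value >= threshold (NaN unsuitable)."""
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must lie in [0, 1]")
    with np.errstate(invalid="ignore"):
        data = smap.grid.data >= threshold
    return BinaryRangeMap(
        grid=Grid(smap.spec, data),
        taxon_id=smap.taxon_id,
        scenario=scenario,
        threshold=threshold,
        from_dispersal_fit=from_dispersal_fit,
    )


def apply_dispersal(
    current: BinaryRangeMap,
    future: BinaryRangeMap,
    mode: str,
) -> BinaryRangeMap:
    """Impose a dispersal framework on a future range.

    * ``unlimited`` — any newly suitable cell is colonizable: future as-is.
    * ``limited`` — the constraint already lives inside the fit (the
      cumulative-distance predictor); future as-is, but only legal for maps
      that came from a dispersal-aware fit.
    * ``none`` — the species keeps only cells it already occupies: cellwise
      AND of future and current.
    """
    if current.spec != future.spec:
        raise ValueError("current and future maps must share a grid geometry")
    if mode == "unlimited":
        return future
    if mode == "limited":
        if not future.from_dispersal_fit:
            raise ValueError(
                "limited dispersal requires a future map from a dispersal-constrained fit"
            )
        return future
    if mode == "none":
        return future.replace_grid(future.grid.data & current.grid.data)
    raise ValueError(f"unknown dispersal mode {mode!r}")


def apply_forest_mask(
    range_map: BinaryRangeMap,
    mask: Grid,
    scenario: Optional[ScenarioSpec] = None,
) -> BinaryRangeMap:
    """Restrict a range to forested cells (cellwise AND with the mask)."""
    if range_map.spec != mask.spec:
        raise ValueError("forest mask geometry does not match the range map")
    return range_map.replace_grid(
        range_map.grid.data & mask.data.astype(bool), scenario=scenario
    )
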