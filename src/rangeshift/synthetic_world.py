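"""Virtual worlds for pipeline validation.

Generates the full cast of inputs an SDM study needs — a multi-layer climate
stack with controllable spatial autocorrelation, perturbed future replicates
emulating a GCM ensemble under two emission pathways, nested deforestation
masks, and virtual species with known Gaussian niches — so that every
downstream stage can be scored against a known truth.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import linalg
from scipy.ndimage import gaussian_filter

from .grids import Grid, GridSpec
from .maps import SuitabilityMap
from .occurrences import OccurrenceSet

__all__ = [
    "BIOCLIM_ROLES",
    "RCP_PRESETS",
    "ClimateStack",
    "NicheDefinition",
    "ForestMaskSet",
    "make_climate_stack",
    "perturb_to_future",
    "make_forest_masks",
    "true_suitability",
    "sample_occurrences",
    "niche_from_stack",
]

# The five bioclim roles retained after collinearity screening, with plausible
# eastern-Amazon lowland means and spatial standard deviations:
#   bio1  mean annual temperature (deg C)
#   bio3  isothermality (ratio x 100)
#   bio4  temperature seasonality (sd x 100)
#   bio12 annual precipitation (mm)
#   bio13 precipitation of the wettest month (mm)
BIOCLIM_ROLES: dict[str, tuple[float, float]] = {
    "bio1": (26.0, 1.5),
    "bio3": (85.0, 4.0),
    "bio4": (55.0, 12.0),
    "bio12": (2100.0, 350.0),
    "bio13": (320.0, 60.0),
}

# Mid-century (2050) deltas per emission pathway as (mean shift, inter-GCM
# spread), in each variable's units.  rcp85 shifts are uniformly larger in
# magnitude than rcp45, emulating stronger warming and drying in the
# pessimistic pathway.
RCP_PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "rcp45": {
        "bio1": (1.6, 0.5),
        "bio3": (-0.5, 0.4),
        "bio4": (4.0, 2.0),
        "bio12": (-120.0, 90.0),
        "bio13": (-18.0, 12.0),
    },
    "rcp85": {
        "bio1": (2.9, 0.7),
        "bio3": (-1.0, 0.6),
        "bio4": (8.0, 3.0),
        "bio12": (-240.0, 130.0),
        "bio13": (-36.0, 18.0),
    },
}


@dataclass
class ClimateStack:
    """Named predictor layers sharing one grid geometry.

    ``realization_id`` identifies the emulated GCM and is present iff the
    stack is a future scenario.
    """

    spec: GridSpec
    layers: dict[str, np.ndarray]
    scenario_tag: str = "current"
    rcp_tag: str = "none"
    realization_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.scenario_tag not in {"current", "future"}:
            raise ValueError(f"unknown scenario_tag {self.scenario_tag!r}")
        if (self.realization_id is None) != (self.scenario_tag == "current"):
            raise ValueError("realization_id must be present iff scenario_tag is future")
        for name, arr in self.layers.items():
            if arr.shape != self.spec.shape:
                raise ValueError(f"layer {name!r} does not match the grid spec")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def as_matrix(self, names: Optional[Sequence[str]] = None) -> np.ndarray:
        """(n_cells, n_layers) matrix of values in row-major cell order."""
        names = list(self.layers) if names is None else list(names)
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"missing predictor layer(s): {missing}")
        return np.column_stack([self.layers[n].ravel() for n in names])

    def grid(self, name: str) -> Grid:
        return Grid(self.spec, self.layers[name])


@dataclass
class NicheDefinition:
    """Gaussian niche in predictor space: mode ``mean_vector``, shape
    ``covariance``, peak ``max_suitability``."""

    mean_vector: np.ndarray
    covariance: np.ndarray
    max_suitability: float = 1.0
    variable_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.mean_vector = np.asarray(self.mean_vector, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        k = self.mean_vector.size
        if self.covariance.shape != (k, k):
            raise ValueError("covariance shape does not match mean vector")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        if not (0 < self.max_suitability <= 1):
            raise ValueError("max_suitability must lie in (0, 1]")


@dataclass
class ForestMaskSet:
    """Current and 2050 forest-cover masks, nested by construction:
    BAU ⊆ GOV ⊆ current."""

    current: Grid
    gov_2050: Grid
    bau_2050: Grid

    def __post_init__(self) -> None:
        cur, gov, bau = self.current.data, self.gov_2050.data, self.bau_2050.data
        if not (np.all(gov <= cur) and np.all(bau <= gov)):
            raise ValueError("forest masks must nest: BAU ⊆ GOV ⊆ current")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean, unit-sd spatially autocorrelated surface."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = f.std()
    # a kernel much wider than the domain leaves only float-precision residue;
    # treat the field as constant rather than standardizing numerical noise
    if sd < 1e-6:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def make_climate_stack(
    spec: GridSpec,
    seed: int,
    smoothness: float = 6.0,
    roles: Mapping[str, tuple[float, float]] = BIOCLIM_ROLES,
) -> ClimateStack:
    """Build a current-climate stack of spatially autocorrelated layers.

    Each layer is a Gaussian-smoothed white-noise field (correlation length
    set by ``smoothness``, in cells) standardized to the role's mean and
    spatial sd, plus a small rough component whose amplitude shrinks as
    ``smoothness`` grows.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    layers: dict[str, np.ndarray] = {}
    for i, (name, (mu, sd)) in enumerate(roles.items()):
        rng = np.random.default_rng([seed, 11, i])
        z = _smooth_field(rng, spec.shape, smoothness)
        rough = rng.standard_normal(spec.shape)
        z = z + (0.5 / (1.0 + smoothness)) * rough
        layers[name] = mu + sd * z
    return ClimateStack(spec=spec, layers=layers, scenario_tag="current")


def perturb_to_future(
    stack: ClimateStack,
    rcp_tag: str,
    n_realizations: int = 11,
    delta_mean: Optional[Mapping[str, float]] = None,
    delta_spread: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    anomaly_amplitude: Optional[Mapping[str, float]] = None,
    anomaly_smoothness: float = 8.0,
) -> list[ClimateStack]:
    """Emulate a GCM ensemble: shifted, spatially perturbed future stacks.

    Realization ``r`` of variable ``v`` is
    ``current + (delta_mean[v] + delta_spread[v]·ε_r) + a[v]·anomaly_r`` where
    ``ε_r`` is standard normal and ``anomaly_r`` a zero-mean smooth field.
    Presets for ``delta_mean``/``delta_spread`` come from :data:`RCP_PRESETS`;
    ``anomaly_amplitude`` defaults to half the spread.
    """
    if stack.scenario_tag != "current":
        raise ValueError("perturb_to_future starts from a current-climate stack")
    if rcp_tag not in RCP_PRESETS:
        raise ValueError(f"unknown rcp_tag {rcp_tag!r}; expected one of {sorted(RCP_PRESETS)}")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    preset = RCP_PRESETS[rcp_tag]
    names = stack.layer_names
    dm = {v: (delta_mean[v] if delta_mean is not None else preset[v][0]) for v in names}
    ds = {v: (delta_spread[v] if delta_spread is not None else preset[v][1]) for v in names}
    if anomaly_amplitude is None:
        amp = {v: 0.5 * ds[v] for v in names}
    else:
        amp = {v: anomaly_amplitude[v] for v in names}

    futures: list[ClimateStack] = []
    for r in range(1, n_realizations + 1):
        layers: dict[str, np.ndarray] = {}
        for i, v in enumerate(names):
            rng = np.random.default_rng([seed, 23, r, i])
            shift = dm[v] + ds[v] * rng.standard_normal()
            if amp[v] != 0:
                anomaly = amp[v] * _smooth_field(rng, stack.spec.shape, anomaly_smoothness)
            else:
                anomaly = 0.0
            layers[v] = stack.layers[v] + shift + anomaly
        futures.append(
            ClimateStack(
                spec=stack.spec,
                layers=layers,
                scenario_tag="future",
                rcp_tag=rcp_tag,
                realization_id=r,
            )
        )
    return futures


def make_forest_masks(
    spec: GridSpec,
    frac_current: float = 0.24,
    frac_gov: float = 0.17,
    frac_bau: float = 0.08,
    seed: int = 0,
    smoothness: float = 5.0,
) -> ForestMaskSet:
    """Nested forest-cover masks with spatially contiguous clearing fronts.

    Current forest keeps the cells with the highest values of a smooth
    "habitat" field (target fraction hit to the nearest cell).  The two 2050
    scenarios carve cells out of the current mask in increasing order of a
    shared smooth "clearing-pressure" field, so BAU ⊆ GOV ⊆ current holds
    exactly and cleared areas form contiguous fronts.

    Defaults reflect a heavily deforested study region (~24% forest left now)
    under an optimistic-governance and a business-as-usual 2050 outlook.
    """
    if not (0 <= frac_bau <= frac_gov <= frac_current <= 1):
        raise ValueError("need 0 <= frac_bau <= frac_gov <= frac_current <= 1")
    n = spec.n_cells
    habitat = _smooth_field(np.random.default_rng([seed, 31]), spec.shape, smoothness)
    pressure = _smooth_field(np.random.default_rng([seed, 37]), spec.shape, smoothness)
    # tiny jitter breaks ties so counts are exact even on degenerate fields
    jit = np.random.default_rng([seed, 41]).uniform(0, 1e-9, spec.shape)
    habitat = habitat + jit
    pressure = pressure + jit

    k_cur = int(round(frac_current * n))
    k_gov = int(round(frac_gov * n))
    k_bau = int(round(frac_bau * n))
    k_gov, k_bau = min(k_gov, k_cur), min(k_bau, min(k_gov, k_cur))

    order = np.argsort(habitat.ravel())[::-1]
    current = np.zeros(n, dtype=bool)
    current[order[:k_cur]] = True

    cur_idx = np.flatnonzero(current)
    survive_order = cur_idx[np.argsort(pressure.ravel()[cur_idx])]
    gov = np.zeros(n, dtype=bool)
    gov[survive_order[:k_gov]] = True
    bau = np.zeros(n, dtype=bool)
    bau[survive_order[:k_bau]] = True

    return ForestMaskSet(
        current=Grid(spec, current.reshape(spec.shape)),
        gov_2050=Grid(spec, gov.reshape(spec.shape)),
        bau_2050=Grid(spec, bau.reshape(spec.shape)),
    )


def true_suitability(niche: NicheDefinition, stack: ClimateStack) -> SuitabilityMap:
    """Evaluate the known niche on a climate stack.

    Cell value is ``max_suitability · exp(−½ (v−μ)ᵀ Σ⁻¹ (v−μ))`` with ``v``
    the cell's predictor vector.
    """
    names = niche.variable_names or stack.layer_names
    if niche.mean_vector.size != len(names):
        raise ValueError("niche dimension must equal the number of predictor layers")
    V = stack.as_matrix(names)
    d = V - niche.mean_vector
    try:
        cho = linalg.cho_factor(niche.covariance)
    except linalg.LinAlgError as exc:
        raise ValueError("niche covariance is singular or not positive-definite") from exc
    q = np.einsum("ij,ij->i", d, linalg.cho_solve(cho, d.T).T)
    s = niche.max_suitability * np.exp(-0.5 * q)
    return SuitabilityMap(
        grid=Grid(stack.spec, s.reshape(stack.spec.shape)),
        taxon_id="truth",
        scenario_tag=stack.scenario_tag,
        provenance=[("truth", None, 1.0)],
    )


def niche_from_stack(
    stack: ClimateStack,
    seed: int = 0,
    center_quantile_range: tuple[float, float] = (0.35, 0.65),
    breadth: float = 1.5,
    max_suitability: float = 1.0,
) -> NicheDefinition:
    """Draw a realistic virtual niche anchored in the realized climate.

    The niche mode sits at a per-layer quantile drawn uniformly from
    ``center_quantile_range`` so the species' optimum exists inside the
    domain; the covariance is diagonal with sd ``breadth`` times each layer's
    spatial sd, giving a species occupying roughly a quarter to a third of
    the landscape at half-maximum suitability.
    """
    rng = np.random.default_rng([seed, 53])
    names = stack.layer_names
    mu = np.empty(len(names))
    sds = np.empty(len(names))
    for i, v in enumerate(names):
        vals = stack.layers[v].ravel()
        q = rng.uniform(*center_quantile_range)
        mu[i] = np.quantile(vals, q)
        sds[i] = vals.std()
    cov = np.diag((breadth * sds) ** 2)
    return NicheDefinition(mu, cov, max_suitability, variable_names=list(names))


def sample_occurrences(
    truth: SuitabilityMap,
    n: int,
    bias_strength: float = 0.0,
    seed: int = 0,
    taxon_id: str = "virtual",
) -> OccurrenceSet:
    """Sample presence records from a truth surface.

    Cells are drawn without replacement with weight proportional to
    suitability times an accessibility kernel: records decay in probability
    with distance from a random "road" line when ``bias_strength > 0``,
    emulating the roadside clustering of opportunistic occurrence databases.
    Coordinates are cell centers.
    """
    if bias_strength < 0:
        raise ValueError("bias_strength must be >= 0")
    spec = truth.spec
    w = truth.grid.data.ravel().astype(float).copy()
    w[np.isnan(w)] = 0.0
    positive = w > 0
    if positive.sum() < n:
        raise ValueError(
            f"requested {n} occurrences but only {int(positive.sum())} cells have positive suitability"
        )
    rng = np.random.default_rng([seed, 61])
    centers = spec.all_centers()
    if bias_strength > 0:
        # random road: a line through a random point at a random angle
        p0 = centers[rng.integers(len(centers))]
        theta = rng.uniform(0, np.pi)
        normal = np.array([-np.sin(theta), np.cos(theta)])
        dist = np.abs((centers - p0) @ normal)
        scale = spec.diagonal / 4.0
        w = w * np.exp(-bias_strength * dist / scale)
        positive = w > 0
        if positive.sum() < n:
            raise ValueError("accessibility bias left fewer positive-weight cells than n")
    # Efraimidis-Spirakis: weighted sampling without replacement via Gumbel keys
    keys = np.full(w.size, -np.inf)
    keys[positive] = np.log(w[positive]) + rng.gumbel(size=int(positive.sum()))
    chosen = np.argsort(keys)[::-1][:n]
    pts = centers[chosen]
    return OccurrenceSet(
        taxon_id=taxon_id,
        points=pts,
        source=["synthetic"] * n,
    )
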