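"""End-to-end orchestration.

``run_pipeline`` drives one reproducible run over a virtual world: generate
climate, futures and forest masks; simulate taxa and their occurrence
records; clean records; screen predictors; fit and score the three
algorithms on bootstrap partitions (with and without the dispersal
predictor); project every taxon onto the GCM-realization consensus for both
emission pathways; binarize, apply the three dispersal frameworks, overlay
the paired deforestation masks; and assemble the change table, summary
report and richness maps.

``reproduce_table2_summaries`` is the worked example: it recomputes the
published aggregate statistics from the packaged transcription of the
printed change table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import impact, predictors, projection, sdm, synthetic_world as sw
from .grids import Grid, GridSpec, write_ascii_grid
from .maps import BinaryRangeMap, ScenarioSpec
from .occurrences import OccurrenceSet, deduplicate_per_pixel, moran_profile, thin

logger = logging.getLogger("rangeshift")

__all__ = [
    "TaxonConfig",
    "RunConfig",
    "run_pipeline",
    "reproduce_table2_summaries",
    "TABLE2_EXPECTED",
]


@dataclass
class TaxonConfig:
    taxon_id: str
    n_occurrences: int = 80
    bias_strength: float = 0.0
    niche_breadth: float = 1.5
    max_suitability: float = 1.0


@dataclass
class RunConfig:
    """Everything one run needs; every stochastic stage draws from ``seed``."""

    n_rows: int = 60
    n_cols: int = 60
    cell_size: float = 1.0
    smoothness: float = 6.0
    frac_forest_current: float = 0.24
    frac_forest_gov: float = 0.17
    frac_forest_bau: float = 0.08
    n_realizations: int = 11
    taxa: list[TaxonConfig] = field(
        default_factory=lambda: [
            TaxonConfig("taxon_a"),
            TaxonConfig("taxon_b"),
            TaxonConfig("taxon_c"),
        ]
    )
    n_partitions: int = 5
    train_frac: float = 0.7
    correlation_threshold: float = 0.8
    apply_thinning: bool = True
    thin_restarts: int = 10
    min_records_after_thinning: int = 8
    seed: int = 0
    outdir: Optional[str] = None

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, cell_size=self.cell_size)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        taxa = [TaxonConfig(**t) for t in raw.pop("taxa", [])]
        cfg = cls(**raw)
        if taxa:
            cfg.taxa = taxa
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TaxonResult:
    taxon_id: str
    occurrences: OccurrenceSet
    scores: pd.DataFrame
    threshold: float
    threshold_limited: float
    current_range: BinaryRangeMap
    current_range_limited: BinaryRangeMap
    flagged_limited_exceeds_unlimited: bool


@dataclass
class PipelineResult:
    config: RunConfig
    change_table: impact.ChangeTable
    summaries: dict
    richness: dict
    taxa: dict[str, TaxonResult]
    excluded_taxa: list[str]
    manifest: dict


def _scenario(colname: str) -> ScenarioSpec:
    name, dispersal = colname.rsplit("_", 1)
    climate = "rcp45" if name == "mitigation" else "rcp85"
    deforestation = "GOV" if name == "mitigation" else "BAU"
    return ScenarioSpec(climate, deforestation, dispersal, "2050")


def _fit_taxon(
    cfg: RunConfig,
    taxon: TaxonConfig,
    occ: OccurrenceSet,
    stack: sw.ClimateStack,
    feature_names: list[str],
    use_dispersal: bool,
    dispersal: Optional[np.ndarray],
    absences: np.ndarray,
    seed: int,
) -> tuple[sdm.EnsembleModel, pd.DataFrame]:
    spec = cfg.grid
    names = list(feature_names)
    cells_p = spec.cells_of(occ.points)
    cells_a = spec.cells_of(absences)

    def features(cells: np.ndarray) -> np.ndarray:
        cols = [stack.layers[v][cells[:, 0], cells[:, 1]] for v in feature_names]
        if use_dispersal:
            cols.append(dispersal[cells[:, 0], cells[:, 1]])
        return np.column_stack(cols)

    if use_dispersal:
        names = names + ["cumdist"]
    Xp, Xa = features(cells_p), features(cells_a)

    # background for the presence-background learner: all cells (small grids)
    bg = stack.as_matrix(feature_names)
    if use_dispersal:
        bg = np.column_stack([bg, dispersal.ravel()])
    n_bg = min(10_000, bg.shape[0])
    if n_bg < bg.shape[0]:
        rng = np.random.default_rng([seed, 131])
        bg = bg[rng.choice(bg.shape[0], n_bg, replace=False)]

    parts = sdm.bootstrap_partitions(
        Xp, Xa, train_frac=cfg.train_frac, n_reps=cfg.n_partitions,
        seed=seed, feature_names=names,
    )
    fits, scores, rows = [], [], []
    for part in parts:
        for alg in sdm.ALGORITHMS:
            fit = sdm.fit_model(alg, part, background=bg, seed=seed, taxon_id=taxon.taxon_id)
            score = sdm.score_fit(fit, part.X_test, part.y_test)
            fits.append(fit)
            scores.append(score)
            rows.append(
                {
                    "taxon": taxon.taxon_id,
                    "algorithm": alg,
                    "partition": part.partition_id,
                    "sorensen": score.sorensen,
                    "threshold": score.threshold_used,
                    "dispersal_fit": use_dispersal,
                }
            )
    ens = sdm.build_ensemble(fits, scores, uses_dispersal=use_dispersal)
    return ens, pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full chain; identical config and seed give identical outputs."""
    cfg = config
    spec = cfg.grid
    seed = cfg.seed
    logger.info("[world] generating climate, futures and forest masks")
    stack = sw.make_climate_stack(spec, seed=seed, smoothness=cfg.smoothness)
    futures = {
        "rcp45": sw.perturb_to_future(stack, "rcp45", cfg.n_realizations, seed=seed),
        "rcp85": sw.perturb_to_future(stack, "rcp85", cfg.n_realizations, seed=seed + 1),
    }
    masks = sw.make_forest_masks(
        spec, cfg.frac_forest_current, cfg.frac_forest_gov, cfg.frac_forest_bau, seed=seed
    )
    scenario_mask = {"GOV": masks.gov_2050, "BAU": masks.bau_2050}

    logger.info("[predictors] collinearity screening")
    cm = predictors.pearson_matrix(stack)
    selected = predictors.select_uncorrelated(cm, cfg.correlation_threshold)

    current_maps: dict[str, dict[str, BinaryRangeMap]] = {}
    future_maps: dict[str, dict[str, BinaryRangeMap]] = {}
    taxa_results: dict[str, TaxonResult] = {}
    excluded: list[str] = []
    score_frames = []

    for t_i, taxon in enumerate(cfg.taxa):
        tseed = seed + 1000 * (t_i + 1)
        logger.info("[taxon %s] simulating and cleaning occurrences", taxon.taxon_id)
        niche = sw.niche_from_stack(
            stack, seed=tseed, breadth=taxon.niche_breadth,
            max_suitability=taxon.max_suitability,
        )
        truth = sw.true_suitability(niche, stack)
        occ = sw.sample_occurrences(
            truth, taxon.n_occurrences, bias_strength=taxon.bias_strength,
            seed=tseed, taxon_id=taxon.taxon_id,
        )
        occ = deduplicate_per_pixel(occ, spec)
        if cfg.apply_thinning and len(occ) >= 5:
            profile = moran_profile(occ, stack)
            thinned = thin(occ, profile.chosen_lag, n_restarts=cfg.thin_restarts, seed=tseed)
            # a thinning distance that leaves too few records to partition is
            # stepped down the lag ladder until enough records survive
            if len(thinned) < cfg.min_records_after_thinning:
                for lag in sorted(profile.lags[profile.lags < profile.chosen_lag])[::-1]:
                    thinned = thin(occ, lag, n_restarts=cfg.thin_restarts, seed=tseed)
                    if len(thinned) >= cfg.min_records_after_thinning:
                        break
            if len(thinned) >= cfg.min_records_after_thinning:
                occ = thinned

        absences = sdm.sample_pseudo_absences(occ, spec, seed=tseed)
        disp_layer = sdm.cumulative_distance_layer(occ, spec)

        logger.info("[taxon %s] fitting %d algorithms x %d partitions (x2 variants)",
                    taxon.taxon_id, len(sdm.ALGORITHMS), cfg.n_partitions)
        ens_u, sc_u = _fit_taxon(cfg, taxon, occ, stack, selected, False, None, absences, tseed)
        ens_l, sc_l = _fit_taxon(
            cfg, taxon, occ, stack, selected, True, disp_layer.grid.data, absences, tseed
        )
        score_frames += [sc_u, sc_l]

        # taxon-level binarization threshold: maximize Sørensen of the
        # ensemble prediction at the presence/pseudo-absence points
        cells_all = spec.cells_of(np.vstack([occ.points, absences]))
        y_all = np.concatenate([np.ones(len(occ)), np.zeros(len(absences))]).astype(bool)

        def _threshold(ens, dl):
            smap = projection.project(ens, stack, dispersal_layer=dl)
            preds = smap.grid.data[cells_all[:, 0], cells_all[:, 1]]
            return sdm.select_threshold(preds, y_all).threshold_used, smap

        thr_u, cur_map_u = _threshold(ens_u, None)
        thr_l, cur_map_l = _threshold(ens_l, disp_layer)
        present = ScenarioSpec()
        cur_u = projection.binarize(cur_map_u, thr_u, scenario=present)
        cur_l = projection.binarize(cur_map_l, thr_l, scenario=present, from_dispersal_fit=True)

        logger.info("[taxon %s] projecting 2x%d realizations", taxon.taxon_id, cfg.n_realizations)
        fut_bin: dict[str, BinaryRangeMap] = {}
        for rcp, scen_name in (("rcp45", "mitigation"), ("rcp85", "bau")):
            cons_u = projection.gcm_consensus(
                [projection.project(ens_u, f) for f in futures[rcp]]
            )
            cons_l = projection.gcm_consensus(
                [projection.project(ens_l, f, dispersal_layer=disp_layer) for f in futures[rcp]]
            )
            fut_bin[f"{scen_name}_unlimited"] = projection.binarize(cons_u, thr_u)
            fut_bin[f"{scen_name}_limited"] = projection.binarize(
                cons_l, thr_l, from_dispersal_fit=True
            )
            fut_bin[f"{scen_name}_none"] = fut_bin[f"{scen_name}_unlimited"]

        flagged = any(
            fut_bin[f"{s}_limited"].suitable_cell_count
            > fut_bin[f"{s}_unlimited"].suitable_cell_count
            for s in ("mitigation", "bau")
        )
        if flagged:
            logger.warning("[taxon %s] limited-dispersal area exceeds unlimited; flagged",
                           taxon.taxon_id)

        cur_masked_u = projection.apply_forest_mask(cur_u, masks.current, scenario=present)
        cur_masked_l = projection.apply_forest_mask(cur_l, masks.current, scenario=present)
        tax_current: dict[str, BinaryRangeMap] = {}
        tax_future: dict[str, BinaryRangeMap] = {}
        for col in impact.SCENARIO_COLUMNS:
            scen = _scenario(col)
            base_cur = cur_l if scen.dispersal == "limited" else cur_u
            fut = projection.apply_dispersal(base_cur, fut_bin[col], scen.dispersal)
            fut = projection.apply_forest_mask(fut, scenario_mask[scen.deforestation], scenario=scen)
            tax_future[col] = fut
            tax_current[col] = cur_masked_l if scen.dispersal == "limited" else cur_masked_u

        res = TaxonResult(
            taxon_id=taxon.taxon_id,
            occurrences=occ,
            scores=pd.concat([sc_u, sc_l], ignore_index=True),
            threshold=thr_u,
            threshold_limited=thr_l,
            current_range=cur_masked_u,
            current_range_limited=cur_masked_l,
            flagged_limited_exceeds_unlimited=flagged,
        )
        taxa_results[taxon.taxon_id] = res
        if cur_masked_u.suitable_cell_count == 0 or cur_masked_l.suitable_cell_count == 0:
            logger.warning("[taxon %s] zero current area; excluded from the change table",
                           taxon.taxon_id)
            excluded.append(taxon.taxon_id)
            continue
        current_maps[taxon.taxon_id] = tax_current
        future_maps[taxon.taxon_id] = tax_future

    if not future_maps:
        raise RuntimeError("every taxon had zero current area; no change table")

    logger.info("[impact] change table, summaries and richness stacks")
    table = impact.build_change_table(current_maps, future_maps)
    summaries = {
        "overall_mean_loss_pct": impact.summarize_mean(table).loss_magnitude,
        "mitigation_mean_loss_pct": impact.summarize_mean(
            table, cols=impact.SCENARIO_COLUMNS[:3]
        ).loss_magnitude,
        "bau_mean_loss_pct": impact.summarize_mean(
            table, cols=impact.SCENARIO_COLUMNS[3:]
        ).loss_magnitude,
    }
    richness = {
        "present": impact.stack_richness(
            [taxa_results[t].current_range for t in future_maps]
        )
    }
    for col in impact.SCENARIO_COLUMNS:
        richness[col] = impact.stack_richness([future_maps[t][col] for t in future_maps])

    manifest = {
        "config": cfg.to_dict(),
        "seed": seed,
        "selected_predictors": selected,
        "excluded_taxa": excluded,
        "flagged_taxa": [t for t, r in taxa_results.items()
                         if r.flagged_limited_exceeds_unlimited],
        "n_occurrences_used": {t: len(r.occurrences) for t, r in taxa_results.items()},
    }
    result = PipelineResult(cfg, table, summaries, richness, taxa_results, excluded, manifest)
    if cfg.outdir is not None:
        _write_outputs(result, Path(cfg.outdir), cm, masks)
    return result


def _write_outputs(res: PipelineResult, outdir: Path, cm, masks) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res.change_table.to_csv(outdir / "change_table.csv")
    pd.concat([r.scores for r in res.taxa.values()], ignore_index=True).to_csv(
        outdir / "model_scores.csv", index=False
    )
    cm.to_csv(outdir / "predictor_correlations.csv")
    for name, grid in (
        ("forest_current", masks.current),
        ("forest_gov_2050", masks.gov_2050),
        ("forest_bau_2050", masks.bau_2050),
    ):
        write_ascii_grid(grid, outdir / f"{name}.asc")
    for name, rich in res.richness.items():
        write_ascii_grid(rich.grid, outdir / f"richness_{name}.asc")
    for taxon, r in res.taxa.items():
        pd.DataFrame(
            {
                "taxon": taxon,
                "lon": r.occurrences.points[:, 0],
                "lat": r.occurrences.points[:, 1],
                "source": r.occurrences.source,
            }
        ).to_csv(outdir / f"occurrences_{taxon}.csv", index=False)
    with open(outdir / "summaries.json", "w") as fh:
        json.dump(res.summaries, fh, indent=2, sort_keys=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, sort_keys=True)


# Published aggregate statistics of the transcribed change table: the
# worked-example expectations the summarizers must reproduce.
TABLE2_EXPECTED = {
    "overall_mean_loss_pct": 73.80,
    "mitigation_unlimited_mean_loss_pct": 41.27,
    "mitigation_mean_loss_pct": 59.0,
    "bau_limited_mean_loss_pct": 78.0,
    "bau_mean_loss_pct": 88.0,
    "limited_minus_unlimited_gap_pct": 12.0,
    "psophia_obscura_bau_mean_loss_pct": 95.82,
    "frugivore_trio_mean_loss_pct": 44.57,
    "n_gaining_taxa_mitigation_unlimited": 4,
    "n_taxa_loss_gt80_mitigation_none": 8,
    "n_taxa_loss_gt90_bau_unlimited": 11,
}

FRUGIVORE_TRIO = [
    "Pteroglossus bitorquatus bitorquatus",
    "Crax fasciolata pinima",
    "Tangara velia signata",
]


def compute_table2_summaries(table: impact.ChangeTable) -> dict:
    """The published aggregates, recomputed from a change table."""
    mit = impact.SCENARIO_COLUMNS[:3]
    bau = impact.SCENARIO_COLUMNS[3:]
    gap = (
        impact.summarize_mean(table, cols=["mitigation_limited"], rounding=6).loss_magnitude
        - impact.summarize_mean(table, cols=["mitigation_unlimited"], rounding=6).loss_magnitude
    )
    return {
        "overall_mean_loss_pct": impact.summarize_mean(table).loss_magnitude,
        "mitigation_unlimited_mean_loss_pct": impact.summarize_mean(
            table, cols=["mitigation_unlimited"]
        ).loss_magnitude,
        "mitigation_mean_loss_pct": impact.summarize_mean(table, cols=mit, rounding=0).loss_magnitude,
        "bau_limited_mean_loss_pct": impact.summarize_mean(
            table, cols=["bau_limited"], rounding=0
        ).loss_magnitude,
        "bau_mean_loss_pct": impact.summarize_mean(table, cols=bau, rounding=0).loss_magnitude,
        "limited_minus_unlimited_gap_pct": impact.round_half_up(gap, 0),
        "psophia_obscura_bau_mean_loss_pct": impact.summarize_mean(
            table, rows=["Psophia obscura"], cols=bau
        ).loss_magnitude,
        "frugivore_trio_mean_loss_pct": impact.summarize_mean(
            table, rows=FRUGIVORE_TRIO
        ).loss_magnitude,
        "n_gaining_taxa_mitigation_unlimited": impact.count_rows_where(
            table, ["mitigation_unlimited"], "gain_gt", 0
        ),
        "n_taxa_loss_gt80_mitigation_none": impact.count_rows_where(
            table, ["mitigation_none"], "loss_gt", 80
        ),
        "n_taxa_loss_gt90_bau_unlimited": impact.count_rows_where(
            table, ["bau_unlimited"], "loss_gt", 90
        ),
    }


def reproduce_table2_summaries(fixture_path: Optional[str | Path] = None) -> dict:
    """Worked-example reproduction report.

    Loads the packaged (or a caller-supplied) transcription of the published
    change table, recomputes every aggregate, and reports each alongside its
    published expectation with a pass flag.
    """
    if fixture_path is None:
        table = impact.load_table2_transcription()
    else:
        table = impact.ChangeTable.from_csv(fixture_path)
    if len(table.taxa) != len(set(table.taxa)):
        raise ValueError("duplicate taxon rows in the fixture")
    missing = [t for t in FRUGIVORE_TRIO + ["Psophia obscura"] if t not in table.taxa]
    if missing:
        raise ValueError(f"fixture is missing expected taxon rows: {missing}")
    computed = compute_table2_summaries(table)
    report = {}
    for key, expected in TABLE2_EXPECTED.items():
        value = computed[key]
        report[key] = {
            "value": value,
            "expected": expected,
            "pass": bool(np.isclose(value, expected, atol=1e-9)),
        }
    report["all_pass"] = all(v["pass"] for k, v in report.items() if isinstance(v, dict))
    return report
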