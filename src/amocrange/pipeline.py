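"""End-to-end orchestration: world -> bioclim -> SDMs -> impacts -> maps.

A single :class:`PipelineConfig` (synthetic-world mode or real-data paths)
drives every stage with seeds derived from one master seed, so a rerun
with the same config reproduces all tables bit-identically.  Stages:

1. ``simulate``     synthetic climate world + virtual species ground truth
2. ``prep``         horizon climatologies, delta bias correction, bioclim
3. ``occurrences``  range filtering, pseudoabsences, 70/30 run splits
4. ``fit``          three learners x ten runs per species, validation, TSS filter
5. ``binarize``     run-averaged suitability -> thresholded range maps
6. ``impact``       per-species range change q, ensembling, group summaries
7. ``assemblage``   stacked 1° richness and percent-species-loss maps
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .assemblage_mapping import (
    DeficitMap,
    RichnessMap,
    algorithm_average_map,
    deficit_map,
    stack_richness,
)
from .binarization import BinaryRangeMap, apply_threshold, compute_threshold
from .climate_prep import (
    BioclimStack,
    compute_bioclim,
    delta_bias_correct,
    horizon_mean,
)
from .errors import ConfigurationError, FitError, RangeUndefinedError
from .grid import RealmMask
from .impact_assessment import (
    ENSEMBLE,
    ensemble_range_change,
    range_change,
    records_to_frame,
    summarize_contractions,
)
from .niche_models import (
    DEFAULT_ALGORITHMS,
    DEFAULT_TSS_MIN,
    evaluate_model,
    exclude_poor_models,
    fit_suitability,
)
from .seeds import derived_seed
from .species_occurrence import (
    SpeciesRecord,
    build_design,
    rasterize_and_filter,
)
from .synthetic_world import (
    WorldRealization,
    WorldSpec,
    generate_climate_world,
    generate_virtual_species,
    true_range_change,
)

STAGES = ("simulate", "prep", "occurrences", "fit", "binarize", "impact", "assemblage")


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run.  ``seed`` is mandatory."""

    seed: int
    mode: str = "synthetic"
    outdir: str = "results/run"

    # synthetic world
    # 0.33 deg cells in 3x3 blocks per 1 deg assemblage cell: dims stay
    # divisible by the aggregation factor
    grid_rows: int = 42
    grid_cols: int = 81
    cell_size: float = 0.33
    n_realms: int = 2
    n_species: int = 40

    # real-data mode paths
    obs_baseline_path: str = ""
    model_baseline_path: str = ""
    scenario_paths: dict[str, str] = field(default_factory=dict)
    realm_mask_path: str = ""
    occurrences_path: str = ""
    species_meta_path: str = ""

    # analysis choices
    scenarios: tuple[str, ...] = ("RCP85", "A", "B", "C", "D")
    horizons: tuple[int, ...] = (2030, 2050, 2070)
    horizon_width: int = 30
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS
    n_runs: int = 10
    train_frac: float = 0.7
    pa_ratio: int = 3
    tss_min: float = DEFAULT_TSS_MIN
    criterion: str = "P10TP"
    dispersal_modes: tuple[str, ...] = ("full", "none")
    min_presence: int = 50
    aggregation_factor: int = 3  # 0.33 deg analysis cells -> 1 deg assemblage cells
    n_boot: int = 1000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        self.seed = int(self.seed)
        if self.mode not in ("synthetic", "real"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        self.scenarios = tuple(self.scenarios)
        self.horizons = tuple(int(h) for h in self.horizons)
        self.algorithms = tuple(self.algorithms)
        self.dispersal_modes = tuple(self.dispersal_modes)
        if self.mode == "real":
            paths = [
                self.obs_baseline_path,
                self.model_baseline_path,
                self.realm_mask_path,
                self.occurrences_path,
                *self.scenario_paths.values(),
            ]
            for p in paths:
                if not p or not Path(p).exists():
                    raise ConfigurationError(f"real-data path missing: {p!r}")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        if "seed" not in d:
            raise ConfigurationError("seed is mandatory")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must be a flat key-value mapping")
        return cls.from_dict(data)

    def world_spec(self) -> WorldSpec:
        return WorldSpec(
            grid_shape=(self.grid_rows, self.grid_cols),
            cell_size=self.cell_size,
            n_realms=self.n_realms,
            horizons=self.horizons,
            seed=derived_seed(self.seed, "world"),
        )

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle of everything a run produced."""

    config: PipelineConfig
    world: WorldRealization | None = None
    realm_mask: RealmMask | None = None
    stacks: dict = field(default_factory=dict)  # "current" or (scenario, horizon)
    species: list[SpeciesRecord] = field(default_factory=list)
    virtual_species: list = field(default_factory=list)
    designs: dict = field(default_factory=dict)
    exclusions: list[dict] = field(default_factory=list)
    metrics: pd.DataFrame | None = None
    retained: pd.DataFrame | None = None
    models: dict = field(default_factory=dict)  # (species_id, algorithm) -> [models]
    thresholds: list[dict] = field(default_factory=list)
    binary_maps: dict = field(default_factory=dict)  # (sid, alg, key) -> BinaryRangeMap
    range_changes: pd.DataFrame | None = None
    summaries: pd.DataFrame | None = None
    richness: dict = field(default_factory=dict)
    deficits: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    stages_done: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(res: PipelineResult) -> None:
    cfg = res.config
    if cfg.mode == "synthetic":
        res.world = generate_climate_world(cfg.world_spec())
        res.realm_mask = res.world.realm_mask
    else:
        res.realm_mask = aio.read_realm_mask(cfg.realm_mask_path)
    res.stages_done.append("simulate")


def _stage_prep(res: PipelineResult) -> None:
    cfg = res.config
    if cfg.mode == "synthetic":
        world = res.world
        obs_cube, model_cube = world.obs_baseline, world.model_baseline
        scen_cubes = {s: world.scenarios[s] for s in cfg.scenarios}
        y0, y1 = world.spec.baseline_years
    else:
        obs_cube = aio.read_cube(cfg.obs_baseline_path)
        model_cube = aio.read_cube(cfg.model_baseline_path)
        scen_cubes = {s: aio.read_cube(p) for s, p in cfg.scenario_paths.items()}
        y0, y1 = int(obs_cube.years.min()), int(obs_cube.years.max())

    width = y1 - y0 + 1
    center = (y0 + y1 + 1) // 2
    obs_clim = horizon_mean(obs_cube, center_year=center, width=width)
    model_clim = horizon_mean(model_cube, center_year=center, width=width)

    current = compute_bioclim(obs_clim)
    current.label = "current"
    res.stacks = {"current": current}
    for scen in cfg.scenarios:
        cube = scen_cubes[scen]
        for horizon in cfg.horizons:
            target = horizon_mean(cube, center_year=horizon, width=cfg.horizon_width)
            corrected = delta_bias_correct(model_clim, obs_clim, target)
            stack = compute_bioclim(corrected)
            stack.label = f"{scen}_{horizon}"
            res.stacks[(scen, horizon)] = stack
    res.stages_done.append("prep")


def _stage_occurrences(res: PipelineResult) -> None:
    cfg = res.config
    if cfg.mode == "synthetic":
        res.virtual_species = generate_virtual_species(
            res.world,
            cfg.n_species,
            seed=derived_seed(cfg.seed, "species"),
            min_presence=cfg.min_presence,
        )
        ranges = {sp.species_id: sp.presence_cells for sp in res.virtual_species}
        meta = {
            sp.species_id: {"family": sp.family, "status": sp.status}
            for sp in res.virtual_species
        }
    else:
        occ = pd.read_csv(cfg.occurrences_path)
        ranges = {
            str(sid): grp["cell_id"].to_numpy()
            for sid, grp in occ.groupby("species_id")
        }
        meta = {}
        if cfg.species_meta_path:
            mdf = pd.read_csv(cfg.species_meta_path).set_index("species_id")
            meta = {
                str(i): {"family": r.get("family", "unknown"), "status": r.get("status", "DD")}
                for i, r in mdf.iterrows()
            }
    grid = res.realm_mask.grid
    records, excl = rasterize_and_filter(
        ranges, grid, res.realm_mask, metadata=meta, min_presence=cfg.min_presence
    )
    res.species = records
    res.exclusions.extend(excl)
    res.designs = {
        r.species_id: build_design(
            r,
            res.realm_mask,
            seed=derived_seed(cfg.seed, "design", r.species_id),
            ratio=cfg.pa_ratio,
            train_frac=cfg.train_frac,
            n_runs=cfg.n_runs,
        )
        for r in records
    }
    res.stages_done.append("occurrences")


def _stage_fit(res: PipelineResult) -> None:
    cfg = res.config
    current = res.stacks["current"]
    rows: list[dict] = []
    res.models = {}
    for rec in res.species:
        design = res.designs[rec.species_id]
        for alg in cfg.algorithms:
            models = []
            for run_idx, split in enumerate(design.runs):
                feats = {
                    part: current.features(getattr(split, part))
                    for part in (
                        "train_presence",
                        "train_background",
                        "test_presence",
                        "test_background",
                    )
                }
                x = np.vstack([feats["train_presence"], feats["train_background"]])
                y = np.concatenate(
                    [
                        np.ones(len(feats["train_presence"]), dtype=int),
                        np.zeros(len(feats["train_background"]), dtype=int),
                    ]
                )
                try:
                    model = fit_suitability(
                        alg,
                        x,
                        y,
                        seed=derived_seed(cfg.seed, "fit", rec.species_id, alg, run_idx),
                        species_id=rec.species_id,
                        run=run_idx,
                    )
                except FitError:
                    res.exclusions.append(
                        {"species_id": rec.species_id, "reason": "fit_error",
                         "algorithm": alg, "run": run_idx}
                    )
                    continue
                models.append(model)
                rows.append(
                    evaluate_model(
                        model,
                        feats["test_presence"],
                        feats["test_background"],
                        feats["train_presence"],
                        feats["train_background"],
                        criterion=cfg.criterion,
                    )
                )
            res.models[(rec.species_id, alg)] = models
    res.metrics = pd.DataFrame(rows)
    retained, tss_log = exclude_poor_models(res.metrics, tss_min=cfg.tss_min)
    res.retained = retained
    for row in tss_log.to_dict("records"):
        res.exclusions.append(
            {"species_id": row["species_id"], "reason": "tss",
             "algorithm": row["algorithm"], "mean_tss": row["mean_tss"]}
        )
    res.stages_done.append("fit")


def _retained_pairs(res: PipelineResult) -> list[tuple[str, str]]:
    if res.retained is None or res.retained.empty:
        return []
    return sorted(
        {(r.species_id, r.algorithm) for r in res.retained.itertuples()}
    )


def _stage_binarize(res: PipelineResult) -> None:
    """Run-averaged suitability per species x algorithm, one threshold, maps
    for the current climate and every scenario x horizon."""
    cfg = res.config
    by_species = {r.species_id: r for r in res.species}
    res.binary_maps = {}
    res.thresholds = []
    for sid, alg in _retained_pairs(res):
        rec = by_species[sid]
        design = res.designs[sid]
        models = res.models[(sid, alg)]
        if not models:
            continue
        background = res.realm_mask.mask_for(rec.realm)
        realm_cells = res.realm_mask.cells_for(rec.realm)

        def avg_suit(stack: BioclimStack) -> np.ndarray:
            feats = stack.features(realm_cells)
            s = np.mean([m.predict(feats) for m in models], axis=0)
            full = np.zeros(stack.grid.shape)
            full.ravel()[realm_cells] = s
            return full

        current_suit = avg_suit(res.stacks["current"])
        pres_scores = current_suit.ravel()[design.presence_cells]
        pa_scores = current_suit.ravel()[design.pseudoabsence_cells]
        thr = compute_threshold(
            pres_scores,
            scores=np.concatenate([pres_scores, pa_scores]),
            labels=np.concatenate(
                [np.ones(len(pres_scores), int), np.zeros(len(pa_scores), int)]
            ),
            criterion=cfg.criterion,
        )
        res.thresholds.append(
            {"species_id": sid, "algorithm": alg, "criterion": thr.criterion,
             "value": thr.value}
        )
        res.binary_maps[(sid, alg, "current")] = apply_threshold(
            current_suit, thr, background, species_id=sid, algorithm=alg,
            scenario="current",
        )
        for scen in cfg.scenarios:
            for horizon in cfg.horizons:
                res.binary_maps[(sid, alg, (scen, horizon))] = apply_threshold(
                    avg_suit(res.stacks[(scen, horizon)]), thr, background,
                    species_id=sid, algorithm=alg, scenario=scen, horizon=horizon,
                )
    res.stages_done.append("binarize")


def _stage_impact(res: PipelineResult) -> None:
    cfg = res.config
    by_species = {r.species_id: r for r in res.species}
    vsp = {sp.species_id: sp for sp in res.virtual_species}
    records = []
    pairs = _retained_pairs(res)
    species_ids = sorted({sid for sid, _ in pairs})
    for sid in species_ids:
        rec = by_species[sid]
        algs = [a for s, a in pairs if s == sid]
        current_maps = {
            a: res.binary_maps.get((sid, a, "current"))
            for a in algs
            if (sid, a, "current") in res.binary_maps
        }
        for scen in cfg.scenarios:
            for horizon in cfg.horizons:
                for disp in cfg.dispersal_modes:
                    per_alg = []
                    for alg, cur in current_maps.items():
                        fut = res.binary_maps.get((sid, alg, (scen, horizon)))
                        if fut is None:
                            continue
                        try:
                            r = range_change(cur, fut, disp)
                        except RangeUndefinedError:
                            res.exclusions.append(
                                {"species_id": sid, "reason": "empty_p1",
                                 "algorithm": alg}
                            )
                            continue
                        r = dataclasses.replace(
                            r, realm=rec.realm, family=rec.family, status=rec.status
                        )
                        per_alg.append(r)
                    if per_alg:
                        records.extend(per_alg)
                        records.append(ensemble_range_change(per_alg))

    df = records_to_frame(records)
    if cfg.mode == "synthetic" and not df.empty:
        truths = {}
        for sid in species_ids:
            sp = vsp.get(sid)
            if sp is None:
                continue
            for scen in cfg.scenarios:
                for horizon in cfg.horizons:
                    for disp in cfg.dispersal_modes:
                        truths[(sid, scen, horizon, disp)] = true_range_change(
                            sp, res.stacks[(scen, horizon)], disp, res.realm_mask
                        )
        df["q_true"] = [
            truths.get((r.species_id, r.scenario, r.horizon, r.dispersal), np.nan)
            for r in df.itertuples()
        ]
    df = df.sort_values(
        ["species_id", "scenario", "horizon", "dispersal", "algorithm"]
    ).reset_index(drop=True)
    res.range_changes = df

    ens = df[df["algorithm"] == ENSEMBLE]
    summaries = []
    if not ens.empty:
        for grouping in (
            ["scenario", "horizon", "dispersal"],
            ["realm", "scenario", "horizon", "dispersal"],
            ["status", "scenario", "horizon", "dispersal"],
        ):
            s = summarize_contractions(
                ens, grouping, contracting_only=True, n_boot=cfg.n_boot,
                seed=derived_seed(cfg.seed, "bootstrap", *grouping),
            )
            s["grouping"] = "/".join(grouping)
            summaries.append(s)
    res.summaries = (
        pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    )
    res.stages_done.append("impact")


def _stage_assemblage(res: PipelineResult) -> None:
    cfg = res.config
    factor = cfg.aggregation_factor
    pairs = _retained_pairs(res)
    res.richness = {}
    res.deficits = {}
    coarse_cell = res.realm_mask.grid.cell_size * factor
    for disp in cfg.dispersal_modes:
        for alg in cfg.algorithms:
            sids = [s for s, a in pairs if a == alg]
            cur_maps = [
                res.binary_maps[(s, alg, "current")]
                for s in sids
                if (s, alg, "current") in res.binary_maps
            ]
            if not cur_maps:
                continue
            cur_rich = stack_richness(
                cur_maps, factor=factor, cell_size=coarse_cell,
                scenario="current", algorithm=alg, dispersal=disp,
            )
            res.richness[("current", None, alg, disp)] = cur_rich
            for scen in cfg.scenarios:
                for horizon in cfg.horizons:
                    fut_maps = []
                    for s in sids:
                        fut = res.binary_maps.get((s, alg, (scen, horizon)))
                        cur = res.binary_maps.get((s, alg, "current"))
                        if fut is None or cur is None:
                            continue
                        if disp == "none":
                            fut = BinaryRangeMap(
                                species_id=fut.species_id,
                                presence=fut.presence & cur.presence,
                                background=fut.background,
                                criterion=fut.criterion,
                                scenario=fut.scenario,
                                horizon=fut.horizon,
                                algorithm=fut.algorithm,
                            )
                        fut_maps.append(fut)
                    fut_rich = stack_richness(
                        fut_maps, factor=factor, cell_size=coarse_cell,
                        scenario=scen, horizon=horizon, algorithm=alg, dispersal=disp,
                    )
                    res.richness[(scen, horizon, alg, disp)] = fut_rich
                    res.deficits[(scen, horizon, alg, disp)] = deficit_map(
                        cur_rich, fut_rich
                    )
        # algorithm-averaged deficits
        for scen in cfg.scenarios:
            for horizon in cfg.horizons:
                maps = [
                    res.deficits[(scen, horizon, alg, disp)]
                    for alg in cfg.algorithms
                    if (scen, horizon, alg, disp) in res.deficits
                ]
                if maps:
                    res.deficits[(scen, horizon, ENSEMBLE, disp)] = (
                        algorithm_average_map(maps)
                    )
    res.stages_done.append("assemblage")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "prep": _stage_prep,
    "occurrences": _stage_occurrences,
    "fit": _stage_fit,
    "binarize": _stage_binarize,
    "impact": _stage_impact,
    "assemblage": _stage_assemblage,
}


def run_pipeline(
    config: PipelineConfig,
    through_stage: str = "assemblage",
    write: bool = True,
) -> PipelineResult:
    """Execute stages up to ``through_stage`` and (optionally) write outputs."""
    if through_stage not in STAGES:
        raise ConfigurationError(f"unknown stage {through_stage!r}")
    res = PipelineResult(config=config)
    for stage in STAGES[: STAGES.index(through_stage) + 1]:
        try:
            _STAGE_FUNCS[stage](res)
        except Exception as exc:  # annotate failures with the stage name
            raise type(exc)(f"[stage {stage}] {exc}") from exc
    res.manifest = _build_manifest(res)
    if write:
        write_outputs(res)
    return res


def _build_manifest(res: PipelineResult) -> dict:
    from . import __version__

    cfg = res.config
    reasons = pd.Series([e["reason"] for e in res.exclusions]).value_counts().to_dict()
    return {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "stages_done": list(res.stages_done),
        "n_species_input": len(res.species) + sum(
            1 for e in res.exclusions if e["reason"] in ("min_presence", "not_endemic", "outside_grid")
        ),
        "n_species_modeled": len(res.species),
        "n_models_fit": 0 if res.metrics is None else int(len(res.metrics)),
        "n_retained_pairs": len(_retained_pairs(res)),
        "n_range_change_records": 0
        if res.range_changes is None
        else int(len(res.range_changes)),
        "exclusion_reasons": reasons,
    }


def write_outputs(res: PipelineResult) -> Path:
    """Write tables (CSV), maps (TIFF) and the run manifest (JSON)."""
    cfg = res.config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if res.realm_mask is not None:
        aio.write_realm_mask(res.realm_mask, out / "realm_mask.tif")
    if res.world is not None:
        aio.write_cube(res.world.obs_baseline, out / "cube_obs_baseline.nc")
    if res.species:
        aio.write_table(
            pd.DataFrame(
                [
                    {"species_id": r.species_id, "realm": r.realm, "family": r.family,
                     "status": r.status, "n_presence": r.n_presence}
                    for r in res.species
                ]
            ),
            out / "species.csv",
        )
    if res.designs:
        rows = []
        for sid in sorted(res.designs):
            d = res.designs[sid]
            n_runs = len(d.runs)
            for label, cells in (("P", d.presence_cells), ("PA", d.pseudoabsence_cells)):
                train_sets = [
                    set(r.train_presence if label == "P" else r.train_background)
                    for r in d.runs
                ]
                for c in cells:
                    rows.append(
                        {"species_id": sid, "cell_id": int(c), "label": label,
                         "runs_train": "".join(
                             "1" if c in train_sets[k] else "0" for k in range(n_runs)
                         )}
                    )
        aio.write_table(pd.DataFrame(rows), out / "occurrences.csv")
    if res.exclusions:
        aio.write_table(pd.DataFrame(res.exclusions), out / "exclusions.csv")
    if res.metrics is not None and not res.metrics.empty:
        aio.write_table(
            res.metrics.sort_values(["species_id", "algorithm", "run"]),
            out / "metrics.csv",
        )
    if res.thresholds:
        aio.write_table(pd.DataFrame(res.thresholds), out / "thresholds.csv")
    if res.range_changes is not None and not res.range_changes.empty:
        aio.write_table(res.range_changes, out / "range_changes.csv")
    if res.summaries is not None and not res.summaries.empty:
        aio.write_table(res.summaries, out / "summaries.csv")
    for (scen, horizon, alg, disp), dmap in res.deficits.items():
        aio.write_raster(
            dmap.percent_loss.astype(np.float32),
            dmap.grid,
            out / f"deficit_{scen}_{horizon}_{disp}_{alg}.tif",
            scenario=str(scen), horizon=str(horizon), dispersal=disp, algorithm=alg,
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, sort_keys=True, default=str)
    return out
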