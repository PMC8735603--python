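"""End-to-end pipeline: screening, per-species ESMs, richness, concordance.

`run_pipeline` composes the whole analysis with reproducible seeding: a
predictor stack (loaded or simulated) is screened for collinearity, a
shared background sample is drawn, each rare species is modeled with an
Ensemble of Small Models, binary maps are stacked into richness surfaces
overall and per guild, and (optionally) two richness surfaces are
compared with local Lee's L. Per-species failures are logged and do not
abort the run; a manifest records the config hash and per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, lee as lee_mod, predictors, richness, synthetic
from .errors import InvalidArgumentError
from .esm import EsmSpeciesModel, make_background
from .raster import RasterStack, write_ascii
from .predictors import DEFAULT_KEEP_PRIORITY

__all__ = ["RunConfig", "select_rare_species", "run_pipeline", "PipelineResult"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``predictor_dir`` (a directory of .asc layers) or ``scenario``
    (a synthetic landscape) must be provided; likewise ``occurrence_csv``
    or synthetic ``species``. Rarity bounds follow the field convention:
    fewer than ``rarity_max_occurrences`` records (exclusive) and at
    least ``rarity_min_occurrences`` (inclusive).
    """

    predictor_dir: str | None = None
    occurrence_csv: str | None = None
    scenario: synthetic.SyntheticScenario | None = None
    species: list[synthetic.SpeciesSpec] | None = None
    rarity_min_occurrences: int = 5
    rarity_max_occurrences: int = 30
    n_background: int = 10_000
    correlation_threshold: float = 0.7
    keep_priority: tuple[str, ...] = DEFAULT_KEEP_PRIORITY
    techniques: tuple[str, ...] = ("maxent", "rf")
    n_reps: int = 10
    train_frac: float = 0.8
    rf_trees: int = 500
    aggregation_factor: int = 10
    lee_scheme: str = "queen"
    lee_n_sims: int = 999
    run_lee: bool = False
    lee_pair: tuple[str, str] = ("all", "moss")
    stack_only_better_than_random: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rarity_min_occurrences <= self.rarity_max_occurrences:
            raise InvalidArgumentError("invalid rarity bounds")
        if not 0 < self.train_frac < 1:
            raise InvalidArgumentError("train_frac must be in (0, 1)")

    def content_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__"):
                return {k: v for k, v in vars(o).items()}
            return str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def select_rare_species(
    occurrence_table: pd.DataFrame,
    min_occ: int = 5,
    max_occ_exclusive: int = 30,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the rarity selection rules to an occurrence table.

    Returns (per-species counts of the retained species, report). The
    report counts species at each selection stage: total distinct
    species, those under the rarity ceiling, and those also meeting the
    modeling floor.
    """
    if occurrence_table.empty:
        raise InvalidArgumentError("empty occurrence table")
    if "species_id" not in occurrence_table.columns:
        raise InvalidArgumentError("occurrence table needs a species_id column")
    counts = occurrence_table.groupby("species_id").size()
    rare = counts[counts < max_occ_exclusive]
    retained = rare[rare >= min_occ]
    report = {
        "total_species": int(counts.size),
        "rare_species": int(rare.size),
        "retained_species": int(retained.size),
    }
    out = retained.rename("n_occurrences").reset_index()
    if "guild" in occurrence_table.columns:
        guilds = occurrence_table.groupby("species_id")["guild"].first()
        out["guild"] = out["species_id"].map(guilds)
    return out, report


@dataclass
class PipelineResult:
    """Everything a run produced, in memory."""

    manifest: dict
    metrics: pd.DataFrame
    correlation_matrix: pd.DataFrame
    retained_predictors: list[str]
    selection_report: dict[str, int]
    species_results: dict[str, object]
    continuous_maps: dict[str, object]
    binary_maps: dict[str, object]
    richness_maps: dict[str, object]
    lee_result: object | None = None


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis; optionally write all artifacts to out_dir."""
    seed = config.seed
    # --- inputs -----------------------------------------------------------
    if config.scenario is not None:
        species = config.species or synthetic.default_species_set(
            config.scenario, seed=_stage_seed(seed, 0)
        )
        stack, plots, occurrences = synthetic.gen_study(config.scenario, species)
    elif config.predictor_dir and config.occurrence_csv:
        stack = RasterStack.read_dir(config.predictor_dir)
        occurrences = pd.read_csv(config.occurrence_csv)
    else:
        raise InvalidArgumentError(
            "config needs predictor_dir+occurrence_csv or a scenario"
        )

    # --- screening --------------------------------------------------------
    bg_xy_seed = _stage_seed(seed, 1)
    background = make_background(stack, n=config.n_background, seed=bg_xy_seed)
    retained, corr = predictors.correlation_filter(
        stack,
        background[["x", "y"]].to_numpy(),
        threshold=config.correlation_threshold,
        keep_priority=config.keep_priority,
    )
    log.info("retained predictors: %s", retained)
    stack = stack.subset(retained)

    # --- species selection ------------------------------------------------
    selected, report = select_rare_species(
        occurrences, config.rarity_min_occurrences, config.rarity_max_occurrences
    )
    log.info("species selection report: %s", report)

    # --- per-species ESMs -------------------------------------------------
    species_results: dict[str, object] = {}
    continuous_maps: dict[str, object] = {}
    binary_maps: dict[str, object] = {}
    metric_rows = []
    guild_of: dict[str, str] = {}
    for si, sp_id in enumerate(selected["species_id"]):
        occ = occurrences[occurrences["species_id"] == sp_id]
        try:
            model = EsmSpeciesModel.from_occurrences(
                stack,
                occ,
                background,
                predictor_names=retained,
                techniques=config.techniques,
                n_reps=config.n_reps,
                train_frac=config.train_frac,
                rf_trees=config.rf_trees,
            )
            res = model.fit(seed=_stage_seed(seed, 100 + si))
        except Exception:  # per-species failures must not abort the run
            log.exception("species %s failed; skipping", sp_id)
            continue
        species_results[sp_id] = res
        metric_rows.append(res.metrics)
        guild_of[sp_id] = res.model.guild or "moss"
        if not res.unmodellable:
            cont = res.predict(stack)
            continuous_maps[sp_id] = cont
            if res.better_than_random or not config.stack_only_better_than_random:
                binary_maps[sp_id] = evaluation.binarize(cont, res.threshold)
    metrics = pd.DataFrame(metric_rows).reset_index(drop=True)

    # --- richness ---------------------------------------------------------
    richness_maps: dict[str, object] = {}
    if binary_maps:
        richness_maps = richness.guild_richness(
            binary_maps, {sp: guild_of[sp] for sp in binary_maps}
        )

    # --- Lee concordance (optional) ---------------------------------------
    lee_result = None
    if config.run_lee and richness_maps:
        a_name, b_name = config.lee_pair
        a = lee_mod.aggregate_mean(richness_maps[a_name], config.aggregation_factor)
        b = lee_mod.aggregate_mean(richness_maps[b_name], config.aggregation_factor)
        model = lee_mod.LeeConcordance(a, b, scheme=config.lee_scheme)
        lee_result = model.fit(n_sims=config.lee_n_sims, seed=_stage_seed(seed, 2))

    manifest = {
        "config_hash": config.content_hash(),
        "master_seed": seed,
        "stage_seeds": {
            "species_set": _stage_seed(seed, 0),
            "background": bg_xy_seed,
            "lee": _stage_seed(seed, 2),
            "species": {
                sp: _stage_seed(seed, 100 + i)
                for i, sp in enumerate(selected["species_id"])
            },
        },
        "retained_predictors": retained,
        "selection_report": report,
        "n_background": config.n_background,
        "species_outcomes": {
            sp: {
                "better_than_random": bool(r.better_than_random),
                "unmodellable": bool(r.unmodellable),
            }
            for sp, r in species_results.items()
        },
        "software": "esmsdm 0.1.0",
    }

    result = PipelineResult(
        manifest=manifest,
        metrics=metrics,
        correlation_matrix=corr,
        retained_predictors=retained,
        selection_report=report,
        species_results=species_results,
        continuous_maps=continuous_maps,
        binary_maps=binary_maps,
        richness_maps=richness_maps,
        lee_result=lee_result,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write metrics CSV, correlation CSV, maps (.asc), manifest and sidecars."""
    out = Path(out_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(out / "metrics.csv", index=False)
    result.correlation_matrix.to_csv(out / "predictor_correlations.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    for sp, r in result.continuous_maps.items():
        write_ascii(r, out / "maps" / f"{sp}_continuous.asc")
    for sp, r in result.binary_maps.items():
        write_ascii(r, out / "maps" / f"{sp}_binary.asc")
    for name, r in result.richness_maps.items():
        write_ascii(r, out / "maps" / f"richness_{name}.asc")
    sidecar = {
        name: sorted(result.binary_maps)
        if name == "all"
        else sorted(
            sp
            for sp in result.binary_maps
            if result.species_results[sp].model.guild == name
        )
        for name in result.richness_maps
    }
    with open(out / "richness_contributors.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    if result.lee_result is not None:
        for name, r in result.lee_result.rasters().items():
            write_ascii(r, out / "maps" / f"{name}.asc")
        with open(out / "lee_metadata.json", "w") as fh:
            json.dump(result.lee_result.to_metadata(), fh, indent=2)
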