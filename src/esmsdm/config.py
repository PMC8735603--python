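"""YAML configuration loading for pipeline runs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .errors import InvalidArgumentError
from .pipeline import RunConfig
from .synthetic import SpeciesSpec, SyntheticScenario

__all__ = ["load_config", "dump_scenario"]


def _scenario_from_dict(d: dict) -> SyntheticScenario:
    d = dict(d)
    if "pairwise_target_correlations" in d and d["pairwise_target_correlations"]:
        d["pairwise_target_correlations"] = np.asarray(
            d["pairwise_target_correlations"], dtype=float
        )
    if "predictor_names" in d and d["predictor_names"]:
        d["predictor_names"] = tuple(d["predictor_names"])
    return SyntheticScenario(**d)


def _species_from_dict(d: dict) -> SpeciesSpec:
    d = dict(d)
    d["response_pair"] = tuple(d["response_pair"])
    d["coefficients"] = tuple(float(c) for c in d["coefficients"])
    return SpeciesSpec(**d)


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file.

    Recognized top-level keys mirror the RunConfig fields; a ``scenario``
    mapping and a ``species`` list describe a synthetic study.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidArgumentError("config must be a YAML mapping")
    kwargs = dict(raw)
    if "scenario" in kwargs and kwargs["scenario"]:
        kwargs["scenario"] = _scenario_from_dict(kwargs["scenario"])
    if "species" in kwargs and kwargs["species"]:
        kwargs["species"] = [_species_from_dict(s) for s in kwargs["species"]]
    for key in ("keep_priority", "techniques", "lee_pair"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)


def dump_scenario(scenario: SyntheticScenario, path: str | Path) -> None:
    """Write a scenario back out as YAML (arrays become nested lists)."""
    d = {
        "grid_rows": scenario.grid_rows,
        "grid_cols": scenario.grid_cols,
        "cell_size": scenario.cell_size,
        "n_predictors": scenario.n_predictors,
        "autocorr_range": scenario.autocorr_range,
        "pairwise_target_correlations": np.asarray(
            scenario.pairwise_target_correlations
        ).tolist(),
        "n_plots": scenario.n_plots,
        "seed": scenario.seed,
        "predictor_names": list(scenario.predictor_names),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
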