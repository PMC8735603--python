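"""Synthetic landscapes, plot networks and virtual rare species.

The generators emulate the statistical structure the downstream analysis
assumes: a handful of standardized, weakly inter-correlated, spatially
autocorrelated predictor layers over a regular grid; a network of survey
plots; and rare species whose occurrence probability is a logistic
function of two predictors (with interaction), with per-species presence
counts in the rare-species range (5-29). Every generator is a pure
function of its seed and parameters, so downstream stages are testable
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GenerationFailureError, InvalidArgumentError
from .raster import GridSpec, Raster, RasterStack

__all__ = [
    "GUILDS",
    "SyntheticScenario",
    "SpeciesSpec",
    "gen_gaussian_field",
    "gen_predictor_stack",
    "gen_plot_network",
    "gen_species_occurrences",
    "gen_study",
]

GUILDS = ("moss", "liverwort", "sphagna")


@dataclass
class SyntheticScenario:
    """Parameters of a synthetic landscape and sampling design.

    Defaults mirror the structure of a boreal field study: five
    standardized predictors on a 30 m grid, 389 survey plots, and weak
    pairwise correlation between predictors.
    """

    grid_rows: int = 100
    grid_cols: int = 100
    cell_size: float = 30.0
    n_predictors: int = 5
    autocorr_range: float = 8.0
    pairwise_target_correlations: np.ndarray | None = None
    n_plots: int = 389
    seed: int = 0
    predictor_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.grid_rows < 10 or self.grid_cols < 10:
            raise InvalidArgumentError("grid must be at least 10x10")
        if self.n_predictors < 2:
            raise InvalidArgumentError("need at least 2 predictors")
        if self.pairwise_target_correlations is None:
            self.pairwise_target_correlations = np.eye(self.n_predictors)
        C = np.asarray(self.pairwise_target_correlations, dtype=float)
        if C.shape != (self.n_predictors, self.n_predictors):
            raise InvalidArgumentError("correlation matrix shape mismatch")
        if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise InvalidArgumentError(
                "target correlations must be symmetric with unit diagonal"
            )
        self.pairwise_target_correlations = C
        if self.predictor_names is None:
            self.predictor_names = tuple(f"P{i + 1}" for i in range(self.n_predictors))
        if len(self.predictor_names) != self.n_predictors:
            raise InvalidArgumentError("predictor_names length mismatch")
        if self.n_plots > self.grid_rows * self.grid_cols:
            raise InvalidArgumentError("more plots than grid cells")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_rows, self.grid_cols, cell_size=self.cell_size)


@dataclass
class SpeciesSpec:
    """A virtual rare species responding to a pair of predictors.

    ``coefficients`` are (intercept, linear_a, linear_b, interaction) on
    the logit scale, applied to the two ``response_pair`` predictors.
    ``target_occurrences`` is the exact presence count to generate, within
    the rare-species range [5, 29].
    """

    species_id: str
    guild: str
    response_pair: tuple[str, str]
    coefficients: tuple[float, float, float, float]
    target_occurrences: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise InvalidArgumentError(f"unknown guild {self.guild!r}")
        if len(set(self.response_pair)) != 2:
            raise InvalidArgumentError("response_pair members must be distinct")
        if not 5 <= self.target_occurrences <= 29:
            raise InvalidArgumentError("target_occurrences must be in [5, 29]")


def _standardize(a: np.ndarray) -> np.ndarray:
    return (a - a.mean()) / a.std()


def gen_gaussian_field(
    rows: int, cols: int, autocorr_range: float, seed: int
) -> np.ndarray:
    """Standardized Gaussian random field with tunable autocorrelation.

    White noise is smoothed with a Gaussian kernel (sigma = range/2,
    wrap-around boundaries for stationarity) and z-scored. Correlation
    between neighboring cells decays over roughly ``autocorr_range``
    cells; the exact kernel is an implementation choice, only the decay
    contract is relied upon downstream.
    """
    if rows < 10 or cols < 10:
        raise InvalidArgumentError("field must be at least 10x10")
    if autocorr_range <= 0:
        raise InvalidArgumentError("autocorr_range must be positive")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((rows, cols))
    smooth = ndimage.gaussian_filter(white, sigma=autocorr_range / 2.0, mode="wrap")
    return _standardize(smooth)


def gen_predictor_stack(scenario: SyntheticScenario) -> RasterStack:
    """Correlated, standardized predictor layers for a scenario.

    Independent Gaussian fields are linearly mixed through the Cholesky
    factor of the target correlation matrix, which controls the expected
    pairwise Pearson correlations exactly; each mixed layer is then
    re-standardized. Raises if the target matrix is not positive
    semi-definite.
    """
    C = scenario.pairwise_target_correlations
    try:
        L = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
    except np.linalg.LinAlgError as exc:
        raise InvalidArgumentError(
            "target correlation matrix is not positive semi-definite"
        ) from exc
    fields = np.stack(
        [
            gen_gaussian_field(
                scenario.grid_rows,
                scenario.grid_cols,
                scenario.autocorr_range,
                seed=np.random.SeedSequence([scenario.seed, i]).generate_state(1)[0],
            )
            for i in range(scenario.n_predictors)
        ]
    )
    flat = fields.reshape(scenario.n_predictors, -1)
    mixed = L @ flat
    layers = {}
    for name, layer in zip(scenario.predictor_names, mixed):
        z = _standardize(layer).reshape(scenario.grid_rows, scenario.grid_cols)
        layers[name] = Raster(z, scenario.grid)
    return RasterStack(layers)


def gen_plot_network(scenario: SyntheticScenario) -> pd.DataFrame:
    """Survey plot locations: distinct cell centers, uniform without replacement.

    Returns a DataFrame with columns ``plot_id, x, y, row, col``.
    """
    n_cells = scenario.grid_rows * scenario.grid_cols
    if scenario.n_plots > n_cells:
        raise InvalidArgumentError("more plots requested than grid cells")
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 10_001]))
    flat = rng.choice(n_cells, size=scenario.n_plots, replace=False)
    rows, cols = np.unravel_index(flat, (scenario.grid_rows, scenario.grid_cols))
    xy = np.array([scenario.grid.cell_center(r, c) for r, c in zip(rows, cols)])
    return pd.DataFrame(
        {
            "plot_id": [f"plot_{i:04d}" for i in range(scenario.n_plots)],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "row": rows,
            "col": cols,
        }
    )


def gen_species_occurrences(
    stack: RasterStack, plots: pd.DataFrame, spec: SpeciesSpec
) -> pd.DataFrame:
    """Presence records for one virtual species at the plot network.

    The true per-plot presence probability is the inverse logit of
    ``b0 + b1*A + b2*B + b3*A*B`` over the response pair (A, B). The
    exact presence count is achieved by weighted sampling of plots
    without replacement, with probability proportional to the true
    probability surface — a seeded, reproducible procedure that matches
    per-species occurrence counts exactly.

    Returns a DataFrame ``species_id, x, y, guild`` with
    ``attrs["true_probability"]`` holding the per-plot probability vector
    (aligned with ``plots``) for recovery tests.
    """
    if plots.empty:
        raise InvalidArgumentError("plot network is empty")
    for name in spec.response_pair:
        if name not in stack:
            raise InvalidArgumentError(f"predictor {name!r} not in stack")
    a = stack[spec.response_pair[0]].values_at(plots[["x", "y"]].to_numpy())
    b = stack[spec.response_pair[1]].values_at(plots[["x", "y"]].to_numpy())
    b0, b1, b2, b3 = spec.coefficients
    eta = b0 + b1 * a + b2 * b + b3 * a * b
    with np.errstate(over="ignore"):  # exp overflow maps cleanly to p = 0
        p = 1.0 / (1.0 + np.exp(-eta))
    positive = np.count_nonzero(p > 0)
    if positive < spec.target_occurrences:
        raise GenerationFailureError(
            f"only {positive} plots with positive probability; "
            f"cannot reach {spec.target_occurrences} occurrences"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 20_002]))
    chosen = rng.choice(
        len(plots), size=spec.target_occurrences, replace=False, p=p / p.sum()
    )
    out = pd.DataFrame(
        {
            "species_id": spec.species_id,
            "x": plots["x"].to_numpy()[chosen],
            "y": plots["y"].to_numpy()[chosen],
            "guild": spec.guild,
        }
    )
    out.attrs["true_probability"] = p
    out.attrs["presence_index"] = np.sort(chosen)
    return out


def gen_study(
    scenario: SyntheticScenario,
    species: list[SpeciesSpec],
) -> tuple[RasterStack, pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic study: stack, plots, stacked occurrence table."""
    stack = gen_predictor_stack(scenario)
    plots = gen_plot_network(scenario)
    tables = []
    for sp in species:
        t = gen_species_occurrences(stack, plots, sp)
        t.attrs = {}  # per-species attrs cannot survive a concat
        tables.append(t)
    occurrences = pd.concat(tables, ignore_index=True)
    return stack, plots, occurrences


def default_species_set(
    scenario: SyntheticScenario,
    n_species: int = 52,
    guild_counts: tuple[int, int, int] = (33, 14, 5),
    seed: int = 0,
) -> list[SpeciesSpec]:
    """A study-sized community of virtual rare species.

    Guild sizes default to 33 mosses, 14 liverworts, 5 sphagna (52 in
    total). Each species responds to a random predictor pair with a
    strong linear signal plus a mild interaction; occurrence counts are
    drawn uniformly from [5, 29].
    """
    if sum(guild_counts) != n_species:
        raise InvalidArgumentError("guild counts must sum to n_species")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 30_003]))
    names = list(scenario.predictor_names)
    specs: list[SpeciesSpec] = []
    guild_labels = [g for g, k in zip(GUILDS, guild_counts) for _ in range(k)]
    for i, guild in enumerate(guild_labels):
        pair = tuple(rng.choice(names, size=2, replace=False))
        sign = rng.choice([-1.0, 1.0])
        coeffs = (
            float(rng.normal(-1.0, 0.5)),
            float(sign * rng.uniform(2.0, 4.0)),
            float(rng.normal(0.0, 1.0)),
            float(rng.normal(0.0, 0.5)),
        )
        specs.append(
            SpeciesSpec(
                species_id=f"sp_{i + 1:03d}",
                guild=guild,
                response_pair=pair,  # type: ignore[arg-type]
                coefficients=coeffs,
                target_occurrences=int(rng.integers(5, 30)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs
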