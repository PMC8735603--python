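"""Ensembles of Small Models (ESMs) for presence-background data.

An ESM sidesteps overfitting at very low sample size by fitting *all*
bivariate (two-predictor) models from a predictor set, scoring each by
cross-validated Somers' D (2*AUC - 1), discarding those no better than
random, and averaging the rest weighted by their scores. Two learner
families are ensembled: a Maxent-style penalized presence-background
logistic model and a random forest; the two technique-level ensembles
are themselves averaged with weights proportional to their own
cross-validated Somers' D.

The public surface follows the Model -> fit() -> Results idiom:
:class:`EsmSpeciesModel` is built from a :class:`TrainingData` (or from
occurrences + a raster stack), ``fit()`` returns an :class:`EsmResults`
carrying sub-model weights, technique scores, pooled out-of-split
predictions, evaluation metrics, ``predict()`` and ``summary()``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from . import evaluation
from .errors import InvalidArgumentError
from .raster import Raster, RasterStack

__all__ = [
    "TrainingData",
    "make_background",
    "assemble_training",
    "enumerate_pairs",
    "crossvalidate_bivariate",
    "fit_esm_technique",
    "combine_techniques",
    "predict_esm",
    "rf_learner",
    "maxent_learner",
    "RandomForestLearner",
    "MaxentLearner",
    "TechniqueEnsemble",
    "EsmSpeciesModel",
    "EsmResults",
]

SCALE = 1000  # continuous suitability maps are integers on [0, 1000]

_TECH_CODE = {"maxent": 101, "rf": 202}  # stable per-technique seed offsets


# ---------------------------------------------------------------------------
# training data


@dataclass
class TrainingData:
    """Presence + background rows with per-row case weights.

    Class weight totals are equal: presences carry weight 1, each
    background row carries n_presences / n_background.
    """

    X: pd.DataFrame
    y: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.w = np.asarray(self.w, dtype=float)
        if not (len(self.X) == len(self.y) == len(self.w)):
            raise InvalidArgumentError("X, y, w length mismatch")
        if self.X.isna().any().any():
            raise InvalidArgumentError("missing predictor values in training rows")

    @property
    def n_presences(self) -> int:
        return int((self.y == 1).sum())

    @property
    def predictor_names(self) -> list[str]:
        return list(self.X.columns)


def make_background(
    stack: RasterStack,
    n: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    replace: bool = True,
) -> pd.DataFrame:
    """Random background (pseudo-absence) points over the unmasked area.

    Cells are drawn uniformly over jointly valid cells; returned frame has
    ``x, y`` plus one column per predictor. One shared background set per
    run serves all species.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    valid = stack.valid_mask()
    idx = np.flatnonzero(valid.ravel())
    if not replace and n > idx.size:
        raise InvalidArgumentError(
            f"{n} points without replacement exceeds {idx.size} valid cells"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n, replace=replace)
    rows, cols = np.unravel_index(chosen, stack.shape)
    xy = np.array([stack.grid.cell_center(r, c) for r, c in zip(rows, cols)])
    out = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]})
    for name in stack.names:
        out[name] = stack[name].data[rows, cols]
    return out


def assemble_training(
    presence_values: pd.DataFrame, background_values: pd.DataFrame
) -> TrainingData:
    """Stack presence and background predictor rows with equal class weighting."""
    pres = presence_values.dropna()
    bg = background_values.dropna()
    if len(pres) == 0:
        raise InvalidArgumentError("no presence rows")
    if len(bg) == 0:
        raise InvalidArgumentError("no background rows")
    cols = [c for c in pres.columns if c in bg.columns and c not in ("x", "y")]
    X = pd.concat([pres[cols], bg[cols]], ignore_index=True)
    y = np.concatenate([np.ones(len(pres), dtype=int), np.zeros(len(bg), dtype=int)])
    w = np.concatenate([np.ones(len(pres)), np.full(len(bg), len(pres) / len(bg))])
    return TrainingData(X, y, w)


def enumerate_pairs(predictor_names: Sequence[str]) -> list[tuple[str, str]]:
    """All C(n, 2) unordered predictor pairs, lexicographic order."""
    names = list(predictor_names)
    if len(names) < 2 or len(set(names)) != len(names):
        raise InvalidArgumentError("need >= 2 distinct predictor names")
    return list(itertools.combinations(sorted(names), 2))


# ---------------------------------------------------------------------------
# learners


class RandomForestLearner:
    """Bagged decision trees honoring case weights; probability = mean vote."""

    def __init__(self, seed: int = 0, n_trees: int = 500):
        if n_trees < 1:
            raise InvalidArgumentError("n_trees must be >= 1")
        self.seed = int(seed)
        self.n_trees = int(n_trees)
        self._clf: RandomForestClassifier | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, w: np.ndarray) -> "RandomForestLearner":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise InvalidArgumentError("single-class training labels")
        self._clf = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.seed, n_jobs=1
        )
        self._clf.fit(np.asarray(X, dtype=float), y, sample_weight=w)
        return self

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        assert self._clf is not None, "learner not fitted"
        return self._clf.predict_proba(np.asarray(X, dtype=float))[:, 1]


class MaxentLearner:
    """Penalized presence-background logistic model on an expanded feature set.

    Features are the linear, quadratic and pairwise-product terms of the
    two predictors (the low-order subset of classic maximum-entropy
    feature classes), z-scored on the training rows. The L1 penalty
    strength is selected over a small path by internal stratified
    cross-validation scored by held-out deviance (log loss), the standard
    criterion for penalized likelihood paths. Probability is the inverse
    logit of the linear predictor.
    """

    def __init__(self, seed: int = 0, n_Cs: int = 5, inner_cv: int = 3):
        self.seed = int(seed)
        self.n_Cs = int(n_Cs)
        self.inner_cv = int(inner_cv)
        self._clf: LogisticRegressionCV | None = None
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    @staticmethod
    def _expand(X: np.ndarray) -> np.ndarray:
        a, b = X[:, 0], X[:, 1]
        return np.column_stack([a, b, a * a, b * b, a * b])

    def fit(self, X: np.ndarray, y: np.ndarray, w: np.ndarray) -> "MaxentLearner":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.isfinite(X).all():
            raise InvalidArgumentError("non-finite features")
        if len(np.unique(y)) < 2:
            raise InvalidArgumentError("single-class training labels")
        F = self._expand(X)
        self._mu = F.mean(axis=0)
        self._sd = F.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        Fz = (F - self._mu) / self._sd
        n_pres = int((y == 1).sum())
        folds = max(2, min(self.inner_cv, n_pres))
        self._clf = LogisticRegressionCV(
            Cs=np.logspace(-2, 2, self.n_Cs),
            cv=StratifiedKFold(folds),
            l1_ratios=(1.0,),  # pure L1 path
            solver="liblinear",
            scoring="neg_log_loss",
            max_iter=500,
            random_state=self.seed,
            use_legacy_attributes=False,
        )
        self._clf.fit(Fz, y, sample_weight=np.asarray(w, dtype=float))
        return self

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        assert self._clf is not None, "learner not fitted"
        Fz = (self._expand(np.asarray(X, dtype=float)) - self._mu) / self._sd
        return self._clf.predict_proba(Fz)[:, 1]


def rf_learner(seed: int = 0, n_trees: int = 500) -> RandomForestLearner:
    return RandomForestLearner(seed=seed, n_trees=n_trees)


def maxent_learner(seed: int = 0, regularization: float | None = None) -> MaxentLearner:
    """Maxent-style learner; ``regularization`` is selected internally when None."""
    if regularization is not None and regularization < 0:
        raise InvalidArgumentError("regularization must be >= 0")
    return MaxentLearner(seed=seed)


LEARNER_FACTORIES: dict[str, Callable[..., object]] = {
    "rf": RandomForestLearner,
    "maxent": MaxentLearner,
}


# ---------------------------------------------------------------------------
# cross-validation machinery


def _stratified_splits(
    y: np.ndarray,
    n_reps: int,
    train_frac: float,
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated random stratified train/validation splits.

    Each class contributes at least one row to the validation fold, so a
    validation AUC is always defined; a species with 5 presences
    validates on exactly 1 presence per split.
    """
    if not 0 < train_frac < 1:
        raise InvalidArgumentError("train_frac must be in (0, 1)")
    y = np.asarray(y)
    splits = []
    for _ in range(n_reps):
        train_idx, val_idx = [], []
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            if idx.size < 2:
                raise InvalidArgumentError("class with < 2 rows cannot be split")
            n_val = max(1, int(round((1 - train_frac) * idx.size)))
            n_val = min(n_val, idx.size - 1)
            perm = rng.permutation(idx)
            val_idx.append(perm[:n_val])
            train_idx.append(perm[n_val:])
        splits.append((np.concatenate(train_idx), np.concatenate(val_idx)))
    return splits


def _learner_seed(root: int, *path: int) -> int:
    return int(np.random.SeedSequence([root, *path]).generate_state(1)[0] % (2**31))


def crossvalidate_bivariate(
    data: TrainingData,
    pair: tuple[str, str],
    learner_factory: Callable[[int], object],
    n_reps: int = 10,
    train_frac: float = 0.8,
    seed: int = 0,
) -> float:
    """Cross-validated Somers' D of one bivariate model.

    Ten (by default) seeded random splits stratified by class, 80% train /
    20% validation; the learner is refit per split and scored by
    validation AUC; returns 2*(mean AUC) - 1.
    """
    if data.n_presences < 5:
        raise InvalidArgumentError("need >= 5 presences")
    for name in pair:
        if name not in data.X.columns:
            raise InvalidArgumentError(f"predictor {name!r} not in training data")
    rng = np.random.default_rng(seed)
    splits = _stratified_splits(data.y, n_reps, train_frac, rng)
    Xp = data.X[list(pair)].to_numpy()
    aucs = []
    for si, (tr, va) in enumerate(splits):
        learner = learner_factory(_learner_seed(seed, si))
        learner.fit(Xp[tr], data.y[tr], data.w[tr])
        aucs.append(evaluation.auc(learner.predict_probability(Xp[va]), data.y[va]))
    return evaluation.somers_d(float(np.mean(aucs)))


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class TechniqueEnsemble:
    """Retained bivariate models of one technique with normalized weights."""

    technique: str
    pairs: list[tuple[str, str]]
    scores: np.ndarray  # Somers' D of each retained pair
    weights: np.ndarray  # normalized, sum to 1 (empty if no pair retained)
    learners: list[object]  # refit on all data, aligned with pairs
    somers_d: float | None = None  # ensemble-level cross-validated score

    @property
    def empty(self) -> bool:
        return len(self.pairs) == 0

    def predict_probability(self, X: pd.DataFrame) -> np.ndarray:
        if self.empty:
            raise InvalidArgumentError("empty ensemble cannot predict")
        out = np.zeros(len(X))
        for pair, wgt, learner in zip(self.pairs, self.weights, self.learners):
            out += wgt * learner.predict_probability(X[list(pair)].to_numpy())
        return out


def fit_esm_technique(
    data: TrainingData,
    pairs: Sequence[tuple[str, str]],
    learner_family: str,
    seed: int = 0,
    n_reps: int = 10,
    train_frac: float = 0.8,
    learner_kwargs: dict | None = None,
) -> TechniqueEnsemble:
    """Fit and score every bivariate model of one technique.

    Models with cross-validated Somers' D > 0 are retained with weights
    proportional to their scores and refit on all data; an empty ensemble
    (no model better than random) is a valid, flagged outcome.
    """
    if not pairs:
        raise InvalidArgumentError("no pairs supplied")
    factory = LEARNER_FACTORIES[learner_family]
    kwargs = learner_kwargs or {}
    scored = []
    for pi, pair in enumerate(pairs):
        score = crossvalidate_bivariate(
            data,
            pair,
            lambda s, kw=kwargs: factory(seed=s, **kw),
            n_reps=n_reps,
            train_frac=train_frac,
            seed=_learner_seed(seed, pi),
        )
        scored.append((pair, score))
    retained = [(p, s) for p, s in scored if s > 0]
    if not retained:
        return TechniqueEnsemble(learner_family, [], np.array([]), np.array([]), [])
    r_pairs = [p for p, _ in retained]
    r_scores = np.array([s for _, s in retained])
    weights = r_scores / r_scores.sum()
    learners = []
    for pi, pair in enumerate(r_pairs):
        learner = factory(seed=_learner_seed(seed, 900_000 + pi), **kwargs)
        learner.fit(data.X[list(pair)].to_numpy(), data.y, data.w)
        learners.append(learner)
    return TechniqueEnsemble(learner_family, r_pairs, r_scores, weights, learners)


def combine_techniques(
    ensembles: dict[str, TechniqueEnsemble],
    scores: dict[str, float] | None = None,
    equal_weights: bool = False,
) -> dict[str, float]:
    """Cross-technique weights from technique-level Somers' D (clamped at 0).

    If one technique is empty or non-positive, the other receives weight
    1; both empty raises (species unmodellable). ``equal_weights`` forces
    a plain average over non-empty techniques.
    """
    non_empty = {k: e for k, e in ensembles.items() if not e.empty}
    if not non_empty:
        raise InvalidArgumentError("all technique ensembles are empty")
    if equal_weights or scores is None:
        return {k: 1.0 / len(non_empty) for k in non_empty}
    clamped = {k: max(0.0, scores.get(k, 0.0)) for k in non_empty}
    total = sum(clamped.values())
    if total == 0:
        return {k: 1.0 / len(non_empty) for k in non_empty}
    return {k: v / total for k, v in clamped.items()}


def predict_esm(
    ensembles: dict[str, TechniqueEnsemble],
    cross_weights: dict[str, float],
    stack: RasterStack,
) -> Raster:
    """Continuous suitability map on the 0-1000 integer scale.

    Per cell: Somers'-D-weighted mean of bivariate probabilities within
    each technique, then weighted across techniques; cells where any
    needed predictor is masked are nodata.
    """
    used = sorted({n for k in cross_weights for p in ensembles[k].pairs for n in p})
    for name in used:
        if name not in stack:
            raise InvalidArgumentError(f"stack missing predictor {name!r}")
    if not used:
        raise InvalidArgumentError("no retained models to predict from")
    valid = stack.valid_mask(used)
    idx = np.flatnonzero(valid.ravel())
    X = pd.DataFrame(
        {n: stack[n].data.ravel()[idx] for n in used}
    )
    prob = np.zeros(len(X))
    for tech, wgt in cross_weights.items():
        prob += wgt * ensembles[tech].predict_probability(X)
    out = np.full(stack.shape[0] * stack.shape[1], np.nan)
    out[idx] = np.rint(prob * SCALE)
    return Raster(out.reshape(stack.shape), stack.grid)


# ---------------------------------------------------------------------------
# model / results


class EsmSpeciesModel:
    """Ensemble-of-Small-Models for one species.

    Parameters
    ----------
    training : TrainingData
        Presence and background rows with case weights.
    species_id, guild : str
        Carried into results and summaries.
    techniques : sequence of {"maxent", "rf"}
        Learner families to ensemble.
    n_reps, train_frac : int, float
        Repeated stratified split scheme (default 10 reps, 80/20).
    rf_trees : int
        Trees per random forest (default 500).
    cross_technique_weighting : {"somers_d", "equal"}
        How the technique-level ensembles are averaged.
    """

    def __init__(
        self,
        training: TrainingData,
        species_id: str = "species",
        guild: str | None = None,
        techniques: Sequence[str] = ("maxent", "rf"),
        n_reps: int = 10,
        train_frac: float = 0.8,
        rf_trees: int = 500,
        cross_technique_weighting: str = "somers_d",
    ):
        unknown = set(techniques) - set(LEARNER_FACTORIES)
        if unknown:
            raise InvalidArgumentError(f"unknown techniques {unknown}")
        self.training = training
        self.species_id = species_id
        self.guild = guild
        self.techniques = tuple(techniques)
        self.n_reps = n_reps
        self.train_frac = train_frac
        self.rf_trees = rf_trees
        self.cross_technique_weighting = cross_technique_weighting

    @classmethod
    def from_occurrences(
        cls,
        stack: RasterStack,
        occurrences: pd.DataFrame,
        background: pd.DataFrame,
        predictor_names: Sequence[str] | None = None,
        **kwargs,
    ) -> "EsmSpeciesModel":
        """Build from an occurrence table (``x, y`` columns) and a shared
        background table; predictor values are extracted from the stack."""
        names = list(predictor_names) if predictor_names else stack.names
        pres_vals = pd.DataFrame(
            stack.subset(names).table_at(occurrences[["x", "y"]].to_numpy()),
            columns=names,
        )
        sid = kwargs.pop("species_id", None)
        if sid is None and "species_id" in occurrences.columns:
            sid = str(occurrences["species_id"].iloc[0])
        guild = kwargs.pop("guild", None)
        if guild is None and "guild" in occurrences.columns:
            guild = str(occurrences["guild"].iloc[0])
        return cls(
            assemble_training(pres_vals, background[names]),
            species_id=sid or "species",
            guild=guild,
            **kwargs,
        )

    def _learner_kwargs(self, technique: str) -> dict:
        return {"n_trees": self.rf_trees} if technique == "rf" else {}

    def fit(self, seed: int = 0) -> "EsmResults":
        """Fit, score and combine all bivariate models; evaluate out-of-split.

        One shared set of ``n_reps`` stratified 80/20 splits drives every
        stage: per-pair scoring, technique-level ensemble scoring, and the
        pooled final-ensemble evaluation, so no stage ever trains on its
        own validation rows.
        """
        data = self.training
        pairs = enumerate_pairs(data.predictor_names)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        splits = _stratified_splits(data.y, self.n_reps, self.train_frac, rng)

        records = []  # per (technique, pair) diagnostics
        ensembles: dict[str, TechniqueEnsemble] = {}
        val_cache: dict[tuple[str, tuple[str, str], int], np.ndarray] = {}
        auc_mat: dict[str, dict[tuple[str, str], np.ndarray]] = {}

        for tech in self.techniques:
            factory = LEARNER_FACTORIES[tech]
            kwargs = self._learner_kwargs(tech)
            auc_mat[tech] = {}
            scored = []
            for pi, pair in enumerate(pairs):
                Xp = data.X[list(pair)].to_numpy()
                aucs = []
                for si, (tr, va) in enumerate(splits):
                    learner = factory(
                        seed=_learner_seed(seed, _TECH_CODE[tech], pi, si), **kwargs
                    )
                    learner.fit(Xp[tr], data.y[tr], data.w[tr])
                    pred = learner.predict_probability(Xp[va])
                    val_cache[(tech, pair, si)] = pred
                    aucs.append(evaluation.auc(pred, data.y[va]))
                auc_mat[tech][pair] = np.asarray(aucs)
                score = evaluation.somers_d(float(np.mean(aucs)))
                scored.append((pair, score))
                records.append(
                    {"technique": tech, "pair": "+".join(pair), "somers_d": score}
                )
            retained = [(p, s) for p, s in scored if s > 0]
            if not retained:
                ensembles[tech] = TechniqueEnsemble(
                    tech, [], np.array([]), np.array([]), []
                )
                continue
            r_pairs = [p for p, _ in retained]
            r_scores = np.array([s for _, s in retained])
            weights = r_scores / r_scores.sum()
            # ensemble-level CV score from the cached per-split predictions
            tech_aucs = []
            for si, (_, va) in enumerate(splits):
                ens_pred = np.zeros(len(va))
                for pair, wgt in zip(r_pairs, weights):
                    ens_pred += wgt * val_cache[(tech, pair, si)]
                tech_aucs.append(evaluation.auc(ens_pred, data.y[va]))
            tech_score = evaluation.somers_d(float(np.mean(tech_aucs)))
            learners = []
            for pi, pair in enumerate(r_pairs):
                learner = factory(
                    seed=_learner_seed(seed, 77, _TECH_CODE[tech], pi), **kwargs
                )
                learner.fit(data.X[list(pair)].to_numpy(), data.y, data.w)
                learners.append(learner)
            ensembles[tech] = TechniqueEnsemble(
                tech, r_pairs, r_scores, weights, learners, somers_d=tech_score
            )

        table = pd.DataFrame(records)
        non_empty = {k: e for k, e in ensembles.items() if not e.empty}
        if not non_empty:
            return EsmResults(
                model=self,
                ensembles=ensembles,
                cross_weights={},
                bivariate_table=table,
                pooled=pd.DataFrame(columns=["split", "row", "label", "probability"]),
                metrics=_empty_metrics(self, data),
            )

        tech_scores = {k: e.somers_d for k, e in non_empty.items()}
        cross_weights = combine_techniques(
            ensembles,
            tech_scores,
            equal_weights=self.cross_technique_weighting == "equal",
        )

        # Pooled out-of-split predictions of the final ensemble, evaluated
        # honestly: the prediction on split s uses sub-model selection,
        # sub-model weights and cross-technique weights derived from the
        # other splits only (leave-one-split-out). This removes the
        # selection optimism that would otherwise inflate the final AUC of
        # weak species, at no extra fitting cost.
        pooled_rows = []
        for si, (_, va) in enumerate(splits):
            keep = np.ones(self.n_reps, dtype=bool)
            keep[si] = False
            tech_preds: dict[str, np.ndarray] = {}
            tech_scores_ex: dict[str, float] = {}
            for tech in self.techniques:
                sc = {
                    pair: evaluation.somers_d(float(a[keep].mean()))
                    for pair, a in auc_mat[tech].items()
                }
                kept = [(p, s) for p, s in sc.items() if s > 0]
                if not kept:
                    continue
                w = np.array([s for _, s in kept])
                w = w / w.sum()
                pred = np.zeros(len(va))
                for (pair, _), pw in zip(kept, w):
                    pred += pw * val_cache[(tech, pair, si)]
                tech_preds[tech] = pred
                # technique skill on the selection splits, for cross weights
                t_aucs = []
                for sj in np.flatnonzero(keep):
                    p_j = np.zeros(len(splits[sj][1]))
                    for (pair, _), pw in zip(kept, w):
                        p_j += pw * val_cache[(tech, pair, sj)]
                    t_aucs.append(evaluation.auc(p_j, data.y[splits[sj][1]]))
                tech_scores_ex[tech] = max(
                    0.0, evaluation.somers_d(float(np.mean(t_aucs)))
                )
            if tech_preds:
                if self.cross_technique_weighting == "equal" or not any(
                    tech_scores_ex.values()
                ):
                    cw = {t: 1.0 / len(tech_preds) for t in tech_preds}
                else:
                    tot = sum(tech_scores_ex[t] for t in tech_preds)
                    cw = {t: tech_scores_ex[t] / tot for t in tech_preds}
                final_pred = np.zeros(len(va))
                for t, p in tech_preds.items():
                    final_pred += cw[t] * p
            else:
                # nothing selectable from the other splits: uninformative
                final_pred = np.full(len(va), 0.5)
            for row, label, prob in zip(va, data.y[va], final_pred):
                pooled_rows.append(
                    {"split": si, "row": int(row), "label": int(label),
                     "probability": float(prob)}
                )
        pooled = pd.DataFrame(pooled_rows)
        metrics = evaluate_pooled(pooled, self.species_id, self.guild, data.n_presences)
        return EsmResults(
            model=self,
            ensembles=ensembles,
            cross_weights=cross_weights,
            bivariate_table=table,
            pooled=pooled,
            metrics=metrics,
        )


def evaluate_pooled(
    pooled: pd.DataFrame,
    species_id: str,
    guild: str | None,
    n_presences: int,
) -> pd.Series:
    """Final-ensemble metrics from pooled out-of-split predictions.

    AUC, the max-SSS threshold (on the 0-1000 map scale), sensitivity,
    specificity and TSS at that threshold; sensitivity is only reported
    for species better than random.
    """
    scores = pooled["probability"].to_numpy() * SCALE
    labels = pooled["label"].to_numpy()
    auc_val = evaluation.auc(scores, labels)
    thr = evaluation.max_sss_threshold(scores, labels)
    sens = evaluation.sensitivity_at(scores, labels, thr)
    spec = evaluation.specificity_at(scores, labels, thr)
    better = auc_val > 0.5
    return pd.Series(
        {
            "species_id": species_id,
            "guild": guild,
            "n_occurrences": n_presences,
            "auc": auc_val,
            "somers_d": evaluation.somers_d(auc_val),
            "tss": evaluation.tss(sens, spec),
            "sensitivity": sens if better else np.nan,
            "specificity": spec,
            "threshold": thr,
            "better_than_random": better,
        }
    )


def _empty_metrics(model: "EsmSpeciesModel", data: TrainingData) -> pd.Series:
    return pd.Series(
        {
            "species_id": model.species_id,
            "guild": model.guild,
            "n_occurrences": data.n_presences,
            "auc": np.nan,
            "somers_d": np.nan,
            "tss": np.nan,
            "sensitivity": np.nan,
            "specificity": np.nan,
            "threshold": np.nan,
            "better_than_random": False,
        }
    )


@dataclass
class EsmResults:
    """Fitted ESM: retained sub-models, weights, diagnostics and metrics."""

    model: EsmSpeciesModel
    ensembles: dict[str, TechniqueEnsemble]
    cross_weights: dict[str, float]
    bivariate_table: pd.DataFrame
    pooled: pd.DataFrame
    metrics: pd.Series

    @property
    def unmodellable(self) -> bool:
        """True when no bivariate model of any technique beat random."""
        return not self.cross_weights

    @property
    def better_than_random(self) -> bool:
        return bool(self.metrics["better_than_random"])

    @property
    def threshold(self) -> float:
        return float(self.metrics["threshold"])

    def predict(self, stack: RasterStack) -> Raster:
        """Continuous suitability map, integers on [0, 1000]."""
        if self.unmodellable:
            raise InvalidArgumentError("species has no retained models")
        return predict_esm(self.ensembles, self.cross_weights, stack)

    def predict_binary(self, stack: RasterStack) -> Raster:
        """Presence/absence map at the max-SSS threshold."""
        return evaluation.binarize(self.predict(stack), self.threshold)

    def plot_map(self, stack: RasterStack, ax=None, binary: bool = False):
        """Render the suitability (or binary) map; requires matplotlib."""
        import matplotlib.pyplot as plt

        r = self.predict_binary(stack) if binary else self.predict(stack)
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(r.data, cmap="viridis", interpolation="nearest")
        ax.set_title(f"{self.model.species_id}" + (" (binary)" if binary else ""))
        plt.colorbar(im, ax=ax, shrink=0.8)
        return ax

    def to_metadata(self) -> dict:
        """JSON-serializable description of the fitted ensemble."""
        return {
            "species_id": self.model.species_id,
            "guild": self.model.guild,
            "n_occurrences": int(self.metrics["n_occurrences"]),
            "cross_weights": {k: float(v) for k, v in self.cross_weights.items()},
            "techniques": {
                k: {
                    "pairs": ["+".join(p) for p in e.pairs],
                    "scores": [float(s) for s in e.scores],
                    "weights": [float(w) for w in e.weights],
                    "somers_d": None if e.somers_d is None else float(e.somers_d),
                }
                for k, e in self.ensembles.items()
            },
            "metrics": {
                k: (None if pd.isna(v) else (bool(v) if k == "better_than_random" else v))
                for k, v in self.metrics.items()
                if k not in ("species_id", "guild")
            },
        }

    def summary(self) -> str:
        """Human-readable fit report, one block per technique."""
        m = self.metrics
        lines = [
            "Ensemble of Small Models" + " " * 14 + f"species: {self.model.species_id}",
            "=" * 64,
            f"guild: {m['guild']}    occurrences: {m['n_occurrences']}"
            f"    candidate pairs: {len(self.bivariate_table) // max(1, len(self.model.techniques))}",
        ]
        if self.unmodellable:
            lines.append("no bivariate model better than random — species flagged")
            return "\n".join(lines)
        for tech, ens in self.ensembles.items():
            w = self.cross_weights.get(tech, 0.0)
            lines.append("-" * 64)
            lines.append(
                f"{tech}: {len(ens.pairs)} retained, ensemble Somers' D = "
                f"{ens.somers_d if ens.somers_d is not None else float('nan'):.3f}, "
                f"cross-technique weight = {w:.3f}"
            )
            for pair, s, wgt in zip(ens.pairs, ens.scores, ens.weights):
                lines.append(f"    {'+'.join(pair):24s} D = {s:+.3f}  weight = {wgt:.3f}")
        lines.append("-" * 64)
        lines.append(
            f"AUC = {m['auc']:.3f}   TSS = {m['tss']:.3f}   "
            f"sensitivity = {m['sensitivity'] if pd.notna(m['sensitivity']) else float('nan'):.3f}   "
            f"threshold = {m['threshold']:.0f}/1000"
        )
        lines.append(
            "better than random: " + ("yes" if self.better_than_random else "no")
        )
        return "\n".join(lines)
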