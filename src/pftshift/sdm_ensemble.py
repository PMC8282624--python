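"""Per-species ensembles: pseudo-absences, replicate fits, prediction, averaging.

For each species, presence cells are contrasted with pseudo-absence points
drawn by a learner-specific strategy; each learner is fitted on many random
70/30 presence splits ("replicates"), holdout metrics are stored per
replicate, and predicted suitability maps are combined as unweighted
arithmetic means across learners and replicates.

Four concrete learners are provided behind a plug-in interface:

* ``gam``    — smooth additive logistic model (per-variable cubic spline basis);
* ``mars``   — adaptive piecewise-linear logistic model (hinge basis at
               quantile knots);
* ``maxent`` — presence-vs-background exponential-family density-ratio model
               (logistic on linear + quadratic features); presence-only, so
               its scores are habitat ranks rather than probabilities;
* ``rf``     — bagged-tree ensemble (random forest).

Pseudo-absences are down-weighted so the total presence and absence weights
are equal, making learner scores comparable across pseudo-absence counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
import zlib

from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

from . import evaluation
from .synthetic_landscape import EnvStack, OccurrenceSet

__all__ = [
    "LearnerSpec",
    "ReplicateFit",
    "SpeciesEnsemble",
    "default_learners",
    "make_learner",
    "presence_cells",
    "draw_pseudo_absences",
    "fit_replicates",
    "predict_map",
    "ensemble_mean",
    "select_projection_replicates",
]

PA_STRATEGIES = ("random", "disk", "stratified")


@dataclass(frozen=True)
class LearnerSpec:
    """Algorithm roster entry: name, pseudo-absence strategy, hyperparameters."""

    name: str
    pa_strategy: str = "random"
    pa_count: int | str = 10_000  # integer, or "equal" for one per presence
    hyperparams: dict = field(default_factory=dict)
    presence_only: bool = False

    def __post_init__(self) -> None:
        if self.pa_strategy not in PA_STRATEGIES:
            raise ValueError(f"unknown pseudo-absence strategy {self.pa_strategy!r}")


def default_learners() -> list[LearnerSpec]:
    """Default four-algorithm roster with per-family pseudo-absence settings.

    Regression-family learners and the background-based density-ratio model
    use 10,000 random points; the bagged-tree learner uses presence-equal
    pseudo-absences drawn from a distance annulus around presences (standard
    recommendations for each family).
    """
    return [
        LearnerSpec("gam", pa_strategy="random", pa_count=10_000),
        LearnerSpec("mars", pa_strategy="random", pa_count=10_000),
        LearnerSpec("maxent", pa_strategy="random", pa_count=10_000, presence_only=True),
        LearnerSpec(
            "rf",
            pa_strategy="disk",
            pa_count="equal",
            hyperparams={"d_min": 2.0, "d_max": np.inf},
        ),
    ]


class HingeFeatures(BaseEstimator, TransformerMixin):
    """Hinge (rectified-linear) basis at per-variable quantile knots.

    Expands each column x into x plus max(0, x-k) and max(0, k-x) for knots k
    at training quantiles, giving an adaptive piecewise-linear regression
    spline basis.
    """

    def __init__(self, quantiles=(0.25, 0.5, 0.75)):
        self.quantiles = quantiles

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.knots_ = np.quantile(X, self.quantiles, axis=0)  # (n_knots, n_vars)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        feats = [X]
        for k in self.knots_:
            feats.append(np.maximum(X - k, 0.0))
            feats.append(np.maximum(k - X, 0.0))
        return np.hstack(feats)


class QuadraticFeatures(BaseEstimator, TransformerMixin):
    """Linear plus squared terms (exponential-family sufficient statistics)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.hstack([X, X**2])


def make_learner(spec: LearnerSpec, seed: int = 0):
    """Instantiate the sklearn estimator backing a learner spec."""
    hp = dict(spec.hyperparams)
    hp.pop("d_min", None)
    hp.pop("d_max", None)
    if spec.name == "gam":
        return Pipeline(
            [
                ("spline", SplineTransformer(
                    n_knots=hp.get("n_knots", 5), degree=3, knots="quantile")),
                ("scale", StandardScaler()),
                ("logit", LogisticRegression(max_iter=1000, C=hp.get("C", 1.0))),
            ]
        )
    if spec.name == "mars":
        return Pipeline(
            [
                ("hinge", HingeFeatures(quantiles=hp.get("quantiles", (0.25, 0.5, 0.75)))),
                ("scale", StandardScaler()),
                ("logit", LogisticRegression(max_iter=1000, C=hp.get("C", 1.0))),
            ]
        )
    if spec.name == "maxent":
        return Pipeline(
            [
                ("quad", QuadraticFeatures()),
                ("scale", StandardScaler()),
                ("logit", LogisticRegression(max_iter=1000, C=hp.get("C", 1.0))),
            ]
        )
    if spec.name == "rf":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100),
            min_samples_leaf=hp.get("min_samples_leaf", 2),
            random_state=seed,
            n_jobs=1,
        )
    raise ValueError(f"unknown learner {spec.name!r}")


@dataclass
class ReplicateFit:
    species_id: str
    learner: str
    replicate: int
    model: object
    variables: list[str]
    metrics: evaluation.EvaluationMetrics
    train_idx: np.ndarray  # indices into the pooled presence+absence rows
    holdout_idx: np.ndarray
    holdout_scores: np.ndarray  # predicted scores on the holdout rows
    holdout_labels: np.ndarray


@dataclass
class SpeciesEnsemble:
    species_id: str
    fits: list[ReplicateFit]
    retained_learners: list[str]
    learner_maps: dict[str, np.ndarray]  # per-learner mean probability map
    overall_map: np.ndarray  # unweighted mean across retained learner x replicate
    thresholds: dict[str, float]  # per-learner maxSSS threshold


def presence_cells(occ: OccurrenceSet, env: EnvStack) -> np.ndarray:
    """Boolean grid of cells containing at least one record."""
    mask = np.zeros(env.grid.shape, dtype=bool)
    if len(occ):
        r, c = env.grid.cell_of(occ.lon, occ.lat)
        mask[r, c] = True
    mask &= ~env.mask
    return mask


def draw_pseudo_absences(
    env: EnvStack,
    occ: OccurrenceSet,
    spec: LearnerSpec,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-absence cells for one species under the spec's strategy.

    Returns (rows, cols). Strategies:

    * ``random``     — uniform over unmasked non-presence cells;
    * ``disk``       — uniform over cells whose distance (in cells) to the
                       nearest presence lies in [d_min, d_max];
    * ``stratified`` — uniform within environmental bins (per-layer terciles)
                       that contain no presence.

    Never lands on a presence cell; deterministic per seed. Samples with
    replacement only if the candidate pool is smaller than the request.
    """
    rng = np.random.default_rng(seed)
    pres = presence_cells(occ, env)
    n = len(occ) if spec.pa_count == "equal" else int(spec.pa_count)
    if n < 1:
        raise ValueError("pseudo-absence count must be >= 1")
    candidates = ~pres & ~env.mask

    if spec.pa_strategy == "disk":
        d_min = float(spec.hyperparams.get("d_min", 2.0))
        d_max = float(spec.hyperparams.get("d_max", np.inf))
        dist = ndimage.distance_transform_edt(~pres)
        candidates &= (dist >= d_min) & (dist <= d_max)
        if not candidates.any():
            raise ValueError(
                f"empty disk annulus for radii [{d_min}, {d_max}] cells"
            )
    elif spec.pa_strategy == "stratified":
        # combined tercile bin over all layers; keep bins with no presence
        bin_id = np.zeros(env.grid.shape, dtype=np.int64)
        for name in env.layer_names:
            x = env.layers[name]
            q = np.nanquantile(x[~env.mask], [1 / 3, 2 / 3])
            bin_id = bin_id * 3 + np.digitize(x, q)
        occupied = np.unique(bin_id[pres]) if pres.any() else np.array([], dtype=np.int64)
        candidates &= ~np.isin(bin_id, occupied)
        if not candidates.any():
            raise ValueError("no environmental bin free of presences")

    pool = np.flatnonzero(candidates.ravel())
    if pool.size == 0:
        raise ValueError("no candidate pseudo-absence cells")
    replace = pool.size < n
    idx = rng.choice(pool, size=n, replace=replace)
    return np.unravel_index(idx, env.grid.shape)


def _design_rows(env: EnvStack, rows, cols, variables: list[str]) -> np.ndarray:
    return np.column_stack([env.layers[v][rows, cols] for v in variables])


def fit_replicates(
    spec: LearnerSpec,
    presences: tuple[np.ndarray, np.ndarray],
    absences: tuple[np.ndarray, np.ndarray],
    env: EnvStack,
    variables: list[str],
    species_id: str = "species",
    n_replicates: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
) -> list[ReplicateFit]:
    """Fit ``n_replicates`` random-split replicates of one learner.

    Each replicate draws an independent 70/30 split of the presences and of
    the pseudo-absences; holdout AUC, CBI and (for probability-scale
    learners) the calibration statistic are computed on the 30% split.
    A replicate whose fit fails is skipped with a warning; all failing is an
    error.
    """
    import warnings

    pr, pc = presences
    ar, ac = absences
    n_pres, n_abs = len(pr), len(ar)
    if n_pres < 10:
        raise ValueError("need at least 10 presence cells")
    Xp = _design_rows(env, pr, pc, variables)
    Xa = _design_rows(env, ar, ac, variables)
    X = np.vstack([Xp, Xa])
    y = np.concatenate([np.ones(n_pres), np.zeros(n_abs)])
    # equalize total class weights
    w = np.concatenate([np.full(n_pres, 1.0), np.full(n_abs, n_pres / n_abs)])

    ss = np.random.SeedSequence(
        [seed & 0x7FFFFFFF, zlib.crc32(spec.name.encode()) & 0x7FFFFFFF]
    )
    child_seeds = ss.generate_state(n_replicates)
    fits: list[ReplicateFit] = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(child_seeds[rep])
        tr_p = rng.permutation(n_pres)[: int(round(train_frac * n_pres))]
        tr_a = rng.permutation(n_abs)[: int(round(train_frac * n_abs))] + n_pres
        train = np.concatenate([tr_p, tr_a])
        holdout = np.setdiff1d(np.arange(n_pres + n_abs), train)
        model = make_learner(spec, seed=int(child_seeds[rep] & 0x7FFFFFFF))
        try:
            _fit(model, X[train], y[train], w[train])
        except Exception as exc:  # noqa: BLE001 - replicate-level resilience
            warnings.warn(f"{spec.name} replicate {rep} failed: {exc}")
            continue
        scores = _predict_scores(model, X[holdout])
        lab = y[holdout].astype(bool)
        cal = (
            None
            if spec.presence_only
            else evaluation.calibration_statistic(scores, lab)
        )
        metrics = evaluation.EvaluationMetrics(
            auc=evaluation.auc(scores, lab),
            cbi=_safe_cbi(scores[lab], scores[~lab]),
            calibration=cal,
            n_presences=int(lab.sum()),
            n_absences=int((~lab).sum()),
        )
        fits.append(
            ReplicateFit(
                species_id=species_id,
                learner=spec.name,
                replicate=rep,
                model=model,
                variables=list(variables),
                metrics=metrics,
                train_idx=train,
                holdout_idx=holdout,
                holdout_scores=scores,
                holdout_labels=lab,
            )
        )
    if not fits:
        raise RuntimeError(f"all {n_replicates} replicates failed for {spec.name}")
    return fits


def _fit(model, X, y, w):
    if isinstance(model, Pipeline):
        model.fit(X, y, **{f"{model.steps[-1][0]}__sample_weight": w})
    else:
        model.fit(X, y, sample_weight=w)


def _predict_scores(model, X) -> np.ndarray:
    proba = model.predict_proba(X)
    return proba[:, list(model.classes_).index(1)]


def _safe_cbi(pres_scores, back_scores) -> float:
    try:
        return evaluation.boyce_index(pres_scores, back_scores)
    except ValueError:
        return np.nan


def predict_map(fit: ReplicateFit, env: EnvStack) -> np.ndarray:
    """Suitability map of one replicate on a (possibly scenario) stack."""
    missing = [v for v in fit.variables if v not in env.layers]
    if missing:
        raise KeyError(f"stack lacks variable(s) used in training: {missing}")
    out = np.full(env.grid.shape, np.nan)
    valid = ~env.mask
    X = np.column_stack([env.layers[v][valid] for v in fit.variables])
    out[valid] = _predict_scores(fit.model, X)
    return out


def ensemble_mean(maps: list[np.ndarray]) -> np.ndarray:
    """Cellwise unweighted arithmetic mean; missing cells stay missing."""
    if not maps:
        raise ValueError("need at least one map")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ValueError("maps are not co-registered")
    return np.mean(np.stack(maps), axis=0)


def select_projection_replicates(
    fits: list[ReplicateFit], k: int = 10, seed: int = 0
) -> list[ReplicateFit]:
    """Uniform random subset of k replicates per learner (projection thinning)."""
    rng = np.random.default_rng(seed)
    out: list[ReplicateFit] = []
    learners = sorted({f.learner for f in fits})
    for name in learners:
        group = [f for f in fits if f.learner == name]
        if k > len(group):
            raise ValueError(
                f"requested {k} replicates but only {len(group)} available for {name}"
            )
        idx = rng.choice(len(group), size=k, replace=False)
        out.extend(group[i] for i in sorted(idx))
    return out
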