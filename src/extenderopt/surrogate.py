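"""Surrogate motility models: neural network and Gaussian-process regression.

Both models regress post-thaw motility on a 12-dimensional encoding of a
formulation: the 11 design components min–max scaled to [0, 1] by their
bounds, plus the water-filler volume fraction (1 minus the summed v/v
fractions) as the twelfth input.  The network is a single-hidden-layer
ReLU regressor (12-12-1, L2 penalty 1e-4, mean-squared-error loss); the
Gaussian process uses an anisotropic squared-exponential kernel with an
additive observation-noise term, hyperparameters by marginal-likelihood
optimization, and — unlike the network — exposes a predictive standard
deviation.

Model fitness is compared by k-fold cross-validated mean squared error, and
deployment-model selection follows the campaign's rule: among models whose
predictions are not significantly different in location from the
experimental motilities, prefer the one whose prediction *spread* is
homoscedastic with the experimental spread (Fligner–Killeen); fall back to
the lower cross-validated MSE.  The selected model screens oversampled DE
trial pools down to the experimental batch size by greedy predicted mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from .equivstats import (
    RankTestResult,
    EquivalenceConfig,
    EquivalenceResult,
    dunn_posthoc,
    fligner_killeen,
    kruskal_wallis,
    mann_whitney_equivalence,
)
from .evolution import Population
from .exceptions import AlignmentError, ConfigError, DataError, StateError
from .formulation_space import Formulation, FormulationSpace


@dataclass(frozen=True)
class SurrogateConfig:
    input_dim: int = 12
    hidden_units: int = 12
    l2_penalty: float = 1e-4
    cv_folds: int = 10
    seed: int = 0
    max_iter: int = 2000
    gpr_restarts: int = 0
    #: surrogate fits use at most this many most-recent training pairs
    #: (recent generations reflect the current search region; bounds the
    #: cubic Gaussian-process fit cost)
    max_training_pairs: int = 320

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ConfigError("input_dim must be >= 1")
        if self.l2_penalty < 0:
            raise ConfigError("l2_penalty must be >= 0")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")


@dataclass(frozen=True)
class TrainingPair:
    """One (normalized formulation features, motility %) observation."""

    features: np.ndarray
    target: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", np.asarray(self.features, dtype=float))
        if not np.all(np.isfinite(self.features)):
            raise DataError("features must be finite")
        if not (0 <= self.target <= 100):
            raise DataError("target motility must be in [0, 100]")


@dataclass(frozen=True)
class CVResult:
    fold_mse: tuple[float, ...]
    mean_mse: float
    model_tag: str


# --------------------------------------------------------------------------
# Feature encoding
# --------------------------------------------------------------------------

_VOLUME_UNIT = "percent v/v"


def featurize(f: Formulation, space: FormulationSpace) -> np.ndarray:
    """Encode a formulation as the surrogate input vector.

    Min–max scaling per component (frozen zero-width components map to 0),
    with the water-filler volume fraction appended as the final coordinate.
    """
    lower, upper = space.lower, space.upper
    width = upper - lower
    core = np.zeros(len(space))
    mask = width > 0
    core[mask] = (f.concentrations[mask] - lower[mask]) / width[mask]
    vv = sum(
        f.concentrations[j]
        for j, c in enumerate(space.components)
        if c.unit == _VOLUME_UNIT
    )
    water = max(0.0, 1.0 - vv / 100.0)
    return np.concatenate([core, [water]])


def defeaturize(features: np.ndarray, space: FormulationSpace) -> Formulation:
    """Invert :func:`featurize` on the component coordinates (water dropped)."""
    features = np.asarray(features, dtype=float)
    if len(features) != len(space) + 1:
        raise AlignmentError("feature vector length must be n_components + 1")
    lower, upper = space.lower, space.upper
    conc = lower + features[: len(space)] * (upper - lower)
    return Formulation("defeaturized", conc)


def featurize_population(
    members: Sequence[Formulation], space: FormulationSpace
) -> np.ndarray:
    return np.stack([featurize(m, space) for m in members])


def pairs_to_xy(pairs: Sequence[TrainingPair]) -> tuple[np.ndarray, np.ndarray]:
    if len(pairs) == 0:
        raise DataError("no training pairs")
    X = np.stack([p.features for p in pairs])
    y = np.array([p.target for p in pairs])
    return X, y


# --------------------------------------------------------------------------
# Models
# --------------------------------------------------------------------------


class AnnSurrogate:
    """Single-hidden-layer ReLU network (12-12-1) behind the surrogate contract."""

    tag = "ann"

    def __init__(self, cfg: SurrogateConfig):
        self.cfg = cfg
        self._model = MLPRegressor(
            hidden_layer_sizes=(cfg.hidden_units,),
            activation="relu",
            alpha=cfg.l2_penalty,
            solver="adam",
            batch_size=10_000,  # full batch in practice (clipped to n)
            learning_rate_init=0.01,
            max_iter=cfg.max_iter,
            tol=1e-7,
            n_iter_no_change=50,
            random_state=cfg.seed,
        )
        self.fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AnnSurrogate":
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings at the iter cap
            self._model.fit(X, y)
        self.fitted = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise StateError("model not fitted")
        return self._model.predict(np.atleast_2d(X))

    @property
    def loss_history(self) -> list[float]:
        if not self.fitted:
            raise StateError("model not fitted")
        return list(self._model.loss_curve_)

    @property
    def topology(self) -> tuple[int, int, int]:
        if not self.fitted:
            return (self.cfg.input_dim, self.cfg.hidden_units, 1)
        return (self._model.coefs_[0].shape[0], self.cfg.hidden_units, 1)


class GprSurrogate:
    """GP regressor: anisotropic squared-exponential kernel + observation noise."""

    tag = "gpr"

    def __init__(self, cfg: SurrogateConfig, noise_level: float = 1.0):
        self.cfg = cfg
        kernel = (
            ConstantKernel(1.0, (1e-3, 1e4))
            * RBF(np.ones(cfg.input_dim), (1e-2, 1e2))
            + WhiteKernel(noise_level, (1e-10, 1e4))
        )
        self._model = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            n_restarts_optimizer=cfg.gpr_restarts,
            random_state=cfg.seed,
        )
        self.fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GprSurrogate":
        import warnings

        if len(y) < 2:
            raise DataError("GPR needs at least 2 training pairs")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                self._model.fit(X, y)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise DataError(
                    "singular covariance; increase the white-noise jitter"
                ) from exc
        self.fitted = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise StateError("model not fitted")
        return self._model.predict(np.atleast_2d(X))

    def predict_sd(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise StateError("model not fitted")
        _, sd = self._model.predict(np.atleast_2d(X), return_std=True)
        return sd


def fit_ann(pairs: Sequence[TrainingPair], cfg: SurrogateConfig) -> AnnSurrogate:
    X, y = pairs_to_xy(pairs)
    return AnnSurrogate(cfg).fit(X, y)


def fit_gpr(
    pairs: Sequence[TrainingPair], cfg: SurrogateConfig, noise_level: float = 1.0
) -> GprSurrogate:
    X, y = pairs_to_xy(pairs)
    return GprSurrogate(cfg, noise_level=noise_level).fit(X, y)


# --------------------------------------------------------------------------
# Cross-validation and model selection
# --------------------------------------------------------------------------


def kfold_cv(
    model_factory: Callable[[], object],
    pairs: Sequence[TrainingPair],
    cfg: SurrogateConfig,
    model_tag: str | None = None,
) -> CVResult:
    """k-fold cross-validated MSE; folds are a seeded disjoint partition."""
    X, y = pairs_to_xy(pairs)
    if cfg.cv_folds > len(y):
        raise ConfigError("more folds than training pairs")
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    fold_mse = []
    tag = model_tag or getattr(model_factory, "tag", "model")
    for train_idx, val_idx in kf.split(X):
        model = model_factory()
        model.fit(X[train_idx], y[train_idx])
        pred = np.asarray(model.predict(X[val_idx]))
        fold_mse.append(float(np.mean((pred - y[val_idx]) ** 2)))
    return CVResult(tuple(fold_mse), float(np.mean(fold_mse)), tag)


@dataclass(frozen=True)
class ModelSelectionReport:
    """Everything :func:`compare_models` computed, plus the selected tag."""

    omnibus: RankTestResult
    dunn: tuple[RankTestResult, ...]
    fligner: Mapping[str, RankTestResult]
    equivalence: Mapping[str, EquivalenceResult]
    selected: str
    rule: str
    cv: Mapping[str, CVResult] = field(default_factory=dict)


def compare_models(
    ann_preds: Sequence[float],
    gpr_preds: Sequence[float],
    experimental: Sequence[float],
    alpha: float = 0.05,
    equivalence_cfg: EquivalenceConfig | None = None,
    cv_results: Mapping[str, CVResult] | None = None,
    tags: tuple[str, str] = ("ann", "gpr"),
) -> ModelSelectionReport:
    """Select the deployment surrogate by comparison with experimental motility.

    Runs the omnibus Kruskal–Wallis over {experimental, model A, model B},
    Dunn pairwise post-hocs, a per-model Fligner–Killeen variance comparison
    against the experimental sample, and per-model Mann–Whitney equivalence
    tests.  Selection: among models not significantly different in location
    from the experimental sample, prefer the one homoscedastic with it; break
    remaining ties by lower cross-validated MSE when available, else by the
    larger variance-homogeneity p-value.
    """
    preds = {
        tags[0]: np.asarray(ann_preds, dtype=float),
        tags[1]: np.asarray(gpr_preds, dtype=float),
    }
    experimental = np.asarray(experimental, dtype=float)
    for tag, p in preds.items():
        if len(p) != len(experimental):
            raise AlignmentError(
                f"{tag} predictions ({len(p)}) not aligned with "
                f"experimental sample ({len(experimental)})"
            )
    labels = ["experimental", *preds]
    omnibus = kruskal_wallis([experimental, *preds.values()])
    dunn = tuple(dunn_posthoc([experimental, *preds.values()], labels=labels))
    fligner = {t: fligner_killeen(experimental, p) for t, p in preds.items()}
    equivalence = {
        t: mann_whitney_equivalence(experimental, p, equivalence_cfg)
        for t, p in preds.items()
    }

    def _location_ok(tag: str) -> bool:
        for r in dunn:
            if set(r.groups) == {"experimental", tag}:
                return r.p_value >= alpha
        return True

    candidates = [t for t in preds if _location_ok(t)] or list(preds)
    homoscedastic = [t for t in candidates if fligner[t].p_value >= alpha]
    if len(homoscedastic) == 1:
        selected, rule = homoscedastic[0], "variance-homogeneity"
    else:
        pool = homoscedastic or candidates
        if cv_results and all(t in cv_results for t in pool):
            selected = min(pool, key=lambda t: (cv_results[t].mean_mse, t))
            rule = "cv-mse-fallback"
        else:
            selected = max(pool, key=lambda t: (fligner[t].p_value, t))
            rule = "fligner-p-fallback"
    return ModelSelectionReport(
        omnibus=omnibus,
        dunn=dunn,
        fligner=fligner,
        equivalence=equivalence,
        selected=selected,
        rule=rule,
        cv=dict(cv_results or {}),
    )


def screen_candidates(
    model,
    candidates: Population,
    k: int,
    space: FormulationSpace,
) -> tuple[Population, np.ndarray]:
    """Keep the k candidates with the highest predicted motility.

    Deterministic rank order: predicted mean descending, ties by formulation
    id.  Returns the screened population and the predictions for *all*
    candidates (for the predictions ledger).
    """
    if not getattr(model, "fitted", False):
        raise StateError("screening requires a fitted model")
    if len(candidates) < k:
        raise ConfigError("fewer candidates than the requested batch size")
    X = featurize_population(candidates.members, space)
    preds = np.asarray(model.predict(X), dtype=float)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-preds[i], candidates.members[i].id),
    )
    keep = order[:k]
    screened = Population(
        generation=candidates.generation,
        members=[candidates.members[i] for i in keep],
    )
    return screened, preds
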