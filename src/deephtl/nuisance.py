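"""Bagged neural-network nuisance learners and K-fold cross-fitting.

Nuisance functions — the propensity e(X) = E[Z|X] and the outcome
regressions mu(X) = E[Y|X], mu*(X) = E[Y*|X] — are estimated with bagged
multilayer perceptrons: each ensemble member is trained on a bootstrap
resample, scored on its out-of-bag rows, and members whose out-of-bag loss
is far above the ensemble median are discarded before averaging.  Bagging
plus filtering stabilizes the fits against the randomness of network
initialization at moderate sample sizes.

Cross-fitting partitions the sample into K folds and, for each fold, trains
the ensembles on the complement so that every subject's nuisance prediction
comes from models that never saw that subject.  This sample splitting is
what makes the downstream treatment-effect estimating equations insensitive
(to first order) to nuisance estimation error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import log_loss, mean_squared_error
from sklearn.neural_network import MLPClassifier, MLPRegressor

Task = Literal["regression", "binary"]

__all__ = [
    "LearnerConfig",
    "BaggedEnsemble",
    "CrossFitNuisances",
    "make_folds",
    "fit_bagged",
    "cross_fit",
    "cross_fit_target",
]


class DegenerateFoldError(ValueError):
    """A cross-fitting fold cannot support the requested fit."""


@dataclass(frozen=True)
class LearnerConfig:
    """Hyperparameters of the bagged base learner.

    ``n_members`` bootstrap-trained networks are fitted per ensemble;
    members whose out-of-bag loss exceeds the member median by more than
    ``filter_threshold`` (relative) are discarded before averaging.
    ``base_learner="ridge"`` swaps the networks for penalized linear
    models — useful for fast smoke tests, not for the confounding
    structures the networks are meant to capture.
    """

    base_learner: Literal["mlp", "ridge"] = "mlp"
    hidden_layer_sizes: tuple[int, ...] = (50, 50)
    solver: Literal["adam", "lbfgs"] = "adam"
    alpha: float = 1e-4
    max_epochs: int = 200
    batch_size: int = 64
    n_members: int = 20
    filter_threshold: float = 0.2
    n_folds: int = 5
    clip_lo: float = 0.01
    early_stopping: bool = True
    validation_fraction: float = 0.2
    ridge_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not 0 < self.clip_lo < 0.5:
            raise ValueError("clip_lo must lie in (0, 0.5)")
        if self.filter_threshold < 0:
            raise ValueError("filter_threshold must be >= 0")


def make_folds(
    n: int,
    n_folds: int,
    seed: int,
    stratify: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Random disjoint fold assignment, sizes differing by at most one.

    Returns a length-``n`` integer array with values in ``{0, ..., K-1}``.
    With ``stratify`` given (e.g. the treatment vector), folds are balanced
    within each stratum so no training complement loses a whole class.
    """
    if n_folds < 2 or n_folds > n:
        raise ValueError(f"need 2 <= n_folds <= n, got K={n_folds}, n={n}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    if stratify is None:
        strata = [np.arange(n)]
    else:
        stratify = np.asarray(stratify)
        strata = [np.flatnonzero(stratify == v) for v in np.unique(stratify)]
    # deal fold labels round-robin from a random start within each stratum,
    # so global fold sizes stay within one of each other
    offset = 0
    for idx in strata:
        perm = rng.permutation(idx)
        fold_of[perm] = (np.arange(offset, offset + len(perm))) % n_folds
        offset += len(perm)
    return fold_of


def _spawn_seeds(seed: int, k: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(k) % np.uint32(2**31)


def _make_member(task: Task, config: LearnerConfig, seed: int, n_rows: int):
    if config.base_learner == "ridge":
        if task == "regression":
            return Ridge(alpha=config.ridge_alpha)
        return LogisticRegression(max_iter=1000, C=1.0)
    common = dict(
        hidden_layer_sizes=config.hidden_layer_sizes,
        solver=config.solver,
        max_iter=config.max_epochs,
        random_state=int(seed),
    )
    if config.solver == "adam":
        # minibatch training with validation-based early stopping
        common.update(
            batch_size=min(config.batch_size, max(2, n_rows // 2)),
            early_stopping=config.early_stopping and n_rows >= 50,
            validation_fraction=config.validation_fraction,
            n_iter_no_change=10,
        )
    if task == "regression":
        return MLPRegressor(**common)
    return MLPClassifier(**common)


def _member_predict(model, Xs: np.ndarray, task: Task) -> np.ndarray:
    if task == "regression":
        return model.predict(Xs)
    return model.predict_proba(Xs)[:, 1]


@dataclass
class BaggedEnsemble:
    """A filtered bootstrap ensemble; prediction averages the kept members.

    ``kept_mask`` marks the members that survived out-of-bag filtering.
    Probability outputs are clipped to ``[clip_lo, 1 - clip_lo]`` to keep
    the overlap weights (Z - e)^2 bounded away from zero.
    """

    members: list
    kept_mask: np.ndarray
    task: Task
    oob_losses: np.ndarray
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    clip_lo: float

    def __post_init__(self) -> None:
        if not self.kept_mask.any():
            raise ValueError("ensemble must keep at least one member")

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self._standardize(X)
        preds = [
            _member_predict(m, Xs, self.task)
            for m, keep in zip(self.members, self.kept_mask)
            if keep
        ]
        out = np.mean(preds, axis=0)
        if self.task == "binary":
            out = np.clip(out, self.clip_lo, 1.0 - self.clip_lo)
        return out


def fit_bagged(
    X: np.ndarray,
    t: np.ndarray,
    task: Task,
    config: LearnerConfig,
    seed: int,
    sample_weight: Optional[np.ndarray] = None,
) -> BaggedEnsemble:
    """Fit a filtered bagging ensemble of networks (or ridge models).

    Each member is trained on a bootstrap resample and scored on its
    out-of-bag rows (mean squared error for regression, log loss for
    binary targets); members whose loss exceeds the median by more than
    ``config.filter_threshold`` relative are dropped.  When every member
    would be dropped (degenerate losses), the single best one is kept and
    a warning is emitted.

    ``sample_weight`` turns the squared loss into a weighted one.  The
    networks do not take per-row weights directly, so the weights enter
    through the bootstrap: resamples are drawn with probability
    proportional to the weights, which targets the same weighted
    objective; the linear models receive the weights exactly.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    n = X.shape[0]
    if n < 20:
        raise ValueError(f"need at least 20 rows to fit an ensemble, got {n}")
    if task == "binary":
        classes = np.unique(t)
        if len(classes) < 2:
            raise DegenerateFoldError(
                "binary target has a single class; cannot fit a propensity model"
            )
    if sample_weight is not None:
        sample_weight = np.asarray(sample_weight, dtype=float)
        if (sample_weight < 0).any() or sample_weight.sum() <= 0:
            raise ValueError("sample weights must be nonnegative with positive sum")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    weighted_boot = sample_weight is not None and config.base_learner == "mlp"
    boot_p = None
    if weighted_boot:
        boot_p = sample_weight / sample_weight.sum()

    seeds = _spawn_seeds(seed, 2 * config.n_members)
    rng = np.random.default_rng(seeds[0])
    members, oob_losses = [], []
    for b in range(config.n_members):
        # resample until the bootstrap contains both classes (binary task)
        for _ in range(100):
            idx = rng.choice(n, size=n, replace=True, p=boot_p)
            if task != "binary" or len(np.unique(t[idx])) > 1:
                break
        model = _make_member(task, config, seeds[config.n_members + b], n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            if config.base_learner == "ridge" and sample_weight is not None:
                model.fit(Xs[idx], t[idx], sample_weight=sample_weight[idx])
            else:
                model.fit(Xs[idx], t[idx])
        oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        score_idx = oob if len(oob) >= 2 else np.arange(n)
        pred = _member_predict(model, Xs[score_idx], task)
        sw = None if sample_weight is None else sample_weight[score_idx]
        if task == "binary":
            loss = log_loss(t[score_idx], np.clip(pred, 1e-7, 1 - 1e-7),
                            labels=[0.0, 1.0], sample_weight=sw)
        else:
            loss = mean_squared_error(t[score_idx], pred, sample_weight=sw)
        members.append(model)
        oob_losses.append(float(loss))

    oob_losses = np.asarray(oob_losses)
    med = np.median(oob_losses)
    kept = oob_losses <= med * (1.0 + config.filter_threshold)
    if not kept.any():
        warnings.warn(
            "all ensemble members filtered out; keeping the single best member",
            RuntimeWarning,
        )
        kept = oob_losses == oob_losses.min()
    return BaggedEnsemble(
        members=members,
        kept_mask=kept,
        task=task,
        oob_losses=oob_losses,
        scaler_mean=mean,
        scaler_scale=scale,
        clip_lo=config.clip_lo,
    )


@dataclass
class CrossFitNuisances:
    """Out-of-fold nuisance predictions plus the fold map that made them.

    Each entry ``e_hat[i]`` / ``mu_hat[i]`` / ``mu_star_hat[i]`` was
    produced by an ensemble whose training set excluded subject ``i``'s
    fold.  ``ensembles`` keeps the per-fold fitted ensembles per target so
    new data can be scored (by averaging the K fold models).
    """

    fold_of: np.ndarray
    e_hat: Optional[np.ndarray] = None
    mu_hat: Optional[np.ndarray] = None
    mu_star_hat: Optional[np.ndarray] = None
    ensembles: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return int(self.fold_of.max()) + 1

    def predict_target(self, target: str, X: np.ndarray) -> np.ndarray:
        """Score new data with the average of the K fold-specific ensembles."""
        if target not in self.ensembles:
            raise KeyError(f"no fitted ensembles stored for target {target!r}")
        preds = [ens.predict(X) for ens in self.ensembles[target]]
        return np.mean(preds, axis=0)


def cross_fit_target(
    X: np.ndarray,
    t: np.ndarray,
    fold_of: np.ndarray,
    task: Task,
    config: LearnerConfig,
    seed: int,
    sample_weight: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, list]:
    """Cross-fit one target over an existing fold partition.

    For each fold k the ensemble is trained on the complement of k and
    predicts only the held-out rows; returns the assembled length-n
    out-of-fold prediction vector and the per-fold ensembles.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    n_folds = int(fold_of.max()) + 1
    seeds = _spawn_seeds(seed, n_folds)
    preds = np.empty(len(t))
    fold_models = []
    for k in range(n_folds):
        hold = fold_of == k
        train = ~hold
        if task == "binary" and len(np.unique(t[train])) < 2:
            raise DegenerateFoldError(
                f"training complement of fold {k} contains a single treatment "
                "class; use fewer folds or a larger sample"
            )
        sw = None if sample_weight is None else sample_weight[train]
        ens = fit_bagged(X[train], t[train], task, config, int(seeds[k]),
                         sample_weight=sw)
        preds[hold] = ens.predict(X[hold])
        fold_models.append(ens)
    return preds, fold_models


def cross_fit(
    dataset,
    targets: Sequence[str] = ("e", "mu"),
    config: LearnerConfig = LearnerConfig(),
    seed: int = 0,
    y_star: Optional[np.ndarray] = None,
    fold_of: Optional[np.ndarray] = None,
    config_e: Optional[LearnerConfig] = None,
) -> CrossFitNuisances:
    """Cross-fit the requested nuisance targets on one fold partition.

    ``targets`` is a subset of ``{"e", "mu", "mu_star"}``; fitting
    ``mu_star`` requires the centered outcome ``y_star = Y - tau0*Z``.
    One partition (stratified on Z) is shared by every target — and is
    reused by the treatment-effect stage — so the fold bookkeeping of the
    permutation test stays consistent.

    ``config_e`` optionally overrides the hyperparameters for the
    propensity task: probability estimation typically benefits from
    stronger regularization than the outcome regressions, and residual
    propensity bias multiplies outcome bias in the downstream score test.
    """
    known = {"e", "mu", "mu_star"}
    bad = set(targets) - known
    if bad:
        raise ValueError(f"unknown nuisance targets {sorted(bad)}; expected {known}")
    if "mu_star" in targets and y_star is None:
        raise ValueError("fitting mu_star requires the centered outcome y_star")
    n = dataset.n
    if fold_of is None:
        fold_of = make_folds(n, config.n_folds, seed, stratify=dataset.Z)
    out = CrossFitNuisances(fold_of=fold_of)
    seeds = _spawn_seeds(seed + 1, 3)
    if "e" in targets:
        out.e_hat, out.ensembles["e"] = cross_fit_target(
            dataset.X, dataset.Z, fold_of, "binary",
            config_e if config_e is not None else config, int(seeds[0])
        )
    if "mu" in targets:
        out.mu_hat, out.ensembles["mu"] = cross_fit_target(
            dataset.X, dataset.Y, fold_of, "regression", config, int(seeds[1])
        )
    if "mu_star" in targets:
        out.mu_star_hat, out.ensembles["mu_star"] = cross_fit_target(
            dataset.X, y_star, fold_of, "regression", config, int(seeds[2])
        )
    return out
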