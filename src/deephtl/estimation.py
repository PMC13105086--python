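"""R-learner estimation of heterogeneous treatment effects.

Under the partially linear model ``Y = tau(X) Z + f(X) + eps``, the
Robinson transformation ``Y - mu(X) = tau(X) (Z - e(X)) + eps`` reduces
estimation of tau to a residual-on-residual regression.  The *unrevised*
estimator minimizes the squared Robinson loss directly; the *revised*
estimator first removes the constant component tau0 (a double-robust
scalar), recenters the outcome as ``Y* = Y - tau0 Z``, re-fits the outcome
regression mu*(X) = E[Y*|X] on the centered scale — where the residual is
unimodal even when |tau| is large — and then estimates only the residual
heterogeneity r(X), returning ``tau*(X) = tau0 + r(X)``.

Both tau/r minimizations are carried out as weighted regressions of the
pseudo-outcome ``residual / (Z - e)`` on X with weights ``w = (Z - e)^2``,
which is algebraically the same squared loss and lets any regression
learner serve as the function class.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

from .nuisance import (
    CrossFitNuisances,
    LearnerConfig,
    cross_fit_target,
)

__all__ = [
    "DegenerateOverlapError",
    "HTEEstimate",
    "estimate_tau0",
    "center_outcome",
    "estimate_tau_star_global",
    "fit_r_learner",
    "fit_revised",
    "log_mse",
]


class DegenerateOverlapError(ValueError):
    """The overlap weights sum to zero; tau is not identified."""


def _check_lengths(*arrays) -> int:
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("input vectors must have equal length")
    return n


def estimate_tau0(Y, Z, mu_hat, e_hat) -> float:
    """Double-robust estimate of the constant treatment-effect component.

    ``tau0 = sum (Y - mu)(Z - e) / sum (Z - e)^2`` — the weighted
    least-squares solution of the Robinson residual regression restricted
    to a constant effect.
    """
    Y, Z, mu_hat, e_hat = map(lambda a: np.asarray(a, float), (Y, Z, mu_hat, e_hat))
    _check_lengths(Y, Z, mu_hat, e_hat)
    d = Z - e_hat
    denom = float(d @ d)
    if denom <= 0:
        raise DegenerateOverlapError(
            "sum of (Z - e)^2 is zero: propensity estimates coincide with "
            "treatment; no overlap to identify the effect"
        )
    return float(((Y - mu_hat) * d).sum() / denom)


def center_outcome(Y, Z, tau0: float) -> np.ndarray:
    """Centered outcome ``Y* = Y - tau0 * Z`` (removes the constant effect)."""
    Y = np.asarray(Y, float)
    Z = np.asarray(Z, float)
    _check_lengths(Y, Z)
    return Y - tau0 * Z


def estimate_tau_star_global(Y, Z, mu_star_hat, e_hat, tau0: float) -> float:
    """Bias-corrected global effect ``tau* = tau0 + correction``.

    The correction re-runs the constant-effect estimating equation on the
    centered residuals: ``sum (Y - tau0 Z - mu*)(Z - e) / sum (Z - e)^2``.
    """
    Y, Z, mu_star_hat, e_hat = map(
        lambda a: np.asarray(a, float), (Y, Z, mu_star_hat, e_hat)
    )
    _check_lengths(Y, Z, mu_star_hat, e_hat)
    d = Z - e_hat
    denom = float(d @ d)
    if denom <= 0:
        raise DegenerateOverlapError("sum of (Z - e)^2 is zero")
    corr = float(((Y - tau0 * Z - mu_star_hat) * d).sum() / denom)
    return tau0 + corr


@dataclass
class HTEEstimate:
    """Fitted treatment-effect function with out-of-fold predictions.

    ``tau_star`` holds the per-subject out-of-fold estimates
    tau(X_i); for the revised variant ``tau_star = tau0 + r_hat``
    elementwise and ``tau_star_global`` is the bias-corrected scalar.
    ``predict`` scores new covariates by averaging the K fold-specific
    heterogeneity ensembles.
    """

    variant: str
    tau0: float
    tau_star_global: float
    r_hat: np.ndarray
    tau_star: np.ndarray
    fold_of: np.ndarray
    _fold_models: list = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._fold_models:
            raise ValueError("no fitted fold models stored; cannot predict")
        pred = np.mean([m.predict(X) for m in self._fold_models], axis=0)
        if self.variant == "revised":
            pred = self.tau0 + pred
        return pred

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "tau0": self.tau0,
            "tau_star_global": self.tau_star_global,
            "r_hat": self.r_hat.tolist(),
            "tau_star": self.tau_star.tolist(),
            "fold_of": self.fold_of.tolist(),
        }

    def save(self, path) -> None:
        """Serialize scalars and per-subject arrays to JSON.

        Fitted fold models are not serialized; reload gives access to the
        stored estimates but not to ``predict`` on new data.
        """
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "HTEEstimate":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(
            variant=d["variant"],
            tau0=d["tau0"],
            tau_star_global=d["tau_star_global"],
            r_hat=np.asarray(d["r_hat"]),
            tau_star=np.asarray(d["tau_star"]),
            fold_of=np.asarray(d["fold_of"], dtype=int),
        )


def _fit_effect_stage(
    X: np.ndarray,
    residual: np.ndarray,
    d: np.ndarray,
    fold_of: np.ndarray,
    config: LearnerConfig,
    seed: int,
) -> tuple[np.ndarray, list]:
    """Weighted cross-fitted regression of residual/(Z-e) on X, weights d^2."""
    w = d**2
    if not (w > 0).all():
        raise DegenerateOverlapError(
            "some overlap weights (Z - e)^2 are exactly zero; clip the "
            "propensity estimates away from {0, 1}"
        )
    pseudo = residual / d
    return cross_fit_target(
        X, pseudo, fold_of, "regression", config, seed, sample_weight=w
    )


def fit_r_learner(
    dataset,
    nuisances: CrossFitNuisances,
    config: LearnerConfig = LearnerConfig(),
    seed: int = 0,
) -> HTEEstimate:
    """Unrevised R-learner: minimize the Robinson squared loss directly.

    tau_hat minimizes ``(1/n) sum {(Y - mu) - tau(X)(Z - e)}^2`` over the
    bagged-network class, with out-of-fold predictions produced on the
    nuisance fold partition.
    """
    if nuisances.e_hat is None or nuisances.mu_hat is None:
        raise ValueError("unrevised estimator needs cross-fitted e_hat and mu_hat")
    Y, Z = dataset.Y, dataset.Z
    d = Z - nuisances.e_hat
    tau0 = estimate_tau0(Y, Z, nuisances.mu_hat, nuisances.e_hat)
    tau_hat, models = _fit_effect_stage(
        dataset.X, Y - nuisances.mu_hat, d, nuisances.fold_of, config, seed
    )
    return HTEEstimate(
        variant="unrevised",
        tau0=tau0,
        tau_star_global=tau0,
        r_hat=tau_hat - tau0,
        tau_star=tau_hat,
        fold_of=nuisances.fold_of,
        _fold_models=models,
    )


def fit_revised(
    dataset,
    nuisances: CrossFitNuisances,
    config: LearnerConfig = LearnerConfig(),
    seed: int = 0,
) -> HTEEstimate:
    """Revised (centered) estimator: ``tau*(X) = tau0 + r(X)``.

    Computes tau0, centers the outcome, cross-fits mu*(X) = E[Y*|X] on the
    same fold partition (stored back into ``nuisances.mu_star_hat``), then
    estimates the residual heterogeneity r(X) by the weighted Robinson
    regression of the centered residuals.
    """
    if nuisances.e_hat is None or nuisances.mu_hat is None:
        raise ValueError("revised estimator needs cross-fitted e_hat and mu_hat")
    Y, Z = dataset.Y, dataset.Z
    d = Z - nuisances.e_hat
    tau0 = estimate_tau0(Y, Z, nuisances.mu_hat, nuisances.e_hat)
    y_star = center_outcome(Y, Z, tau0)
    if nuisances.mu_star_hat is None:
        nuisances.mu_star_hat, nuisances.ensembles["mu_star"] = cross_fit_target(
            dataset.X, y_star, nuisances.fold_of, "regression", config, seed + 1
        )
    r_hat, models = _fit_effect_stage(
        dataset.X, y_star - nuisances.mu_star_hat, d, nuisances.fold_of, config, seed
    )
    tau_star_global = estimate_tau_star_global(
        Y, Z, nuisances.mu_star_hat, nuisances.e_hat, tau0
    )
    return HTEEstimate(
        variant="revised",
        tau0=tau0,
        tau_star_global=tau_star_global,
        r_hat=r_hat,
        tau_star=tau0 + r_hat,
        fold_of=nuisances.fold_of,
        _fold_models=models,
    )


def log_mse(tau_hat, tau_true, on_zero: str = "ninf") -> float:
    """Natural log of the mean squared error between two effect vectors.

    ``on_zero`` controls the MSE = 0 edge case: ``"ninf"`` returns
    ``-inf``, ``"raise"`` raises.
    """
    tau_hat = np.asarray(tau_hat, float)
    tau_true = np.asarray(tau_true, float)
    n = _check_lengths(tau_hat, tau_true)
    if n < 1:
        raise ValueError("need at least one observation")
    mse = float(np.mean((tau_hat - tau_true) ** 2))
    if mse == 0.0:
        if on_zero == "raise":
            raise ValueError("MSE is exactly zero; log-MSE undefined")
        return float("-inf")
    return float(np.log(mse))
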