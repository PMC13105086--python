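"""Synthetic observational data with nonlinear, non-additive confounding.

The generator draws covariates ``X ~ N_p(0, I)``, assigns treatment through
a nonlinear propensity ``e(X) = logit^{-1}(0.8 sin(pi X1 X2) + 0.6 X3 X4 +
0.5 tanh X5)``, and builds the outcome from the partially linear model
``Y = tau(X) Z + f(X) + eps`` with Gaussian noise.  Four treatment-effect
scenarios are provided, ranging from the sharp null ``tau = 0`` to a
non-additive interaction surface, so estimators and heterogeneity tests can
be calibrated under known truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

TAU_SCENARIOS = ("zero", "constant3", "simple_hte", "complex_hte")

_MIN_DIM = 5  # propensity, f and tau all reference X1..X5


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated observational study.

    Parameters
    ----------
    n : int
        Number of subjects.
    p : int
        Covariate dimension; must be at least 5 because the structural
        functions reference the first five coordinates.
    sigma : float
        Standard deviation of the additive Gaussian noise.
    tau_scenario : str
        One of ``zero`` (sharp null), ``constant3`` (homogeneous effect of
        3), ``simple_hte`` (softplus ridge) or ``complex_hte``
        (interactions, cosine and hinge terms).
    seed : int
        Seed of the single RNG stream used for covariates, treatment and
        noise, in that order.
    """

    n: int = 1000
    p: int = 20
    sigma: float = 1.0
    tau_scenario: str = "zero"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n}")
        if self.p < _MIN_DIM:
            raise ValueError(f"p must be >= {_MIN_DIM}, got {self.p}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.tau_scenario not in TAU_SCENARIOS:
            raise ValueError(
                f"unknown tau_scenario {self.tau_scenario!r}; "
                f"expected one of {TAU_SCENARIOS}"
            )


@dataclass
class ObservationalDataset:
    """One observational sample ``(Y, Z, X)``, optionally with known truth.

    ``e_true``, ``f_true`` and ``tau_true`` are populated by the simulator
    and carried alongside the data so downstream oracle checks never have
    to re-derive them; they are absent (``None``) for real data.
    """

    X: np.ndarray
    Z: np.ndarray
    Y: np.ndarray
    e_true: Optional[np.ndarray] = None
    f_true: Optional[np.ndarray] = None
    tau_true: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Z = np.asarray(self.Z)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D array")
        n = self.X.shape[0]
        if self.Z.shape != (n,) or self.Y.shape != (n,):
            raise ValueError("Y, Z and X must have matching lengths")
        if n and not np.isin(self.Z, (0, 1)).all():
            raise ValueError("Z entries must be 0 or 1")
        self.Z = self.Z.astype(int)
        if n and not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise ValueError("non-finite values in X or Y")
        if self.e_true is not None:
            self.e_true = np.asarray(self.e_true, dtype=float)
            if n and not ((self.e_true > 0) & (self.e_true < 1)).all():
                raise ValueError("e_true must lie strictly in (0, 1)")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def has_truth(self) -> bool:
        return self.tau_true is not None

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: Y, Z, X1..Xp and, when present, the truth columns."""
        cols = {"Y": self.Y, "Z": self.Z}
        for j in range(self.p):
            cols[f"X{j + 1}"] = self.X[:, j]
        for name, arr in (
            ("e_true", self.e_true),
            ("f_true", self.f_true),
            ("tau_true", self.tau_true),
        ):
            if arr is not None:
                cols[name] = arr
        return pd.DataFrame(cols)

    def to_csv(self, path, **kwargs) -> None:
        self.to_frame().to_csv(path, index=False, **kwargs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservationalDataset":
        xcols = sorted(
            (c for c in df.columns if c.startswith("X") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        if not xcols:
            raise ValueError("no covariate columns X1..Xp found")
        return cls(
            X=df[xcols].to_numpy(float),
            Z=df["Z"].to_numpy(),
            Y=df["Y"].to_numpy(float),
            e_true=df["e_true"].to_numpy(float) if "e_true" in df else None,
            f_true=df["f_true"].to_numpy(float) if "f_true" in df else None,
            tau_true=df["tau_true"].to_numpy(float) if "tau_true" in df else None,
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ObservationalDataset":
        return cls.from_frame(pd.read_csv(path, **kwargs))


def _as_matrix(x) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    if arr.shape[1] < _MIN_DIM:
        raise ValueError(
            f"covariate vectors need at least {_MIN_DIM} coordinates, "
            f"got {arr.shape[1]}"
        )
    return arr


def true_propensity(x) -> np.ndarray | float:
    """Treatment-assignment probability e(x) of the simulator.

    ``e(x) = logit^{-1}(0.8 sin(pi x1 x2) + 0.6 x3 x4 + 0.5 tanh x5)``;
    strictly inside (0, 1).  Accepts one vector or an (n, p) matrix.
    """
    arr = _as_matrix(x)
    lin = (
        0.8 * np.sin(np.pi * arr[:, 0] * arr[:, 1])
        + 0.6 * arr[:, 2] * arr[:, 3]
        + 0.5 * np.tanh(arr[:, 4])
    )
    out = expit(lin)
    return float(out[0]) if np.asarray(x).ndim == 1 else out


def true_f(x) -> np.ndarray | float:
    """Structural confounding surface f(x).

    ``f(x) = log(|x1| + 1) - x2^2 + sin x3 + 0.5 x4 x5``.  The absolute
    value in the first term keeps f finite for every real x1.
    """
    arr = _as_matrix(x)
    out = (
        np.log(np.abs(arr[:, 0]) + 1.0)
        - arr[:, 1] ** 2
        + np.sin(arr[:, 2])
        + 0.5 * arr[:, 3] * arr[:, 4]
    )
    return float(out[0]) if np.asarray(x).ndim == 1 else out


def true_tau(x, scenario: str) -> np.ndarray | float:
    """Treatment-effect surface tau(x) for one of the four scenarios.

    ``zero`` and ``constant3`` are homogeneous; ``simple_hte`` is
    ``-1 + 2 softplus(x1 + ... + x5)`` (a pronounced, mildly nonlinear
    signal with population variance ~6); ``complex_hte`` is
    ``-1 + x1 x2 + cos(2 x3) + max(x4 - x5, 0)``, a weaker and more
    intricate signal.
    """
    if scenario not in TAU_SCENARIOS:
        raise ValueError(
            f"unknown tau scenario {scenario!r}; expected one of {TAU_SCENARIOS}"
        )
    arr = _as_matrix(x)
    if scenario == "zero":
        out = np.zeros(arr.shape[0])
    elif scenario == "constant3":
        out = np.full(arr.shape[0], 3.0)
    elif scenario == "simple_hte":
        # softplus computed stably via logaddexp
        out = -1.0 + 2.0 * np.logaddexp(0.0, arr[:, :5].sum(axis=1))
    else:  # complex_hte
        out = (
            -1.0
            + arr[:, 0] * arr[:, 1]
            + np.cos(2.0 * arr[:, 2])
            + np.maximum(arr[:, 3] - arr[:, 4], 0.0)
        )
    return float(out[0]) if np.asarray(x).ndim == 1 else out


def simulate_dataset(config: SimulationConfig) -> ObservationalDataset:
    """Draw one observational study from the generative model.

    A single RNG stream (seeded from ``config.seed``) draws covariates,
    treatment and noise in that fixed order, so two calls with the same
    config are bit-identical.  ``n = 0`` yields an empty dataset.
    """
    rng = np.random.default_rng(config.seed)
    X = rng.standard_normal((config.n, config.p))
    if config.n == 0:
        z = np.zeros(0, dtype=int)
        return ObservationalDataset(
            X=X, Z=z, Y=np.zeros(0),
            e_true=np.zeros(0), f_true=np.zeros(0), tau_true=np.zeros(0),
        )
    e = true_propensity(X)
    Z = (rng.random(config.n) < e).astype(int)
    f = true_f(X)
    tau = true_tau(X, config.tau_scenario)
    eps = rng.normal(0.0, config.sigma, size=config.n)
    Y = tau * Z + f + eps
    return ObservationalDataset(X=X, Z=Z, Y=Y, e_true=e, f_true=f, tau_true=tau)
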