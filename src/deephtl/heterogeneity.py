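"""Global tests of treatment-effect heterogeneity, H0: Var{tau(X)} = 0.

Two complementary procedures share the cross-fitted nuisance estimates:

* **Kernel score test** — studentized residual scores from the
  constant-effect fit are projected off the estimation constraint
  direction and contracted with an RBF kernel matrix; the quadratic form
  ``Q = s~' K s~`` follows a weighted mixture of 1-df chi-squares under
  the null, whose tail probability is evaluated analytically by
  characteristic-function inversion (Davies/Imhof), with a moment-matching
  fallback.

* **Permutation test** — the cross-fitted prediction loss of the fitted
  effect function is compared with losses obtained after shuffling the
  held-out effect predictions within each (fold, treatment-arm) cell.
  Under the null, covariates carry no heterogeneity signal and shuffling
  leaves the loss distribution unchanged; under the alternative it
  destroys the alignment and inflates the permuted losses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate
from scipy.linalg import eigvalsh
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2, ncx2

from .estimation import (
    DegenerateOverlapError,
    center_outcome,
    estimate_tau0,
    estimate_tau_star_global,
)
from .nuisance import CrossFitNuisances

__all__ = [
    "KernelScoreResult",
    "PermutationResult",
    "compute_scores",
    "projection_matrix",
    "rbf_kernel_matrix",
    "kernel_score_test",
    "davies_pvalue",
    "observed_loss",
    "permutation_test",
]

_EIG_RTOL = 1e-8  # eigenvalues below this fraction of the largest are noise


def compute_scores(Y, Z, e_hat, mu_star_hat, tau0, tau_star_global):
    """Raw and studentized residual scores of the constant-effect fit.

    u_i = (Y_i - tau0 Z_i - mu*_i)(Z_i - e_i) - (tau* - tau0) w_i with
    w_i = (Z_i - e_i)^2; sigma^2 = n^{-1} sum u_i^2 / w_i estimates the
    conditional noise variance; s_i = u_i / (sigma sqrt(w_i)).  Because
    tau* solves the weighted constant-effect equation, sum u_i = 0 holds
    exactly, i.e. the scores satisfy a's = 0 with a = (sqrt(w_i)).

    Returns ``(u, s, w, sigma2_hat)``.
    """
    Y, Z, e_hat, mu_star_hat = map(
        lambda a: np.asarray(a, float), (Y, Z, e_hat, mu_star_hat)
    )
    d = Z - e_hat
    w = d**2
    if not (w > 0).all():
        raise DegenerateOverlapError(
            "zero overlap weight encountered; clip the propensity estimates"
        )
    u = (Y - tau0 * Z - mu_star_hat) * d - (tau_star_global - tau0) * w
    sigma2 = float(np.mean(u**2 / w))
    if sigma2 <= 0:
        raise ValueError("degenerate residuals: estimated noise variance is zero")
    s = u / np.sqrt(sigma2 * w)
    return u, s, w, sigma2


def projection_matrix(a: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the complement of span(a).

    P = I - a a' / (a'a): symmetric, idempotent, P a = 0, rank n-1.
    """
    a = np.asarray(a, float)
    nrm2 = float(a @ a)
    if nrm2 == 0:
        raise ValueError("cannot project along the zero vector")
    return np.eye(len(a)) - np.outer(a, a) / nrm2


def rbf_kernel_matrix(X: np.ndarray, bandwidth="median") -> np.ndarray:
    """Gaussian RBF kernel matrix on standardized covariates.

    K_ij = exp(-||x_i - x_j||^2 / (2 h^2)).  ``bandwidth="median"`` uses
    the median heuristic: h = median pairwise Euclidean distance of the
    standardized covariates (the standard default for kernel score tests).
    """
    X = np.asarray(X, float)
    if not np.isfinite(X).all():
        raise ValueError("covariate matrix contains non-finite rows")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    dists = pdist(Xs)
    if bandwidth == "median":
        h = float(np.median(dists))
        if h <= 0:
            h = 1.0
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    D2 = squareform(dists**2)
    return np.exp(-D2 / (2.0 * h**2))


def _imhof_tail(q: float, lambdas: np.ndarray, acc: float) -> Optional[float]:
    """Pr{sum lambda_j chi^2_1j >= q} by characteristic-function inversion."""

    def integrand(u):
        u = np.atleast_1d(u)
        lu = np.outer(u, lambdas)
        theta = 0.5 * np.arctan(lu).sum(axis=1) - 0.5 * q * u
        log_rho = 0.25 * np.log1p(lu**2).sum(axis=1)  # log-space: no overflow
        return np.sin(theta) * np.exp(-log_rho) / u

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, err = integrate.quad(
                lambda u: float(integrand(u)[0]),
                0.0,
                np.inf,
                epsabs=acc * 0.1,
                epsrel=acc,
                limit=500,
            )
    except Exception:  # pragma: no cover - inversion failure path
        return None
    if err > max(acc, 1e-4):
        return None
    p = 0.5 + val / np.pi
    if p < -1e-3 or p > 1 + 1e-3:
        return None
    return float(np.clip(p, 0.0, 1.0))


def _liu_tail(q: float, lambdas: np.ndarray) -> float:
    """Moment-matched (Liu-type) noncentral chi-square approximation."""
    c1 = lambdas.sum()
    c2 = (lambdas**2).sum()
    c3 = (lambdas**3).sum()
    c4 = (lambdas**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = c2**3 / c3**2 if c3 > 0 else 1.0
        a = np.sqrt(df) if c3 <= 0 else 1.0 / s1
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    t_star = (q - mu_q) / sigma_q
    mu_x = df + delta
    sigma_x = np.sqrt(2 * (df + 2 * delta))
    x = t_star * sigma_x + mu_x
    if delta > 0:
        return float(ncx2.sf(x, df, delta))
    return float(chi2.sf(x, df))


def davies_pvalue(Q: float, lambdas, acc: float = 1e-6) -> float:
    """Tail probability Pr{sum_j lambda_j chi^2_{1,j} >= Q}.

    Computed by numerical inversion of the characteristic function of the
    chi-square mixture; on inversion failure a Liu-type moment-matching
    approximation is used instead.
    """
    lambdas = np.asarray(lambdas, float).ravel()
    if lambdas.size == 0:
        raise ValueError("need at least one mixture weight")
    lam_max = lambdas.max()
    if lam_max <= 0:
        raise ValueError("mixture weights must include a positive value")
    if (lambdas < -_EIG_RTOL * lam_max).any():
        raise ValueError("negative mixture weights beyond numerical tolerance")
    lambdas = lambdas[lambdas > 0]
    if Q < 0:
        if Q < -1e-8 * lam_max:
            raise ValueError("test statistic must be nonnegative")
        Q = 0.0
    if Q == 0.0:
        return 1.0
    if lambdas.size == 1:
        return float(chi2.sf(Q / lambdas[0], df=1))
    p = _imhof_tail(Q, lambdas, acc)
    if p is None:
        p = _liu_tail(Q, lambdas)
    return float(min(max(p, 0.0), 1.0))


@dataclass
class KernelScoreResult:
    """Outcome of the kernel score test."""

    variant: str
    u: np.ndarray
    s: np.ndarray
    w: np.ndarray
    sigma2_hat: float
    Q: float
    lambdas: np.ndarray
    p_value: float
    k_eff: float
    bandwidth: float
    used_fallback: bool = False

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "Q": self.Q,
            "p_davies": self.p_value,
            "k_eff": self.k_eff,
            "n_lambdas": int(len(self.lambdas)),
            "sigma2_hat": self.sigma2_hat,
            "bandwidth": self.bandwidth,
            "used_fallback": self.used_fallback,
        }


def kernel_score_test(
    dataset,
    nuisances: CrossFitNuisances,
    variant: str = "revised",
    bandwidth="median",
) -> KernelScoreResult:
    """Analytic kernel score test of H0: Var{tau(X)} = 0.

    Builds the studentized scores from the cross-fitted nuisances
    (revised variant: centered residuals against mu*; unrevised variant:
    raw residuals against mu with the uncorrected tau0), projects off the
    constraint direction a = (sqrt(w_i)), forms Q = s' P K P s and
    evaluates the chi-square-mixture tail probability by the Davies
    method.  ``k_eff = (sum lambda)^2 / sum lambda^2`` summarizes the
    effective degrees of freedom of the detected heterogeneity.
    """
    if variant not in ("revised", "unrevised"):
        raise ValueError("variant must be 'revised' or 'unrevised'")
    Y, Z = dataset.Y, dataset.Z
    if nuisances.e_hat is None or nuisances.mu_hat is None:
        raise ValueError("kernel score test needs cross-fitted e_hat and mu_hat")
    tau0 = estimate_tau0(Y, Z, nuisances.mu_hat, nuisances.e_hat)
    if variant == "revised":
        if nuisances.mu_star_hat is None:
            raise ValueError(
                "revised test needs mu_star_hat; run fit_revised or cross_fit "
                "with the centered outcome first"
            )
        tau_star = estimate_tau_star_global(
            Y, Z, nuisances.mu_star_hat, nuisances.e_hat, tau0
        )
        u, s, w, sigma2 = compute_scores(
            Y, Z, nuisances.e_hat, nuisances.mu_star_hat, tau0, tau_star
        )
    else:
        # scores built directly from the unrevised residuals: the roles of
        # (tau0, mu*, tau*) are played by (0, mu, tau0)
        u, s, w, sigma2 = compute_scores(
            Y, Z, nuisances.e_hat, nuisances.mu_hat, 0.0, tau0
        )
    K = rbf_kernel_matrix(dataset.X, bandwidth)
    h = (
        float(np.median(pdist(_standardized(dataset.X))))
        if bandwidth == "median"
        else float(bandwidth)
    )
    # M = P K P with P = I - aa'/(a'a): rank-1 update, assembled in O(n^2)
    a = np.sqrt(w)
    a = a / np.linalg.norm(a)
    Ka = K @ a
    aKa = float(a @ Ka)
    M = K - np.outer(a, Ka) - np.outer(Ka, a) + aKa * np.outer(a, a)
    M = 0.5 * (M + M.T)
    lams = eigvalsh(M)
    lam_max = lams.max() if len(lams) else 0.0
    lams = lams[lams > _EIG_RTOL * max(lam_max, 0.0)]
    Q = float(s @ M @ s)
    used_fallback = False
    if lams.size == 0 or lam_max <= 0:
        warnings.warn(
            "projected kernel matrix has no eigenvalue above tolerance; p = 1",
            RuntimeWarning,
        )
        p = 1.0
        k_eff = 0.0
    else:
        Q = max(Q, 0.0)
        p_imhof = _imhof_tail(Q, lams, 1e-6) if Q > 0 else 1.0
        if p_imhof is None:
            p = _liu_tail(Q, lams)
            used_fallback = True
        else:
            p = p_imhof
        k_eff = float(lams.sum() ** 2 / (lams**2).sum())
    return KernelScoreResult(
        variant=variant,
        u=u,
        s=s,
        w=w,
        sigma2_hat=sigma2,
        Q=Q,
        lambdas=lams,
        p_value=float(min(max(p, 0.0), 1.0)),
        k_eff=k_eff,
        bandwidth=h,
        used_fallback=used_fallback,
    )


def _standardized(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return (X - mean) / scale


def _loss_components(dataset, nuisances, variant, tau0):
    """Residual A_i and overlap residual d_i = Z_i - e_i for the loss."""
    Y, Z = dataset.Y, dataset.Z
    d = Z - nuisances.e_hat
    if variant == "revised":
        if tau0 is None:
            raise ValueError("revised loss requires tau0 to center the outcome")
        if nuisances.mu_star_hat is None:
            raise ValueError("revised loss requires mu_star_hat")
        A = center_outcome(Y, Z, tau0) - nuisances.mu_star_hat
    elif variant == "unrevised":
        A = Y - nuisances.mu_hat
    else:
        raise ValueError("variant must be 'revised' or 'unrevised'")
    return A, d


def observed_loss(
    dataset,
    nuisances: CrossFitNuisances,
    tau_predictions: np.ndarray,
    variant: str = "revised",
    tau0: Optional[float] = None,
) -> float:
    """Cross-fitted prediction loss of the effect function.

    Revised: L = n^{-1} sum {Y*_i - mu*_i - tau*(X_i)(Z_i - e_i)}^2;
    unrevised: the analogous Robinson loss with Y, mu and tau-hat.  The
    tau predictions must be the out-of-fold ones.
    """
    tau_predictions = np.asarray(tau_predictions, float)
    if len(tau_predictions) != dataset.n:
        raise ValueError("tau_predictions length does not match the dataset")
    A, d = _loss_components(dataset, nuisances, variant, tau0)
    return float(np.mean((A - tau_predictions * d) ** 2))


@dataclass
class PermutationResult:
    """Outcome of the within-arm permutation test."""

    L_obs: float
    L_perm: np.ndarray
    B: int
    p_value: float
    variant: str

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "L_obs": self.L_obs,
            "B": self.B,
            "p_perm": self.p_value,
        }


def permutation_test(
    dataset,
    nuisances: CrossFitNuisances,
    tau_predictions: np.ndarray,
    B: int = 2000,
    seed: int = 0,
    variant: str = "revised",
    tau0: Optional[float] = None,
) -> PermutationResult:
    """Within-arm permutation test of H0: Var{tau(X)} = 0.

    For each of B permutations the held-out effect predictions are
    shuffled independently within every (fold, treatment-arm) cell and
    the cross-fitted loss recomputed; the p-value is
    ``(1 + #{L_perm <= L_obs}) / (B + 1)``.  Permuting within arms keeps
    the marginal coupling of predictions and treatment intact, so only
    the covariate alignment of the heterogeneity is broken.
    """
    tau_predictions = np.asarray(tau_predictions, float)
    if len(tau_predictions) != dataset.n:
        raise ValueError("tau_predictions length does not match the dataset")
    A, d = _loss_components(dataset, nuisances, variant, tau0)
    L_obs = float(np.mean((A - tau_predictions * d) ** 2))
    if B < 1:
        warnings.warn("B = 0 permutations: p-value is trivially 1", RuntimeWarning)
        return PermutationResult(L_obs, np.empty(0), 0, 1.0, variant)

    fold_of = nuisances.fold_of
    Z = dataset.Z
    cells = []
    for k in range(int(fold_of.max()) + 1):
        for z in (0, 1):
            idx = np.flatnonzero((fold_of == k) & (Z == z))
            if len(idx) == 0:
                raise ValueError(
                    f"fold {k} has no subjects in arm {z}; cannot permute "
                    "within arms — use fewer folds"
                )
            cells.append(idx)

    rng = np.random.default_rng(seed)
    L_perm = np.empty(B)
    perm = np.arange(dataset.n)
    for b in range(B):
        for idx in cells:  # deterministic nested (b, fold, arm) order
            perm[idx] = idx[rng.permutation(len(idx))]
        L_perm[b] = np.mean((A - tau_predictions[perm] * d) ** 2)
    p = (1.0 + np.sum(L_perm <= L_obs + 1e-15)) / (B + 1.0)
    return PermutationResult(L_obs, L_perm, B, float(p), variant)
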