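"""Bayesian phylogenetic predictive modelling (PPM).

The model is a linear regression observed at the tips of a time-scaled
phylogeny with Brownian-motion structured residuals:

    y ~ MVN(alpha + beta * x,  sigma2 * C_lambda)

where C is the matrix of shared root-to-MRCA path lengths (Myr) and
C_lambda scales its off-diagonal entries by Pagel's lambda (lambda = 1,
pure Brownian motion, is the default; lambda can optionally be estimated).
Here x is log10 skull width (mm) and y log10 A_Phys (mm^2), but the engine
is agnostic to what the traits are.

Inference is by MCMC: Gibbs draws for (alpha, beta) from their conditional
normal and for sigma2 from its conditional inverse-gamma density, with a
Metropolis step for lambda when estimated.  Priors are improper flat on
(alpha, beta), uniform on log(sigma2) over a wide fixed range, and
uniform(0, 1) on lambda, so posterior means of the regression coefficients
coincide with the generalized-least-squares estimator.

Posterior predictive distributions for tips with unobserved y condition on
both the regression line and the phylogenetically correlated residuals of
the observed tips (the conditional multivariate normal), so a target's
phylogenetic position — not just its x value — informs its prediction.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky

from .tree import TimeTree, phylo_vcv, _canon

__all__ = [
    "McmcConfig",
    "PosteriorSample",
    "PredictiveDistribution",
    "SingularCovarianceError",
    "load_trait_table",
    "validate_trait_table",
    "fit_ppm",
    "predict_tip",
    "predict_batch",
    "log_likelihood",
    "gls_estimates",
]

_SIGMA2_MIN, _SIGMA2_MAX = 1e-12, 1e12  # bounds of the uniform-on-log prior


class SingularCovarianceError(np.linalg.LinAlgError):
    """Phylogenetic covariance not invertible."""


@dataclass(frozen=True)
class McmcConfig:
    """MCMC chain settings.

    Defaults retain 1,000 posterior draws, the posterior size used for
    prediction throughout; the thinning/burn-in structure mirrors standard
    BayesTraits-style runs and full-length settings can be requested
    explicitly.
    """

    iterations: int = 2000
    burnin: int = 1000
    thin: int = 1
    chains: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.burnin < self.iterations:
            raise ValueError("burn-in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burnin + self.thin - 1) // self.thin


@dataclass(frozen=True)
class PosteriorSample:
    """Pooled MCMC draws of the regression parameters."""

    alpha: np.ndarray
    beta: np.ndarray
    sigma2: np.ndarray
    lam: np.ndarray
    chain: np.ndarray
    seed: int
    lambda_estimated: bool = False

    def __post_init__(self) -> None:
        if not (self.sigma2 > 0).all():
            raise ValueError("sigma2 draws must be positive")
        if ((self.lam < 0) | (self.lam > 1)).any():
            raise ValueError("lambda draws must lie in [0, 1]")

    @property
    def n_draws(self) -> int:
        return self.alpha.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": self.chain,
                "alpha": self.alpha,
                "beta": self.beta,
                "sigma2": self.sigma2,
                "lambda": self.lam,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed: int = 0) -> "PosteriorSample":
        return cls(
            alpha=df["alpha"].to_numpy(float),
            beta=df["beta"].to_numpy(float),
            sigma2=df["sigma2"].to_numpy(float),
            lam=df["lambda"].to_numpy(float),
            chain=df["chain"].to_numpy(int),
            seed=seed,
        )


@dataclass
class PredictiveDistribution:
    """Posterior predictive draws of y for one target tip."""

    taxon: str
    draws: np.ndarray
    level: float = 0.95

    @property
    def median(self) -> float:
        return float(np.median(self.draws))

    @property
    def interval(self) -> tuple[float, float]:
        lo = (1 - self.level) / 2
        return tuple(np.quantile(self.draws, [lo, 1 - lo]))

    def summary(self) -> dict:
        lo, hi = self.interval
        return {"taxon": self.taxon, "median": self.median, "lo": lo, "hi": hi}


# -- trait tables ----------------------------------------------------------


def validate_trait_table(data: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a trait table.

    Columns: ``taxon`` (unique), ``x`` (finite predictor), ``y`` (response,
    NaN for prediction targets), ``status`` (``extant`` | ``extinct``,
    optional, defaults to extant).
    """
    required = {"taxon", "x", "y"}
    if not required.issubset(data.columns):
        raise ValueError(f"trait table must have columns {sorted(required)}")
    df = data.copy()
    df["taxon"] = df["taxon"].map(_canon)
    if df["taxon"].duplicated().any():
        dupes = sorted(df.loc[df["taxon"].duplicated(), "taxon"])
        raise ValueError(f"duplicate taxa in trait table: {dupes}")
    df["x"] = df["x"].astype(float)
    df["y"] = df["y"].astype(float)
    if not np.isfinite(df["x"]).all():
        raise ValueError("predictor x must be finite for every row")
    if "status" not in df.columns:
        df["status"] = "extant"
    return df


def load_trait_table(path, group: str | None = None) -> pd.DataFrame:
    """Read a trait table CSV.

    Two schemas are accepted:

    * generic: ``taxon,x,y[,status]`` — used as-is;
    * measured: ``taxon,muscle_group,wsk_mm,aphys_mm2[,status]`` — filtered
      to ``group`` and log10-transformed (x = log10 W_Sk, y = log10 A_Phys;
      empty A_Phys marks a prediction target).
    """
    df = pd.read_csv(path, comment="#")
    if "muscle_group" in df.columns:
        if group is None:
            raise ValueError("measured-schema trait table requires a muscle group")
        df = df[df["muscle_group"] == group].copy()
        if df.empty:
            raise ValueError(f"no rows for muscle group {group!r}")
        df["x"] = np.log10(df["wsk_mm"].astype(float))
        df["y"] = np.log10(df["aphys_mm2"].astype(float))
    return validate_trait_table(df)


# -- linear algebra helpers ------------------------------------------------


def _lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal entries of C by Pagel's lambda."""
    if lam == 1.0:
        return C
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def _chol_with_jitter(C: np.ndarray):
    """Cholesky factorisation, adding a diagonal jitter of 1e-8 * max(diag)
    (with a warning) if C is numerically singular, e.g. because two tips are
    phylogenetically identical."""
    def _factor(mat):
        cho = cho_factor(mat, lower=True)
        d = np.diag(cho[0])
        # LAPACK can return a factor with zero/NaN pivots for an exactly
        # singular input instead of raising; treat that as failure too
        tol = np.sqrt(16 * np.finfo(float).eps * mat.max())
        if not (np.isfinite(d).all() and (d > tol).all()):
            raise np.linalg.LinAlgError("singular covariance")
        return cho

    try:
        return _factor(C)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * float(np.max(np.diag(C)))
        warnings.warn(
            "phylogenetic covariance is singular; adding diagonal jitter "
            f"{jitter:.3g} (consider resolving zero-length branches)",
            RuntimeWarning,
            stacklevel=3,
        )
        try:
            return _factor(C + jitter * np.eye(C.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise SingularCovarianceError(
                "phylogenetic covariance is singular even after jitter; "
                "resolve zero-length branches or remove duplicate tips"
            ) from exc


def _gls_quantities(C: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Sufficient quantities for the Gibbs conditionals at fixed lambda."""
    cho = _chol_with_jitter(C)
    Ci_X = cho_solve(cho, X)
    Ci_y = cho_solve(cho, y)
    A = X.T @ Ci_X                      # X' C^-1 X
    Xy = X.T @ Ci_y                     # X' C^-1 y
    yy = float(y @ Ci_y)                # y' C^-1 y
    b_gls = np.linalg.solve(A, Xy)
    L_Ainv = cholesky(np.linalg.inv(A), lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return cho, A, Xy, yy, b_gls, L_Ainv, logdet


def gls_estimates(tree: TimeTree, data: pd.DataFrame, lam: float = 1.0):
    """Closed-form GLS estimates (b_hat, cov_unscaled, s2_hat) on observed rows.

    ``cov_unscaled`` is (X' C^-1 X)^-1; multiply by a residual variance to
    get the coefficient covariance.
    """
    obs = validate_trait_table(data)
    obs = obs[np.isfinite(obs["y"])]
    C = _lambda_transform(phylo_vcv(tree, list(obs["taxon"])).matrix, lam)
    X = np.column_stack([np.ones(len(obs)), obs["x"].to_numpy()])
    y = obs["y"].to_numpy()
    cho, A, Xy, yy, b_gls, _, _ = _gls_quantities(C, X, y)
    resid = y - X @ b_gls
    s2 = float(resid @ cho_solve(cho, resid)) / max(len(obs) - 2, 1)
    return b_gls, np.linalg.inv(A), s2


def log_likelihood(
    tree: TimeTree,
    data: pd.DataFrame,
    alpha: float,
    beta: float,
    sigma2: float,
    lam: float = 1.0,
) -> float:
    """Log density of the observed y under MVN(alpha + beta x, sigma2 C_lambda)."""
    obs = validate_trait_table(data)
    obs = obs[np.isfinite(obs["y"])]
    n = len(obs)
    C = _lambda_transform(phylo_vcv(tree, list(obs["taxon"])).matrix, lam)
    cho = _chol_with_jitter(C)
    r = obs["y"].to_numpy() - (alpha + beta * obs["x"].to_numpy())
    quad = float(r @ cho_solve(cho, r)) / sigma2
    logdet = n * np.log(sigma2) + 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


# -- fitting ---------------------------------------------------------------


def _check_overlap(tree: TimeTree, taxa: Sequence[str]) -> None:
    tips = set(tree.tip_labels)
    missing = sorted(set(taxa) - tips)
    if missing:
        raise ValueError(f"trait-table taxa not found in the tree: {missing}")
    if not taxa:
        raise ValueError("no taxa shared between tree and trait table")


def _run_chain(
    C: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    config: McmcConfig,
    rng: np.random.Generator,
    estimate_lambda: bool,
    lambda_step: float = 0.15,
):
    n = y.size
    lam = 0.5 if estimate_lambda else 1.0
    quant = _gls_quantities(_lambda_transform(C, lam), X, y)
    cho, A, Xy, yy, b_gls, L_Ainv, logdet = quant

    def rss(b: np.ndarray) -> float:
        return yy - 2.0 * float(b @ Xy) + float(b @ (A @ b))

    b = b_gls.copy()
    sigma2 = max(rss(b) / n, _SIGMA2_MIN)

    keep = config.retained_per_chain
    out = np.empty((keep, 4))
    k = 0
    for it in range(config.iterations):
        # (alpha, beta) | sigma2, lambda  ~  N(b_gls, sigma2 (X'C^-1X)^-1)
        b = b_gls + np.sqrt(sigma2) * (L_Ainv @ rng.standard_normal(2))
        # sigma2 | (alpha, beta), lambda  ~  InvGamma(n/2, RSS/2)
        sigma2 = float(np.clip((rss(b) / 2.0) / rng.gamma(n / 2.0), _SIGMA2_MIN, _SIGMA2_MAX))
        if estimate_lambda:
            prop = lam + lambda_step * rng.standard_normal()
            prop = abs(prop) % 2.0
            prop = 2.0 - prop if prop > 1.0 else prop  # reflect into [0, 1]
            quant_p = _gls_quantities(_lambda_transform(C, prop), X, y)
            r = y - X @ b
            cho_p = quant_p[0]
            quad_p = float(r @ cho_solve(cho_p, r))
            quad_c = float(r @ cho_solve(cho, r))
            loglik_p = -0.5 * (quant_p[6] + quad_p / sigma2)
            loglik_c = -0.5 * (logdet + quad_c / sigma2)
            if np.log(rng.uniform()) < loglik_p - loglik_c:
                lam = prop
                cho, A, Xy, yy, b_gls, L_Ainv, logdet = quant_p
        if it >= config.burnin and (it - config.burnin) % config.thin == 0:
            out[k] = (b[0], b[1], sigma2, lam)
            k += 1
    return out[:k]


def fit_ppm(
    tree: TimeTree,
    data: pd.DataFrame,
    config: McmcConfig | None = None,
    estimate_lambda: bool = False,
) -> PosteriorSample:
    """Fit the phylogenetic regression by MCMC on rows with observed y.

    Reproducible: the same config (including seed) yields identical draws.
    """
    config = config or McmcConfig()
    df = validate_trait_table(data)
    obs = df[np.isfinite(df["y"])]
    if len(obs) < 3:
        raise ValueError("need at least 3 taxa with observed y to fit")
    taxa = list(obs["taxon"])
    _check_overlap(tree, taxa)
    C = phylo_vcv(tree, taxa).matrix
    X = np.column_stack([np.ones(len(obs)), obs["x"].to_numpy()])
    y = obs["y"].to_numpy()

    blocks, chain_ids = [], []
    for c in range(config.chains):
        rng = np.random.default_rng([int(config.seed), c])
        draws = _run_chain(C, X, y, config, rng, estimate_lambda)
        blocks.append(draws)
        chain_ids.append(np.full(len(draws), c))
    pooled = np.vstack(blocks)
    return PosteriorSample(
        alpha=pooled[:, 0],
        beta=pooled[:, 1],
        sigma2=pooled[:, 2],
        lam=pooled[:, 3],
        chain=np.concatenate(chain_ids),
        seed=int(config.seed),
        lambda_estimated=estimate_lambda,
    )


# -- prediction ------------------------------------------------------------


def _target_rng(posterior_seed: int, taxon: str) -> np.random.Generator:
    """Deterministic per-target stream: identical for predict_tip and
    predict_batch, and independent of target ordering."""
    return np.random.default_rng(
        [int(posterior_seed), zlib.crc32(taxon.encode("utf8")), 0x70AD]
    )


def _conditional_draws(
    posterior: PosteriorSample,
    C_obs: np.ndarray,
    c_star: np.ndarray,
    c_ss: float,
    x_obs: np.ndarray,
    y_obs: np.ndarray,
    x_star: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample the conditional normal of the target given observed tips,
    one draw per posterior draw."""
    a, b, s2, lam = posterior.alpha, posterior.beta, posterior.sigma2, posterior.lam
    m = posterior.n_draws
    z = rng.standard_normal(m)
    if posterior.lambda_estimated and not np.all(lam == lam[0]):
        draws = np.empty(m)
        for i in range(m):
            Cl = _lambda_transform(C_obs, lam[i])
            cl = c_star * lam[i]
            cho = _chol_with_jitter(Cl)
            k = cho_solve(cho, cl)
            mean = a[i] + b[i] * x_star + k @ (y_obs - a[i] - b[i] * x_obs)
            var = s2[i] * max(c_ss - float(cl @ k), 0.0)
            draws[i] = mean + np.sqrt(var) * z[i]
        return draws
    lam0 = float(lam[0]) if posterior.n_draws else 1.0
    Cl = _lambda_transform(C_obs, lam0)
    cl = c_star * lam0
    cho = _chol_with_jitter(Cl)
    k = cho_solve(cho, cl)
    k1, kx, ky = float(k.sum()), float(k @ x_obs), float(k @ y_obs)
    q = max(c_ss - float(cl @ k), 0.0)
    mean = a * (1.0 - k1) + b * (x_star - kx) + ky
    return mean + np.sqrt(s2 * q) * z


def _prediction_frames(tree: TimeTree, data: pd.DataFrame, targets: Sequence[str]):
    df = validate_trait_table(data)
    obs = df[np.isfinite(df["y"])]
    taxa_obs = list(obs["taxon"])
    _check_overlap(tree, taxa_obs)
    targets = [_canon(t) for t in targets]
    rows = df.set_index("taxon")
    for t in targets:
        if t not in set(tree.tip_labels):
            raise ValueError(f"target {t!r} is not a tip of the tree")
        if t not in rows.index:
            raise ValueError(f"target {t!r} has no row in the trait table")
        if np.isfinite(rows.loc[t, "y"]):
            raise ValueError(
                f"target {t!r} has an observed y; use leave-one-out "
                "cross-validation to score observed taxa"
            )
    V = phylo_vcv(tree, taxa_obs + targets).matrix
    n = len(taxa_obs)
    return obs, rows, targets, V, n


def predict_tip(
    posterior: PosteriorSample,
    tree: TimeTree,
    data: pd.DataFrame,
    target: str,
    level: float = 0.95,
) -> PredictiveDistribution:
    """Posterior predictive distribution for one tip with unobserved y.

    Each posterior draw contributes one draw from the conditional normal of
    the target given the observed tips under that draw's parameters, so the
    result carries both parameter and predictive uncertainty.
    """
    obs, rows, targets, V, n = _prediction_frames(tree, data, [target])
    t = targets[0]
    draws = _conditional_draws(
        posterior,
        V[:n, :n],
        V[:n, n],
        float(V[n, n]),
        obs["x"].to_numpy(),
        obs["y"].to_numpy(),
        float(rows.loc[t, "x"]),
        _target_rng(posterior.seed, t),
    )
    return PredictiveDistribution(taxon=t, draws=draws, level=level)


def predict_batch(
    posterior: PosteriorSample,
    tree: TimeTree,
    data: pd.DataFrame,
    targets: Sequence[str],
    level: float = 0.95,
) -> dict[str, PredictiveDistribution]:
    """Predict several unobserved tips in one pass.

    Targets condition only on observed (y-bearing) tips, never on each
    other, so each result equals the corresponding single-tip prediction.
    """
    if not list(targets):
        raise ValueError("empty target set")
    obs, rows, targets, V, n = _prediction_frames(tree, data, targets)
    x_obs = obs["x"].to_numpy()
    y_obs = obs["y"].to_numpy()
    out = {}
    for j, t in enumerate(targets):
        draws = _conditional_draws(
            posterior,
            V[:n, :n],
            V[:n, n + j],
            float(V[n + j, n + j]),
            x_obs,
            y_obs,
            float(rows.loc[t, "x"]),
            _target_rng(posterior.seed, t),
        )
        out[t] = PredictiveDistribution(taxon=t, draws=draws, level=level)
    return out
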