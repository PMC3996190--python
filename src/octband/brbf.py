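"""Bayesian radial basis function regression fitted by MCMC.

The regressor maps one or two standardized input features to one target
through a fixed-size Gaussian RBF expansion

    f(x) = w0 + sum_k w_k exp(-||x - c_k||^2 / (2 s_k^2)),

with priors over all parameters: zero-mean normal weights (conjugate),
normal centers, log-normal widths, and an inverse-gamma noise variance.
Inference is Metropolis-within-Gibbs: weights and the noise variance have
exact conjugate updates; centers and log-widths move by random-walk
Metropolis with step sizes auto-tuned during burn-in to a 20-50% acceptance
rate.  Predictions are posterior-predictive means over the retained samples,
returned on the original (destandardized) target scale.

Both inputs and the target are standardized to zero mean and unit variance
before sampling, which makes the default prior scales dimensionless and the
predictions scale-equivariant.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping

import numpy as np

from .errors import OctbandError, ValidationError


@dataclasses.dataclass
class BRBFConfig:
    """Sampler and prior settings.

    ``n_basis`` Gaussian kernels; ``mcmc_iterations`` total sweeps of which
    ``burn_in`` are discarded and the rest kept every ``thinning``-th.  Prior
    scales apply on the standardized scale: weights ~ N(0, weight_scale^2),
    centers ~ N(0, center_scale^2), log-widths ~ N(log width_location,
    width_log_scale^2), noise variance ~ InvGamma(noise_shape, noise_rate).
    """

    n_basis: int = 8
    mcmc_iterations: int = 5000
    burn_in: int = 1000
    thinning: int = 5
    weight_scale: float = 0.3
    center_scale: float = 2.0
    width_location: float = 2.0
    width_log_scale: float = 0.5
    noise_shape: float = 2.0
    noise_rate: float = 0.5
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_basis < 1:
            raise ValidationError(f"n_basis: {self.n_basis} < 1")
        if not self.mcmc_iterations > self.burn_in >= 0:
            raise ValidationError(
                f"mcmc_iterations ({self.mcmc_iterations}) must exceed "
                f"burn_in ({self.burn_in}) >= 0"
            )
        if self.thinning < 1:
            raise ValidationError(f"thinning: {self.thinning} < 1")
        for name in (
            "weight_scale", "center_scale", "width_location",
            "width_log_scale", "noise_shape", "noise_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name}: must be > 0")


@dataclasses.dataclass
class StandardizationParams:
    """Per-feature location/scale learned from training data."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray, *, allow_constant: bool = False):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        mean = values.mean(axis=0)
        sd = values.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            if not allow_constant:
                raise ValidationError(
                    "standardize: feature has zero variance; drop the constant "
                    "feature before fitting"
                )
            sd = np.where(sd <= 0, 1.0, sd)
        return cls(mean=mean, sd=sd)


def standardize(values: np.ndarray, params: StandardizationParams) -> np.ndarray:
    """z = (x - mean) / sd, columnwise."""
    if np.any(params.sd <= 0):
        raise ValidationError("standardize: params.sd must be > 0")
    return (np.asarray(values, dtype=float) - params.mean) / params.sd


def destandardize(z: np.ndarray, params: StandardizationParams) -> np.ndarray:
    """Inverse of :func:`standardize`."""
    return np.asarray(z, dtype=float) * params.sd + params.mean


@dataclasses.dataclass
class BRBFPosterior:
    """Retained MCMC samples plus everything needed to predict.

    Samples: ``centers`` (S, K, d), ``widths`` (S, K), ``weights`` (S, K+1)
    with the intercept last, ``noise_var`` (S,).  Standardization parameters
    are those fitted on the training inputs and target.
    """

    centers: np.ndarray
    widths: np.ndarray
    weights: np.ndarray
    noise_var: np.ndarray
    x_params: StandardizationParams
    y_params: StandardizationParams
    acceptance: Mapping[str, float]
    config: BRBFConfig

    @property
    def n_samples(self) -> int:
        return self.centers.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.centers.shape[2]

    def save(self, path) -> None:
        """Serialize to an .npz archive with a JSON config echo."""
        np.savez(
            path,
            centers=self.centers,
            widths=self.widths,
            weights=self.weights,
            noise_var=self.noise_var,
            x_mean=self.x_params.mean,
            x_sd=self.x_params.sd,
            y_mean=self.y_params.mean,
            y_sd=self.y_params.sd,
            meta=np.array(
                json.dumps(
                    {
                        "acceptance": dict(self.acceptance),
                        "config": dataclasses.asdict(self.config),
                    }
                )
            ),
        )

    @classmethod
    def load(cls, path) -> "BRBFPosterior":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            return cls(
                centers=z["centers"],
                widths=z["widths"],
                weights=z["weights"],
                noise_var=z["noise_var"],
                x_params=StandardizationParams(z["x_mean"], z["x_sd"]),
                y_params=StandardizationParams(z["y_mean"], z["y_sd"]),
                acceptance=meta["acceptance"],
                config=BRBFConfig(**meta["config"]),
            )


def _design(x: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """RBF design matrix (n, K+1) with the intercept column last."""
    sq = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    phi = np.exp(-sq / (2.0 * widths[None, :] ** 2))
    return np.hstack([phi, np.ones((x.shape[0], 1))])


def _basis_column(x: np.ndarray, center: np.ndarray, width: float) -> np.ndarray:
    sq = ((x - center[None, :]) ** 2).sum(axis=1)
    return np.exp(-sq / (2.0 * width**2))


def fit(X: np.ndarray, y: np.ndarray, config: BRBFConfig | None = None) -> BRBFPosterior:
    """Sample the posterior of the Bayesian RBF regression.

    ``X`` is (n, d) with d in {1, 2} (a 1-D array is treated as one feature);
    ``y`` is (n,).  Requires n >= 10 and finite values throughout.
    Deterministic for a fixed ``config.rng_seed``.
    """
    config = config or BRBFConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if y.size != n:
        raise ValidationError(f"fit: X has {n} rows but y has {y.size}")
    if n < 10:
        raise ValidationError(f"fit: need >= 10 observations, got {n}")
    if d > 2:
        raise ValidationError(f"fit: at most 2 input features supported, got {d}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValidationError("fit: non-finite values in X or y")

    x_params = StandardizationParams.fit(X)
    y_params = StandardizationParams.fit(y[:, None], allow_constant=True)
    xs = standardize(X, x_params)
    ys = standardize(y[:, None], y_params).ravel()

    rng = np.random.default_rng(config.rng_seed)
    K = config.n_basis

    # deterministic initialization: centers at input quantiles, unit widths
    qs = (np.arange(K) + 0.5) / K
    centers = np.quantile(xs, qs, axis=0)
    log_widths = np.full(K, np.log(config.width_location))
    sigma2 = 1.0

    prior_prec = np.full(K + 1, 1.0 / config.weight_scale**2)
    phi = _design(xs, centers, np.exp(log_widths))

    def gibbs_weights(phi, sigma2):
        A = phi.T @ phi / sigma2 + np.diag(prior_prec)
        chol = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, phi.T @ ys / sigma2)
        z = rng.standard_normal(K + 1)
        return mean + np.linalg.solve(chol.T, z)

    weights = gibbs_weights(phi, sigma2)
    resid = ys - phi @ weights
    rss = resid @ resid

    step_c = np.full(K, 0.25)
    step_w = np.full(K, 0.25)
    acc_c = np.zeros(K)
    acc_w = np.zeros(K)
    prop_c = np.zeros(K)
    prop_w = np.zeros(K)
    win_acc_c = np.zeros(K)
    win_acc_w = np.zeros(K)
    win_n = 0

    kept_centers, kept_widths, kept_weights, kept_noise = [], [], [], []

    for it in range(config.mcmc_iterations):
        # --- conjugate noise-variance update
        shape = config.noise_shape + 0.5 * n
        rate = config.noise_rate + 0.5 * rss
        sigma2 = rate / rng.gamma(shape)

        # --- random-walk Metropolis on each center and log-width
        for k in range(K):
            # center k
            prop = centers[k] + step_c[k] * rng.standard_normal(d)
            col = _basis_column(xs, prop, np.exp(log_widths[k]))
            resid_new = resid - (col - phi[:, k]) * weights[k]
            rss_new = resid_new @ resid_new
            logr = (rss - rss_new) / (2.0 * sigma2) + (
                (centers[k] @ centers[k]) - (prop @ prop)
            ) / (2.0 * config.center_scale**2)
            prop_c[k] += 1
            if np.log(rng.random()) < logr:
                centers[k] = prop
                phi[:, k] = col
                resid, rss = resid_new, rss_new
                acc_c[k] += 1
                win_acc_c[k] += 1
            # log-width k
            lw_prop = log_widths[k] + step_w[k] * rng.standard_normal()
            col = _basis_column(xs, centers[k], np.exp(lw_prop))
            resid_new = resid - (col - phi[:, k]) * weights[k]
            rss_new = resid_new @ resid_new
            logr = (rss - rss_new) / (2.0 * sigma2) + (
                (log_widths[k] - np.log(config.width_location)) ** 2
                - (lw_prop - np.log(config.width_location)) ** 2
            ) / (2.0 * config.width_log_scale**2)
            prop_w[k] += 1
            if np.log(rng.random()) < logr:
                log_widths[k] = lw_prop
                phi[:, k] = col
                resid, rss = resid_new, rss_new
                acc_w[k] += 1
                win_acc_w[k] += 1

        # --- conjugate weight update
        weights = gibbs_weights(phi, sigma2)
        resid = ys - phi @ weights
        rss = resid @ resid

        # --- step-size adaptation during burn-in only
        win_n += 1
        if it < config.burn_in and win_n == 50:
            rate_c = win_acc_c / win_n
            rate_w = win_acc_w / win_n
            step_c *= np.where(rate_c > 0.5, 1.25, np.where(rate_c < 0.2, 0.8, 1.0))
            step_w *= np.where(rate_w > 0.5, 1.25, np.where(rate_w < 0.2, 0.8, 1.0))
            win_acc_c[:] = 0
            win_acc_w[:] = 0
            win_n = 0
        elif win_n == 50:
            win_n = 0
            win_acc_c[:] = 0
            win_acc_w[:] = 0

        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            kept_centers.append(centers.copy())
            kept_widths.append(np.exp(log_widths))
            kept_weights.append(weights.copy())
            kept_noise.append(sigma2)

    posterior = BRBFPosterior(
        centers=np.array(kept_centers),
        widths=np.array(kept_widths),
        weights=np.array(kept_weights),
        noise_var=np.array(kept_noise),
        x_params=x_params,
        y_params=y_params,
        acceptance={
            "centers": float(acc_c.sum() / prop_c.sum()),
            "widths": float(acc_w.sum() / prop_w.sum()),
        },
        config=config,
    )
    if posterior.n_samples < 100:
        raise OctbandError(
            f"only {posterior.n_samples} retained samples (< 100); increase "
            "mcmc_iterations or reduce thinning"
        )
    return posterior


def _predictive_draws(posterior: BRBFPosterior, X_new: np.ndarray) -> np.ndarray:
    """Per-sample mean function values (S, m) on the standardized scale."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[:, None]
    if X_new.shape[1] != posterior.n_inputs:
        raise ValidationError(
            f"predict: trained on {posterior.n_inputs} feature(s), "
            f"got {X_new.shape[1]}"
        )
    xs = standardize(X_new, posterior.x_params)
    out = np.empty((posterior.n_samples, xs.shape[0]))
    for s in range(posterior.n_samples):
        phi = _design(xs, posterior.centers[s], posterior.widths[s])
        out[s] = phi @ posterior.weights[s]
    return out


def predict_mean(posterior: BRBFPosterior, X_new: np.ndarray) -> np.ndarray:
    """Posterior-predictive mean on the original target scale, one per row."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.size == 0:
        return np.empty(0)
    fs = _predictive_draws(posterior, X_new).mean(axis=0)
    return destandardize(fs[:, None], posterior.y_params).ravel()


def predict_interval(
    posterior: BRBFPosterior,
    X_new: np.ndarray,
    coverage: float = 0.90,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Central posterior-predictive interval (noise included) per row."""
    if not 0 < coverage < 1:
        raise ValidationError(f"coverage: {coverage} outside (0, 1)")
    fs = _predictive_draws(posterior, X_new)
    rng = np.random.default_rng(rng_seed)
    draws = fs + np.sqrt(posterior.noise_var)[:, None] * rng.standard_normal(fs.shape)
    lo_q, hi_q = (1 - coverage) / 2, 1 - (1 - coverage) / 2
    lo = np.quantile(draws, lo_q, axis=0)
    hi = np.quantile(draws, hi_q, axis=0)
    yp = posterior.y_params
    return (
        destandardize(lo[:, None], yp).ravel(),
        destandardize(hi[:, None], yp).ravel(),
    )
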