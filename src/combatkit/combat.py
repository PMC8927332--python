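"""Empirical-Bayes ComBat harmonization of a feature matrix by one batch effect.

The model, per feature g and sample j in batch i, is

    Y_ijg = alpha_g + X_j beta_g + gamma_ig + delta_ig * eps_ijg

where ``alpha_g`` is the grand intercept, ``X`` holds protected covariates,
``gamma_ig`` is the additive (location) batch effect, ``delta_ig`` the
multiplicative (scale) batch effect and ``eps_ijg ~ N(0, sigma_g^2)``.
Fitting proceeds in three steps:

1. feature-wise least squares of Y on batch indicators plus covariates under
   the identifiability constraint ``sum_i n_i * gamma_hat_ig = 0``;
2. standardization ``Z = (Y - alpha_hat - X beta_hat) / sigma_hat`` with
   ``sigma_hat^2`` the mean squared residual over all samples;
3. parametric empirical-Bayes shrinkage of the per-batch location and scale
   estimates toward batch-level priors (normal prior on location,
   inverse-gamma prior on squared scale), with hyperparameters estimated by
   the method of moments across features and the conditional posterior means
   iterated to convergence.

The adjusted data restore the covariate contribution and remove the batch
contribution:

    Y*_ijg = sigma_hat_g / delta*_ig * (Z_ijg - gamma*_ig) + alpha_hat_g + X_j beta_hat_g
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    check_design_rank,
    encode_covariates,
    validate_batch,
    validate_covariates,
    validate_feature_matrix,
)

__all__ = ["ComBat", "ComBatResults", "harmonize"]

logger = logging.getLogger(__name__)


def _eb_fit_one_batch(
    z_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta2_hat: np.ndarray,
    gamma_bar: float,
    t2: float,
    a_prior: float,
    b_prior: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterate the conditional posterior means for one batch.

    ``z_batch`` is (n_i, G) standardized data; returns (gamma_star,
    delta2_star, iterations). Follows the parametric EB solver of the
    original genomics formulation: the location posterior mean is a
    precision-weighted blend of the observed batch mean and the prior mean,
    and the scale posterior mean is the inverse-gamma mean given the current
    location estimate.
    """
    n_i = z_batch.shape[0]
    gamma_old = gamma_hat.copy()
    delta2_old = delta2_hat.copy()
    for iteration in range(1, max_iter + 1):
        gamma_new = (t2 * n_i * gamma_hat + delta2_old * gamma_bar) / (t2 * n_i + delta2_old)
        sum2 = ((z_batch - gamma_new[None, :]) ** 2).sum(axis=0)
        delta2_new = (0.5 * sum2 + b_prior) / (n_i / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(gamma_new - gamma_old) / np.abs(gamma_old)),
            np.max(np.abs(delta2_new - delta2_old) / np.abs(delta2_old)),
        )
        gamma_old, delta2_old = gamma_new, delta2_new
        if change < tol:
            return gamma_new, delta2_new, iteration
    raise RuntimeError(
        f"empirical-Bayes iteration did not converge within {max_iter} iterations"
    )


@dataclass
class ComBatResults:
    """Fitted ComBat parameters plus the ``transform`` adjustment step.

    Location/scale tables are indexed by batch level (rows) and feature name
    (columns). ``gamma_hat``/``delta2_hat`` are the raw per-batch estimates on
    standardized data; ``gamma_star``/``delta2_star`` the EB-shrunk values
    actually used for adjustment (equal to the raw ones when ``eb=False``).
    """

    model: "ComBat"
    alpha: pd.Series
    beta: pd.DataFrame
    sigma2: pd.Series
    gamma_hat: pd.DataFrame
    gamma_star: pd.DataFrame
    delta2_hat: pd.DataFrame
    delta2_star: pd.DataFrame
    hyper: pd.DataFrame
    batch_levels: list[str]
    n_per_level: pd.Series
    eb: bool
    converged: bool
    n_iterations: int
    constant_features: list[str] = field(default_factory=list)

    def transform(
        self,
        features: pd.DataFrame | None = None,
        batch: pd.Series | None = None,
        covariates: pd.DataFrame | None = None,
    ) -> pd.DataFrame:
        """Apply the fitted adjustment; defaults to the training data.

        New data must carry the same feature set and only batch levels seen
        during fitting; if the model protected covariates, covariate values
        for the new samples are required.
        """
        model = self.model
        if features is None:
            features = model.features
            batch = model.batch
            covariates = model.covariates
        else:
            if batch is None:
                raise ValueError("batch labels are required when transforming new data")
            features = validate_feature_matrix(features, min_samples=1)
            if list(features.columns) != list(model.features.columns):
                raise ValueError("feature set differs from the one the model was fitted on")
            batch = batch.astype(str)
            unseen = sorted(set(batch) - set(self.batch_levels))
            if unseen:
                raise ValueError(f"unseen batch level(s) {unseen}; the model cannot adjust them")
            if model.covariates is not None:
                if covariates is None:
                    raise ValueError(
                        "the model was fitted with protected covariates; supply covariate "
                        "values for the new samples"
                    )
                covariates = validate_covariates(covariates, features.index)

        used = [c for c in features.columns if c not in self.constant_features]
        y = features[used].to_numpy(dtype=np.float64)
        x_cov, cov_names = encode_covariates(covariates)
        if cov_names != list(self.beta.index):
            raise ValueError(
                f"covariate encoding {cov_names} does not match the fitted design "
                f"{list(self.beta.index)} (check categorical levels)"
            )
        beta = self.beta[used].to_numpy() if self.beta.shape[0] else np.empty((0, len(used)))
        cov_part = x_cov @ beta if beta.shape[0] else 0.0
        stand_mean = self.alpha[used].to_numpy()[None, :] + cov_part
        sigma = np.sqrt(self.sigma2[used].to_numpy())
        z = (y - stand_mean) / sigma[None, :]

        codes = pd.Categorical(batch, categories=self.batch_levels).codes
        gamma = self.gamma_star[used].to_numpy()[codes]
        delta = np.sqrt(self.delta2_star[used].to_numpy())[codes]
        adjusted = sigma[None, :] * (z - gamma) / delta + stand_mean

        out = features.copy()
        out[used] = adjusted
        return out

    def summary(self) -> str:
        """Plain-text summary of the fit, per batch level."""
        lines = [
            "ComBat harmonization results",
            "=" * 60,
            f"samples: {len(self.model.features)}   features: {self.model.features.shape[1]}"
            f"   batch effect: {self.model.batch.name!r}",
            f"empirical Bayes: {self.eb}   converged: {self.converged}"
            f"   iterations: {self.n_iterations}",
        ]
        if self.constant_features:
            lines.append(f"constant features passed through: {self.constant_features}")
        lines.append("-" * 60)
        for level in self.batch_levels:
            g = self.gamma_star.loc[level]
            d = self.delta2_star.loc[level]
            lines.append(
                f"level {level!r} (n={int(self.n_per_level[level])}): "
                f"mean gamma* = {g.mean():+.4f}, mean delta2* = {d.mean():.4f}"
            )
            if self.eb:
                h = self.hyper.loc[level]
                lines.append(
                    f"    prior: gamma_bar = {h['gamma_bar']:+.4f}, tau2 = {h['tau2']:.4f}, "
                    f"a = {h['a_prior']:.3f}, b = {h['b_prior']:.3f}"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable parameter dump (for run manifests)."""
        return {
            "batch_effect": str(self.model.batch.name),
            "batch_levels": self.batch_levels,
            "n_per_level": {k: int(v) for k, v in self.n_per_level.items()},
            "eb": self.eb,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "alpha": self.alpha.to_dict(),
            "sigma2": self.sigma2.to_dict(),
            "gamma_star": {lvl: self.gamma_star.loc[lvl].to_dict() for lvl in self.batch_levels},
            "delta2_star": {lvl: self.delta2_star.loc[lvl].to_dict() for lvl in self.batch_levels},
            "hyper": self.hyper.to_dict(orient="index") if self.eb else {},
            "constant_features": self.constant_features,
        }


class ComBat:
    """Location/scale batch-effect model for a feature matrix.

    Parameters
    ----------
    features : DataFrame, samples x features, finite floats.
    batch : Series of categorical labels aligned to ``features.index``; its
        ``name`` identifies the batch effect.
    covariates : optional DataFrame of clinical covariates to protect.
        Categorical columns are reference-coded against the alphabetically
        first level; numeric columns enter as-is.

    Examples
    --------
    >>> result = ComBat(features, metadata["manufacturer"],
    ...                 covariates=metadata[["histology"]]).fit()
    >>> harmonized = result.transform()
    """

    def __init__(
        self,
        features: pd.DataFrame,
        batch: pd.Series,
        covariates: pd.DataFrame | None = None,
    ) -> None:
        self.features = validate_feature_matrix(features)
        self.batch = validate_batch(batch, self.features.index)
        self.covariates = validate_covariates(covariates, self.features.index)
        if self.covariates is not None and self.batch.name in self.covariates.columns:
            raise ValueError(
                f"batch effect {self.batch.name!r} also appears among the covariates"
            )

    @classmethod
    def from_metadata(
        cls,
        features: pd.DataFrame,
        metadata: pd.DataFrame,
        batch_col: str,
        covar_cols: list[str] | None = None,
    ) -> "ComBat":
        """Build the model from a metadata table by column name."""
        if batch_col not in metadata.columns:
            raise KeyError(f"batch column {batch_col!r} not found in metadata")
        missing = [c for c in (covar_cols or []) if c not in metadata.columns]
        if missing:
            raise KeyError(f"covariate column(s) {missing} not found in metadata")
        covariates = metadata[list(covar_cols)] if covar_cols else None
        return cls(features, metadata[batch_col], covariates)

    def fit(self, eb: bool = True, tol: float = 1e-4, max_iter: int = 1000) -> ComBatResults:
        """Estimate the model; returns a :class:`ComBatResults`.

        ``eb=False`` skips the shrinkage step (gamma* = gamma_hat,
        delta2* = delta2_hat), useful for very small feature sets.
        """
        features = self.features
        arr = features.to_numpy()
        spans = arr.max(axis=0) - arr.min(axis=0)  # exact-zero span = constant
        constant = [c for c, s in zip(features.columns, spans) if s == 0.0]
        if constant:
            logger.warning(
                "feature(s) %s have zero variance; passed through unharmonized", constant
            )
        used = [c for c in features.columns if c not in constant]
        if not used:
            raise ValueError("all features have zero variance; nothing to harmonize")
        if eb and len(used) < 2:
            raise ValueError(
                "empirical-Bayes hyperpriors need at least two non-constant features; "
                "refit with eb=False"
            )

        y = features[used].to_numpy(dtype=np.float64)
        n, n_feat = y.shape
        levels = sorted(self.batch.unique())
        codes = pd.Categorical(self.batch, categories=levels).codes
        n_levels = len(levels)
        batch_design = np.eye(n_levels)[codes]
        n_per_level = batch_design.sum(axis=0)

        x_cov, cov_names = encode_covariates(self.covariates)
        design = np.hstack([batch_design, x_cov]) if cov_names else batch_design
        check_design_rank(design, [f"batch[{lv}]" for lv in levels] + cov_names)

        # feature-wise least squares; batch one-hot encoding means the grand
        # intercept is the sample-size-weighted mean of the level intercepts,
        # which enforces sum_i n_i * gamma_hat_i = 0
        b_hat, *_ = np.linalg.lstsq(design, y, rcond=None)
        grand_mean = (n_per_level / n) @ b_hat[:n_levels]
        resid = y - design @ b_hat
        var_pooled = (resid**2).mean(axis=0)
        if np.any(var_pooled == 0):
            bad = [used[i] for i in np.flatnonzero(var_pooled == 0)]
            raise ValueError(f"feature(s) {bad} are perfectly explained by the design")

        beta = b_hat[n_levels:]
        cov_part = x_cov @ beta if cov_names else 0.0
        stand_mean = grand_mean[None, :] + cov_part
        sigma = np.sqrt(var_pooled)
        z = (y - stand_mean) / sigma[None, :]

        gamma_hat = np.empty((n_levels, n_feat))
        delta2_hat = np.empty((n_levels, n_feat))
        for i in range(n_levels):
            zi = z[codes == i]
            gamma_hat[i] = zi.mean(axis=0)
            delta2_hat[i] = zi.var(axis=0, ddof=1)

        hyper_rows = []
        if eb:
            gamma_star = np.empty_like(gamma_hat)
            delta2_star = np.empty_like(delta2_hat)
            total_iter = 0
            for i in range(n_levels):
                gamma_bar = gamma_hat[i].mean()
                tau2 = gamma_hat[i].var(ddof=1)
                m = delta2_hat[i].mean()
                s2 = delta2_hat[i].var(ddof=1)
                a_prior = (2.0 * s2 + m**2) / s2
                b_prior = (m * s2 + m**3) / s2
                gamma_star[i], delta2_star[i], iters = _eb_fit_one_batch(
                    z[codes == i], gamma_hat[i], delta2_hat[i],
                    gamma_bar, tau2, a_prior, b_prior, tol, max_iter,
                )
                total_iter = max(total_iter, iters)
                hyper_rows.append(
                    {"gamma_bar": gamma_bar, "tau2": tau2, "a_prior": a_prior, "b_prior": b_prior}
                )
            converged = True
            n_iterations = total_iter
        else:
            if np.any(delta2_hat == 0):
                i, j = np.argwhere(delta2_hat == 0)[0]
                raise ValueError(
                    f"feature {used[j]!r} is constant within batch level {levels[i]!r}; "
                    "scale cannot be estimated without empirical Bayes"
                )
            gamma_star, delta2_star = gamma_hat.copy(), delta2_hat.copy()
            converged, n_iterations = True, 0

        idx = pd.Index(levels, name=str(self.batch.name))
        return ComBatResults(
            model=self,
            alpha=pd.Series(grand_mean, index=used, name="alpha"),
            beta=pd.DataFrame(beta, index=cov_names, columns=used),
            sigma2=pd.Series(var_pooled, index=used, name="sigma2"),
            gamma_hat=pd.DataFrame(gamma_hat, index=idx, columns=used),
            gamma_star=pd.DataFrame(gamma_star, index=idx, columns=used),
            delta2_hat=pd.DataFrame(delta2_hat, index=idx, columns=used),
            delta2_star=pd.DataFrame(delta2_star, index=idx, columns=used),
            hyper=pd.DataFrame(hyper_rows, index=idx) if hyper_rows else pd.DataFrame(index=idx),
            batch_levels=levels,
            n_per_level=pd.Series(n_per_level.astype(int), index=idx),
            eb=eb,
            converged=converged,
            n_iterations=n_iterations,
            constant_features=constant,
        )


def harmonize(
    features: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    eb: bool = True,
) -> pd.DataFrame:
    """Fit ComBat and adjust the same data in one call."""
    return ComBat(features, batch, covariates).fit(eb=eb).transform()
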