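"""Linear discriminant analysis with equal priors and posterior thresholds.

The model is the classical equal-covariance Gaussian discriminant: class
means are estimated per variable, a pooled within-class covariance (with
denominator N - K) is shared across classes, and priors are equal by
construction — an unknown seized sample carries no prior information about
which isomer it is.  Posterior probabilities follow from Bayes' rule; a
likelihood ratio is reported as highest / second-highest posterior, flagged
indicative only since no calibration is performed.

Variables whose pooled within-class variance falls below a tolerance
(default 1.0e-8) are removed before fitting and recorded on the model.
Beyond that per-variable guard, the pooled covariance is *structurally*
singular whenever ion-current normalisation is used (each voltage segment
sums to one, a hard linear constraint) or a variable is duplicated.  Null
within-class directions along which the class means do not differ are
projected out with a collinearity warning — the same behaviour as the
classical R implementation of LDA — and the coefficient mass is shared
among the collinear variables.  A null direction along which the means
*do* differ (infinite apparent separation) raises an explicit error
suggesting a smaller variable set, e.g. a higher percent-abundance
threshold, rather than silently regularising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import Conclusion, threshold_conclusion

logger = logging.getLogger(__name__)

DEFAULT_VARIANCE_TOLERANCE = 1.0e-8


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled within-class covariance is numerically singular."""


@dataclass
class LdaModel:
    classes: tuple[str, ...]
    variables: tuple[str, ...]
    means: np.ndarray                 # K x p
    pooled_cov: np.ndarray            # p x p
    priors: np.ndarray                # equal, sums to 1
    scalings: np.ndarray              # p x (K-1) discriminant-axis coefficients
    dropped_variables: tuple[str, ...]
    _cov_inv_means: np.ndarray = field(repr=False, default=None)  # K x p
    _const: np.ndarray = field(repr=False, default=None)          # K


@dataclass
class PosteriorResult:
    sample_id: str
    posteriors: dict[str, float]
    likelihood_ratio: float           # top / second posterior; indicative only


def fit_lda(
    values: pd.DataFrame,
    labels: pd.Series | Sequence[str],
    tolerance: float = DEFAULT_VARIANCE_TOLERANCE,
) -> LdaModel:
    """Fit the equal-prior, equal-covariance Gaussian discriminant.

    Raises :class:`SingularCovarianceError` when the pooled covariance is
    not positive definite after the per-variable variance guard.
    """
    y = pd.Series(np.asarray(labels), index=values.index)
    classes = tuple(sorted(y.unique()))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    sizes = y.value_counts()
    if (sizes < 2).any():
        raise ValueError(f"every class needs >= 2 samples, got {sizes.to_dict()}")

    X = values.to_numpy(dtype=float)
    n, p = X.shape
    K = len(classes)
    codes = np.array([classes.index(c) for c in y])
    means = np.vstack([X[codes == k].mean(axis=0) for k in range(K)])
    centered = X - means[codes]
    pooled_var = (centered**2).sum(axis=0) / (n - K)
    low = pooled_var < tolerance
    dropped = tuple(np.asarray(values.columns)[low])
    for name in dropped:
        logger.warning(
            "variable %s has within-class variance below %.1e; removed", name, tolerance
        )
    keep = ~low
    if not keep.any():
        raise ValueError("all variables removed by the variance guard")
    X, means, centered = X[:, keep], means[:, keep], centered[:, keep]
    variables = tuple(np.asarray(values.columns)[keep])
    p = X.shape[1]

    Sw = centered.T @ centered / (n - K)
    grand = X.mean(axis=0)
    counts = np.array([(codes == k).sum() for k in range(K)])
    dev = means - grand

    # structural singularity guard: project out within-class null directions
    lam, U = np.linalg.eigh(Sw)
    null = lam < max(lam[-1], tolerance) * 1e-10
    if null.any():
        # safe only when the class means do not separate along a null
        # direction (true for normalisation constraints and duplicates)
        mean_component = np.abs(dev @ U[:, null]).max() if dev.size else 0.0
        scale = np.abs(dev).max() + 1e-30
        if mean_component > 1e-8 * scale:
            raise SingularCovarianceError(
                "class means differ along a direction with no within-class "
                "variance; consider a smaller variable set, e.g. a higher "
                "percent-abundance threshold"
            )
        logger.warning(
            "pooled covariance is collinear in %d direction(s); projected out",
            int(null.sum()),
        )
    U = U[:, ~null]
    lam = lam[~null]
    if U.shape[1] == 0:
        raise SingularCovarianceError(
            "no non-degenerate within-class direction left; consider a "
            "smaller variable set"
        )

    # work in the whitened non-degenerate subspace: Z = X U diag(1/sqrt(lam))
    W = U / np.sqrt(lam)                       # p x r, whitening map
    means_z = means @ W                        # K x r
    dev_z = dev @ W
    Sb_z = (dev_z.T * counts) @ dev_z / (K - 1)
    wvals, wvecs = np.linalg.eigh(Sb_z)
    order = np.argsort(wvals)[::-1][: min(K - 1, U.shape[1])]
    scalings = W @ wvecs[:, order]             # back on the original variables

    priors = np.full(K, 1.0 / K)
    cov_inv_means = (W @ means_z.T).T          # K x p, = pinv(Sw) @ means
    const = -0.5 * (means_z**2).sum(axis=1) + np.log(priors)
    return LdaModel(
        classes=classes, variables=variables, means=means, pooled_cov=Sw,
        priors=priors, scalings=scalings, dropped_variables=dropped,
        _cov_inv_means=cov_inv_means, _const=const,
    )


def _check_variables(model: LdaModel, values: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in model.variables if c not in values.columns]
    if missing:
        raise KeyError(f"sample is missing model variables: {missing}")
    return values[list(model.variables)]


def posterior_table(model: LdaModel, values: pd.DataFrame) -> pd.DataFrame:
    """Posterior probability per class for each row; rows sum to 1."""
    X = _check_variables(model, values).to_numpy(dtype=float)
    scores = X @ model._cov_inv_means.T + model._const   # n x K
    scores -= scores.max(axis=1, keepdims=True)
    post = np.exp(scores)
    post /= post.sum(axis=1, keepdims=True)
    return pd.DataFrame(post, index=values.index, columns=list(model.classes))


def posterior(model: LdaModel, sample: pd.Series | Mapping[str, float]) -> PosteriorResult:
    """Posterior for a single sample plus the top-two likelihood ratio."""
    row = pd.DataFrame([pd.Series(sample)])
    table = posterior_table(model, row)
    posts = table.iloc[0].to_dict()
    ranked = sorted(posts.values(), reverse=True)
    lr = float(np.inf) if ranked[1] == 0 else ranked[0] / ranked[1]
    sample_id = str(getattr(sample, "name", "") or "")
    return PosteriorResult(sample_id=sample_id, posteriors=posts, likelihood_ratio=lr)


def project(model: LdaModel, values: pd.DataFrame) -> pd.DataFrame:
    """Discriminant scores (projections onto the discriminant axes)."""
    X = _check_variables(model, values).to_numpy(dtype=float)
    Z = (X - model.means.mean(axis=0)) @ model.scalings
    cols = [f"LD{i + 1}" for i in range(Z.shape[1])]
    return pd.DataFrame(Z, index=values.index, columns=cols)


def scaling_influence(model: LdaModel) -> pd.DataFrame:
    """Absolute scaling coefficients per discriminant axis, ranked.

    A large absolute coefficient means the variable strongly drives the
    projection onto that axis.
    """
    cols = [f"LD{i + 1}" for i in range(model.scalings.shape[1])]
    out = pd.DataFrame(np.abs(model.scalings), index=list(model.variables), columns=cols)
    for c in cols:
        out[f"rank_{c}"] = out[c].rank(ascending=False, method="min").astype(int)
    out.index.name = "variable"
    return out.sort_values(cols[0], ascending=False)


def classify(
    model: LdaModel, values: pd.DataFrame, threshold: float = 0.5
) -> list[Conclusion]:
    """Threshold conclusions from posterior probabilities."""
    table = posterior_table(model, values)
    return [
        threshold_conclusion(row.to_dict(), threshold, id=str(idx))
        for idx, row in table.iterrows()
    ]
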