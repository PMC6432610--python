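"""Two-class Bayesian linear discriminant for wake/sleep epochs.

The model assumes Gaussian class-conditional densities with a shared
(pooled) covariance, which yields a linear decision boundary.  Following
the Bayes rule for minimal probability of error, an epoch is assigned to
the class with the larger posterior probability.  Wake is the positive
class and the class priors are *equalized* at (0.5, 0.5) regardless of the
empirical wake prevalence, so the classifier is not biased toward the
majority (sleep) class.

For a feature vector x the wake posterior has the closed logistic form

    P(wake | x) = sigmoid(w . x + b + log(pi_w / pi_s)),
    w = Sigma^-1 (mu_w - mu_s),
    b = -1/2 (mu_w + mu_s)^T Sigma^-1 (mu_w - mu_s).

The API follows the model/results idiom: construct :class:`BayesianLDA`
from data, call :meth:`~BayesianLDA.fit` to obtain :class:`LDAResults`
which carries the estimates and exposes prediction and a summary table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .exceptions import InvalidInputError, UnderdeterminedModelError

__all__ = ["LDAModel", "LDAResults", "BayesianLDA", "fit_lda", "posterior_wake", "predict"]

WAKE, SLEEP = "wake", "sleep"


@dataclass
class LDAModel:
    """Fitted parameters: class means, pooled covariance, priors."""

    mu_wake: np.ndarray
    mu_sleep: np.ndarray
    sigma_pooled: np.ndarray
    priors: tuple[float, float] = (0.5, 0.5)
    feature_names: tuple[str, ...] = ()
    ridge_applied: float = 0.0
    normalization: str = "min-max per recording"

    def __post_init__(self) -> None:
        self.mu_wake = np.asarray(self.mu_wake, dtype=float)
        self.mu_sleep = np.asarray(self.mu_sleep, dtype=float)
        self.sigma_pooled = np.asarray(self.sigma_pooled, dtype=float)
        pw, ps = self.priors
        if not (pw > 0 and ps > 0 and abs(pw + ps - 1.0) < 1e-9):
            raise InvalidInputError("priors must be positive and sum to 1")

    @property
    def n_features(self) -> int:
        return len(self.mu_wake)

    def coefficients(self) -> tuple[np.ndarray, float]:
        """Return (w, b) of the linear discriminant logit w.x + b
        (including the log prior ratio)."""
        diff = self.mu_wake - self.mu_sleep
        w = np.linalg.solve(self.sigma_pooled, diff)
        b = -0.5 * float((self.mu_wake + self.mu_sleep) @ w)
        b += float(np.log(self.priors[0] / self.priors[1]))
        return w, b

    # -- plain-text serialization ------------------------------------
    def to_text(self) -> str:
        payload = {
            "model": "bayesian-lda",
            "feature_names": list(self.feature_names),
            "mu_wake": self.mu_wake.tolist(),
            "mu_sleep": self.mu_sleep.tolist(),
            "sigma_pooled": self.sigma_pooled.tolist(),
            "priors": {"wake": float(self.priors[0]), "sleep": float(self.priors[1])},
            "ridge_applied": float(self.ridge_applied),
            "normalization": self.normalization,
        }
        return yaml.safe_dump(payload, sort_keys=False)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "LDAModel":
        d = yaml.safe_load(text)
        return cls(
            mu_wake=np.array(d["mu_wake"]),
            mu_sleep=np.array(d["mu_sleep"]),
            sigma_pooled=np.array(d["sigma_pooled"]),
            priors=(d["priors"]["wake"], d["priors"]["sleep"]),
            feature_names=tuple(d.get("feature_names", ())),
            ridge_applied=float(d.get("ridge_applied", 0.0)),
            normalization=d.get("normalization", ""),
        )

    @classmethod
    def load(cls, path) -> "LDAModel":
        with open(path) as fh:
            return cls.from_text(fh.read())


def fit_lda(features: np.ndarray, binary_labels, ridge_fraction: float = 1e-6,
            feature_names: tuple[str, ...] = ()) -> LDAModel:
    """Estimate class means and the pooled covariance.

    ``binary_labels`` holds 'wake'/'sleep' strings (epochs labelled
    unable-to-score must already be excluded).  The pooled covariance is
    the bias-corrected within-class average; if it is singular or badly
    conditioned a ridge of ``ridge_fraction * trace / dim`` is added to the
    diagonal.  Priors are fixed at (0.5, 0.5).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise InvalidInputError("non-finite feature values")
    y = np.asarray(binary_labels)
    if len(y) != len(X):
        raise InvalidInputError("features and labels differ in length")
    is_wake = y == WAKE
    is_sleep = y == SLEEP
    if not (is_wake | is_sleep).all():
        raise InvalidInputError("labels must be 'wake' or 'sleep'")
    n_w, n_s = int(is_wake.sum()), int(is_sleep.sum())
    if n_w < 2 or n_s < 2:
        raise UnderdeterminedModelError(
            f"need >= 2 epochs per class, got wake={n_w}, sleep={n_s}"
        )
    Xw, Xs = X[is_wake], X[is_sleep]
    mu_w, mu_s = Xw.mean(axis=0), Xs.mean(axis=0)
    Sw = np.cov(Xw, rowvar=False).reshape(X.shape[1], X.shape[1])
    Ss = np.cov(Xs, rowvar=False).reshape(X.shape[1], X.shape[1])
    sigma = ((n_w - 1) * Sw + (n_s - 1) * Ss) / (n_w + n_s - 2)

    ridge = 0.0
    eigvals = np.linalg.eigvalsh(sigma)
    cond = eigvals[-1] / eigvals[0] if eigvals[0] > 0 else np.inf
    if eigvals[0] <= 0 or cond > 1e8:
        ridge = ridge_fraction * np.trace(sigma) / sigma.shape[0]
        if ridge <= 0:  # all-zero covariance: fall back to an absolute floor
            ridge = ridge_fraction
        sigma = sigma + ridge * np.eye(sigma.shape[0])

    return LDAModel(
        mu_wake=mu_w,
        mu_sleep=mu_s,
        sigma_pooled=sigma,
        priors=(0.5, 0.5),
        feature_names=tuple(feature_names) or tuple(f"x{i}" for i in range(X.shape[1])),
        ridge_applied=ridge,
    )


def posterior_wake(model: LDAModel, x: np.ndarray) -> np.ndarray | float:
    """P(wake | x) from the Gaussian class-conditionals, in log space."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    X = x[None, :] if scalar else x
    if X.shape[-1] != model.n_features:
        raise InvalidInputError(
            f"expected {model.n_features} features, got {X.shape[-1]}"
        )
    w, b = model.coefficients()
    p = expit(X @ w + b)
    return float(p[0]) if scalar else p


def predict(model: LDAModel, x: np.ndarray, threshold: float = 0.5):
    """Classify as wake iff the wake posterior >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise InvalidInputError("threshold must lie in (0, 1)")
    p = posterior_wake(model, x)
    if np.isscalar(p):
        return WAKE if p >= threshold else SLEEP
    return np.where(p >= threshold, WAKE, SLEEP)


class BayesianLDA:
    """Wake/sleep linear discriminant model, constructed from data.

    Parameters
    ----------
    features : array-like, shape (n_epochs, n_features)
        Normalized per-epoch feature vectors.
    labels : array-like of {'wake', 'sleep'}
        Binary epoch labels; unable-to-score epochs must be excluded.
    feature_names : sequence of str, optional

    Examples
    --------
    >>> model = BayesianLDA(X, y, feature_names=("mact_norm", "pslp_norm"))
    >>> res = model.fit()
    >>> res.predict_proba(X[:5])
    """

    def __init__(self, features, labels, feature_names: tuple[str, ...] = ()):
        self.features = np.asarray(features, dtype=float)
        if self.features.ndim == 1:
            self.features = self.features[:, None]
        self.labels = np.asarray(labels)
        self.feature_names = tuple(feature_names) or tuple(
            f"x{i}" for i in range(self.features.shape[1])
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, feature_columns, label_column: str = "label"):
        feature_columns = list(feature_columns)
        return cls(
            df[feature_columns].to_numpy(),
            df[label_column].to_numpy(),
            feature_names=tuple(feature_columns),
        )

    def fit(self, ridge_fraction: float = 1e-6) -> "LDAResults":
        params = fit_lda(
            self.features, self.labels, ridge_fraction=ridge_fraction,
            feature_names=self.feature_names,
        )
        return LDAResults(self, params)


class LDAResults:
    """Fitted discriminant: parameter estimates, prediction, summary."""

    def __init__(self, model: BayesianLDA, params: LDAModel):
        self.model = model
        self.params = params

    def predict_proba(self, x) -> np.ndarray | float:
        """Wake posterior probability for one vector or a batch."""
        return posterior_wake(self.params, x)

    def predict(self, x, threshold: float = 0.5):
        return predict(self.params, x, threshold=threshold)

    def save(self, path) -> None:
        self.params.save(path)

    def summary(self) -> str:
        p = self.params
        w, b = p.coefficients()
        buf = io.StringIO()
        buf.write("Bayesian linear discriminant (wake vs sleep)\n")
        buf.write("=" * 44 + "\n")
        tbl = pd.DataFrame(
            {
                "mu_wake": p.mu_wake,
                "mu_sleep": p.mu_sleep,
                "discriminant_w": w,
            },
            index=list(p.feature_names),
        )
        buf.write(tbl.to_string(float_format=lambda v: f"{v: .4f}") + "\n")
        buf.write(f"intercept b (incl. prior ratio): {b: .4f}\n")
        buf.write(f"priors (wake, sleep): {p.priors}\n")
        buf.write(f"pooled covariance:\n{np.array2string(p.sigma_pooled, precision=5)}\n")
        if p.ridge_applied > 0:
            buf.write(f"ridge applied to covariance diagonal: {p.ridge_applied:.3e}\n")
        return buf.getvalue()
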