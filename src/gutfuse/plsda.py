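"""From-scratch PLS-DA: NIPALS fitting, posterior calibration, LOOCV, ranking.

The classifier regresses an encoded class vector (IBS -> +1, HLT -> -1) on
autoscaled features via univariate-response NIPALS partial least squares,
then calibrates the continuous prediction y_hat into a posterior
probability of IBS with class-conditional Gaussians and Bayes' rule
(a two-Gaussian reconstruction of the study's Bayesian classification
step).  Feature ranking by first-component |weight| yields the
discriminating variables consumed by the patient discrimination index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import FeatureTable, SampleMeta

_SD_FLOOR = 1e-12
_ENCODING = {"IBS": 1.0, "HLT": -1.0}


@dataclass
class ScalingParams:
    """Per-feature mean and standard deviation (sample sd, floored at 1e-12)."""

    mean: np.ndarray
    sd: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def autoscale(X: np.ndarray) -> tuple[np.ndarray, ScalingParams]:
    """Mean-center and scale each feature to unit sample variance.

    Constant features are scaled by the sd floor (result 0), not dropped.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("autoscaling needs at least 2 samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.maximum(sd, _SD_FLOOR)
    params = ScalingParams(mean, sd)
    return params.apply(X), params


def _nipals_pls1(X, y, n_components, tol=1e-10, max_iter=500):
    """Univariate-response NIPALS with X and y deflation per component.

    Convergence: successive weight estimates differ by < tol in norm.
    Per-component sign is fixed by forcing the largest-magnitude weight
    entry positive (NIPALS sign ambiguity).
    """
    Xd = np.array(X, dtype=float)
    yd = np.array(y, dtype=float)
    n, p = Xd.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    c = np.zeros(n_components)
    for a in range(n_components):
        u = yd.copy()
        w = None
        for _ in range(max_iter):
            w_new = Xd.T @ u
            nrm = np.linalg.norm(w_new)
            if nrm < 1e-14:
                raise np.linalg.LinAlgError(
                    f"X is exhausted after {a} components; reduce n_components"
                )
            w_new = w_new / nrm
            if w is not None and np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
            t = Xd @ w
            q = (yd @ t) / (t @ t)
            if q == 0.0:
                break
            u = yd / q
        t = Xd @ w
        tt = t @ t
        q = (yd @ t) / tt
        p_load = Xd.T @ t / tt
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w, t, q, p_load = -w, -t, -q, -p_load
        W[:, a], T[:, a], c[a], P[:, a] = w, t, q, p_load
        Xd -= np.outer(t, p_load)
        yd = yd - q * t
    return W, P, T, c


@dataclass
class PosteriorCalibration:
    """Class-conditional Gaussians on y_hat plus a prior probability of IBS."""

    mu_ibs: float
    sd_ibs: float
    mu_hlt: float
    sd_hlt: float
    prior_ibs: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.prior_ibs < 1.0):
            raise ValueError("prior_ibs must be in (0, 1)")
        if self.sd_ibs <= 0 or self.sd_hlt <= 0:
            raise ValueError("calibration sds must be > 0")

    def p_ibs(self, yhat: np.ndarray) -> np.ndarray:
        yhat = np.asarray(yhat, dtype=float)
        log_odds = (
            np.log(self.prior_ibs) - np.log1p(-self.prior_ibs)
            + norm.logpdf(yhat, self.mu_ibs, self.sd_ibs)
            - norm.logpdf(yhat, self.mu_hlt, self.sd_hlt)
        )
        return expit(log_odds)


def calibrate_posterior(
    train_scores: np.ndarray, train_groups, prior_ibs: float = 0.5
) -> PosteriorCalibration:
    """Fit one-dimensional class-conditional normals to the training y_hat."""
    scores = np.asarray(train_scores, dtype=float)
    groups = np.asarray(train_groups)
    stats = {}
    for g in ("IBS", "HLT"):
        s = scores[groups == g]
        if s.size == 0:
            raise ValueError(f"no training samples in group {g}")
        sd = s.std(ddof=1) if s.size > 1 else 0.0
        if sd < _SD_FLOOR:
            warnings.warn(
                f"degenerate within-group variance for {g}; flooring sd at {_SD_FLOOR}"
            )
            sd = _SD_FLOOR
        stats[g] = (float(s.mean()), float(sd))
    return PosteriorCalibration(
        stats["IBS"][0], stats["IBS"][1], stats["HLT"][0], stats["HLT"][1], prior_ibs
    )


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """Two-class PLS-DA with NIPALS latent components and Bayes calibration.

    Parameters
    ----------
    n_components : number of latent components (default 2, matching the
        two-dimensional T vs T_orthogonal ordination view of the model).
    prior_ibs : prior probability of the IBS class used by the posterior
        calibration.
    tol, max_iter : NIPALS convergence controls.

    Attributes (after ``fit``)
    --------------------------
    x_weights_ : (n_features, n_components), unit-norm columns.
    x_loadings_ : (n_features, n_components).
    y_loadings_ : (n_components,).
    x_scores_ : (n_samples, n_components) training scores, mutually orthogonal.
    coef_ : (n_features,) regression vector on the autoscaled features.
    scaling_ : ScalingParams of the training features.
    calibration_ : PosteriorCalibration on the training y_hat.
    classes_ : ``array(['HLT', 'IBS'])``.
    feature_ids_ : feature names when fitted from a FeatureTable, else None.
    """

    def __init__(self, n_components: int = 2, prior_ibs: float = 0.5,
                 tol: float = 1e-10, max_iter: int = 500):
        self.n_components = n_components
        self.prior_ibs = prior_ibs
        self.tol = tol
        self.max_iter = max_iter

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, feature_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be 2-D with one row per label")
        labels = set(np.unique(y).tolist())
        if labels != set(_ENCODING):
            raise ValueError(
                f"y must contain both classes {sorted(_ENCODING)}, got {sorted(labels)}"
            )
        n, p = X.shape
        if not (1 <= self.n_components <= min(n - 1, p)):
            raise ValueError(
                f"n_components must be in [1, min(n_samples-1, n_features)] = "
                f"[1, {min(n - 1, p)}], got {self.n_components}"
            )
        y_enc = np.array([_ENCODING[g] for g in y])
        Xs, self.scaling_ = autoscale(X)
        self.y_mean_ = float(y_enc.mean())
        W, P, T, c = _nipals_pls1(
            Xs, y_enc - self.y_mean_, self.n_components, self.tol, self.max_iter
        )
        self.x_weights_, self.x_loadings_, self.x_scores_, self.y_loadings_ = W, P, T, c
        # regression vector: B = W (P'W)^-1 c
        self.coef_ = W @ np.linalg.solve(P.T @ W, c)
        self.classes_ = np.array(["HLT", "IBS"])
        self.feature_ids_ = list(feature_ids) if feature_ids is not None else None
        yhat = self.decision_function(X)
        self.calibration_ = calibrate_posterior(yhat, y, self.prior_ibs)
        return self

    # -- prediction --------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        """Continuous PLS prediction y_hat (positive leans IBS)."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.scaling_.mean.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects "
                f"{self.scaling_.mean.shape[0]}"
            )
        return self.y_mean_ + self.scaling_.apply(X) @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        p_ibs = self.calibration_.p_ibs(self.decision_function(X))
        return np.column_stack([1.0 - p_ibs, p_ibs])

    def predict(self, X) -> np.ndarray:
        # ties at p_ibs = 0.5 are assigned to IBS
        p_ibs = self.predict_proba(X)[:, 1]
        return np.where(p_ibs >= 0.5, "IBS", "HLT")


# -- FeatureTable-aware wrappers ------------------------------------------


@dataclass
class ChannelPosterior:
    """Per-sample posterior probability of IBS from one data channel."""

    sample_id: str
    p_ibs: float
    channel: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_ibs <= 1.0):
            raise ValueError(f"p_ibs out of [0,1]: {self.p_ibs}")


def _channel_name(kind: str) -> str:
    return "microbiota" if kind == "genus" else "metabolite"


def fit_channel_model(
    table: FeatureTable, meta: SampleMeta, n_components: int = 2,
    prior_ibs: float = 0.5,
) -> PLSDAClassifier:
    """Fit a PLS-DA model to one channel's full table."""
    if table.sample_ids != meta.sample_ids:
        raise ValueError("table and metadata sample ids differ (align first)")
    clf = PLSDAClassifier(n_components=n_components, prior_ibs=prior_ibs)
    return clf.fit(table.values, np.array(meta.group), feature_ids=table.feature_ids)


def _match_features(model: PLSDAClassifier, table: FeatureTable) -> np.ndarray:
    if model.feature_ids_ is None:
        return table.values
    have, want = set(table.feature_ids), set(model.feature_ids_)
    if have != want:
        diff = sorted(have.symmetric_difference(want))
        raise ValueError(f"feature mismatch between model and table: {diff}")
    pos = {f: j for j, f in enumerate(table.feature_ids)}
    idx = [pos[f] for f in model.feature_ids_]
    return table.values[:, idx]


def predict_continuous(model: PLSDAClassifier, table: FeatureTable) -> np.ndarray:
    """Continuous y_hat for a table, matching features by identifier."""
    return model.decision_function(_match_features(model, table))


def predict_posteriors(model: PLSDAClassifier, table: FeatureTable) -> list[ChannelPosterior]:
    p = model.calibration_.p_ibs(predict_continuous(model, table))
    channel = _channel_name(table.kind)
    return [ChannelPosterior(s, float(pi), channel)
            for s, pi in zip(table.sample_ids, p)]


def loocv_posteriors(
    table: FeatureTable, meta: SampleMeta, n_components: int = 2,
    prior_ibs: float = 0.5,
) -> list[ChannelPosterior]:
    """Leave-one-out posteriors: scaling, PLS fit and calibration are all
    recomputed on the n-1 retained samples, so the held-out sample never
    leaks into its own prediction."""
    if table.sample_ids != meta.sample_ids:
        raise ValueError("table and metadata sample ids differ (align first)")
    groups = np.array(meta.group)
    for g in ("IBS", "HLT"):
        if (groups == g).sum() < 2:
            raise ValueError(f"LOOCV needs >= 2 samples per group; {g} has fewer")
    channel = _channel_name(table.kind)
    out = []
    n = table.n_samples
    for i in range(n):
        keep = np.arange(n) != i
        clf = PLSDAClassifier(n_components=n_components, prior_ibs=prior_ibs)
        try:
            clf.fit(table.values[keep], groups[keep])
        except Exception as exc:
            raise RuntimeError(
                f"LOOCV fit failed with sample {table.sample_ids[i]!r} held out"
            ) from exc
        p = float(clf.predict_proba(table.values[i:i + 1])[0, 1])
        out.append(ChannelPosterior(table.sample_ids[i], p, channel))
    return out


def posterior_assignments(posteriors: list[ChannelPosterior]) -> list[str]:
    """IBS iff p_ibs >= 0.5 (ties to IBS)."""
    return ["IBS" if cp.p_ibs >= 0.5 else "HLT" for cp in posteriors]


def rank_discriminators(model: PLSDAClassifier, k: int) -> list[tuple[str, int]]:
    """Top-k features by descending first-component |weight|.

    Ties break by second-component |weight|, then feature id.  The
    direction is +1 when the feature is elevated in IBS (sign of
    weight_1 * y_loading_1 under the IBS -> +1 encoding).
    """
    W = model.x_weights_
    p = W.shape[0]
    if not (1 <= k <= p):
        raise ValueError(f"k must be in [1, {p}], got {k}")
    ids = model.feature_ids_ or [f"f{j}" for j in range(p)]
    w1 = W[:, 0]
    w2 = W[:, 1] if W.shape[1] > 1 else np.zeros(p)
    order = sorted(range(p), key=lambda j: (-abs(w1[j]), -abs(w2[j]), ids[j]))
    c1 = model.y_loadings_[0]
    out = []
    for j in order[:k]:
        direction = 1 if w1[j] * c1 >= 0 else -1
        out.append((ids[j], direction))
    return out
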