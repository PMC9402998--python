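"""Logistic risk models and restricted-cubic-spline cutoff exploration.

The score-to-mortality models are univariable logistic regressions fitted
by iteratively reweighted least squares (IRLS) with step-halving, so the
log-likelihood is non-decreasing across iterations.  The integer score
enters linearly by default (parsimonious, and it yields a smooth bedside
calculator); a categorical one-coefficient-per-level parametrization is
available via ``categorical=True``.

Restricted (natural) cubic splines support the empirical choice of
biomarker cut points: the fitted log-odds curve is cubic between knots and
constrained to be linear beyond the boundary knots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "SeparationError",
    "RiskModel",
    "RcsFit",
    "fit_logistic",
    "predict_prob",
    "rcs_basis",
    "default_rcs_knots",
    "fit_rcs_logistic",
    "explore_cutoffs",
]

_MAX_ABS_COEF = 1e3  # coefficient magnitude treated as divergence/separation


class SeparationError(RuntimeError):
    """Raised when the likelihood has no finite maximizer (separated data)."""


@dataclass
class RiskModel:
    """A fitted logistic mapping from a score to event probability."""

    predictor_name: str
    coefficients: np.ndarray  # intercept first
    covariance: np.ndarray
    converged: bool
    n_events: int
    n_total: int
    log_likelihood: float
    categorical: bool = False
    levels: np.ndarray | None = None  # distinct score levels, categorical only
    loglik_path: list[float] = field(default_factory=list, repr=False)

    def design(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.categorical:
            cols = [np.ones_like(x)]
            # reference level = lowest score; one indicator per higher level
            cols += [(x == lv).astype(float) for lv in self.levels[1:]]
            return np.column_stack(cols)
        return np.column_stack([np.ones_like(x), x])

    def predict(self, x):
        return predict_prob(self, x)

    def to_json(self, path=None) -> str:
        payload = {
            "predictor_name": self.predictor_name,
            "coefficients": self.coefficients.tolist(),
            "covariance": self.covariance.tolist(),
            "converged": self.converged,
            "n_events": self.n_events,
            "n_total": self.n_total,
            "log_likelihood": self.log_likelihood,
            "categorical": self.categorical,
            "levels": None if self.levels is None else self.levels.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RiskModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        payload.pop("provenance", None)
        levels = payload.pop("levels", None)
        return cls(
            predictor_name=payload["predictor_name"],
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            covariance=np.asarray(payload["covariance"], dtype=float),
            converged=payload["converged"],
            n_events=payload["n_events"],
            n_total=payload["n_total"],
            log_likelihood=payload["log_likelihood"],
            categorical=payload.get("categorical", False),
            levels=None if levels is None else np.asarray(levels, dtype=float),
        )


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood in terms of log-odds
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-10, max_iter: int = 100):
    """IRLS with step-halving; returns (beta, cov, converged, ll, path)."""
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    ll = _log_likelihood(eta, y)
    path = [ll]
    converged = False
    for _ in range(max_iter):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        XtW = X.T * w
        hessian = XtW @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(hessian, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix; data may be separated or the "
                "design collinear"
            ) from exc
        # step-halving guarantees likelihood ascent
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            ll_new = _log_likelihood(X @ cand, y)
            if ll_new >= ll - 1e-14:
                break
            scale *= 0.5
        beta = beta + scale * step
        eta = X @ beta
        ll_new = _log_likelihood(eta, y)
        path.append(ll_new)
        if np.max(np.abs(beta)) > _MAX_ABS_COEF:
            raise SeparationError(
                "coefficients diverged during fitting; the outcome is "
                "(quasi-)separated by the predictor"
            )
        if abs(ll_new - ll) <= tol * (abs(ll) + 1e-12):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    mu = expit(eta)
    if not converged and mu[y == 1].min() > 1 - 1e-6 and mu[y == 0].max() < 1e-6:
        # likelihood is maximized only in the limit |beta| -> inf
        raise SeparationError(
            "coefficients diverged during fitting; the outcome is perfectly "
            "separated by the predictor"
        )
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, cov, converged, ll, path


def fit_logistic(x, y, predictor_name: str = "score", categorical: bool = False) -> RiskModel:
    """Maximum-likelihood logistic fit of event indicators on a score.

    Raises :class:`SeparationError` when the data are perfectly separated
    (diverging coefficients are reported, never silently clipped), and
    ``ValueError`` for an all-event or all-non-event outcome vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("y must be binary 0/1")
    n_events = int(y.sum())
    if n_events == 0 or n_events == len(y):
        raise ValueError("need at least one event and one non-event")

    if np.ptp(x) == 0:
        # constant predictor: the slope is unidentified and set to 0; the
        # intercept is the closed-form MLE logit(event rate)
        p_hat = n_events / len(y)
        eta = np.full(len(y), np.log(p_hat / (1 - p_hat)))
        return RiskModel(
            predictor_name=predictor_name,
            coefficients=np.array([np.log(p_hat / (1 - p_hat)), 0.0]),
            covariance=np.array([[1.0 / (len(y) * p_hat * (1 - p_hat)), 0.0], [0.0, 0.0]]),
            converged=True,
            n_events=n_events,
            n_total=len(y),
            log_likelihood=_log_likelihood(eta, y),
        )

    levels = None
    if categorical:
        levels = np.unique(x)
        if levels.size < 2:
            categorical = False
            levels = None
    model = RiskModel(
        predictor_name=predictor_name,
        coefficients=np.zeros(2),
        covariance=np.zeros((2, 2)),
        converged=False,
        n_events=n_events,
        n_total=len(y),
        log_likelihood=0.0,
        categorical=categorical,
        levels=levels,
    )
    X = model.design(x)
    beta, cov, converged, ll, path = _irls(X, y)
    model.coefficients = beta
    model.covariance = cov
    model.converged = converged
    model.log_likelihood = ll
    model.loglik_path = path
    return model


def predict_prob(model: RiskModel, x):
    """Predicted event probability (inverse-logit of the linear predictor)."""
    X = model.design(x)
    p = expit(X @ model.coefficients)
    if np.ndim(x) == 0:
        return float(p[0])
    return p


# ---------------------------------------------------------------------------
# Restricted cubic splines


def default_rcs_knots(x, k: int = 4) -> np.ndarray:
    """Knots at the 0.05/0.35/0.65/0.95 quantiles (k=4), or spread evenly
    in probability between 0.05 and 0.95 for other k."""
    x = np.asarray(x, dtype=float)
    probs = np.linspace(0.05, 0.95, k)
    knots = np.quantile(x, probs)
    if np.unique(knots).size < k:
        raise ValueError("data too discrete for distinct knots; supply knots explicitly")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (truncated-power form, Harrell scaling).

    With k knots t_1 < ... < t_k the basis has k-1 columns: the identity
    plus k-2 nonlinear terms

        B_j(x) = [(x-t_j)_+^3 - (x-t_{k-1})_+^3 (t_k-t_j)/(t_k-t_{k-1})
                  + (x-t_k)_+^3 (t_{k-1}-t_j)/(t_k-t_{k-1})] / (t_k-t_1)^2

    which vanish below the first knot and are linear above the last, so any
    fitted curve is linear outside the boundary knots.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    t = knots
    k = t.size
    scale = (t[-1] - t[0]) ** 2

    def pos3(v):
        return np.maximum(v, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            pos3(x - t[j])
            - pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / scale)
    return np.column_stack(cols)


@dataclass
class RcsFit:
    """A logistic fit on a restricted-cubic-spline expansion of a marker."""

    marker_name: str
    knots: np.ndarray
    coefficients: np.ndarray  # intercept + basis coefficients
    covariance: np.ndarray
    converged: bool
    n_events: int
    n_total: int

    def log_odds(self, x):
        X = np.column_stack(
            [np.ones(np.atleast_1d(x).shape[0]), rcs_basis(x, self.knots)]
        )
        eta = X @ self.coefficients
        if np.ndim(x) == 0:
            return float(eta[0])
        return eta

    def predict(self, x):
        p = expit(self.log_odds(np.atleast_1d(x)))
        if np.ndim(x) == 0:
            return float(p[0])
        return p


def fit_rcs_logistic(x, y, knots=None, marker_name: str = "marker") -> RcsFit:
    """Logistic regression of the outcome on an RCS expansion of a marker."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if knots is None:
        knots = default_rcs_knots(x)
    knots = np.asarray(knots, dtype=float)
    B = rcs_basis(x, knots)
    X = np.column_stack([np.ones(len(x)), B])
    n_events = int(y.sum())
    if n_events == 0 or n_events == len(y):
        raise ValueError("need at least one event and one non-event")
    beta, cov, converged, _ll, _path = _irls(X, y)
    return RcsFit(
        marker_name=marker_name,
        knots=knots,
        coefficients=beta,
        covariance=cov,
        converged=converged,
        n_events=n_events,
        n_total=len(y),
    )


def explore_cutoffs(fit: RcsFit, grid) -> "pd.DataFrame":
    """Fitted log-odds (and probability) over a marker grid.

    Supports tabular/visual inspection of candidate cut points; no cutoff
    is selected automatically — that choice is left to the analyst.
    """
    import pandas as pd

    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty grid")
    eta = fit.log_odds(grid)
    return pd.DataFrame(
        {fit.marker_name: grid, "log_odds": eta, "probability": expit(eta)}
    )
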