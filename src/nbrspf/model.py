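"""NB2 resource-selection model with an ln(T) offset.

The model relates the count of GPS fixes in sampling unit i to its habitat
covariates,

    E[t_i] = exp(ln T + b0 + b1*x_1i + ... + bp*x_pi),    var[t_i] = u_i + u_i**2/theta,

so that exp(b0 + sum_j bj*x_ji) is the *relative frequency* of use of unit i
— an RSPF.  Fitting alternates (a) iteratively reweighted least squares for
the coefficients at fixed dispersion with (b) a one-dimensional maximum-
likelihood update of theta at fixed coefficients, until the joint
log-likelihood stabilizes; at convergence this is full joint ML, the same
scheme R's glm.nb uses.  The reported covariance of the coefficients is the
inverse Fisher information at the optimum, conditional on theta — the usual
"ML SE".  Under panel (per-animal) structure these SEs are anti-conservative;
the animal-level bootstrap in :mod:`nbrspf.bootstrap` is the endorsed
inference path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import digamma, gammaln

from .sampling import UnitTable

__all__ = [
    "NegativeBinomialRSPF",
    "RSPFResults",
    "ConvergenceError",
    "fit_nb2",
    "nb2_loglik",
    "nb2_deviance",
]

_THETA_LO = 1e-4
_THETA_HI = 1e7


class ConvergenceError(RuntimeError):
    """Raised when the alternating ML fit fails to converge; carries diagnostics."""

    def __init__(self, message, *, iterations=None, loglik=None, beta=None, theta=None):
        super().__init__(message)
        self.iterations = iterations
        self.loglik = loglik
        self.beta = beta
        self.theta = theta


def nb2_loglik(y, mu, theta):
    """NB2 log-likelihood of counts ``y`` at means ``mu`` and dispersion ``theta``."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogmu = np.where(y > 0, y * np.log(mu), 0.0)
    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1)
            + theta * np.log(theta)
            + ylogmu
            - (theta + y) * np.log(theta + mu)
        )
    )


def nb2_deviance(y, mu, theta):
    """Residual deviance 2*sum[ y*ln(y/mu) - (y+theta)*ln((y+theta)/(mu+theta)) ].

    The y*ln(y) term is taken as 0 at y = 0; D = 0 iff mu = y everywhere.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y + theta) * np.log((y + theta) / (mu + theta))))


def _poisson_irls(y, X, offset, maxiter=50, tol=1e-10):
    """Poisson-regression start values for the coefficients."""
    n, k = X.shape
    beta = np.zeros(k)
    beta[0] = np.log(max(y.mean(), 1e-8)) - (offset if np.isscalar(offset) else np.mean(offset))
    for _ in range(maxiter):
        eta = offset + X @ beta
        mu = np.exp(np.clip(eta, -300, 300))
        w = mu
        z = (eta - offset) + (y - mu) / mu
        beta_new = _wls(X, z, w)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _wls(X, z, w):
    sw = np.sqrt(w)
    return np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)[0]


def _irls_beta(y, X, offset, theta, beta, maxiter=100, tol=1e-12):
    """IRLS update of beta at fixed theta (NB2 working weights mu*theta/(mu+theta))."""
    for _ in range(maxiter):
        eta = offset + X @ beta
        mu = np.exp(np.clip(eta, -300, 300))
        w = mu * theta / (mu + theta)
        z = (eta - offset) + (y - mu) / mu
        beta_new = _wls(X, z, w)
        if np.max(np.abs(beta_new - beta)) < tol * (1.0 + np.max(np.abs(beta))):
            beta = beta_new
            break
        beta = beta_new
    eta = offset + X @ beta
    mu = np.exp(np.clip(eta, -300, 300))
    return beta, mu



def _theta_score(theta, y, mu):
    """d loglik / d theta at fixed means."""
    return float(
        np.sum(
            digamma(y + theta)
            - digamma(theta)
            + np.log(theta)
            + 1.0
            - np.log(theta + mu)
            - (theta + y) / (theta + mu)
        )
    )


def _theta_mle(y, mu):
    """1-D ML update of theta at fixed means, solved on the log scale.

    Near-equidispersed data make the likelihood almost flat in theta up to
    the Poisson end, where the score's sign is numerical noise; whenever the
    interior solution gains less than 1e-4 log-likelihood units over the
    upper boundary, theta snaps to the boundary so the update cannot wander.
    """
    if _theta_score(_THETA_LO, y, mu) < 0:
        return _THETA_LO
    if _theta_score(_THETA_HI, y, mu) > 0:
        return _THETA_HI
    try:
        logt = brentq(
            lambda lt: _theta_score(np.exp(lt), y, mu),
            np.log(_THETA_LO),
            np.log(_THETA_HI),
            xtol=1e-12,
        )
    except ValueError:  # score sign degenerate at a bracket end: pick the better end
        if nb2_loglik(y, mu, _THETA_LO) > nb2_loglik(y, mu, _THETA_HI):
            return _THETA_LO
        return _THETA_HI
    interior = float(np.exp(logt))
    if nb2_loglik(y, mu, _THETA_HI) > nb2_loglik(y, mu, interior) - 1e-4:
        return _THETA_HI
    return interior


def _theta_moment_start(y):
    m = y.mean()
    s2 = y.var(ddof=1) if y.size > 1 else 0.0
    if s2 > m:
        return max(0.01, m**2 / (s2 - m))
    return 100.0  # under-/equi-dispersed data: start near the Poisson side


def _fit_engine(y, X, offset, *, start_beta=None, start_theta=None, maxiter=100, tol=1e-8):
    y = np.asarray(y, dtype=float)
    beta = _poisson_irls(y, X, offset) if start_beta is None else np.asarray(start_beta, float).copy()
    theta = _theta_moment_start(y) if start_theta is None else float(start_theta)
    ll = -np.inf
    for it in range(maxiter):
        beta_prev, theta_prev = beta, theta
        beta, mu = _irls_beta(y, X, offset, theta, beta)
        theta = _theta_mle(y, mu)
        ll_new = nb2_loglik(y, mu, theta)
        params_stable = (
            theta == theta_prev
            and np.max(np.abs(beta - beta_prev)) < 1e-10 * (1.0 + np.max(np.abs(beta)))
        )
        # each exact alternating step is non-decreasing, so an improvement
        # below tol (including a numerical-noise decrease) means convergence
        if np.isfinite(ll) and (ll_new - ll < tol or params_stable):
            ll = max(ll, ll_new)
            break
        ll = ll_new
    else:
        raise ConvergenceError(
            f"NB2 fit did not converge in {maxiter} alternating iterations "
            f"(last loglik {ll:.6f}, theta {theta:.4g})",
            iterations=maxiter,
            loglik=ll,
            beta=beta,
            theta=theta,
        )
    # conditional-on-theta Fisher information, as reported by glm.nb
    w = mu * theta / (mu + theta)
    info = (X * w[:, None]).T @ X
    vcov = np.linalg.inv(info)
    return beta, theta, mu, ll, vcov, it + 1


class NegativeBinomialRSPF:
    """NB2 resource-selection model for per-unit counts of GPS fixes.

    Parameters
    ----------
    counts : array-like of non-negative integers
        Fixes counted in each sampling unit.
    exog : DataFrame
        Covariate columns (one row per unit); an intercept is added.
    offset_total : float, optional
        Total number of recorded fixes T.  When given, ln(T) enters the
        linear predictor as an offset and fitted exp(b0 + x'b) values are
        relative frequencies of use (an RSPF).  Without it the model is on
        the raw count scale.
    radius : float, optional
        Sampling-unit radius in meters, carried along so predictions onto
        new units can check design consistency.
    """

    def __init__(self, counts, exog: pd.DataFrame, offset_total=None, radius=None):
        counts = np.asarray(counts)
        if np.any(counts.astype(float) < 0) or np.any(
            counts.astype(float) != np.round(counts.astype(float))
        ):
            raise ValueError("counts must be non-negative integers")
        self.endog = counts.astype(int)
        if not isinstance(exog, pd.DataFrame):
            exog = pd.DataFrame(np.asarray(exog))
        self.exog_names = ["const"] + [str(c) for c in exog.columns]
        self.exog = np.column_stack([np.ones(len(exog)), exog.to_numpy(dtype=float)])
        self.covariate_frame = exog.astype(float).reset_index(drop=True)
        self.offset_total = None if offset_total is None else float(offset_total)
        self.offset_log = 0.0 if offset_total is None else float(np.log(offset_total))
        self.radius = radius
        n, k = self.exog.shape
        if n < k + 1:
            raise ValueError(f"need at least p + 2 = {k + 1} units to fit, got {n}")
        if np.linalg.matrix_rank(self.exog) < k:
            raise ValueError("design matrix is rank deficient")
        if np.all(self.endog == 0):
            raise ValueError("cannot estimate dispersion: all counts are zero")

    @classmethod
    def from_units(cls, units: UnitTable, covariates=None, offset_total=None):
        """Build the model from a counted :class:`~nbrspf.sampling.UnitTable`."""
        if units.counts is None:
            raise ValueError("unit table has no counts; run count_locations first")
        names = list(units.covariate_names if covariates is None else covariates)
        exog = pd.DataFrame(units.covariates(names), columns=names)
        return cls(units.counts, exog, offset_total=offset_total, radius=units.radius)

    def fit(self, start_params=None, start_theta=None, maxiter=100, tol=1e-8) -> "RSPFResults":
        beta, theta, mu, ll, vcov, n_iter = _fit_engine(
            self.endog,
            self.exog,
            self.offset_log,
            start_beta=start_params,
            start_theta=start_theta,
            maxiter=maxiter,
            tol=tol,
        )
        return RSPFResults(self, beta, theta, mu, ll, vcov, n_iter)


@dataclass
class RSPFResults:
    """Fitted NB2 RSPF: coefficients, dispersion, ML covariance, diagnostics."""

    model: NegativeBinomialRSPF
    _beta: np.ndarray
    theta: float
    fittedvalues: np.ndarray
    llf: float
    _vcov: np.ndarray
    n_iter: int

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._beta, index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self._vcov)), index=self.model.exog_names)

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self._vcov, index=self.model.exog_names, columns=self.model.exog_names)

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    @property
    def df_resid(self) -> int:
        return self.nobs - len(self._beta)

    @property
    def deviance(self) -> float:
        return nb2_deviance(self.model.endog, self.fittedvalues, self.theta)

    @property
    def deviance_ratio(self) -> float:
        """D / df — values substantially above 1 are evidence of groupings in
        the data (e.g. per-animal panels) or other assumption violations."""
        return self.deviance / self.df_resid

    @property
    def aic(self) -> float:
        # theta counts as an estimated parameter, as in glm.nb
        return -2.0 * self.llf + 2.0 * (len(self._beta) + 1)

    def expected_zero_proportion(self) -> float:
        """Average fitted P(Y=0) over units, for comparison with the observed
        zero fraction (a large gap suggests zero inflation)."""
        th = self.theta
        return float(np.mean((th / (th + self.fittedvalues)) ** th))

    def observed_zero_proportion(self) -> float:
        return float(np.mean(self.model.endog == 0))

    def predict(self, exog=None, rescale="none", scale="relative", warn_out_of_range=True):
        """Predicted relative frequency of use; see :func:`nbrspf.prediction.predict_units`."""
        from .prediction import _predict_array

        return _predict_array(
            self, exog, rescale=rescale, scale=scale, warn_out_of_range=warn_out_of_range
        )

    def wald_conf_int(self, level=0.90) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        lo = self._beta - z * np.sqrt(np.diag(self._vcov))
        hi = self._beta + z * np.sqrt(np.diag(self._vcov))
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self.model.exog_names)

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(zip(self.model.exog_names, map(float, self._beta))),
            "ml_se": dict(zip(self.model.exog_names, map(float, self.bse))),
            "theta": float(self.theta),
            "offset_logT": float(self.model.offset_log),
            "offset_total": self.model.offset_total,
            "vcov_ml": self._vcov.tolist(),
            "deviance": float(self.deviance),
            "df": int(self.df_resid),
            "deviance_ratio": float(self.deviance_ratio),
            "n_units": int(self.nobs),
            "loglik": float(self.llf),
            "aic": float(self.aic),
            "expected_zero_proportion": self.expected_zero_proportion(),
            "observed_zero_proportion": self.observed_zero_proportion(),
            "radius": self.model.radius,
            "exog_names": list(self.model.exog_names),
        }

    def summary(self) -> str:
        head = [
            "NB2 resource selection (probability) function",
            "=" * 62,
            f"No. units: {self.nobs:>6d}    Residual df: {self.df_resid:>6d}",
            f"Log-likelihood: {self.llf:>12.3f}    AIC: {self.aic:>10.2f}",
            f"theta (dispersion): {self.theta:>8.4g}",
            f"Deviance: {self.deviance:>10.2f}    D/df: {self.deviance_ratio:>6.3f}",
            f"Zero fraction  observed: {self.observed_zero_proportion():.3f}"
            f"  expected under fit: {self.expected_zero_proportion():.3f}",
        ]
        if self.model.offset_total is not None:
            head.insert(3, f"Offset ln(T), T = {self.model.offset_total:g}"
                           " (predictions are relative frequencies)")
        rows = [f"{'':<26s}{'coef':>10s}{'ML SE':>10s}{'z':>8s}"]
        for name, b, se in zip(self.model.exog_names, self._beta, self.bse):
            z = b / se if se > 0 else np.nan
            rows.append(f"{name:<26s}{b:>10.4f}{se:>10.4f}{z:>8.2f}")
        note = [
            "-" * 62,
            "ML SEs ignore panel (per-animal) structure and are typically",
            "anti-conservative; prefer the animal-level bootstrap SEs/CIs.",
        ]
        return "\n".join(head + ["-" * 62] + rows + note)


def fit_nb2(units: UnitTable, covariates=None, offset_total=None, **fit_kwargs) -> RSPFResults:
    """One-call fit of the NB2 RSPF from a counted unit table."""
    return NegativeBinomialRSPF.from_units(
        units, covariates=covariates, offset_total=offset_total
    ).fit(**fit_kwargs)
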