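"""Predicted relative use, marginal covariate profiles, and predictive surfaces.

Predictions evaluate exp(b0 + sum_j bj*x_j) — the training offset ln(T) is
*not* added back, because it rescaled the response to relative frequencies;
multiplying by T recovers the expected-count scale.  Because mapped units
may overlap or leave gaps, predictions carry no unit-sum constraint; for a
probability-of-use map they can be rescaled to a unit maximum or unit sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import RSPFResults
from .sampling import UnitTable

__all__ = [
    "predict_units",
    "prediction_surface",
    "marginal_profile",
    "PredictionSurface",
    "MarginalProfile",
    "OutOfRangeWarning",
]

RESCALE_MODES = ("none", "max1", "unit_sum")


class OutOfRangeWarning(UserWarning):
    """A prediction covariate lies outside the range of the modeling data."""


def _covariate_ranges(results: RSPFResults) -> pd.DataFrame:
    f = results.model.covariate_frame
    return pd.DataFrame({"min": f.min(), "max": f.max(), "median": f.median()})


def _check_ranges(results: RSPFResults, exog: pd.DataFrame) -> None:
    if results.model.covariate_frame is None:  # refit-from-report: no training data
        return
    ranges = _covariate_ranges(results)
    for name in exog.columns:
        lo, hi = ranges.loc[name, "min"], ranges.loc[name, "max"]
        vals = exog[name].to_numpy(dtype=float)
        if (vals < lo).any() or (vals > hi).any():
            warnings.warn(
                f"covariate '{name}' extends outside the modeling range "
                f"[{lo:g}, {hi:g}]; predictions there are extrapolations",
                OutOfRangeWarning,
                stacklevel=3,
            )


def _exog_frame(results: RSPFResults, exog) -> pd.DataFrame:
    names = [c for c in results.model.exog_names if c != "const"]
    if exog is None:
        return results.model.covariate_frame[names]
    if isinstance(exog, UnitTable):
        exog = exog.frame
    if not isinstance(exog, pd.DataFrame):
        exog = pd.DataFrame(np.asarray(exog), columns=names)
    missing = [c for c in names if c not in exog.columns]
    if missing:
        raise ValueError(f"unknown covariate column(s) for prediction: {', '.join(missing)}")
    return exog[names]


def _linear_predictor(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.exp(beta[0] + X @ beta[1:])


def _apply_rescale(pred: np.ndarray, mode: str) -> np.ndarray:
    if mode not in RESCALE_MODES:
        raise ValueError(f"rescale mode must be one of {RESCALE_MODES}")
    if mode == "max1":
        return pred / pred.max()
    if mode == "unit_sum":
        return pred / pred.sum()
    return pred


def _predict_array(results: RSPFResults, exog=None, rescale="none", scale="relative",
                   warn_out_of_range=True) -> np.ndarray:
    exog = _exog_frame(results, exog)
    if warn_out_of_range:
        _check_ranges(results, exog)
    pred = _linear_predictor(results.params.to_numpy(), exog.to_numpy(dtype=float))
    if scale == "count":
        if results.model.offset_total is None:
            raise ValueError("count-scale predictions need a model fitted with offset_total")
        pred = pred * results.model.offset_total
    elif scale != "relative":
        raise ValueError("scale must be 'relative' or 'count'")
    return _apply_rescale(pred, rescale)


@dataclass
class PredictionSurface:
    """Per-unit predicted relative frequency of use (optionally rescaled)."""

    frame: pd.DataFrame  # unit_id/x/y (when known) + covariates + 'predicted'
    rescale_mode: str = "none"

    @property
    def predicted(self) -> np.ndarray:
        return self.frame["predicted"].to_numpy(dtype=float)

    def plot(self, ax=None, **scatter_kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sc = ax.scatter(
            self.frame["center_x"], self.frame["center_y"],
            c=self.predicted, **scatter_kw,
        )
        ax.set_xlabel("x (m)")
        ax.set_ylabel("y (m)")
        ax.set_aspect("equal")
        plt.colorbar(sc, ax=ax, label="relative frequency of use")
        return ax


def predict_units(results: RSPFResults, new_units, rescale="none") -> PredictionSurface:
    """Predict relative use for new sampling units.

    New units must share the modeling radius — the size and shape of units
    should be consistent from modeling to mapping; covariates outside the
    modeling range trigger a warning, not an error.
    """
    if isinstance(new_units, UnitTable):
        if results.model.radius is not None and not np.isclose(
            new_units.radius, results.model.radius
        ):
            raise ValueError(
                f"unit radius {new_units.radius:g} m does not match the modeling "
                f"radius {results.model.radius:g} m"
            )
        base = new_units.frame.copy()
    else:
        base = pd.DataFrame(new_units).copy()
    pred = _predict_array(results, new_units, rescale=rescale)
    base["predicted"] = pred
    return PredictionSurface(base, rescale_mode=rescale)


def prediction_surface(
    results: RSPFResults, grid: pd.DataFrame, radius=None, rescale="none"
) -> PredictionSurface:
    """Predictive map on a (possibly finer, possibly overlapping) lattice of units.

    ``grid`` holds center coordinates plus the covariates measured on a
    circle of the modeling radius around each center.  Mapping at a finer
    scale than the modeling units is valid; the predictions carry no
    unit-sum constraint unless ``rescale='unit_sum'``.
    """
    if radius is not None and results.model.radius is not None and not np.isclose(
        radius, results.model.radius
    ):
        raise ValueError(
            f"grid radius {radius:g} m does not match the modeling radius "
            f"{results.model.radius:g} m"
        )
    base = pd.DataFrame(grid).copy()
    base["predicted"] = _predict_array(results, base, rescale=rescale)
    return PredictionSurface(base, rescale_mode=rescale)


@dataclass
class MarginalProfile:
    """Median predicted use across one covariate with a bootstrap envelope.

    All three curves are jointly scaled so the overall maximum is 1; other
    covariates are held at their reference (default: median) values.
    """

    covariate: str
    grid: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    reference: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.covariate: self.grid,
                "median": self.median,
                "lower": self.lower,
                "upper": self.upper,
            }
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.grid, self.lower, self.upper, alpha=0.3,
                        label=f"{int(self.level * 100)}% bootstrap envelope")
        ax.plot(self.grid, self.median, label="median prediction")
        ax.set_xlabel(self.covariate)
        ax.set_ylabel("relative probability of use (max = 1)")
        ax.legend()
        return ax


def marginal_profile(boot, covariate, n_grid=50, reference=None, level=0.90) -> MarginalProfile:
    """Marginal response curve with a bootstrap percentile envelope.

    The grid spans the covariate's observed range in the modeling units
    (predictions stay within the range of the modeling data); every
    bootstrap replicate is evaluated at each grid value with the other
    covariates held at reference values, and the pointwise median and
    central percentiles are scaled jointly to an overall maximum of 1.
    """
    names = [c for c in boot.point_fit.model.exog_names if c != "const"]
    if covariate not in names:
        raise ValueError(f"covariate not in the fitted model: {covariate}")
    ranges = _covariate_ranges(boot.point_fit)
    ref = dict(ranges["median"])
    if reference is not None:
        ref.update(reference)
    grid = np.linspace(ranges.loc[covariate, "min"], ranges.loc[covariate, "max"], n_grid)
    X = np.tile([ref[c] for c in names], (n_grid, 1))
    X[:, names.index(covariate)] = grid
    betas = boot.replicates.to_numpy()  # B x (p+1)
    preds = np.exp(betas[:, [0]] + betas[:, 1:] @ X.T)  # B x n_grid
    alpha = (1.0 - level) / 2.0
    med = np.median(preds, axis=0)
    lo = np.quantile(preds, alpha, axis=0)
    hi = np.quantile(preds, 1.0 - alpha, axis=0)
    scale = max(med.max(), lo.max(), hi.max())
    return MarginalProfile(
        covariate=covariate,
        grid=grid,
        median=med / scale,
        lower=lo / scale,
        upper=hi / scale,
        level=level,
        reference={k: float(v) for k, v in ref.items()},
    )
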