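"""Among-animal inference: bootstrap over animals, two-stage averaging, rate ratios.

The individual animal is the experimental unit.  Each bootstrap replicate
redraws m animals with replacement, pools their fixes (an animal drawn k
times contributes its per-unit counts k times), recomputes the offset from
the replicate's own pooled total T_b, and refits the NB2 model.  The SD of
the replicate coefficients estimates each SE; the central `level` percentile
interval is the CI.  Within-animal fixes are never resampled — temporal
correlation inside an animal's track is deliberately left untouched, since
the estimator does not require temporally independent fixes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ConvergenceError, NegativeBinomialRSPF, RSPFResults
from .sampling import UnitTable, count_locations

__all__ = ["bootstrap_by_animal", "BootstrapResults", "two_stage", "TwoStageResults", "rate_ratio"]

logger = logging.getLogger(__name__)


def _per_animal_counts(locations: pd.DataFrame, units: UnitTable):
    """Per-animal count matrix (m x n_units) and per-animal fix totals."""
    if "animal_id" not in locations.columns:
        raise ValueError("location table missing column(s): animal_id")
    animals = sorted(locations["animal_id"].astype(str).unique())
    C = np.empty((len(animals), units.n_units), dtype=int)
    totals = np.empty(len(animals), dtype=int)
    ids = locations["animal_id"].astype(str)
    for a, animal in enumerate(animals):
        sub = locations[ids == animal]
        C[a] = count_locations(units, sub).counts
        totals[a] = len(sub)  # all recorded fixes, inside units or not
    return animals, C, totals


def bootstrap_by_animal(
    locations: pd.DataFrame,
    units: UnitTable,
    covariates=None,
    B: int = 1000,
    level: float = 0.90,
    seed=None,
    max_failed_fraction: float = 0.20,
) -> "BootstrapResults":
    """Animal-level bootstrap of the pooled NB2 RSPF.

    Returns the pooled-data point fit together with B replicate coefficient
    vectors, replicate-SD standard errors and central-percentile CIs.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    animals, C, totals = _per_animal_counts(locations, units)
    m = len(animals)
    if m < 2:
        raise ValueError("bootstrap requires >=2 experimental units (animals)")
    names = list(units.covariate_names if covariates is None else covariates)
    exog = pd.DataFrame(units.covariates(names), columns=names)

    pooled = units.with_counts(C.sum(axis=0))
    point = NegativeBinomialRSPF.from_units(
        pooled, covariates=names, offset_total=int(totals.sum())
    ).fit()

    rng = np.random.default_rng(seed)
    reps, theta_reps = [], []
    n_failed = 0
    start_beta = point.params.to_numpy()
    for _ in range(B):
        idx = rng.integers(0, m, size=m)
        counts_b = C[idx].sum(axis=0)
        T_b = int(totals[idx].sum())
        try:
            model = NegativeBinomialRSPF(counts_b, exog, offset_total=T_b, radius=units.radius)
            res = model.fit(start_params=start_beta, start_theta=point.theta)
        except (ConvergenceError, ValueError) as exc:
            n_failed += 1
            logger.warning("bootstrap replicate failed and was dropped: %s", exc)
            continue
        reps.append(res.params.to_numpy())
        theta_reps.append(res.theta)
    if n_failed > max_failed_fraction * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed to converge "
            f"(> {max_failed_fraction:.0%}); the model is too unstable to bootstrap"
        )
    reps = np.asarray(reps)
    alpha = (1.0 - level) / 2.0
    return BootstrapResults(
        replicates=pd.DataFrame(reps, columns=point.model.exog_names),
        theta_reps=np.asarray(theta_reps),
        point_fit=point,
        se=pd.Series(reps.std(axis=0, ddof=1), index=point.model.exog_names),
        # linear interpolation between order statistics (type-7 convention)
        ci_lower=pd.Series(np.quantile(reps, alpha, axis=0), index=point.model.exog_names),
        ci_upper=pd.Series(np.quantile(reps, 1 - alpha, axis=0), index=point.model.exog_names),
        level=level,
        B=B,
        n_failed=n_failed,
        animals=list(animals),
        units=units,
        covariate_names=names,
    )


@dataclass
class BootstrapResults:
    """B replicate coefficient vectors plus derived SEs and percentile CIs."""

    replicates: pd.DataFrame
    theta_reps: np.ndarray
    point_fit: RSPFResults
    se: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    level: float
    B: int
    n_failed: int
    animals: list = field(default_factory=list)
    units: UnitTable | None = None
    covariate_names: list = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table in the shape of a published RSPF results table:
        estimate, ML SE, bootstrap SE, percentile CI limits."""
        return pd.DataFrame(
            {
                "estimate": self.point_fit.params,
                "ml_se": self.point_fit.bse,
                "bootstrap_se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )

    def summary(self) -> str:
        df = self.summary_frame()
        lines = [
            f"Animal-level bootstrap of the NB2 RSPF "
            f"({self.B} replicates, {self.n_failed} failed; "
            f"{len(self.animals)} animals; {int(self.level * 100)}% percentile CIs)",
            "=" * 78,
            f"{'':<26s}{'coef':>9s}{'ML SE':>9s}{'boot SE':>9s}{'CI lo':>9s}{'CI hi':>9s}",
        ]
        for name, row in df.iterrows():
            lines.append(
                f"{name:<26s}{row['estimate']:>9.4f}{row['ml_se']:>9.4f}"
                f"{row['bootstrap_se']:>9.4f}{row['ci_lower']:>9.4f}{row['ci_upper']:>9.4f}"
            )
        return "\n".join(lines)

    def marginal_profile(self, covariate, n_grid=50, reference=None, level=None):
        from .prediction import marginal_profile

        return marginal_profile(
            self, covariate, n_grid=n_grid, reference=reference,
            level=self.level if level is None else level,
        )

    def to_dict(self) -> dict:
        return {
            "point_fit": self.point_fit.to_dict(),
            "bootstrap_se": {k: float(v) for k, v in self.se.items()},
            "ci_lower": {k: float(v) for k, v in self.ci_lower.items()},
            "ci_upper": {k: float(v) for k, v in self.ci_upper.items()},
            "level": self.level,
            "B": self.B,
            "n_failed": self.n_failed,
            "animals": list(map(str, self.animals)),
            "theta_replicates": [float(t) for t in self.theta_reps],
            "replicates": {c: [float(v) for v in self.replicates[c]] for c in self.replicates},
        }


def two_stage(locations: pd.DataFrame, units: UnitTable, covariates=None) -> "TwoStageResults":
    """Fit one NB2 model per animal, then average coefficients across animals.

    Every estimable animal contributes equally; the population SE is the SD
    of per-animal coefficients over sqrt(m).  Because coefficients (not
    predictions) are averaged, the population model is an RSF — its
    predictions are geometric means of the per-animal models — rather than
    an RSPF.  Animals whose counts cannot support a fit (fewer occupied
    units than parameters, or non-convergence) are flagged and excluded,
    never silently dropped.
    """
    animals, C, totals = _per_animal_counts(locations, units)
    names = list(units.covariate_names if covariates is None else covariates)
    exog = pd.DataFrame(units.covariates(names), columns=names)
    p1 = len(names) + 1

    fits, kept, excluded = [], [], []
    for a, animal in enumerate(animals):
        counts = C[a]
        if int((counts > 0).sum()) < p1 + 1:
            excluded.append((animal, "too few occupied units"))
            logger.warning("two-stage: animal %s excluded (too few occupied units)", animal)
            continue
        try:
            res = NegativeBinomialRSPF(
                counts, exog, offset_total=int(totals[a]), radius=units.radius
            ).fit()
        except (ConvergenceError, ValueError) as exc:
            excluded.append((animal, str(exc)))
            logger.warning("two-stage: animal %s excluded (%s)", animal, exc)
            continue
        fits.append(res)
        kept.append(animal)
    if len(fits) < 2:
        raise ValueError("two-stage averaging requires >=2 estimable animals")
    coef = np.vstack([f.params.to_numpy() for f in fits])
    m = len(fits)
    index = fits[0].model.exog_names
    return TwoStageResults(
        per_animal_fits=fits,
        animals=kept,
        excluded=excluded,
        mean_params=pd.Series(coef.mean(axis=0), index=index),
        se_of_mean=pd.Series(coef.std(axis=0, ddof=1) / np.sqrt(m), index=index),
        m=m,
    )


@dataclass
class TwoStageResults:
    per_animal_fits: list
    animals: list
    excluded: list
    mean_params: pd.Series
    se_of_mean: pd.Series
    m: int

    def summary(self) -> str:
        lines = [
            f"Two-stage RSF: unweighted mean of {self.m} per-animal NB2 fits",
            f"(excluded: {', '.join(a for a, _ in self.excluded) or 'none'})",
            "=" * 58,
            f"{'':<26s}{'mean coef':>12s}{'SE of mean':>12s}",
        ]
        for name in self.mean_params.index:
            lines.append(
                f"{name:<26s}{self.mean_params[name]:>12.4f}{self.se_of_mean[name]:>12.4f}"
            )
        lines.append("-" * 58)
        lines.append("Averaged coefficients give an RSF (geometric-mean predictions).")
        return "\n".join(lines)


def rate_ratio(coef: float, delta: float = 1.0) -> float:
    """Percent change in expected relative use per ``delta`` change in a covariate.

    100*(exp(coef*delta) - 1), other covariates held fixed.  Often labelled
    an "odds ratio" in the wildlife literature, but under a log link
    exp(coef) is a rate (risk) ratio, not an odds ratio.
    """
    return float(100.0 * np.expm1(coef * delta))
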