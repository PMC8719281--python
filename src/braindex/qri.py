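"""Quantile Regression Index (QRI) of deviation from normative aging.

A linear normative-modeling analog of the "brain age" construct. For every
regional phenotype, quantile regressions of the value on age are fitted at
the 5th, 50th and 95th percentiles over the whole sample. Each subject's
regional value is then scored against the fitted age-conditional band:

* +1 — below the 5th-percentile line (structure older than expected),
* -1 — above the 95th-percentile line (younger than expected),
*  0 — otherwise (boundary equality scores 0; inequalities are strict).

Regional scores are averaged within tissue class (cortical thickness,
subcortical volume, white-matter FA) and the whole-brain QRI is the
unweighted mean of the three tissue QRIs, so every QRI lies in [-1, 1].

The check-loss minimization is solved exactly as a linear program (HiGHS),
so fitted lines are vertex solutions interpolating data points.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .errors import (ConfigurationError, DegenerateDesignError,
                     InsufficientDataError)

logger = logging.getLogger(__name__)

QRI_TAUS = (0.05, 0.50, 0.95)

_TISSUE_QRI = {"thickness": "qri_thickness",
               "subcortical_volume": "qri_subcort",
               "FA": "qri_fa"}


@dataclass(frozen=True)
class QuantileFit:
    """One fitted conditional-quantile line: value ~ intercept + slope*age."""

    phenotype: str
    tau: float
    intercept: float
    slope: float
    n: int
    reference: str = "whole_sample"

    def predict(self, age) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(age, dtype=float)

    def check_loss(self, y, age) -> float:
        u = np.asarray(y, float) - self.predict(age)
        return float(np.sum(u * (self.tau - (u < 0))))


def fit_quantile_regression(y, age, tau: float,
                            phenotype: str = "") -> QuantileFit:
    """Minimize the tau check loss of ``y ~ intercept + slope*age`` exactly.

    Formulated as the standard LP with split positive/negative residuals and
    solved with HiGHS; the solution is a basic (vertex) solution, hence for
    non-degenerate data a line through two observations. Constant ``y``
    short-circuits to (c, 0).
    """
    y = np.asarray(pd.Series(y), float)
    age = np.asarray(pd.Series(age), float)
    if y.shape != age.shape:
        raise ConfigurationError("y and age must have equal length")
    if not 0.0 < tau < 1.0:
        raise ConfigurationError(f"tau must be in (0, 1), got {tau}")
    mask = np.isfinite(y) & np.isfinite(age)
    y, age = y[mask], age[mask]
    n = len(y)
    if n < 10:
        raise InsufficientDataError(
            f"quantile regression needs >= 10 paired observations, got {n}")
    if np.ptp(age) == 0:
        raise DegenerateDesignError("age is constant; slope unidentifiable")
    if np.ptp(y) == 0:
        return QuantileFit(phenotype, float(tau), float(y[0]), 0.0, n)

    # Work on standardized y and centered age for conditioning; quantile
    # regression is affine-equivariant so the solution maps back exactly.
    y_loc, y_scale = y.mean(), y.std()
    a_loc = age.mean()
    ys = (y - y_loc) / y_scale
    ac = age - a_loc

    # Dual of  min tau*1'u+ + (1-tau)*1'u-  s.t.  X b + u+ - u- = y :
    #   max y'nu  s.t.  X'nu = 0,  tau - 1 <= nu <= tau.
    # The marginals of the two equality constraints recover -(intercept,
    # slope) of the (vertex) primal solution; only 2 constraints, so HiGHS
    # solves this an order of magnitude faster than the primal at large n.
    X = np.column_stack([np.ones(n), ac])
    res = linprog(-ys, A_eq=X.T, b_eq=np.zeros(2),
                  bounds=np.column_stack([np.full(n, tau - 1.0),
                                          np.full(n, tau)]),
                  method="highs")
    if res.success:
        c0, c1 = -res.eqlin.marginals
    else:
        # Fall back to the (slower, very robust) primal formulation.
        eye = sparse.identity(n, format="csc")
        A_eq = sparse.hstack([sparse.csc_matrix(X), eye, -eye], format="csc")
        c = np.concatenate([[0.0, 0.0], np.full(n, tau),
                            np.full(n, 1.0 - tau)])
        bounds = [(None, None)] * 2 + [(0.0, None)] * (2 * n)
        res = linprog(c, A_eq=A_eq, b_eq=ys, bounds=bounds, method="highs")
        if not res.success:  # pragma: no cover - feasible bounded LP
            raise RuntimeError(
                f"quantile LP failed for {phenotype!r}: {res.message}")
        c0, c1 = res.x[:2]
    slope = y_scale * c1
    intercept = y_scale * c0 + y_loc - slope * a_loc
    return QuantileFit(phenotype, float(tau), float(intercept),
                       float(slope), n)


def fit_quantile_models(y, age, taus=QRI_TAUS,
                        phenotype: str = "") -> dict[float, QuantileFit]:
    return {tau: fit_quantile_regression(y, age, tau, phenotype)
            for tau in taus}


def score_region(values, fit05: QuantileFit, fit95: QuantileFit,
                 age) -> np.ndarray:
    """Score values against the fitted 5th/95th percentile lines.

    Vectorized over subjects; missing values yield missing scores. Crossed
    quantiles (5th prediction above 95th) are scored by the same strict rules
    and logged with the phenotype and the affected age range.
    """
    if fit05.phenotype != fit95.phenotype:
        raise ConfigurationError(
            f"fits are for different phenotypes: {fit05.phenotype!r} vs "
            f"{fit95.phenotype!r}")
    v = np.asarray(pd.Series(values), float)
    a = np.asarray(pd.Series(age), float)
    low = fit05.predict(a)
    high = fit95.predict(a)
    crossed = low > high
    if crossed.any():
        ages = a[crossed]
        warnings.warn(
            f"quantile crossing for {fit05.phenotype!r} at {int(crossed.sum())}"
            f" ages in [{ages.min():.1f}, {ages.max():.1f}]", stacklevel=2)
        logger.warning("quantile crossing: phenotype=%s n=%d age=[%.1f, %.1f]",
                       fit05.phenotype, int(crossed.sum()),
                       ages.min(), ages.max())
    score = np.where(v < low, 1.0, np.where(v > high, -1.0, 0.0))
    score[~np.isfinite(v)] = np.nan
    return score


def aggregate_qri(region_scores: pd.DataFrame,
                  tissue_map: pd.Series) -> pd.DataFrame:
    """Average -1/0/+1 region scores per tissue and whole-brain.

    Tissue QRIs are means over non-missing region scores; the whole-brain QRI
    is the unweighted mean of the three tissue QRIs and is missing when any
    tissue QRI is missing.
    """
    unmapped = [p for p in region_scores.columns if p not in tissue_map.index]
    if unmapped:
        raise ConfigurationError(
            f"region scores not in tissue_map: {unmapped[:5]}")
    out = pd.DataFrame(index=region_scores.index)
    for tissue, column in _TISSUE_QRI.items():
        members = [p for p in region_scores.columns
                   if tissue_map[p] == tissue]
        if not members:
            warnings.warn(f"no scored regions for tissue {tissue!r}; "
                          f"{column} and qri_whole are missing", stacklevel=2)
            out[column] = np.nan
            continue
        out[column] = region_scores[members].mean(axis=1, skipna=True)
    out["qri_whole"] = out[list(_TISSUE_QRI.values())].mean(axis=1,
                                                            skipna=False)
    return out


@dataclass
class QRIResult:
    region_scores: pd.DataFrame   # subjects x phenotypes, values in {-1,0,+1}
    scores: pd.DataFrame          # tissue QRIs + qri_whole
    fits: pd.DataFrame            # long table: phenotype, stratum, tau, ...


def compute_qri(phenotypes: pd.DataFrame, covariates: pd.DataFrame,
                tissue_map: pd.Series, taus=QRI_TAUS,
                stratify_by_sex: bool = False) -> QRIResult:
    """Fit normative quantile lines per phenotype and score every subject.

    Fits use the whole sample with age as the only predictor (the default);
    with ``stratify_by_sex`` the three quantile lines are fitted separately
    within each sex and subjects are scored against their own stratum.
    """
    taus = tuple(sorted(taus))
    if len(taus) != 3:
        raise ConfigurationError("QRI needs exactly three taus (low, mid, high)")
    age = covariates.loc[phenotypes.index, "age"]
    strata = ([("all", np.ones(len(phenotypes), bool))] if not stratify_by_sex
              else [(f"sex={s:g}",
                     covariates.loc[phenotypes.index, "sex"].to_numpy() == s)
                    for s in np.unique(covariates["sex"])])

    scores = pd.DataFrame(np.nan, index=phenotypes.index,
                          columns=phenotypes.columns)
    fit_rows = []
    for name, col in phenotypes.items():
        for label, in_stratum in strata:
            fits = fit_quantile_models(col[in_stratum], age[in_stratum],
                                       taus, phenotype=name)
            scores.loc[in_stratum, name] = score_region(
                col[in_stratum], fits[taus[0]], fits[taus[2]],
                age[in_stratum])
            for tau, fit in fits.items():
                fit_rows.append({"phenotype": name, "stratum": label,
                                 "tau": tau, "intercept": fit.intercept,
                                 "slope": fit.slope, "n": fit.n})
    return QRIResult(region_scores=scores,
                     scores=aggregate_qri(scores, tissue_map),
                     fits=pd.DataFrame(fit_rows))
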