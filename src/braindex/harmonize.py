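"""Covariate residualization and rank-based inverse-normal transformation.

Raw regional phenotypes are converted into a matrix of approximately
standard-normal deviation scores (the P vectors): each phenotype is first
regressed on an intercept plus a covariate set (age, sex, ICV by default)
over a reference sample, and the residuals are then mapped through the
rank-based inverse-normal (Blom) transform. Missing values are preserved
throughout — no imputation anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (AlignmentError, ConfigurationError, DegenerateDesignError,
                     InsufficientDataError)

#: Blom rank offset c in (r - c) / (n - 2c + 1); with c = 3/8 this is the
#: classical (r - 3/8) / (n + 1/4) plotting position.
BLOM_C = 0.375

DEFAULT_COVARIATES = ("age", "sex", "icv")


@dataclass
class ZMatrix:
    """Covariate-residualized, inverse-normal-transformed deviations.

    ``data`` holds one approximately N(0,1) column per phenotype;
    ``provenance`` records how it was produced (covariate set, reference
    sample, Blom constant) and is written as a JSON sidecar by the pipeline.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _design_matrix(covariates: pd.DataFrame, covariate_set,
                   rows: pd.Index) -> np.ndarray:
    missing = rows.difference(covariates.index)
    if len(missing):
        raise AlignmentError(
            f"{len(missing)} subjects have phenotype data but no covariates "
            f"(first: {missing[0]!r})")
    cov = covariates.loc[rows, list(covariate_set)]
    for name in covariate_set:
        col = cov[name].to_numpy(float)
        if not np.all(np.isfinite(col)):
            raise AlignmentError(f"covariate {name!r} has missing values")
        if np.ptp(col) == 0:
            raise DegenerateDesignError(
                f"covariate {name!r} is constant over the reference sample")
    X = np.column_stack([np.ones(len(rows)), cov.to_numpy(float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError(
            f"rank-deficient covariate design for set {tuple(covariate_set)}")
    return X


def residualize(
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_set=DEFAULT_COVARIATES,
    reference: pd.Index | None = None,
) -> pd.DataFrame:
    """Remove covariate effects from every phenotype column by OLS.

    Coefficients are estimated over ``reference`` (default: all subjects) and
    the fitted values are subtracted for *all* subjects, so non-reference
    subjects are expressed as deviations from the reference-sample norm.
    Missing phenotype entries stay missing.
    """
    if not len(tuple(covariate_set)):
        raise ConfigurationError("covariate_set must be non-empty")
    rows = phenotypes.index
    ref = rows if reference is None else rows.intersection(reference)
    X_all = _design_matrix(covariates, covariate_set, rows)
    ref_pos = rows.get_indexer(ref)

    out = {}
    for name, col in phenotypes.items():
        y = col.to_numpy(float)
        mask = np.isfinite(y)
        fit_rows = ref_pos[mask[ref_pos]]
        if len(fit_rows) < X_all.shape[1] + 1:
            raise InsufficientDataError(
                f"phenotype {name!r}: only {len(fit_rows)} reference "
                f"observations for a {X_all.shape[1]}-parameter fit")
        beta, *_ = np.linalg.lstsq(X_all[fit_rows], y[fit_rows], rcond=None)
        resid = np.full_like(y, np.nan)
        resid[mask] = y[mask] - X_all[mask] @ beta
        out[name] = resid
    return pd.DataFrame(out, index=rows)


def inverse_normal_transform(values, c: float = BLOM_C) -> np.ndarray:
    """Map values to normal quantiles of their Blom plotting positions.

    Value with (average, i.e. tie-sharing) rank r among n non-missing entries
    maps to ``Phi^-1((r - c) / (n - 2c + 1))``. Missing entries stay missing;
    an all-tied input maps to zeros with a warning.
    """
    vals = np.asarray(pd.Series(values), dtype=float)
    out = np.full(vals.shape, np.nan)
    mask = np.isfinite(vals)
    n = int(mask.sum())
    if n < 2:
        raise InsufficientDataError(
            "inverse-normal transform needs >= 2 non-missing values")
    if np.ptp(vals[mask]) == 0:
        warnings.warn("all values identical; inverse-normal transform is 0",
                      stacklevel=2)
        out[mask] = 0.0
        return out
    ranks = stats.rankdata(vals[mask], method="average")
    out[mask] = stats.norm.ppf((ranks - c) / (n - 2 * c + 1))
    return out


def _control_anchored_transform(resid: np.ndarray, is_ref: np.ndarray,
                                c: float) -> np.ndarray:
    """Blom-transform reference subjects; interpolate the rest through the
    reference empirical distribution (clamped at its extremes)."""
    out = np.full(resid.shape, np.nan)
    mask = np.isfinite(resid)
    ref_mask = mask & is_ref
    ref_vals = resid[ref_mask]
    if len(ref_vals) < 2:
        raise InsufficientDataError(
            "control-anchored transform needs >= 2 reference values")
    out[ref_mask] = inverse_normal_transform(ref_vals, c=c)
    other = mask & ~is_ref
    if other.any():
        order = np.argsort(ref_vals, kind="stable")
        x_sorted = ref_vals[order]
        z_sorted = out[ref_mask][order]
        # np.interp requires strictly usable x; collapse exact ties.
        x_uniq, idx = np.unique(x_sorted, return_index=True)
        out[other] = np.interp(resid[other], x_uniq, z_sorted[idx])
    return out


def harmonize(
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_set=DEFAULT_COVARIATES,
    reference: str = "all",
    control_index: pd.Index | None = None,
    tissue_map: pd.Series | None = None,
    icv_tissues=None,
    blom_c: float = BLOM_C,
) -> ZMatrix:
    """Residualize then inverse-normal-transform every phenotype column.

    Parameters
    ----------
    reference
        ``"all"`` (default): regression and ranks use the whole sample.
        ``"controls"``: coefficients are estimated on ``control_index`` only
        and applied to everyone; the normal transform then uses
        control-anchored ranks, with non-controls mapped through the control
        empirical distribution by interpolation.
    icv_tissues
        Optional set of tissue classes for which ICV is included as a
        covariate (requires ``tissue_map``); ``None`` regresses ICV from all
        classes.
    """
    if reference not in ("all", "controls"):
        raise ConfigurationError(f"unknown reference {reference!r}")
    if reference == "controls" and control_index is None:
        raise ConfigurationError(
            "reference='controls' requires control_index")
    if icv_tissues is not None and tissue_map is None:
        raise ConfigurationError("icv_tissues requires tissue_map")

    ref_index = None if reference == "all" else control_index

    if icv_tissues is None or "icv" not in covariate_set:
        resid = residualize(phenotypes, covariates, covariate_set, ref_index)
    else:
        with_icv = [p for p in phenotypes.columns
                    if tissue_map.get(p) in set(icv_tissues)]
        without = [p for p in phenotypes.columns if p not in set(with_icv)]
        reduced = tuple(c for c in covariate_set if c != "icv")
        parts = []
        if with_icv:
            parts.append(residualize(phenotypes[with_icv], covariates,
                                     covariate_set, ref_index))
        if without:
            parts.append(residualize(phenotypes[without], covariates,
                                     reduced, ref_index))
        resid = pd.concat(parts, axis=1)[phenotypes.columns]

    if reference == "all":
        z = pd.DataFrame({k: inverse_normal_transform(resid[k], c=blom_c)
                          for k in resid.columns}, index=resid.index)
    else:
        is_ref = resid.index.isin(control_index)
        z = pd.DataFrame(
            {k: _control_anchored_transform(resid[k].to_numpy(float), is_ref,
                                            blom_c)
             for k in resid.columns},
            index=resid.index)

    provenance = {
        "covariate_set": list(covariate_set),
        "reference": reference,
        "blom_c": blom_c,
        "icv_tissues": None if icv_tissues is None else sorted(icv_tissues),
        "n_subjects": int(len(z)),
    }
    return ZMatrix(data=z, provenance=provenance)
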