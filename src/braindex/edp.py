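"""ENIGMA Dot Product (EDP) and whole-brain comparison biomarkers.

The EDP scores how closely an individual's regional deviation profile aligns
with a disorder's meta-analytic case-control deficit pattern:

    EDP = (1/N) * sum_i  P_i * E_i

where P_i is the subject's covariate-residualized, inverse-normal-transformed
deviation for phenotype i and E_i the signed meta-analytic effect size
(structural deficits negative). Deviation in the deficit direction (P and E
of the same sign) increases the score. With missing data the sum runs over
the subject's available phenotypes and N is their count, keeping the scale
comparable across subjects.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError
from .harmonize import ZMatrix


def _as_frame(z) -> pd.DataFrame:
    return z.data if isinstance(z, ZMatrix) else z


def compute_edp(z, effects: pd.Series) -> pd.Series:
    """Per-subject normalized dot product of deviations with effect sizes.

    ``effects`` must name at least one ZMatrix column; subjects with zero
    non-missing shared phenotypes get a missing EDP (counted in a warning).
    """
    zf = _as_frame(z)
    shared = [p for p in effects.index if p in zf.columns]
    if not shared:
        raise AlignmentError(
            "no phenotype shared between ZMatrix and effect vector")
    sub = zf[shared]
    e = effects.loc[shared].to_numpy(float)
    prod = sub.to_numpy(float) * e[None, :]
    n_avail = np.isfinite(prod).sum(axis=1)
    with np.errstate(invalid="ignore"):
        edp = np.nansum(prod, axis=1) / np.where(n_avail > 0, n_avail, np.nan)
    n_empty = int((n_avail == 0).sum())
    if n_empty:
        warnings.warn(
            f"{n_empty} subjects have no non-missing phenotype shared with "
            f"the effect vector; their EDP is missing", stacklevel=2)
    return pd.Series(edp, index=zf.index, name="edp")


_TISSUE_COLUMN = {"thickness": "mean_thickness_z",
                  "subcortical_volume": "mean_subcort_z",
                  "FA": "mean_fa_z"}


def whole_brain_means(z, tissue_map: pd.Series) -> pd.DataFrame:
    """Per-subject mean Z within each tissue class (the comparison biomarkers)."""
    zf = _as_frame(z)
    uncovered = [p for p in zf.columns if p not in tissue_map.index]
    if uncovered:
        raise ConfigurationError(
            f"tissue_map does not cover phenotypes: {uncovered[:5]}")
    out = {}
    for tissue, column in _TISSUE_COLUMN.items():
        members = [p for p in zf.columns if tissue_map[p] == tissue]
        if not members:
            raise ConfigurationError(f"tissue class {tissue!r} has no phenotypes")
        out[column] = zf[members].mean(axis=1, skipna=True)
    return pd.DataFrame(out, index=zf.index)


def read_effect_vector(path: str | Path) -> pd.Series:
    """Read a two-column (phenotype, effect) tab-separated file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"effect vector file not found: {path}")
    table = pd.read_csv(path, sep="\t", comment="#")
    if table.shape[1] < 2:
        raise ConfigurationError(
            f"effect vector file {path} must have (phenotype, effect) columns")
    series = pd.Series(table.iloc[:, 1].to_numpy(float),
                       index=table.iloc[:, 0], name="effect")
    if not (series != 0).any():
        raise ConfigurationError("effect vector has no nonzero entry")
    return series


def write_effect_vector(effects: pd.Series, path: str | Path) -> None:
    frame = effects.rename("effect").to_frame()
    frame.index.name = "phenotype"
    frame.to_csv(path, sep="\t", float_format="%.6g")
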