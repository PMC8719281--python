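"""Group-severity analyses.

Reproduces the group-level and individual-level severity analyses: biomarker
means per depression group (age/sex-corrected and z-scaled over the cohort),
the 4-point correlation between group-mean biomarker and group-mean symptom
severity, and individual Pearson correlations between each biomarker and the
continuous severity score within the pooled depression groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, InsufficientDataError
from .harmonize import residualize
from .synthetic import GROUPS

DEPRESSION_GROUPS = ("subclinical", "single", "recurrent")


def correct_and_zscore(values: pd.DataFrame, covariates: pd.DataFrame,
                       covariate_set=("age", "sex")) -> pd.DataFrame:
    """Residualize each column on age/sex over the cohort, then z-scale.

    A constant column cannot be z-scaled; it is reported as zeros with a
    warning rather than NaN, so degenerate biomarkers stay plottable.
    """
    resid = residualize(values, covariates, covariate_set)
    out = {}
    for name, col in resid.items():
        sd = col.std(ddof=1)
        # a constant input leaves only OLS rounding noise (~1e-15 of the
        # value scale) in the residual; treat that as degenerate too
        scale = max(1.0, float(values[name].abs().max(skipna=True) or 0.0))
        if not np.isfinite(sd) or sd <= 1e-10 * scale:
            warnings.warn(f"biomarker {name!r} is constant; z-scores set to 0",
                          stacklevel=2)
            out[name] = col * 0.0
        else:
            out[name] = (col - col.mean()) / sd
    return pd.DataFrame(out, index=values.index)


@dataclass
class GroupSummary:
    """Group-wise means/SEs of z-scaled biomarkers plus mean severity."""

    table: pd.DataFrame            # index: group; n, severity plus mean/se
    biomarkers: tuple[str, ...]


def group_profile(scores: pd.DataFrame, labels: pd.DataFrame,
                  covariates: pd.DataFrame) -> GroupSummary:
    """Per-group biomarker profile after age/sex correction and z-scaling."""
    unlabeled = scores.index.difference(labels.index)
    if len(unlabeled):
        raise AnalysisError(f"{len(unlabeled)} subjects lack group labels")
    z = correct_and_zscore(scores, covariates)
    group = labels.loc[z.index, "group"]
    rows = []
    for g in GROUPS:
        mask = (group == g).to_numpy()
        n = int(mask.sum())
        if n < 2:
            raise AnalysisError(f"group {g!r} has {n} subjects (needs >= 2)")
        row = {"group": g, "n": n,
               "severity": float(labels.loc[z.index[mask], "severity"].mean())}
        for b in scores.columns:
            vals = z.loc[mask, b].dropna()
            row[f"{b}_mean"] = float(vals.mean())
            row[f"{b}_se"] = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("group")
    return GroupSummary(table=table, biomarkers=tuple(scores.columns))


def groupmean_correlation(summary: GroupSummary, biomarker: str) -> dict:
    """Pearson r (and r^2) of the 4 (mean severity, mean biomarker) points.

    Only four points enter, so the result is descriptive (df = 2); no p-value
    is attached.
    """
    t = summary.table
    x = t["severity"].to_numpy(float)
    y = t[f"{biomarker}_mean"].to_numpy(float)
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError(
            f"group-mean correlation undefined for {biomarker!r} "
            "(zero variance in severity or biomarker means)")
    r = float(np.corrcoef(x, y)[0, 1])
    return {"biomarker": biomarker, "r": r, "r2": r * r,
            "n_groups": len(x), "df": len(x) - 2,
            "note": "4 group means; descriptive only"}


@dataclass(frozen=True)
class SymptomAssociation:
    biomarker: str
    r: float
    t: float
    p: float
    n: int
    subset: str


def _r_to_t_p(r: float, n: int) -> tuple[float, float]:
    df = n - 2
    if abs(r) >= 1.0:
        return float(np.sign(r) * np.inf), float(np.finfo(float).tiny)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(max(p, np.finfo(float).tiny))


def symptom_association(biomarker: pd.Series, labels: pd.DataFrame,
                        covariates: pd.DataFrame,
                        subset=DEPRESSION_GROUPS) -> SymptomAssociation:
    """Pearson correlation of an age/sex-corrected biomarker with severity.

    ``subset`` selects the groups pooled for the correlation (default: the
    three depression groups; pass all four group names for a whole-cohort
    analysis). t and the two-sided p come from the exact t-distribution with
    n - 2 degrees of freedom.
    """
    if not len(tuple(subset)):
        raise AnalysisError("subset must name at least one group")
    name = biomarker.name or "biomarker"
    corrected = correct_and_zscore(biomarker.to_frame(name), covariates)[name]
    mask = labels.loc[corrected.index, "group"].isin(subset)
    sev = labels.loc[corrected.index, "severity"]
    use = mask & corrected.notna() & sev.notna()
    n = int(use.sum())
    if n < 4:
        raise InsufficientDataError(
            f"symptom association needs >= 4 subjects, got {n}")
    r = float(np.corrcoef(corrected[use], sev[use])[0, 1])
    t, p = _r_to_t_p(r, n)
    return SymptomAssociation(biomarker=name, r=r, t=t, p=p, n=n,
                              subset="+".join(subset))
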