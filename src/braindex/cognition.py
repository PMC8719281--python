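"""Cognition pattern-matching analyses.

Three pieces:

* the cognitive deficit profile — per-test two-sample t (pooled variance)
  of the pooled depression groups versus controls, signed so that worse
  performance in the depressed groups is positive;
* biomarker-cognition association profiles ("model 1") — per-test simple
  linear regression of the (age/sex-corrected) cognitive score on a brain
  index within a subject subset, reported as the slope t-statistic with a
  deficit-sign convention (higher index with worse performance => positive t);
* profile comparison — Pearson correlation between two 9-long t-profiles
  (the pattern correlation) plus mean |t| per profile and a paired t-test of
  |t| across the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, AnalysisError, DegenerateDesignError
from .group_analysis import DEPRESSION_GROUPS, _r_to_t_p, correct_and_zscore

_P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class AssociationProfile:
    """Per-cognitive-test association statistics for one contrast/biomarker."""

    name: str
    table: pd.DataFrame    # index: test; columns t, r, p, n

    @property
    def tests(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    @property
    def t(self) -> pd.Series:
        return self.table["t"]


def cognitive_deficit_profile(cognition: pd.DataFrame, labels: pd.DataFrame,
                              covariates: pd.DataFrame,
                              case_groups=DEPRESSION_GROUPS,
                              name: str = "MDD-vs-control",
                              deficit_positive: bool = True,
                              ) -> AssociationProfile:
    """Two-sample t-profile of cases (pooled) versus controls per test.

    Cognitive scores are age/sex-corrected first. With ``deficit_positive``
    (the default) the t is oriented control - case, so lower case scores give
    positive t.
    """
    z = correct_and_zscore(cognition, covariates)
    group = labels.loc[z.index, "group"]
    case = group.isin(case_groups)
    control = group == "control"
    if case.sum() < 10 or control.sum() < 10:
        raise AnalysisError(
            f"deficit profile needs >= 10 subjects per arm, got "
            f"{int(case.sum())} cases / {int(control.sum())} controls")
    rows = []
    for test in cognition.columns:
        a = z.loc[control, test].dropna()
        b = z.loc[case, test].dropna()
        n = len(a) + len(b)
        if np.ptp(np.concatenate([a, b])) == 0:
            warnings.warn(f"cognitive test {test!r} is constant; t undefined",
                          stacklevel=2)
            rows.append({"test": test, "t": np.nan, "r": np.nan,
                         "p": np.nan, "n": n})
            continue
        t, p = stats.ttest_ind(a, b, equal_var=True)
        if not deficit_positive:
            t = -t
        df = n - 2
        r = float(t / np.sqrt(t * t + df))  # point-biserial equivalent
        rows.append({"test": test, "t": float(t), "r": r,
                     "p": float(max(p, _P_FLOOR)), "n": n})
    return AssociationProfile(name=name,
                              table=pd.DataFrame(rows).set_index("test"))


def biomarker_cognition_profile(biomarker: pd.Series, cognition: pd.DataFrame,
                                labels: pd.DataFrame, covariates: pd.DataFrame,
                                subset: str = "controls",
                                name: str | None = None,
                                deficit_sign: bool = True,
                                ) -> AssociationProfile:
    """Model-1 profile: cognition ~ biomarker, per test, within a subset.

    ``subset`` is ``"controls"`` or ``"mdd"`` (the three depression groups
    pooled). Both sides are age/sex-corrected. The reported t is the slope
    t-statistic; with ``deficit_sign`` it is negated so that a biomarker whose
    elevation accompanies worse performance scores positive, matching the
    deficit-profile orientation.
    """
    groups = {"controls": ("control",), "mdd": DEPRESSION_GROUPS}[subset]
    bname = biomarker.name or "biomarker"
    both = correct_and_zscore(
        pd.concat([biomarker.rename(bname), cognition], axis=1), covariates)
    mask = labels.loc[both.index, "group"].isin(groups)
    x_all = both.loc[mask, bname]
    if x_all.dropna().nunique() <= 1:
        raise DegenerateDesignError(
            f"biomarker {bname!r} is constant within subset {subset!r}")
    rows = []
    for test in cognition.columns:
        pair = pd.concat([x_all, both.loc[mask, test]], axis=1).dropna()
        n = len(pair)
        x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        r = float(np.corrcoef(x, y)[0, 1]) if np.ptp(y) > 0 else np.nan
        if not np.isfinite(r):
            rows.append({"test": test, "t": np.nan, "r": np.nan,
                         "p": np.nan, "n": n})
            continue
        r = float(np.clip(r, -1.0, 1.0))
        t, p = _r_to_t_p(r, n)   # slope t == correlation t in simple regression
        if deficit_sign:
            t, r = -t, -r
        rows.append({"test": test, "t": t, "r": r, "p": p, "n": n})
    return AssociationProfile(
        name=name or f"{bname}-in-{subset}",
        table=pd.DataFrame(rows).set_index("test"))


@dataclass(frozen=True)
class ProfileComparison:
    profile_a: str
    profile_b: str
    pattern_r: float
    pattern_p: float
    df: int                       # n_tests - 2 small-sample caveat
    mean_abs_t_a: float
    sd_abs_t_a: float
    mean_abs_t_b: float
    sd_abs_t_b: float
    paired_p: float
    degenerate: bool = False


def compare_profiles(a: AssociationProfile, b: AssociationProfile,
                     use_abs_for_paired: bool = True) -> ProfileComparison:
    """Pattern correlation of two t-profiles plus paired magnitude comparison.

    ``use_abs_for_paired`` pairs |t| across tests (association strength);
    set False to pair signed t.
    """
    if a.tests != b.tests:
        raise AlignmentError(
            f"profiles have different test lists: {a.tests} vs {b.tests}")
    ta, tb = a.t.to_numpy(float), b.t.to_numpy(float)
    ok = np.isfinite(ta) & np.isfinite(tb)
    if ok.sum() < 3:
        raise AnalysisError("need >= 3 finite t pairs to compare profiles")
    ta, tb = ta[ok], tb[ok]
    if np.ptp(ta) == 0 or np.ptp(tb) == 0:
        raise AnalysisError("pattern correlation undefined: constant t-profile")
    r = float(np.corrcoef(ta, tb)[0, 1])
    _, pr = _r_to_t_p(np.clip(r, -1, 1), len(ta))

    pa = np.abs(ta) if use_abs_for_paired else ta
    pb = np.abs(tb) if use_abs_for_paired else tb
    diffs = pa - pb
    degenerate = bool(np.ptp(diffs) == 0)
    if degenerate:
        paired_p = 1.0
    else:
        _, paired_p = stats.ttest_rel(pa, pb)
    return ProfileComparison(
        profile_a=a.name, profile_b=b.name,
        pattern_r=r, pattern_p=float(max(pr, _P_FLOOR)), df=len(ta) - 2,
        mean_abs_t_a=float(np.mean(np.abs(ta))),
        sd_abs_t_a=float(np.std(np.abs(ta), ddof=1)),
        mean_abs_t_b=float(np.mean(np.abs(tb))),
        sd_abs_t_b=float(np.std(np.abs(tb), ddof=1)),
        paired_p=float(paired_p), degenerate=degenerate)
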