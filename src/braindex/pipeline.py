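"""End-to-end orchestration of the index pipeline.

Stages (each reading its inputs from, and writing its outputs to, the run
directory, so any downstream stage can be resumed from disk):

    simulate -> harmonize -> edp -> qri -> analyze

A run is fully described by a :class:`PipelineConfig`; reruns with an
identical configuration produce bit-identical tables. The final stage writes
a machine-readable JSON report with the configuration hash, seed, library
versions, collected warnings and the headline statistics.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import scipy

from . import __version__
from .cognition import (biomarker_cognition_profile, cognitive_deficit_profile,
                        compare_profiles)
from .edp import compute_edp, read_effect_vector, whole_brain_means
from .errors import ConfigurationError
from .group_analysis import (DEPRESSION_GROUPS, correct_and_zscore,
                             group_profile, groupmean_correlation,
                             symptom_association)
from .harmonize import BLOM_C, harmonize
from .qri import QRI_TAUS, compute_qri
from .synthetic import (GROUPS, CohortConfig, read_table, simulate_cohort,
                        write_cohort)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "harmonize", "edp", "qri", "analyze")
BIOMARKERS = ("edp", "qri_whole", "mean_thickness_z", "mean_subcort_z",
              "mean_fa_z")

_INPUT_TABLES = ("phenotypes", "covariates", "labels", "cognition",
                 "tissue_map", "effect_vector")


@dataclass
class PipelineConfig:
    """One pipeline run: either a simulation config or paths to input tables."""

    cohort: CohortConfig | None = None
    input_paths: dict | None = None
    covariate_set: tuple = ("age", "sex", "icv")
    reference: str = "all"
    blom_c: float = BLOM_C
    icv_tissues: tuple | None = None
    effect_vector_path: str | None = None
    taus: tuple = QRI_TAUS
    stratify_by_sex: bool = False
    symptom_subset: str = "depressed"      # or "all"
    outdir: str = "braindex_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.input_paths is None):
            raise ConfigurationError(
                "provide exactly one of a cohort simulation config or "
                "input table paths")
        if self.input_paths is not None:
            missing = [k for k in _INPUT_TABLES if k not in self.input_paths]
            if missing:
                raise ConfigurationError(
                    f"input_paths is missing tables: {missing}")
        if self.symptom_subset not in ("depressed", "all"):
            raise ConfigurationError(
                f"symptom_subset must be 'depressed' or 'all', "
                f"got {self.symptom_subset!r}")
        if self.cohort is not None and self.cohort.seed != self.seed:
            self.cohort = replace(self.cohort, seed=self.seed)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        cohort = doc.pop("cohort", None)
        if cohort is not None and not isinstance(cohort, CohortConfig):
            cohort = CohortConfig(**cohort)
        harmonize_opts = doc.pop("harmonize", {})
        qri_opts = doc.pop("qri", {})
        analysis = doc.pop("analysis", {})
        kwargs = {
            "cohort": cohort,
            "input_paths": doc.pop("inputs", None),
            "covariate_set": tuple(harmonize_opts.get(
                "covariate_set", ("age", "sex", "icv"))),
            "reference": harmonize_opts.get("reference", "all"),
            "blom_c": float(harmonize_opts.get("blom_c", BLOM_C)),
            "icv_tissues": (tuple(harmonize_opts["icv_tissues"])
                            if harmonize_opts.get("icv_tissues") else None),
            "stratify_by_sex": bool(qri_opts.get("stratify_by_sex", False)),
            "symptom_subset": analysis.get("symptom_subset", "depressed"),
        }
        for key in ("effect_vector_path", "outdir", "seed", "log_level"):
            if key in doc:
                kwargs[key] = doc.pop(key)
        return cls(**kwargs)

    def config_hash(self) -> str:
        import hashlib
        # outdir/log_level do not affect the computation and stay out of
        # the hash, so runs into different directories compare equal
        skip = ("cohort", "outdir", "log_level")
        doc = {k: v for k, v in asdict(self).items() if k not in skip}
        doc["cohort"] = (None if self.cohort is None
                         else self.cohort.to_jsonable())
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# stage helpers

def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _input_path(config: PipelineConfig, name: str) -> Path:
    if config.input_paths is not None:
        path = Path(config.input_paths[name])
    else:
        path = _outdir(config) / "cohort" / f"{name}.tsv"
    if not path.exists():
        raise ConfigurationError(f"input table {name!r} not found: {path}")
    return path


def _read_input(config: PipelineConfig, name: str) -> pd.DataFrame:
    index_col = "phenotype" if name in ("tissue_map", "effect_vector") \
        else "subject_id"
    return read_table(_input_path(config, name), index_col=index_col)


def _write_tsv(frame: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, sep="\t", float_format="%.10g")


def stage_simulate(config: PipelineConfig) -> None:
    if config.cohort is None:
        logger.info("external input tables supplied; nothing to simulate")
        return
    cohort = simulate_cohort(config.cohort)
    write_cohort(cohort, _outdir(config) / "cohort")
    logger.info("simulated cohort: %d subjects, %d phenotypes",
                len(cohort.subject_ids), cohort.phenotypes.shape[1])


def stage_harmonize(config: PipelineConfig) -> None:
    phenotypes = _read_input(config, "phenotypes")
    covariates = _read_input(config, "covariates")
    tissue_map = _read_input(config, "tissue_map")["tissue"]
    control_index = None
    if config.reference == "controls":
        labels = _read_input(config, "labels")
        control_index = labels.index[labels["group"] == "control"]
    z = harmonize(phenotypes, covariates,
                  covariate_set=config.covariate_set,
                  reference=config.reference, control_index=control_index,
                  tissue_map=tissue_map, icv_tissues=config.icv_tissues,
                  blom_c=config.blom_c)
    out = _outdir(config)
    _write_tsv(z.data, out / "zmatrix.tsv", config.seed)
    with open(out / "zmatrix.meta.json", "w") as fh:
        json.dump(z.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_scores(config: PipelineConfig) -> pd.DataFrame:
    path = _outdir(config) / "subject_scores.tsv"
    if path.exists():
        return read_table(path)
    return pd.DataFrame()


def _merge_scores(config: PipelineConfig, new: pd.DataFrame) -> pd.DataFrame:
    scores = _load_scores(config)
    if scores.empty:
        scores = new
    else:
        scores = scores.drop(columns=new.columns, errors="ignore").join(new)
    _write_tsv(scores, _outdir(config) / "subject_scores.tsv", config.seed)
    return scores


def stage_edp(config: PipelineConfig) -> None:
    z = read_table(_outdir(config) / "zmatrix.tsv")
    tissue_map = _read_input(config, "tissue_map")["tissue"]
    if config.effect_vector_path is not None:
        effects = read_effect_vector(config.effect_vector_path)
    else:
        effects = _read_input(config, "effect_vector")["effect"]
    edp = compute_edp(z, effects)
    means = whole_brain_means(z, tissue_map)
    _merge_scores(config, pd.concat([edp, means], axis=1))


def stage_qri(config: PipelineConfig) -> None:
    phenotypes = _read_input(config, "phenotypes")
    covariates = _read_input(config, "covariates")
    tissue_map = _read_input(config, "tissue_map")["tissue"]
    result = compute_qri(phenotypes, covariates, tissue_map,
                         taus=config.taus,
                         stratify_by_sex=config.stratify_by_sex)
    out = _outdir(config)
    _write_tsv(result.fits.set_index("phenotype"),
               out / "quantile_fits.tsv", config.seed)
    _write_tsv(result.region_scores, out / "qri_region_scores.tsv",
               config.seed)
    _merge_scores(config, result.scores)


def stage_analyze(config: PipelineConfig) -> dict:
    out = _outdir(config)
    scores = _load_scores(config)
    missing = [b for b in BIOMARKERS if b not in scores.columns]
    if missing:
        raise ConfigurationError(
            f"subject scores missing biomarkers {missing}; run the edp/qri "
            "stages first")
    covariates = _read_input(config, "covariates")
    labels = _read_input(config, "labels")
    cognition = _read_input(config, "cognition")
    biomarkers = scores[list(BIOMARKERS)]

    summary = group_profile(biomarkers, labels, covariates)
    _write_tsv(summary.table, out / "group_summary.tsv", config.seed)

    gm_corr = {b: groupmean_correlation(summary, b) for b in BIOMARKERS}

    subset = DEPRESSION_GROUPS if config.symptom_subset == "depressed" \
        else GROUPS
    assoc = {b: asdict(symptom_association(biomarkers[b], labels, covariates,
                                           subset=subset))
             for b in BIOMARKERS}
    _write_tsv(pd.DataFrame(assoc).T.set_index("biomarker"),
               out / "symptom_associations.tsv", config.seed)

    # One-way ANOVA of each (corrected) biomarker across the four groups.
    z = correct_and_zscore(biomarkers, covariates)
    group = labels.loc[z.index, "group"]
    separation = {}
    for b in BIOMARKERS:
        arms = [z.loc[group == g, b].dropna() for g in GROUPS]
        F, p = scipy.stats.f_oneway(*arms)
        separation[b] = {"F": float(F), "p": float(p),
                         "significant_at_0.01": bool(p < 0.01)}

    deficit = cognitive_deficit_profile(cognition, labels, covariates)
    profiles = {deficit.name: deficit}
    for g in DEPRESSION_GROUPS:
        prof = cognitive_deficit_profile(cognition, labels, covariates,
                                         case_groups=(g,),
                                         name=f"{g}-vs-control")
        profiles[prof.name] = prof
    comparisons = []
    for arm in ("mdd", "controls"):
        for b in BIOMARKERS:
            prof = biomarker_cognition_profile(
                scores[b], cognition, labels, covariates, subset=arm)
            profiles[prof.name] = prof
            comparisons.append(asdict(compare_profiles(prof, deficit)))
        # head-to-head paired comparison of the two leading biomarkers
        comparisons.append(asdict(compare_profiles(
            profiles[f"edp-in-{arm}"],
            profiles[f"mean_thickness_z-in-{arm}"])))

    long = pd.concat(
        [p.table.assign(profile=p.name) for p in profiles.values()]
    ).reset_index().set_index("profile")
    _write_tsv(long, out / "association_profiles.tsv", config.seed)
    _write_tsv(pd.DataFrame(comparisons).set_index("profile_a"),
               out / "profile_comparisons.tsv", config.seed)

    _plot_group_profile(summary, out / "fig_group_profile.png")
    _plot_deficit_profile(deficit, out / "fig_deficit_profile.png")
    for arm in ("mdd", "controls"):
        _plot_pattern(profiles, deficit, arm, out / f"fig_pattern_{arm}.png")

    return {
        "group_separation": separation,
        "groupmean_correlations": gm_corr,
        "symptom_associations": assoc,
        "profile_comparisons": comparisons,
    }


# ---------------------------------------------------------------------------
# figures

def _plot_group_profile(summary, path: Path) -> None:
    table = summary.table
    panels = ["severity"] + [f"{b}_mean" for b in BIOMARKERS]
    fig, axes = plt.subplots(2, 3, figsize=(11, 6), sharex=True)
    x = np.arange(len(table.index))
    for ax, col in zip(axes.ravel(), panels):
        err = table[col.replace("_mean", "_se")] if col != "severity" else None
        ax.errorbar(x, table[col], yerr=err, marker="o", lw=1.5)
        ax.set_title(col.replace("_mean", ""))
        ax.set_xticks(x, table.index, rotation=30)
    fig.suptitle("Group profiles (age/sex-corrected Z-scores)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_deficit_profile(profile, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(profile.tests, profile.t.to_numpy())
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("t (control - MDD)")
    ax.set_title(profile.name)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_pattern(profiles, deficit, arm: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for b, marker in zip(("edp", "mean_thickness_z"), ("o", "s")):
        prof = profiles[f"{b}-in-{arm}"]
        ax.scatter(deficit.t, prof.t, marker=marker, label=b)
    ax.set_xlabel("MDD-vs-control deficit t")
    ax.set_ylabel(f"model-1 t in {arm}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Run the requested stages in order and write ``report.json``.

    Returns the report document. Errors raised inside a stage are re-raised
    with the stage name prefixed for context.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    runners = {"simulate": stage_simulate, "harmonize": stage_harmonize,
               "edp": stage_edp, "qri": stage_qri, "analyze": stage_analyze}
    unknown = [s for s in stages if s not in runners]
    if unknown:
        raise ConfigurationError(f"unknown stages: {unknown}")

    results = {}
    caught: list[str] = []
    for name in [s for s in STAGES if s in stages]:
        logger.info("stage %s", name)
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            try:
                ret = runners[name](config)
            except Exception as exc:
                exc.args = (f"[stage {name}] {exc}",) + exc.args[1:]
                raise
        caught.extend(f"[{name}] {w.message}" for w in wlist)
        if ret:
            results.update(ret)

    report = {
        "package": "braindex",
        "version": __version__,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": list(stages),
        "warnings": caught,
        "results": results,
    }
    with open(_outdir(config) / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return report
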