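"""Synthetic cohort generator.

Emulates a large epidemiological neuroimaging cohort (UK-Biobank-like) with
the statistical structure the downstream indices assume:

* 64 regional structural phenotypes — 33 cortical gray-matter thickness
  regions, 24 white-matter tract fractional-anisotropy (FA) values and 7
  subcortical gray-matter volumes (left/right pre-averaged) — each depending
  linearly on age, sex and intracranial volume (ICV) plus Gaussian noise;
* four depression groups (control, subclinical, single-episode, recurrent)
  with a continuous symptom-severity score on a 0–4 scale;
* a graded structural deficit planted along a signed meta-analytic effect
  vector, proportional to each subject's severity;
* nine cognitive test scores coupled to the subject's *realized* deficit
  alignment (not the group label), so that controls also carry a
  cognition–vulnerability association.

All randomness flows from a single seed; identical configurations produce
bit-identical cohorts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

GROUPS = ("control", "subclinical", "single", "recurrent")

TISSUE_THICKNESS = "thickness"
TISSUE_SUBCORTICAL = "subcortical_volume"
TISSUE_FA = "FA"
TISSUE_CLASSES = (TISSUE_THICKNESS, TISSUE_FA, TISSUE_SUBCORTICAL)

# Desikan-Killiany cortical parcels (33 regions, bilateral averages).
_THICKNESS_REGIONS = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "insula", "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal",
    "lingual", "medialorbitofrontal", "middletemporal", "paracentral",
    "parahippocampal", "parsopercularis", "parsorbitalis", "parstriangularis",
    "pericalcarine", "postcentral", "posteriorcingulate", "precentral",
    "precuneus", "rostralanteriorcingulate", "rostralmiddlefrontal",
    "superiorfrontal", "superiorparietal", "superiortemporal",
    "supramarginal", "temporalpole", "transversetemporal",
]

# White-matter tracts (24, ENIGMA-DTI style labels, bilateral averages).
_FA_TRACTS = [
    "acr", "alic", "bcc", "cgc", "cgh", "cr", "cst", "ec", "fx", "fxst",
    "gcc", "ic", "ifo", "pcr", "plic", "ptr", "rlic", "scc", "scr", "sfo",
    "slf", "ss", "unc", "averagefa",
]

# Subcortical gray-matter structures (7, bilateral averages).
_SUBCORTICAL_STRUCTURES = [
    "thalamus", "caudate", "putamen", "pallidum",
    "hippocampus", "amygdala", "accumbens",
]

COGNITIVE_TESTS = (
    "Matrix", "ReactionTime", "NumericMemory", "PairsMatch", "Trails1",
    "Trails2", "SymbolDigit", "Tower", "FluidIntelligence",
)

#: Tests carrying a planted cognition–vulnerability coupling by default:
#: the domains where depression-related deficits are typically observed
#: (perceptual reasoning, processing speed, fluid intelligence).
DEFAULT_AFFECTED_TESTS = ("Matrix", "ReactionTime", "FluidIntelligence")


def default_phenotype_spec() -> list[tuple[str, str]]:
    """The default 64-phenotype panel as (name, tissue_class) pairs."""
    spec = [(f"thk_{r}", TISSUE_THICKNESS) for r in _THICKNESS_REGIONS]
    spec += [(f"fa_{t}", TISSUE_FA) for t in _FA_TRACTS]
    spec += [(f"vol_{s}", TISSUE_SUBCORTICAL) for s in _SUBCORTICAL_STRUCTURES]
    return spec


def default_effect_vector(
    phenotype_spec: list[tuple[str, str]] | None = None,
) -> pd.Series:
    """Planted meta-analytic effect vector for the synthetic pipeline.

    Small signed case-control standardized effects, mostly negative
    (structural deficits), with heterogeneous magnitudes in roughly the range
    reported by large-consortium depression meta-analyses. Drawn once from a
    fixed internal stream so the vector is a reproducible constant of the
    package, independent of the cohort seed.
    """
    if phenotype_spec is None:
        phenotype_spec = default_phenotype_spec()
    rng = np.random.default_rng(987654321)
    names = [name for name, _ in phenotype_spec]
    magnitude = rng.uniform(0.03, 0.25, size=len(names))
    sign = np.where(rng.random(len(names)) < 0.9, -1.0, 1.0)
    return pd.Series(np.round(magnitude * sign, 4), index=names, name="effect")


def _default_covariate_betas(
    phenotype_spec: list[tuple[str, str]],
) -> pd.DataFrame:
    """Per-phenotype age slope (per year), sex offset and ICV slope (per mm3).

    Scaled so each covariate moves phenotypes by a fraction of the default
    unit noise SD across its realistic range, giving the residualization
    stage real work without dominating the planted deficit.
    """
    per_class = {
        TISSUE_THICKNESS: (-0.020, 0.25, 2.0e-6),
        TISSUE_FA: (-0.025, 0.15, 1.0e-6),
        TISSUE_SUBCORTICAL: (-0.022, 0.35, 3.0e-6),
    }
    rows = {name: per_class[tissue] for name, tissue in phenotype_spec}
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["age", "sex", "icv"]
    )


def _default_baselines(phenotype_spec: list[tuple[str, str]]) -> pd.Series:
    per_class = {TISSUE_THICKNESS: 2.5, TISSUE_FA: 0.45,
                 TISSUE_SUBCORTICAL: 4000.0}
    return pd.Series({n: per_class[t] for n, t in phenotype_spec})


def default_cognitive_spec(
    affected_tests: tuple[str, ...] = DEFAULT_AFFECTED_TESTS,
    coupling: float = 0.25,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-test coupling of score to latent vulnerability, plus test noise SD.

    ``coupling`` is in SD units of the standardized latent vulnerability;
    nonzero only for the affected subset.
    """
    spec = pd.DataFrame(
        {"coupling": 0.0, "noise_sd": float(noise_sd)},
        index=list(COGNITIVE_TESTS),
    )
    unknown = set(affected_tests) - set(COGNITIVE_TESTS)
    if unknown:
        raise ConfigurationError(f"unknown cognitive tests: {sorted(unknown)}")
    spec.loc[list(affected_tests), "coupling"] = float(coupling)
    return spec


@dataclass
class CohortConfig:
    """Full description of one synthetic cohort.

    The defaults are the package's reference study conditions: 2000 subjects
    per group, a graded deficit along the planted effect vector
    (severity-proportional with ``deficit_scale = 0.5``), unit phenotype
    noise, and cognitive coupling of 0.25 SD in three of nine tests.
    """

    n_per_group: int = 2000
    phenotype_spec: list[tuple[str, str]] = field(
        default_factory=default_phenotype_spec)
    effect_vector: pd.Series | None = None
    severity_means: tuple[float, float, float, float] = (0.3, 1.2, 2.0, 3.0)
    severity_sd: float = 0.5
    deficit_scale: float = 0.5
    age_range: tuple[float, float] = (45.0, 80.0)
    covariate_betas: pd.DataFrame | None = None
    noise_sd: float = 1.0
    cognitive_spec: pd.DataFrame | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        sev = np.asarray(self.severity_means, dtype=float)
        if sev.shape != (4,) or not np.all(np.diff(sev) > 0):
            raise ConfigurationError(
                "severity_means must be 4 strictly increasing values "
                "(control < subclinical < single < recurrent)")
        tissues = {t for _, t in self.phenotype_spec}
        if tissues != set(TISSUE_CLASSES):
            raise ConfigurationError(
                f"phenotype_spec must cover exactly the tissue classes "
                f"{TISSUE_CLASSES}, got {sorted(tissues)}")
        if self.age_range[1] <= self.age_range[0]:
            raise ConfigurationError("age_range must be (min, max), min < max")
        if self.effect_vector is None:
            self.effect_vector = default_effect_vector(self.phenotype_spec)
        names = [n for n, _ in self.phenotype_spec]
        if not set(self.effect_vector.index).issubset(names):
            raise ConfigurationError(
                "effect_vector names must be a subset of phenotype_spec names")
        if self.covariate_betas is None:
            self.covariate_betas = _default_covariate_betas(self.phenotype_spec)
        if self.cognitive_spec is None:
            self.cognitive_spec = default_cognitive_spec()

    @property
    def tissue_map(self) -> pd.Series:
        return pd.Series(dict(self.phenotype_spec), name="tissue")

    def to_jsonable(self) -> dict:
        """JSON-serializable view, used for the manifest and config hash."""
        return {
            "n_per_group": self.n_per_group,
            "phenotype_spec": [list(p) for p in self.phenotype_spec],
            "effect_vector": {k: float(v)
                              for k, v in self.effect_vector.items()},
            "severity_means": list(map(float, self.severity_means)),
            "severity_sd": float(self.severity_sd),
            "deficit_scale": float(self.deficit_scale),
            "age_range": list(map(float, self.age_range)),
            "covariate_betas": {
                k: list(map(float, row))
                for k, row in self.covariate_betas.iterrows()},
            "noise_sd": float(self.noise_sd),
            "cognitive_spec": {
                k: list(map(float, row))
                for k, row in self.cognitive_spec.iterrows()},
            "seed": int(self.seed),
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class SyntheticCohort:
    """One realized cohort; all tables share the subject_id index."""

    phenotypes: pd.DataFrame
    tissue_map: pd.Series
    covariates: pd.DataFrame     # age (years), sex (0/1), icv (mm3)
    labels: pd.DataFrame         # group, severity
    cognition: pd.DataFrame      # subjects x 9 tests
    truth: pd.Series             # standardized latent vulnerability
    effect_vector: pd.Series
    config: CohortConfig

    @property
    def subject_ids(self) -> pd.Index:
        return self.phenotypes.index

    def group_mask(self, *groups: str) -> pd.Series:
        return self.labels["group"].isin(groups)


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort under ``config``.

    Generative model per subject s and phenotype i::

        value = baseline_i + age_s*b_age_i + sex_s*b_sex_i + icv_s*b_icv_i
                + deficit_scale * severity_s * E_i + eps,   eps ~ N(0, noise_sd)

    severity_s ~ N(group mean, severity_sd) truncated (clipped) to [0, 4].
    The latent vulnerability is the realized deficit alignment
    (1/N)*sum_i((shift_i + eps_i) * E_i), standardized across the cohort, and
    each cognitive score is  -coupling_test * vulnerability + N(0, noise_sd_test).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    n_total = 4 * n
    width = len(str(n_total))
    subject_id = pd.Index(
        [f"S{i + 1:0{width}d}" for i in range(n_total)], name="subject_id")

    group = np.repeat(GROUPS, n)
    sev_mean = np.repeat(np.asarray(config.severity_means, float), n)
    severity = np.clip(
        sev_mean + rng.normal(0.0, config.severity_sd, n_total), 0.0, 4.0)

    age = rng.uniform(*config.age_range, size=n_total)
    sex = rng.integers(0, 2, size=n_total).astype(float)
    # ICV log-normal around ~1.5e6 mm3 with ~8% coefficient of variation.
    icv = np.exp(rng.normal(np.log(1.5e6), 0.08, size=n_total))

    names = [nm for nm, _ in config.phenotype_spec]
    betas = config.covariate_betas.loc[names]
    baseline = _default_baselines(config.phenotype_spec).loc[names].to_numpy()
    effects_full = config.effect_vector.reindex(names).fillna(0.0).to_numpy()

    covariate_part = (
        baseline[None, :]
        + np.outer(age, betas["age"].to_numpy())
        + np.outer(sex, betas["sex"].to_numpy())
        + np.outer(icv, betas["icv"].to_numpy())
    )
    shift = config.deficit_scale * np.outer(severity, effects_full)
    noise = rng.normal(0.0, config.noise_sd, size=(n_total, len(names)))
    values = covariate_part + shift + noise

    # Realized deficit alignment over the phenotypes the effect vector names.
    e_mask = np.isin(names, config.effect_vector.index)
    n_e = int(e_mask.sum())
    raw_vuln = ((shift + noise)[:, e_mask] @ effects_full[e_mask]) / max(n_e, 1)
    sd = raw_vuln.std()
    vulnerability = (raw_vuln - raw_vuln.mean()) / sd if sd > 0 else raw_vuln * 0.0

    cog_spec = config.cognitive_spec
    cognition = pd.DataFrame(
        {
            test: (-cog_spec.loc[test, "coupling"] * vulnerability
                   + rng.normal(0.0, cog_spec.loc[test, "noise_sd"], n_total))
            for test in cog_spec.index
        },
        index=subject_id,
    )

    return SyntheticCohort(
        phenotypes=pd.DataFrame(values, index=subject_id, columns=names),
        tissue_map=config.tissue_map,
        covariates=pd.DataFrame(
            {"age": age, "sex": sex, "icv": icv}, index=subject_id),
        labels=pd.DataFrame(
            {"group": group, "severity": severity}, index=subject_id),
        cognition=cognition,
        truth=pd.Series(vulnerability, index=subject_id, name="vulnerability"),
        effect_vector=config.effect_vector.copy(),
        config=config,
    )


# ---------------------------------------------------------------------------
# On-disk representation: tab-separated tables with a seed header line.

def _write_tsv(frame: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, sep="\t", float_format="%.10g")


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict:
    """Write the five subject tables, tissue map, effect vector and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cohort.config.seed
    _write_tsv(cohort.phenotypes, outdir / "phenotypes.tsv", seed)
    _write_tsv(cohort.covariates, outdir / "covariates.tsv", seed)
    _write_tsv(cohort.labels, outdir / "labels.tsv", seed)
    _write_tsv(cohort.cognition, outdir / "cognition.tsv", seed)
    _write_tsv(cohort.truth.to_frame(), outdir / "truth.tsv", seed)
    _write_tsv(cohort.tissue_map.to_frame().rename_axis("phenotype"),
               outdir / "tissue_map.tsv", seed)
    _write_tsv(cohort.effect_vector.to_frame().rename_axis("phenotype"),
               outdir / "effect_vector.tsv", seed)
    manifest = {"seed": seed, "config_hash": cohort.config.config_hash(),
                "n_subjects": int(len(cohort.subject_ids))}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def read_table(path: str | Path, index_col: str = "subject_id") -> pd.DataFrame:
    """Read a tab-separated table written by this package (skips # headers)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
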