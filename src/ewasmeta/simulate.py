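"""Synthetic multi-cohort consortium generator with known ground truth.

Beta values are simulated on the logit scale (probe-specific mean and
scale, Gaussian batch shifts) and inverse-logit transformed, which keeps
them in [0, 1] with 450K-like marginal shapes.  Cell-type proportions are
Dirichlet draws included among the covariates.  BMI is generated on the
BMI-SDS scale from covariate effects plus noise and back-transformed to
raw kg/m2 through the LMS reference, under one of three causal modes:

``meth_to_bmi``
    BMI-SDS gains ``effect * beta`` for each planted probe (effect in
    BMI-SDS per unit beta) -- methylation causes adiposity.
``bmi_to_meth``
    logit(beta) at planted probes is shifted by
    ``age_effect_schedule(age) * effect * BMI-SDS`` (effect on the logit
    scale per BMI-SDS) -- adiposity leaves age-increasing marks.
``null``
    no probe-BMI dependence anywhere.

Each cohort draws from an independent random stream derived from the
master seed and the cohort index, so adding cohorts never perturbs
earlier ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .phenotypes import lms_inverse, iotf_classify
from .references import LMSReference, IOTFCutoffs, load_synthetic_lms, load_synthetic_iotf

__all__ = [
    "SimulationConfig",
    "CohortDataset",
    "generate_manifest",
    "generate_consortium",
    "schedule_multiplier",
    "write_cohort",
    "read_cohort",
]

NA_TOKEN = "NA"
CELL_ALPHA = np.array([7.0, 12.0, 15.0, 55.0, 3.0, 8.0])  # Bcell CD8T CD4T Gran NK Mono
CELL_COLUMNS = ["cellprop_Bcell", "cellprop_CD8T", "cellprop_CD4T",
                "cellprop_Gran", "cellprop_NK", "cellprop_Mono"]
_PROBE_STREAM = 1_000_000  # spawn key for consortium-shared probe parameters
_MANIFEST_STREAM = 2_000_000


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions of a simulated consortium.

    ``planted_set`` maps probe index -> effect size (BMI-SDS per unit
    beta under ``meth_to_bmi``; logit-beta per BMI-SDS under
    ``bmi_to_meth``).  ``age_effect_schedule`` maps age (years) to a
    nonnegative multiplier, interpolated linearly between knots.
    """

    master_seed: int = 0
    n_cohorts: int = 3
    samples_per_cohort: list = field(default_factory=lambda: [300, 300, 300])
    n_probes: int = 1000
    age_window: tuple = (2.0, 10.0)
    causal_mode: str = "null"
    planted_set: dict = field(default_factory=dict)
    age_effect_schedule: dict = field(default_factory=lambda: {2.0: 0.0, 18.0: 1.0})
    probe_mean_logit: np.ndarray | None = None
    probe_sd_logit: np.ndarray | None = None
    covariate_effect_vector: dict = field(
        default_factory=lambda: {
            "maternal_bmi": 0.04,
            "maternal_smoking": 0.20,
            "birth_weight_g": 0.0002,
            "breastfeeding": -0.10,
        }
    )
    overweight_target_fraction: list | None = None
    ancestry_label: list | None = None
    selection_flag: list | None = None
    residual_sd: float = 0.9
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.ancestry_label is None:
            self.ancestry_label = ["European"] * self.n_cohorts
        if self.selection_flag is None:
            self.selection_flag = [False] * self.n_cohorts
        self.validate()

    def validate(self):
        if self.n_cohorts < 1:
            raise ConfigurationError("n_cohorts must be >= 1")
        if self.n_probes < 1:
            raise ConfigurationError("n_probes must be >= 1")
        if len(self.samples_per_cohort) != self.n_cohorts:
            raise ConfigurationError(
                "samples_per_cohort length "
                f"{len(self.samples_per_cohort)} != n_cohorts {self.n_cohorts}"
            )
        if any(n < 1 for n in self.samples_per_cohort):
            raise ConfigurationError("samples_per_cohort entries must be >= 1")
        if self.causal_mode not in ("meth_to_bmi", "bmi_to_meth", "null"):
            raise ConfigurationError(f"unknown causal_mode {self.causal_mode!r}")
        lo, hi = self.age_window
        if not lo < hi:
            raise ConfigurationError("age_window must satisfy min < max")
        if any(m < 0 for m in self.age_effect_schedule.values()):
            raise ConfigurationError("age_effect_schedule multipliers must be >= 0")
        for idx in self.planted_set:
            if not 0 <= int(idx) < self.n_probes:
                raise ConfigurationError(f"planted_set probe index {idx} out of range")
        for name, value in (("ancestry_label", self.ancestry_label),
                            ("selection_flag", self.selection_flag)):
            if len(value) != self.n_cohorts:
                raise ConfigurationError(f"{name} length != n_cohorts")
        if self.overweight_target_fraction is not None and len(
            self.overweight_target_fraction
        ) != self.n_cohorts:
            raise ConfigurationError("overweight_target_fraction length != n_cohorts")
        if self.probe_sd_logit is not None and np.any(np.asarray(self.probe_sd_logit) <= 0):
            raise ConfigurationError("probe_sd_logit must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")

    def to_yaml(self, path):
        d = dataclasses.asdict(self)
        d["age_window"] = list(self.age_window)
        d["planted_set"] = {int(k): float(v) for k, v in self.planted_set.items()}
        d["age_effect_schedule"] = {float(k): float(v) for k, v in self.age_effect_schedule.items()}
        for key in ("probe_mean_logit", "probe_sd_logit"):
            if d[key] is not None:
                d[key] = [float(v) for v in d[key]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "age_window" in d:
            d["age_window"] = tuple(d["age_window"])
        for key in ("probe_mean_logit", "probe_sd_logit"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


@dataclass
class CohortDataset:
    """One cohort: probe x sample beta matrix plus the per-sample sheet."""

    cohort_id: str
    betas: pd.DataFrame
    samples: pd.DataFrame
    ancestry_label: str = "European"
    selection_flag: bool = False

    def validate(self, age_window=None):
        arr = self.betas.to_numpy(dtype=float)
        obs = ~np.isnan(arr)
        if np.any((arr[obs] < 0) | (arr[obs] > 1)):
            raise ValueError(f"cohort {self.cohort_id}: beta values outside [0, 1]")
        cell = self.samples[CELL_COLUMNS].to_numpy(dtype=float)
        if np.any(np.abs(cell.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError(f"cohort {self.cohort_id}: cell proportions do not sum to 1")
        if age_window is not None:
            lo, hi = age_window
            ages = self.samples["age_years"]
            if ((ages < lo) | (ages > hi)).any():
                raise ValueError(f"cohort {self.cohort_id}: ages outside window")
        return self


def schedule_multiplier(schedule: dict, ages) -> np.ndarray:
    """Piecewise-linear interpolation of an age -> multiplier schedule
    (flat extrapolation beyond the knots)."""
    knots = sorted(schedule.items())
    xs = np.array([k for k, _ in knots], dtype=float)
    ys = np.array([v for _, v in knots], dtype=float)
    return np.interp(np.asarray(ages, dtype=float), xs, ys)


def generate_manifest(n_probes: int, master_seed: int, frac_sex: float = 0.02,
                      frac_cross_reactive: float = 0.02, frac_flagged: float = 0.05) -> pd.DataFrame:
    """Synthetic probe manifest: ids, coordinates, nearest gene, QC flags.

    A small fraction of probes land on X/Y or are marked cross-reactive so
    the probe-filtering stage has work to do.
    """
    rng = np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(_MANIFEST_STREAM,)))
    cpg_ids = [f"cg{i:08d}" for i in range(n_probes)]
    chroms = rng.choice([str(c) for c in range(1, 23)], size=n_probes)
    n_sex = int(round(frac_sex * n_probes))
    if n_sex:
        sex_idx = rng.choice(n_probes, size=n_sex, replace=False)
        chroms[sex_idx] = rng.choice(["X", "Y"], size=n_sex)
    positions = rng.integers(1, 150_000_000, size=n_probes)
    flags = {
        name: (rng.random(n_probes) < frac).astype(int)
        for name, frac in (
            ("flag_snp", frac_flagged),
            ("flag_indel", frac_flagged / 2),
            ("flag_repeat", frac_flagged / 2),
            ("flag_cross_reactive", frac_cross_reactive),
        )
    }
    return pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "chromosome": chroms,
            "position": positions,
            "nearest_gene": [f"GENE{i % max(1, n_probes // 3):05d}" for i in range(n_probes)],
            **flags,
        }
    )


def _probe_parameters(config: SimulationConfig):
    """Consortium-shared probe means/scales on the logit scale (bimodal
    mixture mimicking unmethylated/intermediate/methylated probes)."""
    if config.probe_mean_logit is not None and config.probe_sd_logit is not None:
        return (
            np.asarray(config.probe_mean_logit, dtype=float),
            np.asarray(config.probe_sd_logit, dtype=float),
        )
    rng = np.random.default_rng(
        np.random.SeedSequence(config.master_seed, spawn_key=(_PROBE_STREAM,))
    )
    comp = rng.choice(3, size=config.n_probes, p=[0.3, 0.4, 0.3])
    mu = np.where(comp == 0, rng.normal(-2.5, 0.6, config.n_probes),
                  np.where(comp == 1, rng.normal(0.0, 1.0, config.n_probes),
                           rng.normal(2.5, 0.6, config.n_probes)))
    sd = 0.30 + np.abs(rng.normal(0.0, 0.10, config.n_probes))
    if config.probe_mean_logit is not None:
        mu = np.asarray(config.probe_mean_logit, dtype=float)
    if config.probe_sd_logit is not None:
        sd = np.asarray(config.probe_sd_logit, dtype=float)
    return mu, sd


def _simulate_samples(rng, n, config: SimulationConfig, cohort_id: str) -> pd.DataFrame:
    lo, hi = config.age_window
    age = rng.uniform(lo, hi, n)
    sex = rng.choice(["F", "M"], size=n)
    ga = np.clip(rng.normal(39.5, 1.5, n), 30.0, 43.0)
    tanner_base = np.clip(np.rint(1 + (age - 8.5) / 1.9 + rng.normal(0, 0.7, n)), 1, 5)
    tanner_pubic = np.clip(tanner_base + np.rint(rng.normal(0, 0.6, n)), 1, 5)
    cell = rng.dirichlet(CELL_ALPHA, size=n)
    samples = pd.DataFrame(
        {
            "sex": sex,
            "age_years": age,
            "maternal_age": np.clip(rng.normal(30.0, 4.5, n), 16.0, 48.0),
            "maternal_education": rng.choice(["low", "mid", "high"], size=n, p=[0.3, 0.4, 0.3]),
            "maternal_smoking": rng.binomial(1, 0.2, n),
            "maternal_bmi": np.clip(rng.normal(24.0, 4.0, n), 15.0, 45.0),
            "parity": rng.binomial(1, 0.45, n),
            "gestational_age_weeks": ga,
            "birth_weight_g": np.clip(
                3400 + 170 * (ga - 39.5) + rng.normal(0, 420, n), 1200, 5500
            ),
            "breastfeeding": rng.binomial(1, 0.7, n),
            "child_smoking": np.where(age >= 12, rng.binomial(1, 0.12, n), 0),
            "tanner_breast_or_genital": tanner_base.astype(int),
            "tanner_pubic": tanner_pubic.astype(int),
            "menarche_or_voice": rng.binomial(1, expit((age - 13.0) / 0.8)),
            "batch": rng.choice(["b1", "b2"], size=n),
        },
        index=pd.Index([f"{cohort_id}_s{j:04d}" for j in range(n)], name="sample_id"),
    )
    for j, col in enumerate(CELL_COLUMNS):
        samples[col] = cell[:, j]
    return samples


def _covariate_score(samples: pd.DataFrame, effects: dict) -> np.ndarray:
    """Linear predictor of BMI-SDS from (centered) covariates."""
    centers = {"maternal_bmi": 24.0, "maternal_age": 30.0, "birth_weight_g": 3400.0,
               "gestational_age_weeks": 39.5}
    score = np.zeros(len(samples))
    for name, eff in effects.items():
        if name not in samples.columns:
            raise ConfigurationError(f"covariate_effect_vector names unknown covariate {name!r}")
        score += eff * (samples[name].to_numpy(dtype=float) - centers.get(name, 0.0))
    return score


def _tune_overweight_intercept(z, samples, target, lms_ref, iotf, tol=0.02):
    """Shift the BMI-SDS intercept until the IOTF overweight+obesity
    fraction (among non-underweight children) is within +-tol of target."""
    sex = samples["sex"].to_numpy()
    age = samples["age_years"].to_numpy()

    def frac(shift):
        bmi = lms_inverse(np.clip(z + shift, -3.5, 3.5), sex, age, lms_ref)
        cat = iotf_classify(bmi, sex, age, iotf)
        keep = cat != "underweight"
        if keep.sum() == 0:
            return 0.0
        return float(np.isin(cat[keep], ["overweight", "obesity"]).mean())

    lo, hi = -3.0, 3.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f = frac(mid)
        if abs(f - target) <= tol * 0.5:
            return mid
        if f < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_consortium(
    config: SimulationConfig,
    lms_ref: LMSReference | None = None,
    iotf: IOTFCutoffs | None = None,
) -> list:
    """Generate all cohorts of a consortium under the configured causal mode.

    Deterministic given ``config.master_seed``; per-cohort sub-streams are
    spawned as SeedSequence(master_seed, spawn_key=(cohort_index,)).
    """
    config.validate()
    lms_ref = lms_ref or load_synthetic_lms()
    iotf = iotf or load_synthetic_iotf()
    mu, sd = _probe_parameters(config)
    planted_idx = np.array(sorted(int(i) for i in config.planted_set), dtype=int)
    planted_eff = np.array([float(config.planted_set[i]) for i in planted_idx], dtype=float)
    cpg_ids = pd.Index([f"cg{i:08d}" for i in range(config.n_probes)], name="cpg_id")

    cohorts = []
    for i in range(config.n_cohorts):
        cohort_id = f"cohort{i + 1:02d}"
        rng = np.random.default_rng(np.random.SeedSequence(config.master_seed, spawn_key=(i,)))
        n = int(config.samples_per_cohort[i])
        samples = _simulate_samples(rng, n, config, cohort_id)

        batch_levels = {"b1": 0, "b2": 1}
        batch_shift = rng.normal(0.0, 0.08, size=(config.n_probes, len(batch_levels)))
        bidx = samples["batch"].map(batch_levels).to_numpy()
        logit_beta = (
            mu[:, None]
            + batch_shift[:, bidx]
            + sd[:, None] * rng.standard_normal((config.n_probes, n))
        )

        z = _covariate_score(samples, config.covariate_effect_vector) + rng.normal(
            0.0, config.residual_sd, n
        )
        if config.causal_mode == "meth_to_bmi" and planted_idx.size:
            # center each planted probe at its cohort mean so the planted
            # effects change the slope, not the cohort's BMI-SDS location
            planted_beta = expit(logit_beta[planted_idx])
            z = z + planted_eff @ (planted_beta - planted_beta.mean(axis=1, keepdims=True))

        shift = 0.0
        if config.overweight_target_fraction is not None:
            shift = _tune_overweight_intercept(
                z, samples, float(config.overweight_target_fraction[i]), lms_ref, iotf
            )
        z = np.clip(z + shift, -3.5, 3.5)

        if config.causal_mode == "bmi_to_meth" and planted_idx.size:
            mult = schedule_multiplier(config.age_effect_schedule, samples["age_years"])
            logit_beta[planted_idx] += planted_eff[:, None] * mult[None, :] * z[None, :]

        betas = expit(logit_beta)
        if config.missing_rate > 0:
            mask = rng.random(betas.shape) < config.missing_rate
            betas = np.where(mask, np.nan, betas)

        samples["bmi_kg_m2"] = lms_inverse(
            z, samples["sex"].to_numpy(), samples["age_years"].to_numpy(), lms_ref
        )
        cohorts.append(
            CohortDataset(
                cohort_id=cohort_id,
                betas=pd.DataFrame(betas, index=cpg_ids, columns=samples.index),
                samples=samples,
                ancestry_label=str(config.ancestry_label[i]),
                selection_flag=bool(config.selection_flag[i]),
            ).validate(age_window=config.age_window)
        )
    return cohorts


# ---------------------------------------------------------------------------
# on-disk formats


def write_cohort(dataset: CohortDataset, directory, manifest: pd.DataFrame | None = None):
    """Write one cohort as beta-matrix TSV + sample-sheet CSV (+ manifest
    slice) so values round-trip exactly through :func:`read_cohort`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    try:
        dataset.betas.to_csv(directory / "betas.tsv", sep="\t", na_rep=NA_TOKEN)
        dataset.samples.to_csv(directory / "samples.csv")
        meta = {
            "cohort_id": dataset.cohort_id,
            "ancestry_label": dataset.ancestry_label,
            "selection_flag": bool(dataset.selection_flag),
        }
        with open(directory / "cohort.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)
        if manifest is not None:
            sl = manifest[manifest["cpg_id"].isin(dataset.betas.index)]
            sl.to_csv(directory / "manifest.csv", index=False)
    except OSError as exc:
        raise OSError(f"failed writing cohort files under {directory}: {exc}") from exc
    return directory


def read_cohort(directory) -> CohortDataset:
    """Read a cohort written by :func:`write_cohort` (columns matched by
    name, so column order in the sample sheet is irrelevant)."""
    directory = Path(directory)
    betas = pd.read_csv(directory / "betas.tsv", sep="\t", index_col=0, na_values=[NA_TOKEN])
    betas.index.name = "cpg_id"
    samples = pd.read_csv(directory / "samples.csv", index_col=0)
    with open(directory / "cohort.yaml") as fh:
        meta = yaml.safe_load(fh)
    return CohortDataset(
        cohort_id=str(meta["cohort_id"]),
        betas=betas,
        samples=samples,
        ancestry_label=str(meta["ancestry_label"]),
        selection_flag=bool(meta["selection_flag"]),
    )
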