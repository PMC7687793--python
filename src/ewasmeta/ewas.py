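"""Within-cohort per-CpG association models.

Continuous BMI-SDS is modeled with Huber robust linear regression
(iteratively reweighted least squares, tuning constant 1.345, residual
scale from the normalized median absolute deviation, standard errors
from the M-estimator asymptotic covariance).  The binary
overweight/obesity outcome is modeled with maximum-likelihood logistic
regression.  Effects are estimated on the native beta scale (0-1); the
per-10%-methylation rescaling happens at the meta-analysis/reporting
stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .phenotypes import categorize_puberty, build_case_control, lms_zscore
from .qc import iqr_filter_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "CELL_TYPES",
    "fit_robust",
    "fit_logistic",
    "run_cohort_ewas",
    "genomic_lambda",
]

HUBER_T = 1.345
MAX_ITER = 50
TOL = 1e-8
CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549364...

CELL_TYPES = ["Bcell", "CD8T", "CD4T", "Gran", "NK", "Mono"]
CELL_COLUMNS = [f"cellprop_{c}" for c in CELL_TYPES]

# maternal/early-life adjustment set shared by all models
_MATERNAL = [
    "maternal_age",
    "maternal_education",
    "maternal_smoking",
    "maternal_bmi",
    "parity",
    "gestational_age_weeks",
    "batch",
    "cell_proportions",
]
_CHILD = ["birth_weight_g", "breastfeeding"]
_ADOLESCENT = ["sex", "age_years", "child_smoking", "puberty"]


@dataclass(frozen=True)
class ModelSpec:
    """One analysis model: outcome plus its ordered covariate adjustment set."""

    model_id: str
    outcome: str  # 'bmi_sds' or 'overweight_binary'
    covariate_names: tuple
    description: str = ""


MODEL_SPECS = {
    "A": ModelSpec("A", "bmi_sds", tuple(_MATERNAL), "cord blood methylation vs early-childhood BMI"),
    "B": ModelSpec("B", "bmi_sds", tuple(_MATERNAL), "cord blood methylation vs late-childhood BMI"),
    "C": ModelSpec("C", "bmi_sds", tuple(_MATERNAL + _CHILD), "cross-sectional childhood"),
    "D": ModelSpec("D", "bmi_sds", tuple(_MATERNAL + _CHILD + _ADOLESCENT), "cross-sectional adolescence"),
    "case_control": ModelSpec(
        "case_control",
        "overweight_binary",
        tuple(_MATERNAL + _CHILD),
        "overweight/obesity vs normal weight",
    ),
}


def _design_from_covariates(samples: pd.DataFrame, covariate_names) -> pd.DataFrame:
    """Numeric design-matrix columns (no intercept) for the named covariates.

    Categorical covariates (maternal_education, batch, sex) are dummy-coded
    dropping the first level; 'cell_proportions' expands to the six cell
    columns minus one (they sum to 1); 'puberty' is derived from the Tanner
    columns and coded late=1.
    """
    cols = []
    for name in covariate_names:
        if name == "cell_proportions":
            # drop one proportion: the six sum to one
            cols.append(samples[CELL_COLUMNS[:-1]].astype(float))
        elif name == "puberty":
            pub = categorize_puberty(
                samples["tanner_breast_or_genital"].to_numpy(),
                samples["tanner_pubic"].to_numpy(),
                samples["menarche_or_voice"].to_numpy(),
            )
            cols.append(pd.DataFrame({"puberty_late": (pub == "late").astype(float)}, index=samples.index))
        elif name in ("maternal_education", "batch", "sex"):
            dummies = pd.get_dummies(samples[name].astype(str), prefix=name, drop_first=True)
            cols.append(dummies.astype(float))
        else:
            cols.append(samples[[name]].astype(float))
    if not cols:
        return pd.DataFrame(index=samples.index)
    return pd.concat(cols, axis=1)


def _check_design(X: np.ndarray) -> bool:
    return np.linalg.matrix_rank(X) == X.shape[1]


def fit_robust(y, x, covariates=None):
    """Huber M-estimate of the association of y (BMI-SDS) with x (beta).

    Returns dict with beta, se, n, converged, p.  Raises ValueError on a
    rank-deficient design (the caller skips the CpG).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    Z = None if covariates is None else np.asarray(covariates, dtype=float)
    n = y.size
    X = np.column_stack([np.ones(n), x] + ([] if Z is None else [Z]))
    if n <= X.shape[1] + 5:
        raise ValueError(f"too few observations ({n}) for {X.shape[1]} predictors")
    if not _check_design(X):
        raise ValueError("design matrix is rank-deficient")
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(HUBER_T))
    res = model.fit(maxiter=MAX_ITER, tol=TOL, conv="coefs", scale_est="mad")
    converged = res.fit_history["iteration"] < MAX_ITER
    beta, se = float(res.params[1]), float(res.bse[1])
    z = beta / se if se > 0 else np.nan
    return {
        "beta": beta,
        "se": se,
        "n": int(n),
        "converged": bool(converged),
        "p": float(2 * stats.norm.sf(abs(z))),
    }


def fit_logistic(case, x, covariates=None):
    """ML logistic fit of binary case status on x (beta scale).

    Returns dict with beta (log-odds per unit beta), se, n, converged, p,
    odds ratio and its 95% CI (CI geometric mean equals the OR).
    Separation or other fit failure is recorded as converged=False.
    """
    y = np.asarray(case, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    Z = None if covariates is None else np.asarray(covariates, dtype=float)
    n = y.size
    X = np.column_stack([np.ones(n), x] + ([] if Z is None else [Z]))
    if not _check_design(X):
        raise ValueError("design matrix is rank-deficient")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", False))
        beta, se = float(res.params[1]), float(res.bse[1])
    except Exception:  # separation -> singular Hessian
        return {"beta": np.nan, "se": np.nan, "n": int(n), "converged": False,
                "p": np.nan, "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan}
    if not np.isfinite(se) or se <= 0 or se > 1e3 * max(abs(beta), 1.0):
        converged = False
    z = beta / se if se > 0 else np.nan
    with np.errstate(over="ignore"):
        return {
            "beta": beta,
            "se": se,
            "n": int(n),
            "converged": converged,
            "p": float(2 * stats.norm.sf(abs(z))),
            "odds_ratio": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - 1.96 * se)),
            "ci_high": float(np.exp(beta + 1.96 * se)),
        }


def run_cohort_ewas(
    dataset,
    spec: ModelSpec,
    probes=None,
    lms_ref=None,
    iotf_cutoffs=None,
    apply_iqr: bool = True,
    stratify_by: str | None = None,
) -> pd.DataFrame:
    """Fit the per-CpG model across all analyzable probes of one cohort.

    Complete cases on the model's covariates are selected once; per-probe
    sample sizes then reflect probe-specific missingness after the IQR
    filter.  With ``stratify_by`` set to a sample column (e.g. an ethnicity
    label), each stratum is analyzed separately and results carry the
    suffixed cohort id.

    Returns a DataFrame with columns cohort_id, cpg_id, beta, se, n,
    converged, p (plus odds_ratio/ci for the binary model).
    """
    samples = dataset.samples
    if stratify_by is not None:
        out = []
        for level, idx in samples.groupby(stratify_by).groups.items():
            sub = _subset_dataset(dataset, idx, f"{dataset.cohort_id}_{level}")
            out.append(
                run_cohort_ewas(sub, spec, probes, lms_ref, iotf_cutoffs, apply_iqr)
            )
        return pd.concat(out, ignore_index=True) if out else _empty_result(spec)

    betas = dataset.betas
    if probes is not None:
        betas = betas.loc[betas.index.intersection(pd.Index(probes))]
    if apply_iqr:
        betas, _ = iqr_filter_matrix(betas)

    # outcome
    if spec.outcome == "bmi_sds":
        if "bmi_sds" in samples.columns:
            y_all = samples["bmi_sds"].astype(float)
        else:
            if lms_ref is None:
                raise ValueError("lms_ref required to derive BMI-SDS from raw BMI")
            y_all = pd.Series(
                lms_zscore(
                    samples["bmi_kg_m2"].to_numpy(),
                    samples["sex"].to_numpy(),
                    samples["age_years"].to_numpy(),
                    lms_ref,
                ),
                index=samples.index,
            )
    elif spec.outcome == "overweight_binary":
        if iotf_cutoffs is None:
            raise ValueError("iotf_cutoffs required for the case/control outcome")
        y_all, eligible = build_case_control(samples, iotf_cutoffs)
        if not eligible:
            logger.warning("cohort %s ineligible for case/control analysis", dataset.cohort_id)
            return _empty_result(spec)
    else:
        raise ValueError(f"unknown outcome {spec.outcome!r}")

    design = _design_from_covariates(samples, spec.covariate_names)
    complete = design.notna().all(axis=1) & y_all.notna()
    design, y_all = design[complete], y_all[complete]
    keep = [c for c in design.columns if design[c].nunique() > 1]
    Z = design[keep].to_numpy(dtype=float) if keep else None
    sample_ids = samples.index[complete]
    if len(sample_ids) == 0:
        logger.warning("cohort %s: no complete-case samples", dataset.cohort_id)
        return _empty_result(spec)

    beta_arr = betas[sample_ids].to_numpy(dtype=float)
    y_arr = y_all.to_numpy(dtype=float)
    rows = []
    fit = fit_robust if spec.outcome == "bmi_sds" else fit_logistic
    for i, cpg in enumerate(betas.index):
        x = beta_arr[i]
        obs = ~np.isnan(x)
        if obs.sum() == 0:
            continue
        try:
            res = fit(y_arr[obs], x[obs], None if Z is None else Z[obs])
        except ValueError as exc:
            logger.debug("cohort %s probe %s skipped: %s", dataset.cohort_id, cpg, exc)
            continue
        res["cohort_id"] = dataset.cohort_id
        res["cpg_id"] = cpg
        rows.append(res)
    if not rows:
        logger.warning("cohort %s: zero analyzable probes", dataset.cohort_id)
        return _empty_result(spec)
    out = pd.DataFrame(rows)
    lead = ["cohort_id", "cpg_id", "beta", "se", "n", "converged", "p"]
    return out[lead + [c for c in out.columns if c not in lead]]


def _empty_result(spec: ModelSpec) -> pd.DataFrame:
    cols = ["cohort_id", "cpg_id", "beta", "se", "n", "converged", "p"]
    if spec.outcome == "overweight_binary":
        cols += ["odds_ratio", "ci_low", "ci_high"]
    return pd.DataFrame(columns=cols)


def _subset_dataset(dataset, sample_index, new_id):
    from copy import copy

    sub = copy(dataset)
    sub.cohort_id = new_id
    sub.samples = dataset.samples.loc[sample_index]
    sub.betas = dataset.betas[sample_index]
    return sub


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median observed chi-square (1 df) over the
    null chi-square median 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 100:
        warnings.warn(f"genomic_lambda computed on only {p.size} P values", stacklevel=2)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)
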