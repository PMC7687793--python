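"""Phenotype construction: BMI standardization, weight-status classification,
puberty categorization, and sample/cohort selection rules.

BMI is standardized to sex- and age-adjusted SD scores (BMI-SDS) with the
LMS method: z = ((y/M)^L - 1) / (L*S), with the logarithmic limit
z = ln(y/M)/S when L ~ 0.  Weight status uses age/sex-interpolated BMI
cutoff tables in the IOTF layout; BMI exactly at a cutoff is assigned the
category the cutoff names.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .references import IOTFCutoffs, LMSReference

__all__ = [
    "lms_zscore",
    "lms_inverse",
    "iotf_classify",
    "categorize_puberty",
    "build_case_control",
    "overweight_fraction",
    "select_measurement",
]

_L_EPS = 1e-8
WEIGHT_CATEGORIES = ["underweight", "normal", "overweight", "obesity"]


def _as_arrays(*args):
    arrs = [np.asarray(a) for a in args]
    scalar = all(a.ndim == 0 for a in arrs)
    return [np.atleast_1d(a) for a in arrs], scalar


def lms_zscore(bmi, sex, age, ref: LMSReference):
    """BMI-SDS via the LMS transform with age-interpolated parameters.

    Parameters
    ----------
    bmi : float or array, kg/m2 (must be > 0)
    sex : 'F'/'M' or array thereof
    age : years
    ref : LMSReference
    """
    (bmi_a, sex_a, age_a), scalar = _as_arrays(bmi, sex, age)
    bmi_a = bmi_a.astype(float)
    if np.any(bmi_a <= 0):
        raise ValueError("bmi must be positive")
    bmi_a, sex_a, age_a = np.broadcast_arrays(bmi_a, sex_a, age_a)
    L, M, S = ref.lookup(sex_a.ravel(), age_a.ravel())
    L, M, S = (x.reshape(bmi_a.shape) for x in (L, M, S))
    z = np.where(
        np.abs(L) < _L_EPS,
        np.log(np.maximum(bmi_a, 1e-300) / M) / S,
        ((bmi_a / M) ** np.where(np.abs(L) < _L_EPS, 1.0, L) - 1.0)
        / (np.where(np.abs(L) < _L_EPS, 1.0, L) * S),
    )
    return float(z[()][0]) if scalar else z


def lms_inverse(z, sex, age, ref: LMSReference):
    """Raw BMI from BMI-SDS: y = M * (1 + L*S*z)^(1/L), limit M*exp(S*z)."""
    (z_a, sex_a, age_a), scalar = _as_arrays(z, sex, age)
    z_a = z_a.astype(float)
    z_a, sex_a, age_a = np.broadcast_arrays(z_a, sex_a, age_a)
    L, M, S = ref.lookup(sex_a.ravel(), age_a.ravel())
    L, M, S = (x.reshape(z_a.shape) for x in (L, M, S))
    base = 1.0 + L * S * z_a
    if np.any(base <= 0):
        raise ValueError("z outside the invertible range of the LMS transform")
    Lsafe = np.where(np.abs(L) < _L_EPS, 1.0, L)
    y = np.where(np.abs(L) < _L_EPS, M * np.exp(S * z_a), M * base ** (1.0 / Lsafe))
    return float(y[()][0]) if scalar else y


def iotf_classify(bmi, sex, age, cutoffs: IOTFCutoffs):
    """Weight-status category from age/sex-interpolated BMI cutoffs.

    A BMI exactly equal to a cutoff receives the category that cutoff
    names (e.g. bmi == overweight cutoff -> 'overweight').
    """
    (bmi_a, sex_a, age_a), scalar = _as_arrays(bmi, sex, age)
    bmi_a = bmi_a.astype(float)
    bmi_a, sex_a, age_a = np.broadcast_arrays(bmi_a, sex_a, age_a)
    uw, ow, ob = cutoffs.lookup(sex_a.ravel(), age_a.ravel())
    uw, ow, ob = (x.reshape(bmi_a.shape) for x in (uw, ow, ob))
    cat = np.full(bmi_a.shape, "normal", dtype=object)
    cat[bmi_a <= uw] = "underweight"
    cat[bmi_a >= ow] = "overweight"
    cat[bmi_a >= ob] = "obesity"
    return str(cat[()][0]) if scalar else cat


def categorize_puberty(tanner_breast_or_genital, tanner_pubic, menarche_or_voice):
    """'early' iff both Tanner stages are 1-3 and menarche/voice change has
    not occurred; otherwise 'late'."""
    (t1, t2, mv), scalar = _as_arrays(tanner_breast_or_genital, tanner_pubic, menarche_or_voice)
    t1, t2, mv = np.broadcast_arrays(t1.astype(int), t2.astype(int), mv.astype(bool))
    for t in (t1, t2):
        if np.any((t < 1) | (t > 5)):
            raise ValueError("Tanner stages must be in 1..5")
    early = (t1 <= 3) & (t2 <= 3) & ~mv
    out = np.where(early, "early", "late").astype(object)
    return str(out[()][0]) if scalar else out


def build_case_control(samples: pd.DataFrame, cutoffs: IOTFCutoffs, min_group: int = 10):
    """Case/control assignment for the binary overweight/obesity analysis.

    Cases are overweight or obese children, controls have normal weight,
    underweight children are excluded (assignment NaN).  The cohort is
    ineligible when either group has <= ``min_group`` participants.

    Returns
    -------
    (assignment, eligible) : (pd.Series of {1.0, 0.0, NaN}, bool)
    """
    cat = iotf_classify(
        samples["bmi_kg_m2"].to_numpy(),
        samples["sex"].to_numpy(),
        samples["age_years"].to_numpy(),
        cutoffs,
    )
    assignment = pd.Series(np.nan, index=samples.index, name="case")
    assignment[np.isin(cat, ["overweight", "obesity"])] = 1.0
    assignment[cat == "normal"] = 0.0
    n_case = int((assignment == 1.0).sum())
    n_control = int((assignment == 0.0).sum())
    eligible = min(n_case, n_control) > min_group
    return assignment, eligible


def overweight_fraction(samples: pd.DataFrame, cutoffs: IOTFCutoffs, flag_above: float = 0.30):
    """Fraction overweight+obese among non-underweight samples.

    Returns (fraction, flagged) with flagged True when strictly above
    ``flag_above``.  Raises if no non-underweight samples exist.
    """
    cat = iotf_classify(
        samples["bmi_kg_m2"].to_numpy(),
        samples["sex"].to_numpy(),
        samples["age_years"].to_numpy(),
        cutoffs,
    )
    denom = int((cat != "underweight").sum())
    if denom == 0:
        raise ValueError("overweight_fraction undefined: no non-underweight samples")
    frac = float(np.isin(cat, ["overweight", "obesity"]).sum()) / denom
    return frac, frac > flag_above


def select_measurement(timepoints, window):
    """Oldest age within [min, max] (inclusive) at which BMI and methylation
    are both available; None when no timepoint qualifies.

    ``timepoints`` is an iterable of (age, bmi_available, meth_available).
    """
    lo, hi = window
    eligible = [age for age, has_bmi, has_meth in timepoints if has_bmi and has_meth and lo <= age <= hi]
    return max(eligible) if eligible else None
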