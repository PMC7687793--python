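"""Probe-level quality control for methylation beta matrices.

Two filters are applied per cohort before modeling: a per-CpG extreme
value rule (values outside [Q1 - 3*IQR, Q3 + 3*IQR] are set to missing)
and manifest-driven probe exclusion/flagging (X/Y probes, cross-reactive
probes and probes measured in only one study are excluded; SNP, INDEL
and repeat probes are retained but flagged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["iqr_filter", "iqr_filter_matrix", "filter_probes", "validate_betas"]

SEX_CHROMOSOMES = ("X", "Y")
RETAIN_FLAGS = ("flag_snp", "flag_indel", "flag_repeat")


def iqr_filter(values, k: float = 3.0, quantile_method: str = "linear"):
    """Set values outside [Q1 - k*IQR, Q3 + k*IQR] to missing.

    Quartiles are computed once on the input (not iterated), with Q1/Q3
    by linear interpolation between order statistics by default.  With
    fewer than 4 non-missing values the vector is returned unchanged
    with a warning.

    Returns
    -------
    (filtered, n_removed) : (np.ndarray with NaN for missing/removed, int)
    """
    x = np.asarray(values, dtype=float).copy()
    obs = ~np.isnan(x)
    if obs.sum() < 4:
        warnings.warn("iqr_filter: fewer than 4 non-missing values, CpG skipped", stacklevel=2)
        return x, 0
    q1, q3 = np.quantile(x[obs], [0.25, 0.75], method=quantile_method)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    out = obs & ((x < lo) | (x > hi))
    x[out] = np.nan
    return x, int(out.sum())


def iqr_filter_matrix(betas: pd.DataFrame, k: float = 3.0, quantile_method: str = "linear"):
    """Apply :func:`iqr_filter` to each probe row of a probe x sample matrix.

    Returns (filtered matrix, per-probe removal counts).
    """
    arr = betas.to_numpy(dtype=float, copy=True)
    removed = np.zeros(arr.shape[0], dtype=int)
    for i in range(arr.shape[0]):
        obs = ~np.isnan(arr[i])
        if obs.sum() < 4:
            continue
        q1, q3 = np.quantile(arr[i, obs], [0.25, 0.75], method=quantile_method)
        iqr = q3 - q1
        out = obs & ((arr[i] < q1 - k * iqr) | (arr[i] > q3 + k * iqr))
        arr[i, out] = np.nan
        removed[i] = out.sum()
    return (
        pd.DataFrame(arr, index=betas.index, columns=betas.columns),
        pd.Series(removed, index=betas.index, name="n_removed"),
    )


def filter_probes(
    annotation: pd.DataFrame,
    per_study_presence: pd.Series,
    min_studies: int = 2,
) -> pd.DataFrame:
    """Build the analysis probe set with exclusion reasons and retained flags.

    Parameters
    ----------
    annotation : probe manifest indexed or keyed by ``cpg_id`` with columns
        ``chromosome`` and the 0/1 flag columns
        (flag_snp/flag_indel/flag_repeat/flag_cross_reactive).
    per_study_presence : Series mapping cpg_id -> number of studies in which
        the probe was measured; its index defines the probes under
        consideration.

    Returns
    -------
    DataFrame indexed by cpg_id with boolean ``retained``, string
    ``exclusion_reason`` ('' when retained) and string ``flags``
    (comma-joined retained-probe flags, including 'unannotated').
    """
    ann = annotation.set_index("cpg_id") if "cpg_id" in annotation.columns else annotation
    cpgs = per_study_presence.index
    result = pd.DataFrame(
        {"retained": True, "exclusion_reason": "", "flags": ""}, index=cpgs
    )
    result.index.name = "cpg_id"

    single = per_study_presence < min_studies
    result.loc[single, "retained"] = False
    result.loc[single, "exclusion_reason"] = "single_study"

    known = cpgs.intersection(ann.index)
    unknown = cpgs.difference(ann.index)
    if len(unknown):
        logger.warning("filter_probes: %d probes absent from annotation, flagged", len(unknown))
        result.loc[unknown, "flags"] = "unannotated"

    chrom = ann.loc[known, "chromosome"].astype(str)
    sex_probes = known[chrom.isin(SEX_CHROMOSOMES)]
    mask = result.loc[sex_probes, "retained"]
    result.loc[sex_probes, "retained"] = False
    result.loc[sex_probes[mask], "exclusion_reason"] = "sex_chromosome"

    if "flag_cross_reactive" in ann.columns:
        xr = known[ann.loc[known, "flag_cross_reactive"].astype(bool)]
        mask = result.loc[xr, "retained"]
        result.loc[xr, "retained"] = False
        result.loc[xr[mask], "exclusion_reason"] = "cross_reactive"

    flag_cols = [c for c in RETAIN_FLAGS if c in ann.columns]
    for cpg in known:
        flags = [c.removeprefix("flag_") for c in flag_cols if bool(ann.at[cpg, c])]
        if flags:
            result.at[cpg, "flags"] = ",".join(flags)
    return result


@dataclass
class BetaValidationReport:
    n_probes: int
    n_samples: int
    missing_per_probe: pd.Series = field(repr=False)
    missing_per_sample: pd.Series = field(repr=False)
    all_missing_probes: list = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return (self.missing_per_probe == 0).all()


def validate_betas(betas: pd.DataFrame) -> BetaValidationReport:
    """Assert all non-missing values lie in [0, 1]; report missingness.

    Raises ValueError naming the offending probe and sample on any
    out-of-range value.  All-missing probes are reported, not fatal.
    """
    arr = betas.to_numpy(dtype=float)
    bad = ~np.isnan(arr) & ((arr < 0.0) | (arr > 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"beta value out of [0,1]: probe {betas.index[i]!r}, sample "
            f"{betas.columns[j]!r}, value {arr[i, j]!r}"
        )
    miss = np.isnan(arr)
    per_probe = pd.Series(miss.sum(axis=1), index=betas.index, name="n_missing")
    per_sample = pd.Series(miss.sum(axis=0), index=betas.columns, name="n_missing")
    all_missing = list(betas.index[miss.all(axis=1)])
    return BetaValidationReport(
        n_probes=betas.shape[0],
        n_samples=betas.shape[1],
        missing_per_probe=per_probe,
        missing_per_sample=per_sample,
        all_missing_probes=all_missing,
    )
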