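"""Fixed-effects inverse-variance-weighted meta-analysis of cohort EWAS
results, with Cochran-Q/I2 heterogeneity, leave-one-out re-pooling,
Bonferroni and Benjamini-Hochberg multiple-testing control, and the
per-10%-methylation reporting scale.

Per-study estimates (beta_i, se_i) are pooled with weights w_i = 1/se_i^2:

    pooled_beta = sum(w_i * beta_i) / sum(w_i)
    pooled_se   = sum(w_i) ** -0.5
    z = pooled_beta / pooled_se,  two-sided standard-normal P

Q = sum(w_i * (beta_i - pooled_beta)^2), I2 = max(0, 100 * (Q - (k-1)) / Q),
with I2 > 50 flagged as heterogeneous.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ivw_pool",
    "heterogeneity",
    "leave_one_out",
    "bonferroni_threshold",
    "bh_adjust",
    "rescale_per10pct",
    "run_meta",
    "write_metal",
    "manhattan_table",
    "volcano_table",
    "forest_table",
]

I2_FLAG_THRESHOLD = 50.0
PER10PCT = 0.1  # unit beta = 100 percentage points of methylation


def ivw_pool(estimates):
    """Inverse-variance fixed-effects pool of (beta, se) pairs.

    Returns (pooled_beta, pooled_se, z, p).  Raises on any se <= 0,
    naming the offending entry.
    """
    est = list(estimates)
    if not est:
        raise ValueError("ivw_pool: empty estimate list")
    betas = np.array([e[0] for e in est], dtype=float)
    ses = np.array([e[1] for e in est], dtype=float)
    bad = np.where(ses <= 0)[0]
    if bad.size:
        raise ValueError(f"ivw_pool: non-positive SE at entry {bad[0]}")
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = pooled / se
    return pooled, se, z, float(2 * stats.norm.sf(abs(z)))


def heterogeneity(estimates, pooled_beta):
    """Cochran's Q and I2 (percent). I2 is NaN when k < 2."""
    est = list(estimates)
    betas = np.array([e[0] for e in est], dtype=float)
    ses = np.array([e[1] for e in est], dtype=float)
    w = 1.0 / ses**2
    Q = float(np.sum(w * (betas - pooled_beta) ** 2))
    k = len(est)
    if k < 2:
        return Q, float("nan")
    i2 = max(0.0, 100.0 * (Q - (k - 1)) / Q) if Q > 0 else 0.0
    return Q, float(i2)


def bonferroni_threshold(m: int) -> float:
    """Family-wise significance threshold 0.05/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 0.05 / m


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (original order)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("P values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rescale_per10pct(beta_per_unit, se_per_unit):
    """Effect and SE per 10% methylation increase (x 0.1 from the unit-beta
    scale); the z statistic is unchanged."""
    return np.asarray(beta_per_unit) * PER10PCT, np.asarray(se_per_unit) * PER10PCT


def _direction_char(beta):
    if np.isnan(beta):
        return "?"
    return "+" if beta > 0 else ("-" if beta < 0 else "0")


def run_meta(
    cohort_results: dict,
    retained_probes=None,
    subset_rule: str | None = None,
    cohort_info: pd.DataFrame | None = None,
    min_studies: int = 2,
    fdr_q: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pool per-cohort EWAS tables into one per-CpG meta-analysis table.

    Parameters
    ----------
    cohort_results : mapping cohort_id -> DataFrame with columns
        cpg_id, beta, se, n, converged (the unit-beta cohort scale).
    retained_probes : optional iterable restricting the analyzed universe.
    subset_rule : None | 'europeans_only' | 'max_overweight_30pct' |
        'conservative'; drops whole cohorts before pooling using
        ``cohort_info`` columns (ancestry_label, overweight_fraction,
        selection_flag).
    min_studies : probes reported by fewer cohorts are dropped (set to 1
        only for single-cohort unit testing).

    Returns a DataFrame sorted by P (ties broken by cpg_id) with the
    pooled effect on the per-10%-methylation scale.
    """
    selected = _apply_subset_rule(cohort_results, subset_rule, cohort_info)
    if not selected:
        raise ValueError(f"no cohorts remain after subset rule {subset_rule!r}")
    cohort_order = sorted(selected)

    frames = []
    for cid in cohort_order:
        df = selected[cid]
        df = df[df["converged"].astype(bool) & (df["se"] > 0)]
        frames.append(df.assign(cohort_id=cid)[["cohort_id", "cpg_id", "beta", "se", "n"]])
    stacked = pd.concat(frames, ignore_index=True)
    if retained_probes is not None:
        stacked = stacked[stacked["cpg_id"].isin(set(retained_probes))]

    rows = []
    for cpg, grp in stacked.groupby("cpg_id", sort=False):
        k = len(grp)
        if k < min_studies:
            continue
        pooled, se, z, p = ivw_pool(zip(grp["beta"], grp["se"]))
        Q, i2 = heterogeneity(zip(grp["beta"], grp["se"]), pooled)
        by_cohort = dict(zip(grp["cohort_id"], grp["beta"]))
        direction = "".join(
            _direction_char(by_cohort[c]) if c in by_cohort else "?" for c in cohort_order
        )
        b10, s10 = rescale_per10pct(pooled, se)
        rows.append(
            {
                "cpg_id": cpg,
                "pooled_beta_per10pct": float(b10),
                "pooled_se_per10pct": float(s10),
                "z": z,
                "p": p,
                "Q": Q,
                "i2": i2,
                "heterogeneous": bool(i2 > I2_FLAG_THRESHOLD) if np.isfinite(i2) else False,
                "k_studies": k,
                "total_n": int(grp["n"].sum()),
                "direction": direction,
            }
        )
    if not rows:
        warnings.warn("run_meta: no probes met the minimum-study requirement")
        return pd.DataFrame(
            columns=[
                "cpg_id", "pooled_beta_per10pct", "pooled_se_per10pct", "z", "p",
                "p_fdr", "bonferroni_significant", "Q", "i2", "heterogeneous",
                "k_studies", "total_n", "direction",
            ]
        )
    meta = pd.DataFrame(rows)
    m = len(meta)
    meta["p_fdr"] = bh_adjust(meta["p"].to_numpy())
    meta["bonferroni_significant"] = meta["p"] < bonferroni_threshold(m)
    meta["fdr_significant"] = meta["p_fdr"] < fdr_q
    meta = meta.sort_values(["p", "cpg_id"], kind="mergesort").reset_index(drop=True)
    meta.attrs["n_probes"] = m
    meta.attrs["cohort_order"] = cohort_order
    return meta


def _apply_subset_rule(cohort_results, subset_rule, cohort_info):
    if subset_rule is None:
        return dict(cohort_results)
    if cohort_info is None:
        raise ValueError("cohort_info is required to apply a subset rule")
    info = cohort_info.set_index("cohort_id") if "cohort_id" in cohort_info.columns else cohort_info
    keep = {}
    for cid, df in cohort_results.items():
        row = info.loc[cid]
        euro = str(row.get("ancestry_label", "")) == "European"
        lean = float(row.get("overweight_fraction", 0.0)) <= 0.30
        unselected = not bool(row.get("selection_flag", False))
        ok = {
            "europeans_only": euro,
            "max_overweight_30pct": lean,
            "conservative": euro and lean and unselected,
        }.get(subset_rule)
        if ok is None:
            raise ValueError(f"unknown subset rule {subset_rule!r}")
        if ok:
            keep[cid] = df
    return keep


def leave_one_out(cohort_results: dict, cpg_ids=None, **run_meta_kwargs) -> pd.DataFrame:
    """Re-pool with each cohort removed in turn.

    Returns the concatenated meta tables with a ``left_out`` column; empty
    (with a warning) when only one cohort is available.
    """
    cohorts = sorted(cohort_results)
    if len(cohorts) < 2:
        warnings.warn("leave_one_out requires at least 2 cohorts")
        return pd.DataFrame()
    run_meta_kwargs.setdefault("min_studies", 1)
    out = []
    for left_out in cohorts:
        rest = {c: df for c, df in cohort_results.items() if c != left_out}
        sub = run_meta(rest, **run_meta_kwargs)
        if cpg_ids is not None:
            sub = sub[sub["cpg_id"].isin(set(cpg_ids))]
        out.append(sub.assign(left_out=left_out))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# tabular exports


def write_metal(meta: pd.DataFrame, path, header_lines=()) -> None:
    """Write a METAL-style tab-separated result file."""
    cols = {
        "cpg_id": "MarkerName",
        "pooled_beta_per10pct": "Effect",
        "pooled_se_per10pct": "StdErr",
        "z": "Zscore",
        "p": "P",
        "p_fdr": "FDR_P",
        "direction": "Direction",
        "Q": "HetQ",
        "i2": "HetISq",
        "k_studies": "K_Studies",
        "total_n": "Total_N",
    }
    out = meta[list(cols)].rename(columns=cols)
    if "flags" in meta.columns:
        out["Flags"] = meta["flags"]
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False)


def manhattan_table(meta: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    ann = manifest.set_index("cpg_id") if "cpg_id" in manifest.columns else manifest
    joined = meta.join(ann[["chromosome", "position"]], on="cpg_id")
    return pd.DataFrame(
        {
            "cpg_id": joined["cpg_id"],
            "chr": joined["chromosome"],
            "pos": joined["position"],
            "neglog10_p": -np.log10(joined["p"]),
        }
    )


def volcano_table(meta: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cpg_id": meta["cpg_id"],
            "effect_per10pct": meta["pooled_beta_per10pct"],
            "neglog10_p": -np.log10(meta["p"]),
        }
    )


def forest_table(cohort_results: dict, cpg_id: str) -> pd.DataFrame:
    """Per-cohort rows plus the pooled row for one CpG (per-10% scale)."""
    rows = []
    ests = []
    for cid in sorted(cohort_results):
        df = cohort_results[cid]
        hit = df[(df["cpg_id"] == cpg_id) & df["converged"].astype(bool)]
        if hit.empty:
            continue
        b, s = float(hit["beta"].iloc[0]), float(hit["se"].iloc[0])
        ests.append((b, s))
        b10, s10 = rescale_per10pct(b, s)
        rows.append(
            {
                "label": cid,
                "beta_per10pct": float(b10),
                "se_per10pct": float(s10),
                "ci_low": float(b10 - 1.96 * s10),
                "ci_high": float(b10 + 1.96 * s10),
            }
        )
    if ests:
        pooled, se, _, _ = ivw_pool(ests)
        b10, s10 = rescale_per10pct(pooled, se)
        rows.append(
            {
                "label": "pooled",
                "beta_per10pct": float(b10),
                "se_per10pct": float(s10),
                "ci_low": float(b10 - 1.96 * s10),
                "ci_high": float(b10 + 1.96 * s10),
            }
        )
    return pd.DataFrame(rows)
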