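"""Comparison of meta-analysis results with previously published CpG sets:
per-study Bonferroni look-up, hypergeometric enrichment of prior sets among
top hits, Pearson correlation of effect estimates, correlation-difference
tests (Fisher r-to-z), and chi-square overlap of enriched sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PriorCpGSet",
    "EnrichmentResult",
    "lookup_replication",
    "hypergeom_enrichment",
    "top_list",
    "effect_correlation",
    "correlation_pvalue",
    "compare_correlations",
    "overlap_chi2",
    "enrichment_report",
]


@dataclass(frozen=True)
class PriorCpGSet:
    """A published CpG list, optionally with per-CpG effect estimates."""

    source_label: str
    cpg_ids: tuple
    effects: tuple | None = None
    effect_units: str = ""
    n_cpgs_tested_in_source: int | None = None

    def __post_init__(self):
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValueError("prior CpG ids must be unique")
        if self.effects is not None and len(self.effects) != len(self.cpg_ids):
            raise ValueError("effects must align with cpg_ids")

    def __len__(self):
        return len(self.cpg_ids)

    @classmethod
    def from_csv(cls, path, source_label=None) -> "PriorCpGSet":
        """Read a prior-set CSV with columns cpg_id[, effect, source, n_cpgs_tested]."""
        df = pd.read_csv(path)
        label = source_label or (str(df["source"].iloc[0]) if "source" in df else str(path))
        effects = tuple(df["effect"].astype(float)) if "effect" in df else None
        n_tested = int(df["n_cpgs_tested"].iloc[0]) if "n_cpgs_tested" in df else len(df)
        return cls(label, tuple(df["cpg_id"]), effects, n_cpgs_tested_in_source=n_tested)


@dataclass(frozen=True)
class EnrichmentResult:
    source_label: str
    cutoff: float
    K: int  # prior-set size
    n: int  # top-list size
    N: int  # analyzed-probe universe
    k: int  # overlap
    p_upper: float


def lookup_replication(prior: PriorCpGSet, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG look-up of a prior set in a meta table.

    The replication cutoff is Bonferroni within the source study:
    0.05 / n_cpgs_tested_in_source.  CpGs absent from the analyzed
    universe are reported as untested, not as failures.
    """
    if len(prior) == 0:
        raise ValueError("empty prior set")
    n_tested = prior.n_cpgs_tested_in_source or len(prior)
    cutoff = 0.05 / n_tested
    p_by_cpg = meta.set_index("cpg_id")["p"]
    rows = []
    for cpg in prior.cpg_ids:
        tested = cpg in p_by_cpg.index
        p = float(p_by_cpg[cpg]) if tested else np.nan
        rows.append(
            {
                "cpg_id": cpg,
                "source": prior.source_label,
                "tested": tested,
                "p": p,
                "cutoff": cutoff,
                "replicated": bool(tested and p < cutoff),
            }
        )
    return pd.DataFrame(rows)


def hypergeom_enrichment(K: int, n: int, N: int, k: int) -> float:
    """Exact one-sided upper hypergeometric tail P(X >= k).

    X counts prior-set members (K of N in the universe) among the n
    top-list draws.  Evaluated by exact log-space summation (scipy's
    hypergeometric survival function); no normal approximation.
    """
    if not (0 <= k <= min(K, n) <= N and K <= N):
        raise ValueError(f"inconsistent counts K={K}, n={n}, N={N}, k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def top_list(meta: pd.DataFrame, cutoff: float) -> set:
    """CpGs with raw meta P strictly below ``cutoff``."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    return set(meta.loc[meta["p"] < cutoff, "cpg_id"])


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided P for a Pearson r on n pairs: t = r*sqrt(n-2)/sqrt(1-r^2),
    df = n-2."""
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if abs(r) >= 1:
        return float(np.finfo(float).tiny)
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2 * stats.t.sf(abs(t), n - 2))


def effect_correlation(prior_effects, meta_effects):
    """Pearson correlation of matched effect estimates.

    Returns (r, n_pairs, p_two_sided); raises on < 4 pairs or zero
    variance in either vector.
    """
    x = np.asarray(prior_effects, dtype=float)
    y = np.asarray(meta_effects, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("effect_correlation requires >= 4 matched pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in an effect vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, n, correlation_pvalue(r, n)


def compare_correlations(r1: float, n1: int, r2: float, n2: int):
    """Fisher r-to-z test of the difference between two independent
    correlations; returns (z, p_two_sided)."""
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
        if n <= 3:
            raise ValueError("n must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(z), float(2 * stats.norm.sf(abs(z)))


def overlap_chi2(set1, set2, universe):
    """Pearson chi-square (1 df, no continuity correction) on the 2x2
    membership table of two CpG sets within a universe."""
    s1, s2, u = set(set1), set(set2), set(universe)
    if not (s1 <= u and s2 <= u):
        raise ValueError("both sets must be subsets of the universe")
    if not s1 or not s2 or s1 == u or s2 == u:
        raise ValueError("degenerate margins: sets must be nonempty proper subsets")
    a = len(s1 & s2)
    b = len(s1 - s2)
    c = len(s2 - s1)
    d = len(u) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def enrichment_report(meta: pd.DataFrame, priors, cutoffs=(1e-5, 0.05), universe_size=None):
    """Table-3-style enrichment report: one row per (prior set, cutoff).

    The universe N defaults to the analyzed-probe count of the meta table;
    K is the full published prior-set size (restrict externally if the
    intersection-with-universe convention is wanted).
    """
    N = int(universe_size if universe_size is not None else len(meta))
    rows = []
    for prior in priors:
        prior_ids = set(prior.cpg_ids)
        for cutoff in cutoffs:
            top = top_list(meta, cutoff)
            k = len(top & prior_ids)
            K = len(prior)
            res = EnrichmentResult(
                prior.source_label, cutoff, K, len(top), N, k,
                hypergeom_enrichment(K, len(top), N, k),
            )
            rows.append(res.__dict__)
    return pd.DataFrame(rows)
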