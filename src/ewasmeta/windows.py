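"""Positional queries over the probe manifest: neighboring CpGs within a
+-5 kb window, proximity to BMI GWAS loci within +-2 Mb, and nominal
significance summaries of a CpG's neighborhood.

Coordinates are 1-based base pairs (array-manifest convention) and window
bounds are inclusive at exactly +-half_width.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["neighbors", "near_gwas_loci", "nominal_neighbor_summary"]

NEIGHBOR_HALF_WIDTH = 5_000
GWAS_HALF_WIDTH = 2_000_000


def _manifest_indexed(manifest: pd.DataFrame) -> pd.DataFrame:
    return manifest.set_index("cpg_id") if "cpg_id" in manifest.columns else manifest


def neighbors(
    chromosome,
    center_position: int,
    manifest: pd.DataFrame,
    half_width: int = NEIGHBOR_HALF_WIDTH,
    exclude_cpg: str | None = None,
) -> pd.DataFrame:
    """All probes on ``chromosome`` with |position - center| <= half_width.

    The center probe itself (``exclude_cpg``, or any probe at exactly the
    center position when not given) is excluded.  Result is sorted by
    position and carries a signed ``distance`` column.
    """
    if half_width <= 0 or center_position < 1:
        raise ValueError("half_width must be > 0 and center_position >= 1")
    ann = _manifest_indexed(manifest)
    on_chrom = ann[ann["chromosome"].astype(str) == str(chromosome)]
    if on_chrom.empty:
        logger.warning("neighbors: chromosome %r absent from manifest", chromosome)
        return pd.DataFrame(columns=["chromosome", "position", "distance"])
    dist = on_chrom["position"].astype(int) - int(center_position)
    hit = on_chrom[np.abs(dist) <= half_width].copy()
    hit["distance"] = dist[np.abs(dist) <= half_width]
    if exclude_cpg is not None:
        hit = hit[hit.index != exclude_cpg]
    else:
        hit = hit[hit["distance"] != 0]
    return hit.sort_values("position")


def near_gwas_loci(cpg_row, loci: pd.DataFrame, half_width: int = GWAS_HALF_WIDTH):
    """Whether a CpG lies within +-half_width of any GWAS locus.

    ``cpg_row`` needs ``chromosome`` and ``position``; ``loci`` is a frame
    with columns (chromosome, position), 1-based single positions.

    Returns (is_near, nearest_same_chromosome_distance) where the distance
    is NaN if no locus shares the chromosome.
    """
    if loci.empty:
        raise ValueError("loci list must be non-empty")
    chrom = str(cpg_row["chromosome"])
    pos = int(cpg_row["position"])
    same = loci[loci["chromosome"].astype(str) == chrom]
    if same.empty:
        return False, float("nan")
    dist = np.abs(same["position"].astype(int) - pos)
    nearest = int(dist.min())
    return bool(nearest <= half_width), nearest


def nominal_neighbor_summary(
    center_cpg: str,
    meta: pd.DataFrame,
    manifest: pd.DataFrame,
    half_width: int = NEIGHBOR_HALF_WIDTH,
    nominal_p: float = 0.05,
) -> dict:
    """Summarize the +-half_width neighborhood of one CpG in a meta table.

    Returns dict with n_neighbors, n_nominal (neighbor meta P strictly
    below ``nominal_p``), and sign_agreement (fraction of neighbors with
    effect sign equal to the center's; NaN when there are no neighbors
    with results).
    """
    ann = _manifest_indexed(manifest)
    if center_cpg not in ann.index:
        raise KeyError(f"{center_cpg!r} not in manifest")
    by_cpg = meta.set_index("cpg_id")
    if center_cpg not in by_cpg.index:
        raise KeyError(f"{center_cpg!r} not in meta table")
    row = ann.loc[center_cpg]
    nb = neighbors(row["chromosome"], int(row["position"]), ann, half_width, exclude_cpg=center_cpg)
    present = nb.index.intersection(by_cpg.index)
    n_nominal = int((by_cpg.loc[present, "p"] < nominal_p).sum())
    if len(present) == 0:
        agree = float("nan")
    else:
        center_sign = np.sign(by_cpg.at[center_cpg, "pooled_beta_per10pct"])
        signs = np.sign(by_cpg.loc[present, "pooled_beta_per10pct"])
        agree = float((signs == center_sign).mean())
    return {
        "center_cpg": center_cpg,
        "n_neighbors": int(len(nb)),
        "n_with_results": int(len(present)),
        "n_nominal": n_nominal,
        "sign_agreement": agree,
    }
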