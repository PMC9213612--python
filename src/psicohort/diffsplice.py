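"""Cohort-level comparison of exon inclusion (ΔPSI flagging).

Per-sample PSI values are averaged within each cohort; exons whose
cohort means differ by more than a threshold (default 20 percentage
points, strict inequality) are flagged as divergent. Δ is defined
old − young, so positive Δ means the exon is included more often in
the old cohort. Overall concordance between cohorts is summarized by
Spearman's ρ on the paired cohort means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SplicingSummary",
    "cohort_mean_psi",
    "flag_divergent",
    "psi_concordance",
    "compare_cohorts",
    "write_comparison_table",
]

logger = logging.getLogger(__name__)


@dataclass
class SplicingSummary:
    n_exons_compared: int
    n_flagged_exons: int
    n_flagged_genes: int
    rho: float | None


def cohort_mean_psi(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    min_defined_samples: int = 3,
) -> pd.DataFrame:
    """Average defined PSI per exon within each cohort.

    ``matrix`` is the long-form PSI table (exon_key, gene_id,
    sample_id, psi). An exon is dropped when either cohort has fewer
    than ``min_defined_samples`` samples with defined PSI.

    Returns a DataFrame indexed by exon_key with columns gene_id,
    mean_psi_young, mean_psi_old, n_young, n_old.
    """
    unknown = sorted(set(matrix["sample_id"]) - set(groups))
    if unknown:
        raise ValueError(f"samples without cohort assignment: {unknown}")
    cohorts = set(groups.values())
    if cohorts != {"young", "old"}:
        raise ValueError(f"expected cohorts {{'young', 'old'}}, got {sorted(cohorts)}")

    df = matrix.copy()
    df["cohort"] = df["sample_id"].map(groups)
    defined = df.dropna(subset=["psi"])
    agg = (
        defined.groupby(["exon_key", "cohort"])["psi"]
        .agg(["mean", "count"])
        .unstack("cohort")
    )
    genes = matrix.drop_duplicates("exon_key").set_index("exon_key")["gene_id"]
    out = pd.DataFrame(index=agg.index)
    out["gene_id"] = genes
    for cohort in ("young", "old"):
        out[f"mean_psi_{cohort}"] = agg.get(("mean", cohort), np.nan)
        out[f"n_{cohort}"] = (
            agg.get(("count", cohort), pd.Series(0, index=agg.index)).fillna(0).astype(int)
        )
    keep = (out["n_young"] >= min_defined_samples) & (out["n_old"] >= min_defined_samples)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d exons with insufficient defined samples", dropped)
    return out[keep]


def flag_divergent(means: pd.DataFrame, delta_threshold: float = 0.20) -> pd.DataFrame:
    """Flag exons whose cohort-mean PSI differs by more than the threshold.

    Strict inequality: |Δ| must exceed the threshold; |Δ| exactly at
    the boundary is not flagged. Rows are sorted by |Δ| descending.
    """
    if not 0 < delta_threshold < 1:
        raise ValueError(f"delta_threshold must lie in (0, 1), got {delta_threshold}")
    out = means.copy()
    out["delta_psi"] = out["mean_psi_old"] - out["mean_psi_young"]
    out["flagged"] = out["delta_psi"].abs() > delta_threshold
    return out.sort_values("delta_psi", key=lambda s: s.abs(), ascending=False)


def psi_concordance(means: pd.DataFrame) -> float | None:
    """Spearman rank correlation of young vs old cohort-mean PSI.

    Returns None (with a warning) when fewer than 3 exons have both
    means defined.
    """
    paired = means.dropna(subset=["mean_psi_young", "mean_psi_old"])
    if len(paired) < 3:
        logger.warning("psi_concordance: only %d paired exons; rho undefined", len(paired))
        return None
    rho, _p = stats.spearmanr(paired["mean_psi_young"], paired["mean_psi_old"])
    return float(rho)


def compare_cohorts(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    delta_threshold: float = 0.20,
    min_defined_samples: int = 3,
) -> tuple[pd.DataFrame, SplicingSummary]:
    """End-to-end cohort comparison: means -> flags -> summary."""
    means = cohort_mean_psi(matrix, groups, min_defined_samples)
    comparison = flag_divergent(means, delta_threshold)
    flagged = comparison[comparison["flagged"]]
    summary = SplicingSummary(
        n_exons_compared=len(comparison),
        n_flagged_exons=len(flagged),
        n_flagged_genes=flagged["gene_id"].nunique(),
        rho=psi_concordance(means),
    )
    return comparison, summary


def write_comparison_table(comparison: pd.DataFrame, path: str | Path) -> None:
    """TSV mirroring the divergent-exon scatter classes (flagged vs not)."""
    out = comparison.reset_index().rename(columns={"index": "exon_key"})
    cols = [
        "exon_key",
        "gene_id",
        "mean_psi_young",
        "mean_psi_old",
        "delta_psi",
        "flagged",
    ]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
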