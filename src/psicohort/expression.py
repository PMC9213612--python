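"""Expression-level summaries: CPM, detection, fold-change bins, MDS.

Covers the bookkeeping around a cohort RNA-seq comparison that is not
the differential test itself (which an external tool provides as a DEG
table of gene id, fold change, q-value): counts-per-million
normalization, the 0.3-CPM detection rule and cohort-exclusive gene
sets, binning of DEG fold changes, red-blood-cell marker reporting,
cohort metadata statistics, and a multidimensional-scaling embedding of
samples from pairwise log-fold-change distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "cpm",
    "detected_genes",
    "DetectionResult",
    "fold_change_categories",
    "FoldChangeCategories",
    "blood_marker_report",
    "metadata_summary",
    "classical_mds",
    "mds_embedding",
    "homolog_overlap",
    "DEFAULT_BLOOD_MARKERS",
]

logger = logging.getLogger(__name__)

# Canine homologs of transcripts highly expressed in red blood cells,
# used to screen brain tissue for residual blood content.
DEFAULT_BLOOD_MARKERS = (
    "ENSCAFG00000032615",
    "ENSCAFG00000029224",
    "ENSCAFG00000028569",
    "ENSCAFG00000030286",
)


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million sequenced reads.

    ``cpm[g, s] = counts[g, s] / library_size[s] * 1e6``. Library sizes
    default to column sums. With default library sizes every column of
    the result sums to one million.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        bad = library_sizes.index[library_sizes <= 0].tolist()
        raise ValueError(f"non-positive library size for samples: {bad}")
    return counts.div(library_sizes, axis=1) * 1e6


@dataclass
class DetectionResult:
    detected_young: set[str]
    detected_old: set[str]
    exclusive_young: set[str]
    exclusive_old: set[str]
    shared: set[str]
    # for each exclusive gene: fraction of other-cohort samples below threshold
    other_cohort_below: pd.Series


def detected_genes(
    cpm_matrix: pd.DataFrame,
    groups: Mapping[str, str],
    detect_threshold: float = 0.3,
) -> DetectionResult:
    """Apply the CPM detection rule per cohort.

    A gene is detected in a cohort when its CPM reaches the threshold
    (default 0.3, ≈ 20 reads at ~70 M depth) in at least one sample of
    that cohort. Exclusive genes are detected in exactly one cohort;
    for each, the fraction of the *other* cohort's samples below the
    threshold is reported (the emulated study notes most exclusive
    genes sit below detection in ≥ 50% of the other cohort).
    """
    if detect_threshold <= 0:
        raise ValueError("detect_threshold must be > 0")
    young_cols = [s for s in cpm_matrix.columns if groups[s] == "young"]
    old_cols = [s for s in cpm_matrix.columns if groups[s] == "old"]
    det_y = cpm_matrix[young_cols].ge(detect_threshold).any(axis=1)
    det_o = cpm_matrix[old_cols].ge(detect_threshold).any(axis=1)
    detected_young = set(cpm_matrix.index[det_y])
    detected_old = set(cpm_matrix.index[det_o])
    exclusive_young = detected_young - detected_old
    exclusive_old = detected_old - detected_young
    below = {}
    for g in exclusive_young:
        below[g] = float(cpm_matrix.loc[g, old_cols].lt(detect_threshold).mean())
    for g in exclusive_old:
        below[g] = float(cpm_matrix.loc[g, young_cols].lt(detect_threshold).mean())
    return DetectionResult(
        detected_young=detected_young,
        detected_old=detected_old,
        exclusive_young=exclusive_young,
        exclusive_old=exclusive_old,
        shared=detected_young & detected_old,
        other_cohort_below=pd.Series(below, dtype=float).sort_index(),
    )


@dataclass
class FoldChangeCategories:
    """Counts and shares of DEG fold-change bins (FC = old/young, linear)."""

    n_total: int
    n_up: int  # FC > 1
    n_down: int  # FC < 1
    n_ties: int  # FC == 1 exactly
    n_up_gt_1p5: int  # FC > 1.5
    n_down_le_0p5: int  # FC <= 0.5 (a 50% or larger decrease)
    n_small_change: int  # 0.5 < FC < 1.5
    n_large_change: int  # FC <= 0.5 or FC >= 1.5
    pct_up_gt_1p5: float  # of upregulated, one decimal
    pct_down_le_0p5: float  # of downregulated, one decimal


def fold_change_categories(degs: pd.DataFrame) -> FoldChangeCategories:
    """Bin DEG fold changes the way the cohort study reports them.

    ``degs`` needs a ``fold_change`` column (linear old/young). Genes
    with FC exactly 1 are counted neither up nor down (warned).
    Percentages are rounded half-up to one decimal.
    """
    if len(degs) == 0:
        return FoldChangeCategories(0, 0, 0, 0, 0, 0, 0, 0, 0.0, 0.0)
    fc = degs["fold_change"].to_numpy(dtype=float)
    if (fc <= 0).any():
        raise ValueError("fold changes must be positive")
    n_up = int((fc > 1).sum())
    n_down = int((fc < 1).sum())
    n_ties = int((fc == 1).sum())
    if n_ties:
        logger.warning("%d genes with fold change exactly 1 (neither up nor down)", n_ties)
    n_up_gt = int((fc > 1.5).sum())
    n_down_le = int((fc <= 0.5).sum())
    n_small = int(((fc > 0.5) & (fc < 1.5)).sum())
    return FoldChangeCategories(
        n_total=len(fc),
        n_up=n_up,
        n_down=n_down,
        n_ties=n_ties,
        n_up_gt_1p5=n_up_gt,
        n_down_le_0p5=n_down_le,
        n_small_change=n_small,
        n_large_change=len(fc) - n_small,
        pct_up_gt_1p5=_round_half_up(100 * n_up_gt / n_up) if n_up else 0.0,
        pct_down_le_0p5=_round_half_up(100 * n_down_le / n_down) if n_down else 0.0,
    )


def blood_marker_report(
    cpm_matrix: pd.DataFrame,
    groups: Mapping[str, str],
    marker_ids: Sequence[str] = DEFAULT_BLOOD_MARKERS,
) -> pd.DataFrame:
    """Per-sample CPM of blood-marker genes plus cohort means.

    Markers absent from the matrix appear with ``present = False`` and
    NaN values rather than raising.
    """
    rows = []
    for marker in marker_ids:
        present = marker in cpm_matrix.index
        row: dict = {"gene_id": marker, "present": present}
        if present:
            vals = cpm_matrix.loc[marker]
            row.update(vals.to_dict())
            for cohort in sorted(set(groups.values())):
                cols = [s for s in cpm_matrix.columns if groups[s] == cohort]
                row[f"mean_{cohort}"] = float(vals[cols].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def metadata_summary(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort body-mass mean ± sample SD, age range, sex counts.

    ``meta`` needs columns cohort, age, sex, body_mass. Mean and SD
    (ddof=1) are rounded half-up to one decimal, matching how cohort
    tables are conventionally reported.
    """
    rows = []
    for cohort, grp in meta.groupby("cohort"):
        mass = grp["body_mass"].astype(float)
        rows.append(
            {
                "cohort": cohort,
                "n": len(grp),
                "body_mass_mean": _round_half_up(float(mass.mean())),
                "body_mass_sd": _round_half_up(float(mass.std(ddof=1)))
                if len(grp) > 1
                else float("nan"),
                "age_min": grp["age"].min(),
                "age_max": grp["age"].max(),
                "n_female": int((grp["sex"].str.lower() == "female").sum()),
                "n_male": int((grp["sex"].str.lower() == "male").sum()),
            }
        )
    return pd.DataFrame(rows).set_index("cohort")


def classical_mds(dist: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers the squared distances, B = -1/2 J D^2 J, and embeds
    on the top eigenvectors scaled by sqrt(eigenvalue). Negative
    eigenvalues (non-Euclidean input) are truncated to zero.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_components]
    vals = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(vals)


def _pairwise_logfc_distance(
    log_cpm: np.ndarray, s: int, t: int, top_n: int
) -> float:
    diff = np.abs(log_cpm[:, s] - log_cpm[:, t])
    if top_n < diff.size:
        diff = np.partition(diff, diff.size - top_n)[-top_n:]
    return float(np.sqrt(np.mean(diff**2)))


def mds_embedding(
    cpm_matrix: pd.DataFrame,
    top_n: int | None = 500,
    prior_count: float = 2.0,
    mode: str = "logfc",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Embed samples in 2-D from pairwise expression distances.

    In ``logfc`` mode the distance between two samples is the root mean
    square of the ``top_n`` largest absolute log2 fold changes
    ``log2((cpm_s + prior)/(cpm_t + prior))`` over genes — the
    "leading log-fold-change" distance. ``top_n=None`` uses all genes.

    In ``bcv`` mode the per-gene quantity for a sample pair is a
    coefficient-of-variation proxy,
    ``|cpm_s - cpm_t| / (0.5*(cpm_s + cpm_t) + prior)``, evaluated on
    the ``top_n`` genes with the highest log-CPM variance across all
    samples; the distance is its root mean square. This approximates a
    dispersion-based (biological coefficient of variation) distance
    without fitting a count model.

    Returns (coordinates, distance matrix), both indexed by sample.
    """
    if cpm_matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for a 2-D embedding")
    if mode not in {"logfc", "bcv"}:
        raise ValueError(f"unknown mode {mode!r}")
    n_genes, n_samples = cpm_matrix.shape
    if top_n is None:
        top_n = n_genes
    if top_n > n_genes:
        logger.warning("top_n=%d exceeds gene count %d; capped", top_n, n_genes)
        top_n = n_genes

    x = cpm_matrix.to_numpy(dtype=float)
    dist = np.zeros((n_samples, n_samples))
    if mode == "logfc":
        log_cpm = np.log2(x + prior_count)
        for s, t in combinations(range(n_samples), 2):
            dist[s, t] = dist[t, s] = _pairwise_logfc_distance(log_cpm, s, t, top_n)
    else:
        log_var = np.log2(x + prior_count).var(axis=1)
        keep = np.argsort(log_var)[::-1][:top_n]
        sub = x[keep]
        for s, t in combinations(range(n_samples), 2):
            cv = np.abs(sub[:, s] - sub[:, t]) / (0.5 * (sub[:, s] + sub[:, t]) + prior_count)
            dist[s, t] = dist[t, s] = float(np.sqrt(np.mean(cv**2)))

    coords = classical_mds(dist, n_components=2)
    samples = cpm_matrix.columns
    return (
        pd.DataFrame(coords, index=samples, columns=["dim1", "dim2"]),
        pd.DataFrame(dist, index=samples, columns=samples),
    )


def homolog_overlap(sets: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], int]:
    """Cardinalities of every region of the Venn partition of named sets.

    Keys are tuples of the set names whose exclusive intersection the
    count refers to (genes in exactly those sets and no others).
    """
    named = {name: set(s) for name, s in sets.items()}
    if len(named) < 2:
        raise ValueError("need at least 2 sets")
    names = sorted(named)
    universe = set().union(*named.values())
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(named[n] for n in combo))
            outside = set().union(*(named[n] for n in names if n not in combo), set())
            regions[combo] = len(inside - outside)
    # sanity: regions partition the universe
    assert sum(regions.values()) == len(universe)
    return regions
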