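"""Percent-spliced-in (PSI) quantification from split-read junction counts.

For each cassette exon *i* and sample, split reads whose gap matches one
of the two flanking inclusion junctions are inclusion evidence (raw
count ``ir_raw``), and reads whose gap matches the exon-skipping
junction are exclusion evidence (``er_raw``). Raw counts are normalized
for the number of junctions that can support each outcome and for the
number of distinct read placements across a junction, giving normalized
rates IR_n and ER_n, and

    PSI_i = IR_n / (IR_n + ER_n).

PSI = 1 means the exon was included in every sequenced transcript of
its gene; PSI = 0.1 means it was included in 10% of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignments import AlignedRead, junction_anchors, read_sam
from .annotation import CassetteExon

__all__ = [
    "PsiParams",
    "PsiRecord",
    "count_junction_reads",
    "normalize_rates",
    "psi",
    "psi_matrix",
    "write_psi_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PsiParams:
    """Tunable knobs of the quantifier.

    read_length : uniform read length in bp (normalization only).
    anchor_min : minimum aligned bases required on each side of a gap
        for a split read to count as junction evidence.
    min_junction_reads : minimum ``ir_raw + er_raw`` for PSI to be
        defined for an exon in a sample; below it the cell is undefined.
    n_inclusion_junctions : junctions that can evidence inclusion of a
        cassette exon (2: upstream and downstream flank).
    """

    read_length: int = 124
    anchor_min: int = 8
    min_junction_reads: int = 10
    n_inclusion_junctions: int = 2

    def __post_init__(self) -> None:
        if self.read_length <= 2 * self.anchor_min:
            raise ValueError(
                "read_length must exceed 2*anchor_min "
                f"(got {self.read_length} <= {2 * self.anchor_min})"
            )
        if self.min_junction_reads < 0 or self.anchor_min < 0:
            raise ValueError("anchor_min and min_junction_reads must be >= 0")

    @property
    def placements(self) -> int:
        """Distinct placements of a read across one junction."""
        return self.read_length - 2 * self.anchor_min + 1


@dataclass
class PsiRecord:
    exon_key: str
    sample_id: str
    ir_raw: int
    er_raw: int
    ir_n: float
    er_n: float
    psi: float | None


def count_junction_reads(
    reads: Iterable[AlignedRead],
    event: CassetteExon,
    anchor_min: int = 8,
) -> tuple[int, int]:
    """Count split reads supporting inclusion vs skipping of one exon.

    A read supports a junction when one of its gaps matches the
    junction coordinates exactly and the aligned blocks on both sides
    of that gap are >= ``anchor_min`` bases. A read matching both
    inclusion junctions (spanning the whole cassette) counts once.
    """
    chrom = event.exon.chrom
    ir_raw = er_raw = 0
    for read in reads:
        if read.chrom != chrom or not read.is_mapped:
            continue
        inclusion = skip = False
        for junc, left, right in junction_anchors(read):
            if left < anchor_min or right < anchor_min:
                continue
            pair = (junc.donor_end, junc.acceptor_start)
            if pair == event.upstream_junction or pair == event.downstream_junction:
                inclusion = True
            elif pair == event.skip_junction:
                skip = True
        if inclusion:
            ir_raw += 1
        if skip:
            er_raw += 1
    return ir_raw, er_raw


def normalize_rates(
    ir_raw: int,
    er_raw: int,
    params: PsiParams = PsiParams(),
) -> tuple[float, float]:
    """Normalize raw junction counts to per-placement rates.

    Each raw count is divided by (number of junctions able to support
    the outcome) x (number of read placements per junction,
    ``read_length - 2*anchor_min + 1``). Inclusion has two supporting
    junctions, skipping one; with uniform read length the placement
    factor cancels inside PSI, leaving the junction-count correction.
    """
    if ir_raw < 0 or er_raw < 0:
        raise ValueError("raw counts must be >= 0")
    p = params.placements
    return (
        ir_raw / (params.n_inclusion_junctions * p),
        er_raw / (1 * p),
    )


def psi(
    ir_n: float,
    er_n: float,
    *,
    ir_raw: int | None = None,
    er_raw: int | None = None,
    min_junction_reads: int = 0,
) -> float | None:
    """PSI_i = IR_n / (IR_n + ER_n), or None when coverage is too low.

    Coverage is judged on the raw counts (``ir_raw + er_raw <
    min_junction_reads`` -> undefined). A zero denominator is also
    undefined regardless of the threshold.
    """
    if ir_n < 0 or er_n < 0:
        raise ValueError("normalized rates must be >= 0")
    if ir_raw is not None and er_raw is not None:
        if ir_raw + er_raw < min_junction_reads:
            return None
    total = ir_n + er_n
    if total == 0:
        return None
    return ir_n / total


def _index_junction_reads(
    sam_path: str | Path, anchor_min: int
) -> tuple[dict[tuple[str, int, int], int], dict[tuple, int]]:
    """One pass over a SAM file -> read counts per junction and per
    junction pair.

    The pair index lets callers count a read that spans *both*
    inclusion junctions of a cassette exon once (inclusion-exclusion on
    the two single-junction counts).
    """
    counts: dict[tuple[str, int, int], int] = {}
    pair_counts: dict[tuple, int] = {}
    for read in read_sam(sam_path):
        seen: set[tuple[str, int, int]] = set()
        for junc, left, right in junction_anchors(read):
            if left < anchor_min or right < anchor_min:
                continue
            seen.add((read.chrom, junc.donor_end, junc.acceptor_start))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
        if len(seen) > 1:
            ordered = sorted(seen)
            for i, a in enumerate(ordered):
                for b in ordered[i + 1 :]:
                    pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    return counts, pair_counts


def psi_matrix(
    sam_paths: Mapping[str, str | Path],
    catalog: Sequence[CassetteExon],
    params: PsiParams = PsiParams(),
) -> pd.DataFrame:
    """Quantify every cassette exon in every sample.

    Parameters
    ----------
    sam_paths : {sample_id: SAM path}
    catalog : cassette-exon events to quantify
    params : counting/normalization parameters

    Returns
    -------
    Long-form DataFrame with one row per (exon_key, sample) and columns
    gene_id, ir_raw, er_raw, ir_n, er_n, psi (psi is NaN where
    undefined).
    """
    if not sam_paths:
        raise ValueError("sample list is empty")
    rows = []
    for sample_id, path in sam_paths.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"sample {sample_id}: SAM file {path} not found")
        index, pair_index = _index_junction_reads(path, params.anchor_min)
        n_cells = 0
        for event in catalog:
            chrom = event.exon.chrom
            up = (chrom, *event.upstream_junction)
            down = (chrom, *event.downstream_junction)
            ir_raw = index.get(up, 0)
            if down != up:
                ir_raw += index.get(down, 0)
                ir_raw -= pair_index.get((min(up, down), max(up, down)), 0)
            er_raw = index.get((chrom, *event.skip_junction), 0)
            ir_n, er_n = normalize_rates(ir_raw, er_raw, params)
            value = psi(
                ir_n,
                er_n,
                ir_raw=ir_raw,
                er_raw=er_raw,
                min_junction_reads=params.min_junction_reads,
            )
            n_cells += value is not None
            rows.append(
                {
                    "exon_key": event.key,
                    "gene_id": event.gene_id,
                    "sample_id": sample_id,
                    "ir_raw": ir_raw,
                    "er_raw": er_raw,
                    "ir_n": ir_n,
                    "er_n": er_n,
                    "psi": float("nan") if value is None else value,
                }
            )
        logger.info(
            "sample %s: %d/%d exons with defined PSI", sample_id, n_cells, len(catalog)
        )
    return pd.DataFrame(rows)


def write_psi_table(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write the long-form PSI table as TSV (undefined PSI -> empty field)."""
    matrix.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="")
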