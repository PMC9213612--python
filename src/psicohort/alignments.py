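"""SAM alignment parsing: CIGAR walking, aligned blocks, splice junctions.

Split reads — reads whose CIGAR carries an N (skipped reference) op —
are the evidence unit for exon inclusion/exclusion counting. Blocks and
junctions are reported in 0-based half-open coordinates so they compare
exactly against the annotation-derived junctions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

__all__ = [
    "AlignedRead",
    "SpliceJunction",
    "SamParseError",
    "parse_cigar",
    "aligned_blocks",
    "junctions_of",
    "read_sam",
]

# SAM flags
FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

_CIGAR_OPS = set("MIDNSHP=X")
_CIGAR_RE = re.compile(r"(\d+)([A-Za-z=])")
_READ_CONSUMING = set("MIS=X")
_REF_CONSUMING = set("MDN=X")


class SamParseError(ValueError):
    pass


@dataclass(frozen=True)
class SpliceJunction:
    """A donor→acceptor gap implied by an N op.

    ``donor_end`` is the half-open end of the block left of the gap;
    ``acceptor_start`` the start of the block right of it, so the
    skipped intron is ``[donor_end, acceptor_start)``.
    """

    chrom: str
    donor_end: int
    acceptor_start: int

    def __post_init__(self) -> None:
        if self.acceptor_start <= self.donor_end:
            raise ValueError("junction gap must skip at least one reference base")


@dataclass(frozen=True)
class AlignedRead:
    read_id: str
    chrom: str
    pos: int  # leftmost aligned reference position, 0-based
    cigar: tuple[tuple[str, int], ...]
    flag: int = 0
    mapq: int = 60

    @property
    def read_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _READ_CONSUMING)

    @property
    def reference_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    @property
    def is_mapped(self) -> bool:
        return not self.flag & FLAG_UNMAPPED and bool(self.cigar)

    @property
    def is_primary(self) -> bool:
        return not self.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY)


def parse_cigar(cigar_text: str) -> list[tuple[str, int]]:
    """Parse a SAM CIGAR string into an ordered (op, length) list.

    ``"*"`` (no alignment) yields an empty list.
    """
    if cigar_text == "*":
        return []
    ops: list[tuple[str, int]] = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar_text):
        if m.start() != pos:
            raise SamParseError(f"malformed CIGAR {cigar_text!r}")
        op = m.group(2)
        if op not in _CIGAR_OPS:
            raise SamParseError(f"illegal CIGAR op {op!r} in {cigar_text!r}")
        ops.append((op, int(m.group(1))))
        pos = m.end()
    if pos != len(cigar_text) or not ops:
        raise SamParseError(f"malformed CIGAR {cigar_text!r}")
    return ops


def aligned_blocks(read: AlignedRead) -> list[tuple[int, int]]:
    """Reference intervals covered by the read, split at N gaps.

    M/=/X extend the current block; D extends it too (deletions consume
    reference without starting a new block); N closes the block and
    opens a new one after the gap; I/S/H/P do not move the reference
    cursor. Intervals are half-open, 0-based, ascending.
    """
    if not read.cigar:
        raise ValueError(f"read {read.read_id} has no alignment")
    blocks: list[tuple[int, int]] = []
    cursor = read.pos
    block_start = read.pos
    for op, n in read.cigar:
        if op in "M=XD":
            cursor += n
        elif op == "N":
            if cursor > block_start:
                blocks.append((block_start, cursor))
            cursor += n
            block_start = cursor
        # I, S, H, P: reference cursor unchanged
    if cursor > block_start:
        blocks.append((block_start, cursor))
    return blocks


def junctions_of(read: AlignedRead) -> list[SpliceJunction]:
    """One SpliceJunction per N op, in alignment order."""
    out: list[SpliceJunction] = []
    cursor = read.pos
    for op, n in read.cigar:
        if op in "M=XD":
            cursor += n
        elif op == "N":
            out.append(SpliceJunction(read.chrom, cursor, cursor + n))
            cursor += n
    return out


def junction_anchors(read: AlignedRead) -> list[tuple[SpliceJunction, int, int]]:
    """Junctions with the aligned block lengths flanking each gap.

    Anchor lengths are the sizes of the maximal aligned blocks adjacent
    to the gap, used to enforce a minimum-anchor rule when counting
    split-read evidence.
    """
    blocks = aligned_blocks(read)
    juncs = junctions_of(read)
    out = []
    for i, j in enumerate(juncs):
        left = blocks[i][1] - blocks[i][0]
        right = blocks[i + 1][1] - blocks[i + 1][0]
        out.append((j, left, right))
    return out


def read_sam(
    path: str | Path,
    *,
    min_mapq: int = 0,
    primary_only: bool = True,
) -> Iterator[AlignedRead]:
    """Stream mapped reads from a SAM text file.

    Unmapped records are skipped; secondary/supplementary alignments are
    skipped by default so each split read contributes junction evidence
    once. POS is converted 1-based → 0-based.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@"):
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise SamParseError(
                    f"{path}: line {lineno}: expected >= 11 columns, got {len(cols)}"
                )
            qname, flag_s, rname, pos_s, mapq_s, cigar_s = cols[:6]
            flag = int(flag_s)
            if flag & FLAG_UNMAPPED or rname == "*":
                continue
            read = AlignedRead(
                read_id=qname,
                chrom=rname,
                pos=int(pos_s) - 1,
                cigar=tuple(parse_cigar(cigar_s)),
                flag=flag,
                mapq=int(mapq_s),
            )
            if primary_only and not read.is_primary:
                continue
            if read.mapq < min_mapq:
                continue
            yield read
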