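"""Gene annotation IO and cassette-exon event catalog.

GTF is 1-based inclusive on disk; everything in memory is 0-based
half-open. The conversion happens only in :func:`load_gtf` and
:func:`write_gtf`, so junction coordinates from annotation and from
gapped alignments live in the same system and can be compared exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "Exon",
    "GeneModel",
    "CassetteExon",
    "GtfParseError",
    "load_gtf",
    "write_gtf",
    "cassette_exon_catalog",
]


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message carries the line number."""


@dataclass(frozen=True, order=True)
class Exon:
    """One exon in 0-based half-open coordinates.

    ``length = end - start`` (the on-disk GTF interval is 1-based
    inclusive, so a record ``101 200`` becomes ``start=100, end=200``,
    length 100).
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    exon_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"exon {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class GeneModel:
    """A gene as a set of transcripts, each an ordered exon list."""

    gene_id: str
    transcripts: dict[str, list[Exon]] = field(default_factory=dict)

    @property
    def exons(self) -> list[Exon]:
        """Deduplicated exons over all transcripts, sorted by coordinate."""
        return sorted(set(e for exs in self.transcripts.values() for e in exs))

    def validate(self) -> None:
        for tx_id, exs in self.transcripts.items():
            if not exs:
                raise ValueError(f"transcript {tx_id} of {self.gene_id} has no exons")
            ordered = sorted(exs, key=lambda e: (e.chrom, e.start, e.end))
            for a, b in zip(ordered, ordered[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise ValueError(
                        f"transcript {tx_id} of {self.gene_id}: exons "
                        f"{a.start}-{a.end} and {b.start}-{b.end} overlap"
                    )


@dataclass(frozen=True)
class CassetteExon:
    """An internal exon with its three diagnostic splice junctions.

    Junctions are ``(donor_end, acceptor_start)`` pairs in 0-based
    half-open block coordinates: ``donor_end`` is the half-open end of
    the upstream exon block, ``acceptor_start`` the start of the
    downstream block. A split read supports inclusion when its gap
    matches ``upstream_junction`` or ``downstream_junction``, and
    skipping when it matches ``skip_junction``.
    """

    gene_id: str
    exon: Exon
    upstream_junction: tuple[int, int]
    downstream_junction: tuple[int, int]
    skip_junction: tuple[int, int]

    def __post_init__(self) -> None:
        if self.upstream_junction[1] != self.exon.start:
            raise ValueError("upstream junction must land on the exon start")
        if self.downstream_junction[0] != self.exon.end:
            raise ValueError("downstream junction must leave from the exon end")
        if not (
            self.skip_junction[0] == self.upstream_junction[0]
            and self.skip_junction[1] == self.downstream_junction[1]
        ):
            raise ValueError("skip junction must join the two flanking exons")

    @property
    def key(self) -> str:
        e = self.exon
        return f"{e.chrom}:{e.start}-{e.end}"


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def load_gtf(path: str | Path) -> dict[str, GeneModel]:
    """Read exon features from a GTF file into gene models.

    Non-exon feature lines are ignored. Coordinates are converted to
    0-based half-open. Returns ``{gene_id: GeneModel}``.

    Raises
    ------
    GtfParseError
        On a line with fewer than 9 tab-separated columns, a
        non-integer coordinate, or an exon feature lacking ``gene_id``
        or ``transcript_id``; the message names the 1-based line number.
    """
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = cols[:9]
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"line {lineno}: non-integer coordinates {start_s!r}, {end_s!r}"
                ) from None
            attributes = _parse_attributes(attrs)
            if "gene_id" not in attributes:
                raise GtfParseError(f"line {lineno}: exon feature missing gene_id")
            if "transcript_id" not in attributes:
                raise GtfParseError(f"line {lineno}: exon feature missing transcript_id")
            exon = Exon(
                chrom=chrom,
                start=start1 - 1,
                end=end1,
                strand=strand,
                exon_id=attributes.get("exon_id", ""),
            )
            gene_id = attributes["gene_id"]
            model = models.setdefault(gene_id, GeneModel(gene_id=gene_id))
            model.transcripts.setdefault(attributes["transcript_id"], []).append(exon)
    for model in models.values():
        for exs in model.transcripts.values():
            exs.sort()
        model.validate()
    return models


def write_gtf(models: Iterable[GeneModel] | dict[str, GeneModel], path: str | Path) -> None:
    """Write exon features back to GTF (1-based inclusive coordinates)."""
    if isinstance(models, dict):
        models = models.values()
    with open(path, "w") as fh:
        for model in sorted(models, key=lambda m: m.gene_id):
            for tx_id in sorted(model.transcripts):
                for exon in model.transcripts[tx_id]:
                    attrs = f'gene_id "{model.gene_id}"; transcript_id "{tx_id}";'
                    if exon.exon_id:
                        attrs += f' exon_id "{exon.exon_id}";'
                    fh.write(
                        "\t".join(
                            [
                                exon.chrom,
                                "psicohort",
                                "exon",
                                str(exon.start + 1),
                                str(exon.end),
                                ".",
                                exon.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def cassette_exon_catalog(model: GeneModel) -> list[CassetteExon]:
    """Enumerate candidate cassette-exon events of one gene.

    Every exon that is internal (neither first nor last) in at least one
    transcript yields one event, with flanking-junction coordinates
    taken from that transcript. Overlapping variants with different
    boundaries are distinct events keyed by ``(chrom, start, end)``;
    when several transcripts share an internal exon the first transcript
    in sorted id order defines the flanks. Deterministic and sorted by
    (chrom, start, end).
    """
    model.validate()
    events: dict[tuple[str, int, int], CassetteExon] = {}
    for tx_id in sorted(model.transcripts):
        exs = model.transcripts[tx_id]
        for prev, exon, nxt in zip(exs, exs[1:], exs[2:]):
            if exon.key in events:
                continue
            events[exon.key] = CassetteExon(
                gene_id=model.gene_id,
                exon=exon,
                upstream_junction=(prev.end, exon.start),
                downstream_junction=(exon.end, nxt.start),
                skip_junction=(prev.end, nxt.start),
            )
    return [events[k] for k in sorted(events)]
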