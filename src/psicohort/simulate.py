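"""Synthetic cohort data with known ground truth.

Emulates the structure of a two-cohort (6 young vs 7 old) brain
RNA-seq study: per-sample gene-level count tables with planted
fold changes, and splice-aware SAM alignments over multi-exon gene
models in which designated cassette exons have known per-cohort
inclusion fractions. Everything downstream (PSI quantification, ΔPSI
flagging, CPM summaries, MDS) can then be scored against the truth.

Counts model
------------
Gene expression weights are drawn log-normal and scaled to per-sample
library sizes (default mean 74 million reads, scaled by
``depth_factor``). A ``deg_fraction`` of genes receive a planted
old/young fold change; counts are negative binomial with a common
dispersion (variance mu + phi*mu^2), Poisson in the phi -> 0 limit.

Splice model
------------
For each cassette exon, each sample draws a number of transcript
events around ``junction_depth_mean``. Each event includes the exon
with its cohort's true inclusion fraction psi: an inclusion event
emits one split read across each of the two flanking junctions (the
physical coverage of an included exon crosses both), an exclusion
event emits one read across the skip junction. Junction placement
within the read is uniform subject to ``anchor_min`` aligned bases on
each side. Read length is uniform (default 124 bp, the post-trimming
average of the emulated study).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import CassetteExon, GeneModel, write_gtf

__all__ = [
    "SimulationConfig",
    "CountsTruth",
    "SpliceTruth",
    "simulate_counts",
    "simulate_splice_reads",
    "default_splice_models",
    "write_fixture_bundle",
]


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the emulated cohort design: 6 young and 7 old
    samples, ~74 M reads per library, 124 bp reads.
    """

    n_young: int = 6
    n_old: int = 7
    library_size_mean: float = 74_000_000.0
    library_size_cv: float = 0.15
    depth_factor: float = 1.0
    read_length: int = 124
    n_genes: int = 2000
    deg_fraction: float = 0.2
    logfc_sd: float = 1.0
    dispersion: float = 0.05
    junction_depth_mean: float = 200.0
    anchor_min: int = 8
    background_reads_per_exon: float = 0.0
    cassette_truth: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 1 or self.n_old < 1:
            raise ValueError("each cohort needs at least one sample")
        if self.library_size_mean * self.depth_factor <= 0:
            raise ValueError("library sizes must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.read_length <= 2 * self.anchor_min:
            raise ValueError("read_length must exceed 2*anchor_min")
        for key, (py, po) in self.cassette_truth.items():
            if not (0 <= py <= 1 and 0 <= po <= 1):
                raise ValueError(f"cassette {key}: true PSI must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return [f"young_{i + 1}" for i in range(self.n_young)] + [
            f"old_{i + 1}" for i in range(self.n_old)
        ]

    @property
    def groups(self) -> dict[str, str]:
        return {
            s: ("young" if s.startswith("young") else "old") for s in self.sample_ids
        }


@dataclass
class CountsTruth:
    """Ground truth behind a simulated count matrix."""

    true_fc: pd.Series  # old/young linear fold change per gene
    library_sizes: pd.Series  # per sample
    is_deg: pd.Series


@dataclass
class SpliceTruth:
    """Ground truth behind simulated splice-aware alignments.

    ``events`` has one row per (exon_key, sample) with the true PSI,
    the number of inclusion/exclusion transcript events drawn, and the
    read counts emitted per junction.
    """

    psi_true: pd.DataFrame  # exon_key, psi_young, psi_old
    events: pd.DataFrame


def _rng_for(config: SimulationConfig, stream: str) -> np.random.Generator:
    # independent deterministic substream per purpose; stream tag hashed
    # with a stable digest (builtin hash() is salted per process)
    tag = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "big")
    child = np.random.SeedSequence(entropy=config.seed, spawn_key=(tag,))
    return np.random.default_rng(child)


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(config: SimulationConfig) -> tuple[pd.DataFrame, CountsTruth]:
    """Draw a gene x sample integer count matrix with planted DEGs.

    Non-DEG genes share one expected expression weight across cohorts;
    DEG genes have old-cohort weight = young weight x true FC with
    log2 FC ~ Normal(0, logfc_sd). Returns (counts, truth); counts has
    genes as rows and sample ids as columns.
    """
    rng = _rng_for(config, "counts")
    genes = [f"gene_{i:05d}" for i in range(config.n_genes)]
    weights = rng.lognormal(mean=1.0, sigma=1.5, size=config.n_genes)
    is_deg = rng.random(config.n_genes) < config.deg_fraction
    log2fc = np.where(is_deg, rng.normal(0.0, config.logfc_sd, config.n_genes), 0.0)
    fc = 2.0**log2fc

    lib_mean = config.library_size_mean * config.depth_factor
    n_samples = config.n_young + config.n_old
    lib_sizes = rng.normal(lib_mean, config.library_size_cv * lib_mean, n_samples)
    lib_sizes = np.maximum(lib_sizes, 0.05 * lib_mean)

    w_young = weights / weights.sum()
    old_weights = weights * fc
    w_old = old_weights / old_weights.sum()

    cols = {}
    for idx, sample in enumerate(config.sample_ids):
        w = w_young if idx < config.n_young else w_old
        mu = w * lib_sizes[idx]
        cols[sample] = _nb_counts(rng, mu, config.dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    truth = CountsTruth(
        true_fc=pd.Series(fc, index=counts.index, name="true_fc"),
        library_sizes=pd.Series(lib_sizes, index=counts.columns, name="library_size"),
        is_deg=pd.Series(is_deg, index=counts.index, name="is_deg"),
    )
    return counts, truth


def default_splice_models(
    n_genes: int = 10,
    exons_per_gene: int = 3,
    chrom: str = "chrSim",
    exon_length: int = 200,
    intron_length: int = 500,
) -> dict[str, GeneModel]:
    """Lay out simple multi-exon gene models end to end on one contig.

    Each gene has one transcript of ``exons_per_gene`` equal-length
    exons, so every internal exon is a cassette candidate.
    """
    from .annotation import Exon

    models: dict[str, GeneModel] = {}
    cursor = 1000
    for g in range(n_genes):
        gene_id = f"sgene_{g:03d}"
        exons = []
        for e in range(exons_per_gene):
            start = cursor
            exons.append(
                Exon(chrom=chrom, start=start, end=start + exon_length, strand="+")
            )
            cursor += exon_length + intron_length
        cursor += 5000  # intergenic spacer
        models[gene_id] = GeneModel(gene_id=gene_id, transcripts={"t1": exons})
    return models


def _emit_split_read(
    rng: np.random.Generator,
    junction: tuple[int, int],
    read_length: int,
    anchor_min: int,
) -> tuple[int, str]:
    """Place one read across a junction -> (0-based pos, CIGAR)."""
    left = int(rng.integers(anchor_min, read_length - anchor_min + 1))
    right = read_length - left
    gap = junction[1] - junction[0]
    pos = junction[0] - left
    return pos, f"{left}M{gap}N{right}M"


def simulate_splice_reads(
    config: SimulationConfig,
    models: dict[str, GeneModel],
    outdir: str | Path,
) -> tuple[dict[str, Path], SpliceTruth]:
    """Write one SAM file per sample with planted exon inclusion levels.

    ``config.cassette_truth`` maps exon keys (``chrom:start-end``, as
    produced by the cassette catalog) to (psi_young, psi_old). Every
    key must exist among the models' cassette candidates.

    Returns ({sample_id: sam_path}, SpliceTruth).
    """
    from .annotation import cassette_exon_catalog

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog: dict[str, CassetteExon] = {}
    for model in models.values():
        for event in cassette_exon_catalog(model):
            catalog[event.key] = event
    missing = sorted(set(config.cassette_truth) - set(catalog))
    if missing:
        raise ValueError(f"cassette exons absent from gene models: {missing}")

    chrom_len = (
        max(
            e.end
            for m in models.values()
            for exs in m.transcripts.values()
            for e in exs
        )
        + 10_000
    )
    chroms = sorted(
        {e.chrom for m in models.values() for exs in m.transcripts.values() for e in exs}
    )

    rng = _rng_for(config, "splice")
    sam_paths: dict[str, Path] = {}
    event_rows = []
    groups = config.groups
    for sample in config.sample_ids:
        path = outdir / f"{sample}.sam"
        sam_paths[sample] = path
        cohort = groups[sample]
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for c in chroms:
                fh.write(f"@SQ\tSN:{c}\tLN:{chrom_len}\n")
            serial = 0
            for exon_key in sorted(config.cassette_truth):
                event = catalog[exon_key]
                psi_true = config.cassette_truth[exon_key][0 if cohort == "young" else 1]
                n_events = int(rng.poisson(config.junction_depth_mean))
                n_incl = int(rng.binomial(n_events, psi_true)) if n_events else 0
                n_excl = n_events - n_incl
                reads = []
                for _ in range(n_incl):
                    for junction in (event.upstream_junction, event.downstream_junction):
                        reads.append(
                            _emit_split_read(
                                rng, junction, config.read_length, config.anchor_min
                            )
                        )
                for _ in range(n_excl):
                    reads.append(
                        _emit_split_read(
                            rng, event.skip_junction, config.read_length, config.anchor_min
                        )
                    )
                n_background = (
                    int(rng.poisson(config.background_reads_per_exon))
                    if config.background_reads_per_exon > 0
                    else 0
                )
                for _ in range(n_background):
                    # unsplit read fully inside the exon (stress case for
                    # the junction-only counting rules)
                    lo = event.exon.start
                    hi = max(lo + 1, event.exon.end - config.read_length)
                    pos = int(rng.integers(lo, hi))
                    reads.append((pos, f"{config.read_length}M"))
                for pos, cigar in reads:
                    serial += 1
                    fh.write(
                        "\t".join(
                            [
                                f"{sample}.r{serial}",
                                "0",
                                event.exon.chrom,
                                str(pos + 1),
                                "60",
                                cigar,
                                "*",
                                "0",
                                "0",
                                "*",
                                "*",
                            ]
                        )
                        + "\n"
                    )
                event_rows.append(
                    {
                        "exon_key": exon_key,
                        "sample_id": sample,
                        "cohort": cohort,
                        "psi_true": psi_true,
                        "n_events": n_events,
                        "n_inclusion_events": n_incl,
                        "n_exclusion_events": n_excl,
                        "n_inclusion_reads": 2 * n_incl,
                        "n_exclusion_reads": n_excl,
                    }
                )

    psi_true = pd.DataFrame(
        {
            "exon_key": sorted(config.cassette_truth),
            "psi_young": [config.cassette_truth[k][0] for k in sorted(config.cassette_truth)],
            "psi_old": [config.cassette_truth[k][1] for k in sorted(config.cassette_truth)],
        }
    )
    truth = SpliceTruth(psi_true=psi_true, events=pd.DataFrame(event_rows))
    return sam_paths, truth


def write_fixture_bundle(
    config: SimulationConfig,
    models: dict[str, GeneModel],
    outdir: str | Path,
) -> dict:
    """Write GTF + per-sample SAM + counts TSV + truth TSVs + manifest.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(models, outdir / "annotation.gtf")
    counts, counts_truth = simulate_counts(config)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    truth_df = pd.DataFrame(
        {
            "true_fc": counts_truth.true_fc,
            "is_deg": counts_truth.is_deg.astype(int),
        }
    )
    truth_df.to_csv(outdir / "counts_truth.tsv", sep="\t")
    counts_truth.library_sizes.to_frame().to_csv(outdir / "library_sizes.tsv", sep="\t")
    sam_paths, splice_truth = simulate_splice_reads(config, models, outdir)
    splice_truth.psi_true.to_csv(outdir / "psi_truth.tsv", sep="\t", index=False)
    splice_truth.events.to_csv(outdir / "splice_events_truth.tsv", sep="\t", index=False)
    cfg = asdict(config)
    cfg["cassette_truth"] = {k: list(v) for k, v in config.cassette_truth.items()}
    manifest = {
        "seed": config.seed,
        "config": cfg,
        "files": {
            "gtf": "annotation.gtf",
            "counts": "counts.tsv",
            "counts_truth": "counts_truth.tsv",
            "library_sizes": "library_sizes.tsv",
            "psi_truth": "psi_truth.tsv",
            "splice_events_truth": "splice_events_truth.tsv",
            "sam": {s: p.name for s, p in sam_paths.items()},
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
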