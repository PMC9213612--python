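import pytest

from psicohort.annotation import Exon, GeneModel, cassette_exon_catalog
from psicohort.simulate import SimulationConfig, default_splice_models, simulate_splice_reads


@pytest.fixture
def three_exon_model() -> GeneModel:
    """One transcript with exons (101-200), (301-400), (501-600) in GTF
    coordinates, i.e. (100,200), (300,400), (500,600) half-open."""
    exons = [
        Exon("chr1", 100, 200),
        Exon("chr1", 300, 400),
        Exon("chr1", 500, 600),
    ]
    return GeneModel(gene_id="g1", transcripts={"t1": exons})


@pytest.fixture(scope="session")
def splice_fixture(tmp_path_factory):
    """A small simulated splice dataset shared by quantification tests.

    6+7 samples, 12 cassette exons at depth 200: exons 0-2 have a
    planted |Δψ| = 0.4, the rest are null.
    """
    outdir = tmp_path_factory.mktemp("splice_fixture")
    models = default_splice_models(n_genes=12)
    catalog = [e for m in models.values() for e in cassette_exon_catalog(m)]
    truth = {}
    for i, event in enumerate(catalog):
        base = [0.2, 0.5, 0.7][i % 3]
        delta = 0.4 if i < 3 else 0.0
        truth[event.key] = (base, min(1.0, base + delta))
    config = SimulationConfig(seed=20240, cassette_truth=truth)
    sam_paths, truth_tables = simulate_splice_reads(config, models, outdir)
    return {
        "config": config,
        "models": models,
        "catalog": catalog,
        "sam_paths": sam_paths,
        "truth": truth_tables,
        "planted": [catalog[i].key for i in range(3)],
    }
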