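import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from epistruct.fixtures import FixtureSpec, generate_bundle
from epistruct.catalog import parse_epitope_table
from epistruct.io import read_alphafold_model, read_fasta
from epistruct.mapper import AlphaFoldModel
from epistruct.sifts import parse_sifts_xml
from epistruct.structures import build_index


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One default synthetic bundle, generated once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    spec = FixtureSpec(seed=11)
    manifest = generate_bundle(spec, outdir)
    return spec, outdir, manifest


def load_pipeline_inputs(outdir, manifest):
    """Parse every bundle file into the containers the mapper consumes."""
    files = manifest["files"]
    records = parse_epitope_table(outdir / files["epitopes"])
    index = build_index(outdir / files["structures"])
    alignment = parse_sifts_xml(outdir / files["sifts"])
    parents = read_fasta(outdir / files["fasta"])
    accession = manifest["accession"]
    seq, plddt = read_alphafold_model(outdir / files["alphafold"])
    models = {accession: AlphaFoldModel(accession=accession, sequence=seq, plddt=tuple(plddt))}
    return records, index, {alignment.structure_id: alignment}, parents, models


@pytest.fixture(scope="session")
def pipeline_inputs(bundle):
    _, outdir, manifest = bundle
    return load_pipeline_inputs(outdir, manifest)
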