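import pytest

from en2splice.design_ingest import predict_all, parse_design_table, parse_exon_table
from en2splice.synthetic_data import SimulationConfig, write_bundle


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small seeded synthetic bundle written to disk, with parsed views."""
    outdir = tmp_path_factory.mktemp("bundle")
    config = SimulationConfig(seed=11, n_genes=90, fraction_untested=0.3)
    paths = write_bundle(config, outdir)
    exons = parse_exon_table(paths["exons"])
    designs = parse_design_table(paths["designs"])
    return {
        "config": config,
        "paths": paths,
        "exons": exons,
        "designs": designs,
        "report": predict_all(designs, exons),
    }
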