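import json
from pathlib import Path

import pytest

from liconet import PipelineConfig, fingerprints, pipeline


@pytest.fixture(scope="session")
def flavonoid_table() -> Path:
    """Packaged ten-compound licorice flavonoid SMILES table."""
    return fingerprints.packaged_compound_table()


@pytest.fixture(scope="session")
def flavonoid_compounds(flavonoid_table):
    return fingerprints.parse_smiles_table(flavonoid_table).compounds


@pytest.fixture(scope="session")
def synthetic_bundle(tmp_path_factory):
    """A default synthetic input bundle plus a pipeline config wired to it."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = PipelineConfig(outdir=str(out), seed=11, descriptor_table="packaged")
    paths = pipeline.simulate(cfg)
    truth = json.loads(paths["truth"].read_text())
    cfg.fingerprint_table = str(paths["fingerprints"])
    cfg.compound_targets = str(paths["compound_targets"])
    cfg.disease_scores = str(paths["disease_scores"])
    cfg.deg_table = str(paths["deg_table"])
    cfg.ppi_edges = str(paths["ppi_edges"])
    cfg.annotation = str(paths["annotation"])
    cfg.universe = str(paths["universe"])
    cfg.expression = str(paths["expression"])
    cfg.expression_query = truth["expression_query"]
    return cfg, paths, truth
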