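import sys
from pathlib import Path

import pytest

import nickedit as ne

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`


@pytest.fixture(scope="session")
def locus():
    """Standard synthetic locus: 646 bp amplicon, PAM-out pair, 64 bp apart."""
    return ne.build_synthetic_locus(seed=101)


@pytest.fixture(scope="session")
def amplicon(locus):
    return locus[0]


@pytest.fixture(scope="session")
def pair(locus):
    return locus[1]


@pytest.fixture(scope="session")
def vector():
    return ne.build_synthetic_vector(seed=201)


def _bundle(tmp_root, name, **sim_kwargs):
    amp, gpair = ne.build_synthetic_locus(seed=101)
    vec = ne.build_synthetic_vector(seed=201)
    out = tmp_root / name
    paths = ne.write_references(out, amp, vec, gpair)
    cfg = ne.SimConfig(**sim_kwargs)
    res = ne.simulate_dataset(cfg, amp, vec, gpair, out, prefix=name)
    return {
        "amplicon": amp, "vector": vec, "pair": gpair, "cfg": cfg,
        "paths": {**{k: str(v) for k, v in paths.items()},
                  "reads": str(res.fastq[0]), "truth": str(res.truth_path)},
        "result": res,
    }


@pytest.fixture(scope="session")
def mix_bundle(tmp_path_factory):
    """500 reads, default outcome mix, realistic substitution error."""
    return _bundle(tmp_path_factory.mktemp("mix"), "mix", n_reads=500, seed=42)


@pytest.fixture(scope="session")
def clean_bundle(tmp_path_factory):
    """500 reads, default outcome mix, error-free."""
    return _bundle(tmp_path_factory.mktemp("clean"), "clean",
                   n_reads=500, seed=43, sub_error_rate=0.0)


@pytest.fixture(scope="session")
def run_pipeline_on():
    def _run(bundle, out_dir, **overrides):
        paths = bundle["paths"]
        cfg = ne.RunConfig(
            reads=paths["reads"], amplicon_path=paths["amplicon"],
            vector_path=paths["vector"], guides_path=paths["guides"],
            vector_features_path=paths["features"], out_dir=str(out_dir),
            **overrides,
        )
        return ne.run_pipeline(cfg)
    return _run
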