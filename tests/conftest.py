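import pytest

from netpharm.synthetic_data import gen_bundle


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A seeded synthetic input bundle shaped like the published counts."""
    out = tmp_path_factory.mktemp("bundle")
    path, truth = gen_bundle(out / "b", seed=11)
    return path, truth
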