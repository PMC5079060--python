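import pytest

from metahandoff.synthetic import scenario_presets, simulate_community


@pytest.fixture(scope="session")
def tiny_community():
    """A small deterministic community shared across read-only tests."""
    return simulate_community(scenario_presets(seed=11)["tiny"])


@pytest.fixture(scope="session")
def tiny_dir(tiny_community, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny") / "community"
    tiny_community.write(out)
    return out
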