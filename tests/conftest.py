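import pytest

from secproxy import synth_gen


@pytest.fixture(scope="session")
def small_cys_library():
    """A 60-entry labeled-Cys library with generative truth (fixed seed)."""
    config = synth_gen.SynthConfig(n_peptides=60, seed=11)
    lib, truth = synth_gen.generate_cys_library(config)
    return config, lib, truth
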