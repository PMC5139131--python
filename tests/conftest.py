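import numpy as np
import pytest

import satjunction as sj


@pytest.fixture(scope="session")
def family():
    """A fixed synthetic satDNA family (L=170, two palindromes, two blocks)."""
    return sj.generate_family(sj.SimConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """Six fragments with default event rates, plus truth and family."""
    cfg = sj.SimConfig(seed=11, n_fragments=6)
    fragments, truths, fam = sj.generate_dataset(cfg)
    return fragments, truths, fam
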