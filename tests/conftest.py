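import numpy as np
import pytest

from raremet.simulate import EffectSpec, SynthConfig, generate


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_study():
    """A compact two-cohort study with one planted uniform-burden effect."""
    cfg = SynthConfig(
        seed=11,
        n_samples=(300, 250),
        n_genes=12,
        mean_variants_per_gene=6.0,
        n_traits=8,
        maf_min=0.005,
        effects=[EffectSpec(gene="G005", trait="MET001", architecture="uniform-burden", beta=0.8)],
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def null_study():
    """A study with no genetic effects (global null)."""
    cfg = SynthConfig(seed=5, n_samples=(250, 200), n_genes=10, n_traits=6)
    return generate(cfg)
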