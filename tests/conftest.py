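import numpy as np
import pytest

from dsbtox import annot, simdata


@pytest.fixture(scope="session")
def small_screen():
    """A compact isogenic-pair screen with a planted DHS x TP53 interaction."""
    config = simdata.SimConfig(n_genes=100, n_nontargeting=50, seed=3)
    effects = simdata.EffectSpec(
        interaction_effects={"dhs": -0.3},
        essentiality_effect=-0.1,
        feature_correlation={("dhs", "h3k27ac"): 0.7},
    )
    sim = simdata.simulate_screen(config, effects)
    sim["config"] = config
    return sim


@pytest.fixture(scope="session")
def small_features(small_screen):
    return annot.assemble(small_screen["library"], small_screen["annotations"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_817)
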