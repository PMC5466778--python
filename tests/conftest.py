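import numpy as np
import pytest

from musclefish import GeneBurstSpec, packaged_config, simulate_fibre


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def s59_fibre():
    """One clean DT1 fibre with several ON nuclei and well-separated spots
    (separation large enough that Gaussian tails never bridge above the
    detection threshold)."""
    cfg = packaged_config("dt1_s59_stage15")
    cfg.min_separation = 12.0
    cfg.genes[0].p_on_by_stage[14] = 0.45
    return simulate_fibre(cfg, 14, np.random.default_rng(7))


@pytest.fixture(scope="session")
def kr_fibre():
    """One FC-restricted fibre: a single Kr dot at the founder nucleus."""
    cfg = packaged_config("ll1_kr")
    return simulate_fibre(cfg, 13, np.random.default_rng(7))


@pytest.fixture
def always_on_spec():
    return GeneBurstSpec(gene="g", p_on_by_stage={s: 1.0 for s in range(12, 17)})
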