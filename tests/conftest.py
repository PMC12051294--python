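import pytest

from scopeggs.sim import (
    fbr_demo_hic_config,
    simulate_control_pairs,
    simulate_hic_pairs,
)


@pytest.fixture(scope="session")
def demo_sim():
    """Study-condition simulation: 70.5-Mb X-like chromosome, 200k pairs,
    three fold-back loops + one inversion-breakpoint dot, no SVs."""
    cfg = fbr_demo_hic_config(seed=11)
    return cfg, simulate_hic_pairs(cfg)


@pytest.fixture(scope="session")
def demo_sim_with_svs():
    """Same conditions plus two tight SV dots and the matched no-loop control."""
    cfg = fbr_demo_hic_config(seed=21, include_svs=True)
    return cfg, simulate_hic_pairs(cfg), simulate_control_pairs(cfg)
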