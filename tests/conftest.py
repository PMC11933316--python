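import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

import screenpulse as sp


@pytest.fixture(scope="session")
def small_screen():
    """A 60-gene screen with planted hits, small enough for fast fits."""
    lib = sp.make_library(60, 4, 20, seed=0)
    truth = sp.draw_effects(lib, frac_resist=0.1, frac_sens=0.1,
                            effect_size=1.0, seed=11)
    cfg = sp.SimConfig(n_genes=60, n_ntc=20, depth_per_sample=150_000, seed=11)
    cm = sp.simulate_screen(lib, truth, cfg)
    return lib, truth, cfg, cm


@pytest.fixture(scope="session")
def tiling_screen():
    """Tiling screen: NFR domain neutral, every other domain depleted."""
    lib = sp.make_tiling_library(seed=3)
    effects = {d.name: -1.0 for d in sp.KDM1A_DOMAIN_SPEC if d.name != "NFR"}
    truth = sp.draw_tiling_effects(lib, effects, seed=3)
    cfg = sp.SimConfig(n_genes=1, n_ntc=10, timepoints_days=(0, 2, 4, 6),
                       depth_per_sample=100_000, seed=3)
    cm = sp.simulate_screen(lib, truth, cfg)
    return lib, truth, cfg, cm
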