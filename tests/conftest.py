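import numpy as np
import pytest

from painttx import ScreenConfig, generate_screen, scaffold_split, build_pairs


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small screen for fast unit tests (not the benchmark conditions)."""
    return ScreenConfig(
        n_compounds=120,
        n_moa_classes=6,
        d_cp=40,
        d_tx=60,
        d_latent_shared=6,
        d_latent_tx_only=3,
        replicate_count_range=(2, 3),
        n_tasks=25,
        label_density=0.9,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_screen(tiny_cfg):
    return generate_screen(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_split(tiny_screen):
    return scaffold_split(tiny_screen.compounds, seed=7)


@pytest.fixture(scope="session")
def tiny_pairs(tiny_screen, tiny_split):
    pairs = build_pairs(tiny_screen.cp, tiny_screen.tx)
    keep = set(tiny_split.compounds("train")) | set(tiny_split.compounds("valid"))
    return pairs.restrict_to(keep)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
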