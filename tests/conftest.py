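import numpy as np
import pytest

from cemb.connectome_io import Connectome
from cemb.embedding import EmbedConfig, WalkConfig, embed_ensemble
from cemb.synthetic import SynthConfig, generate_symmetric_connectome


@pytest.fixture
def tiny4() -> Connectome:
    """Minimal valid mirrored connectome: two homotopic pairs."""
    w = np.array(
        [
            [0.0, 2.0, 1.0, 0.5],
            [2.0, 0.0, 0.5, 1.0],
            [1.0, 0.5, 0.0, 3.0],
            [0.5, 1.0, 3.0, 0.0],
        ]
    )
    return Connectome(
        labels=["La", "Ra", "Lb", "Rb"],
        hemisphere=["left", "right", "left", "right"],
        homotopic_partner=np.array([1, 0, 3, 2]),
        weights=w,
    )


@pytest.fixture
def fix5() -> Connectome:
    """5-node weighted fixture with irregular weights, used as a walk and
    metric oracle substrate."""
    w = np.array(
        [
            [0.0, 2.0, 1.0, 0.0, 0.5],
            [2.0, 0.0, 3.0, 1.0, 0.0],
            [1.0, 3.0, 0.0, 2.0, 1.5],
            [0.0, 1.0, 2.0, 0.0, 1.0],
            [0.5, 0.0, 1.5, 1.0, 0.0],
        ]
    )
    return Connectome(
        labels=["a", "b", "c", "d", "e"],
        hemisphere=["left", "left", "midline", "right", "right"],
        homotopic_partner=np.array([3, 4, -1, 0, 1]),
        weights=w,
    )


@pytest.fixture(scope="session")
def synth_c() -> Connectome:
    """Full-scale synthetic mirrored connectome (41 pairs + 1 midline)."""
    return generate_symmetric_connectome(SynthConfig(seed=3))


@pytest.fixture(scope="session")
def synth_ens(synth_c):
    """A 20-run walk+CBOW ensemble on the synthetic connectome (shared
    across tests; treat as read-only)."""
    return embed_ensemble(
        synth_c, WalkConfig(), EmbedConfig(), n_runs=20, master_seed=11
    )
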