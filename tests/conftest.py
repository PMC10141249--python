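import numpy as np
import pytest

from reactfactors import Structure
from reactfactors import synthetic_data as synth


@pytest.fixture
def h2_xyz(tmp_path):
    p = tmp_path / "h2.xyz"
    p.write_text("2\nhydrogen molecule\nH 0.0 0.0 0.0\nH 0.0 0.0 0.74\n")
    return p


@pytest.fixture
def frozen_cluster_xyz(tmp_path):
    """10-atom toy cluster, 8 capping atoms frozen (the 3n-24 convention)."""
    lines = ["10", "toy cluster, 8 frozen"]
    rng = np.random.default_rng(5)
    for i in range(10):
        x, y, z = rng.normal(scale=2.0, size=3)
        flag = " F" if i >= 2 else ""
        lines.append(f"C {x:.6f} {y:.6f} {z:.6f}{flag}")
    p = tmp_path / "cluster.xyz"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def diatomic():
    return synth.gen_coupled_oscillator(2, [1.0, 3.0], [0.3])


@pytest.fixture
def default_series():
    return synth.gen_model_series(synth.SeriesSpec(seed=42))


@pytest.fixture
def ts_structure():
    structure, _ = synth.gen_random_hessian(10, seed=11)
    return structure


def random_structure(n: int, seed: int, frozen=None) -> Structure:
    structure, _ = synth.gen_random_hessian(n, seed=seed, frozen=frozen)
    return structure
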