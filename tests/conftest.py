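import numpy as np
import pytest

from phylosignare import MutationSpectrum, SignatureCatalog, make_synthetic_catalog
from phylosignare.phylogeny import Branch, CloneTree
from phylosignare.simulate import TOPOLOGY_5
from phylosignare.spectra import N_CONTEXTS


def simplex_grid_argmin(A: np.ndarray, o: np.ndarray, step: float = 0.001) -> np.ndarray:
    """Exhaustive grid search for min ||A a - o|| on the 2- or 3-signature simplex.

    Independent oracle for the refitting engine: evaluates the quadratic
    objective a'Ga - 2c'a on every simplex grid point at the given step.
    """
    K = A.shape[1]
    n = round(1 / step)
    G = A.T @ A
    c = A.T @ o
    if K == 1:
        return np.ones(1)
    if K == 2:
        a1 = np.arange(n + 1) / n
        pts = np.stack([a1, 1 - a1], axis=1)
    elif K == 3:
        i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        mask = (i + j) <= n
        a1 = i[mask] / n
        a2 = j[mask] / n
        pts = np.stack([a1, a2, 1 - a1 - a2], axis=1)
    else:
        raise ValueError("grid oracle supports at most 3 signatures")
    vals = np.einsum("ij,jk,ik->i", pts, G, pts) - 2 * pts @ c
    return pts[int(np.argmin(vals))]


@pytest.fixture(scope="session")
def small_catalog() -> SignatureCatalog:
    """Three well-separated synthetic signature columns."""
    return make_synthetic_catalog(3, concentration=0.05, seed=11)


@pytest.fixture(scope="session")
def wide_catalog() -> SignatureCatalog:
    """A 30-column peaked synthetic catalog (benchmark-sized, COSMIC-like)."""
    return make_synthetic_catalog(30, seed=23)


def spectrum_from_mixture(
    catalog: SignatureCatalog, activities: dict[str, float], total_n: float
) -> MutationSpectrum:
    a = np.array([activities.get(name, 0.0) for name in catalog.names])
    return MutationSpectrum(total_n * (catalog.matrix @ a))


@pytest.fixture
def five_branch_tree(small_catalog) -> CloneTree:
    """The five-branch example topology with noiseless single-signature spectra."""
    branches = [
        Branch(bid, spectrum_from_mixture(small_catalog, {"SYN1": 1.0}, 50), parent)
        for bid, parent in TOPOLOGY_5.items()
    ]
    return CloneTree(branches)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
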