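import numpy as np
import pytest

from dustrisk import SyntheticConfig, generate_dataset

METALS = ("Ba", "Cd", "Co", "Cr", "Cu", "Fe", "Mn", "Ni", "Pb", "Zn")
BLOCKS = {"Zn": 0, "Fe": 0, "Cu": 0, "Pb": 0, "Cr": 1, "Mn": 1, "Ba": 1, "Co": 2, "Cd": 2, "Ni": 2}


def block_loadings(strength: float = 0.8) -> np.ndarray:
    lam = np.zeros((10, 3))
    for j, metal in enumerate(METALS):
        lam[j, BLOCKS[metal]] = strength
    return lam


def factor_only_config(seed: int, n_sites: int, strength: float = 0.8,
                       lognormal: bool = False) -> SyntheticConfig:
    """Pure latent-factor structure: no cluster shifts, Gaussian scale."""
    return SyntheticConfig(
        n_sites=n_sites,
        seed=seed,
        loadings_true=block_loadings(strength),
        factor_corr_true=np.eye(3),
        cluster_labels_true=np.zeros(n_sites, dtype=int),
        cluster_shifts=np.zeros((1, 10)),
        lognormal=lognormal,
    )


def clustered_config(seed: int, shift_sds: float = 3.0, strength: float = 0.0,
                     lognormal: bool = False, noise_sd: float = 0.3) -> SyntheticConfig:
    """Three planted clusters (5/5/4 sites) on a monotone enrichment gradient.

    ``shift_sds`` is the separation between adjacent cluster means in units
    of the unique-noise SD.
    """
    labels = np.array([0] * 5 + [1] * 5 + [2] * 4)
    step = shift_sds * noise_sd
    shifts = np.outer([2.0, 1.0, 0.0], np.ones(10)) * step
    return SyntheticConfig(
        seed=seed,
        cluster_labels_true=labels,
        cluster_shifts=shifts,
        loadings_true=block_loadings(strength),
        factor_corr_true=np.eye(3),
        noise_sd=noise_sd,
        lognormal=lognormal,
    )


@pytest.fixture
def small_dataset():
    """A 14-site study-condition table (default generator, fixed seed)."""
    return generate_dataset(SyntheticConfig(seed=11))
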