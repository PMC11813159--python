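import numpy as np
import pytest

from fruitspec.spectra import SpectraSet, TraitTable, WavelengthGrid
from fruitspec.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture
def small_grid() -> WavelengthGrid:
    """10 bands in the red region, 2 nm spacing."""
    return WavelengthGrid(np.arange(600.0, 620.0, 2.0))


@pytest.fixture
def small_spectra(small_grid) -> SpectraSet:
    """30 seeded random spectra on the 10-band grid."""
    rng = np.random.default_rng(42)
    refl = 0.2 + 0.6 * rng.random((30, len(small_grid)))
    ids = [f"s{i:02d}" for i in range(30)]
    return SpectraSet(grid=small_grid, reflectance=refl, sample_ids=ids)


@pytest.fixture
def small_traits(small_spectra) -> TraitTable:
    rng = np.random.default_rng(7)
    n = small_spectra.n_samples
    stages = ["unripe"] * 10 + ["ripe"] * 10 + ["overripe"] * 10
    return TraitTable(
        sample_ids=list(small_spectra.sample_ids),
        stage=stages,
        traits={"TSS": 10 + rng.normal(0, 1, n), "firmness": 5 + rng.normal(0, 0.5, n)},
    )


@pytest.fixture(scope="session")
def mango_dataset():
    """Default synthetic mango dataset (75 samples, 25/stage)."""
    return generate_dataset(GeneratorConfig.mango(seed=0))


@pytest.fixture(scope="session")
def strawberry_dataset():
    return generate_dataset(GeneratorConfig.strawberry(seed=0))


@pytest.fixture(scope="session")
def noiseless_mango():
    cfg = GeneratorConfig.mango(seed=3, noise_multiplicative=0.0, noise_additive=0.0)
    return generate_dataset(cfg)


def pair_r2_bruteforce(X: np.ndarray, y: np.ndarray, family: str = "ratio") -> np.ndarray:
    """Independent scalar-loop oracle: index per pair, Pearson r, square."""
    n, b = X.shape
    out = np.full((b, b), np.nan)
    for i in range(b):
        for j in range(b):
            if i == j:
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                if family == "ratio":
                    v = X[:, i] / X[:, j]
                else:
                    v = (X[:, i] - X[:, j]) / (X[:, i] + X[:, j])
            if not np.all(np.isfinite(v)) or np.std(v) == 0:
                continue
            r = np.corrcoef(v, y)[0, 1]
            out[i, j] = r * r
    return out
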