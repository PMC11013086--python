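import numpy as np
import pytest

from kincascade.synthetic import CtDesign, ExprDesign, SynthesisConfig


@pytest.fixture(scope="session")
def small_config() -> SynthesisConfig:
    """A reduced study design used by most fixture-driven tests."""
    return SynthesisConfig(
        seed=42,
        tier_counts={"MAPK": 4, "MAP2K": 3, "MEKK": 3, "RAF": 4,
                     "ZIK": 2, "MAP4K": 4},
        decoy_count=10,
        pairs_per_setting=10,
        n_promoters=5,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240941)


def random_protein(rng: np.random.Generator, n: int) -> str:
    from kincascade.motifs import AA20

    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))
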