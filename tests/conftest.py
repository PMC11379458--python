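import numpy as np
import pytest

from paleoerv.simulate import ElementLibrary, make_element_library, simulate_study


@pytest.fixture(scope="session")
def library() -> ElementLibrary:
    return make_element_library(1)


@pytest.fixture(scope="session")
def small_study():
    """A compact implant scenario for mining/orthology tests."""
    return simulate_study(
        seed=11, n_chrom=1, chrom_len=1_000_000,
        n_full=5, n_pro_pol=2, n_pol_env=2, n_both=1,
        n_nonrecomb=1, n_solo=2, n_decoy=2,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def diverge(seq: str, p: float, rng: np.random.Generator) -> str:
    """Substitution-only divergence at per-site probability p."""
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < p:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)
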