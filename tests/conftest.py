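import numpy as np
import pytest

from regmis import BetaPrior, PairData
from regmis.model import crude_rate_prior


@pytest.fixture
def toy_pair() -> PairData:
    """Two-stratum pair small enough for exact latent enumeration."""
    return PairData(y_S=[3, 2], y_R=[4, 5], n_S=[1000, 1000], n_R=[1000, 1000])


@pytest.fixture
def toy_prior() -> BetaPrior:
    return BetaPrior(2.0, 2.0)


@pytest.fixture
def toy_rate_prior(toy_pair):
    return crude_rate_prior(toy_pair)


@pytest.fixture
def zero_pair() -> PairData:
    """All-zero counts: the posterior collapses to the prior."""
    return PairData(y_S=[0, 0], y_R=[0, 0], n_S=[1000.0, 1000.0], n_R=[1000.0, 1000.0])


@pytest.fixture
def registry_csv(tmp_path):
    """Write a small well-formed two-province registry CSV."""
    from regmis import STRATA

    rng = np.random.default_rng(7)
    lines = ["province,sex,age_band,count,population"]
    for pid in ("A", "B"):
        for s in STRATA:
            lines.append(f"{pid},{s.sex},{s.age_band},{rng.integers(0, 20)},{50000}")
    path = tmp_path / "registry.csv"
    path.write_text("\n".join(lines) + "\n")
    return path
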