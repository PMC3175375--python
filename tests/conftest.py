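import numpy as np
import pytest

import agreemod as am

CATEGORIES = ("non-obstructed", "equivocal", "obstructed")


@pytest.fixture(scope="session")
def renex_table() -> am.ContingencyTable:
    """The bundled RENEX-vs-consensus 3x3 table (185 kidneys)."""
    return am.load_renex_consensus()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def random_table(
    rng: np.random.Generator,
    n_raters: int = 2,
    n_categories: int = 3,
    n: int = 200,
) -> am.ContingencyTable:
    """A random multinomial table with all-positive-probability cells."""
    ncell = n_categories**n_raters
    p = rng.dirichlet(np.full(ncell, 2.0))
    counts = rng.multinomial(n, p).reshape((n_categories,) * n_raters)
    raters = tuple(f"r{i}" for i in range(n_raters))
    cats = tuple(f"c{i}" for i in range(n_categories))
    return am.ContingencyTable(raters, cats, counts)
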