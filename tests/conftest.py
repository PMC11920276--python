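import numpy as np
import pandas as pd
import pytest

from xokit.genome import ChromosomeDef, GeneticMap, SnpPanel, default_genome, uniform_panel
from xokit.pedigree import Pedigree


@pytest.fixture
def toy_chroms():
    """Three chromosomes: two metacentric, one acrocentric."""
    return [
        ChromosomeDef(1, 100_000_000, 40_000_000, "metacentric"),
        ChromosomeDef(2, 80_000_000, 30_000_000, "metacentric"),
        ChromosomeDef(3, 60_000_000, 0, "acrocentric"),
    ]


@pytest.fixture
def toy_map(toy_chroms):
    gmap = GeneticMap()
    for c in toy_chroms:
        for sex, rate in (("M", 0.8), ("F", 1.2)):
            bp = np.linspace(0, c.bp_length, 6)
            gmap.set_anchors(c.index, sex, bp, bp / 1e6 * rate)
    return gmap


@pytest.fixture
def toy_panel(toy_chroms):
    return uniform_panel(toy_chroms, spacing_bp=5_000_000)


@pytest.fixture(scope="session")
def pig_genome():
    """Default 18-autosome synthetic genome with a 2 Mb marker grid."""
    chrom_defs, gmap = default_genome()
    panel = uniform_panel(chrom_defs, spacing_bp=2_000_000)
    return chrom_defs, gmap, panel


@pytest.fixture
def trio_pedigree():
    return Pedigree(
        pd.DataFrame(
            {"id": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2], "sex": ["M", "F", "F"]}
        )
    )


def build_a_matrix_oracle(ped: Pedigree) -> np.ndarray:
    """Independent additive-relationship oracle: memoised pairwise recursion
    a(i,j) = (a(j,sire_i) + a(j,dam_i)) / 2 for i later than j."""
    ids = [int(i) for i in ped.ids]
    order = {v: k for k, v in enumerate(ids)}
    cache: dict[tuple[int, int], float] = {}

    def a(i: int, j: int) -> float:
        if i == 0 or j == 0:
            return 0.0
        if order[i] < order[j]:
            i, j = j, i
        key = (i, j)
        if key in cache:
            return cache[key]
        s, d = ped.parents(i)
        if i == j:
            val = 1.0 + 0.5 * a(s, d)
        else:
            val = 0.5 * (a(j, s) + a(j, d))
        cache[key] = val
        return val

    n = len(ids)
    A = np.empty((n, n))
    for r, i in enumerate(ids):
        for c, j in enumerate(ids):
            A[r, c] = a(i, j)
    return A
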