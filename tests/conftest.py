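import numpy as np
import pytest

from nfymatrix.matrix import PWM, AffinityTable
from nfymatrix.oligos import base_at
from nfymatrix.synthetic_reference import cab2_wt_oligo, synthetic_ccaat_pwm


@pytest.fixture(scope="session")
def wt_oligo():
    return cab2_wt_oligo()


@pytest.fixture(scope="session")
def plant_pwm():
    """The package's synthetic reference CCAAT matrix (N5..N16)."""
    return synthetic_ccaat_pwm()


@pytest.fixture(scope="session")
def ccaat_point_pwm():
    """Width-5 point-mass matrix matching exactly CCAAT."""
    cols = np.zeros((5, 4))
    for i, base in enumerate("CCAAT"):
        cols[i, "ACGT".index(base)] = 1.0
    return PWM(matrix=cols, crystal_positions=tuple(range(8, 13)), id="CCAAT-exact")


def make_affinity_grid(wt, affinities, positions=None):
    """Truth table with one mutant cell per position at the given affinities."""
    positions = positions or tuple(range(5, 5 + len(affinities)))
    wt_ctx = {p: base_at(wt, p) for p in positions}
    cells = {}
    for pos, a in zip(positions, affinities):
        base = next(b for b in "ACGT" if b != wt_ctx[pos])
        cells[(pos, base)] = float(a)
    return AffinityTable(positions=positions, wt_context=wt_ctx, cells=cells)


def random_windows(rng, n, length=50, gc=0.36):
    """Composition-matched random DNA windows."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    return ["".join(alphabet[rng.choice(4, length, p=p)]) for _ in range(n)]
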