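import numpy as np
import pytest

from epiwatershed.synth import TissueParams, generate


@pytest.fixture(scope="session")
def small_tissue():
    """One deterministic 96x96 synthetic epithelium (image + truth)."""
    return generate(TissueParams(shape=(96, 96), rng_seed=11))


@pytest.fixture(scope="session")
def tissue_batch():
    """Ten deterministic small tissues for property-style assertions."""
    return [generate(TissueParams(shape=(80, 80), rng_seed=s)) for s in range(10)]


def random_label_image(rng: np.random.Generator, shape=(24, 24), max_cells=8):
    """Small random label image satisfying the watershed-line convention.

    Built by seeding a few cells and growing them with a nearest-seed rule,
    then carving one-pixel separating lines — independent of the package's
    watershed machinery so it can serve as oracle input.
    """
    h, w = shape
    n = int(rng.integers(1, max_cells + 1))
    seeds = rng.choice(h * w, size=n, replace=False)
    rows, cols = np.divmod(seeds, w)
    rr, cc = np.mgrid[0:h, 0:w]
    d = (rr[None] - rows[:, None, None]) ** 2 + (cc[None] - cols[:, None, None]) ** 2
    lab = np.argmin(d, axis=0) + 1
    out = lab.copy()
    boundary = np.zeros(shape, dtype=bool)
    boundary[:-1, :] |= lab[:-1, :] != lab[1:, :]
    boundary[:, :-1] |= lab[:, :-1] != lab[:, 1:]
    boundary[0, :] = boundary[-1, :] = True
    boundary[:, 0] = boundary[:, -1] = True
    out[boundary] = 0
    # drop labels that vanished entirely under the carved lines
    from scipy import ndimage as ndi

    relabeled, _ = ndi.label(out > 0, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
    return relabeled.astype(np.int32)
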