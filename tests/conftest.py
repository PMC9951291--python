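import numpy as np
import pytest

from cgmapopt import build_chain, build_gnm, demo_structure


def assert_within_se(values, target, n_se=3.0, msg=""):
    """Mean of seed-replicated estimates within n_se standard errors."""
    values = np.asarray(values, dtype=float)
    se = values.std(ddof=1) / np.sqrt(values.size)
    err = abs(values.mean() - target)
    assert err <= n_se * se + 1e-12, (
        f"{msg}: |{values.mean():.6g} - {target:.6g}| = {err:.3g} "
        f"> {n_se} * SE = {n_se * se:.3g}"
    )


@pytest.fixture(scope="session")
def chain_soft_edges():
    """Soft springs at the edges, stiff in the middle (k1 < k2)."""
    return build_chain(4, [1.0, 4.0, 1.0])


@pytest.fixture(scope="session")
def chain_stiff_edges():
    """Stiff springs at the edges, soft in the middle (k1 > k2)."""
    return build_chain(4, [4.0, 1.0, 4.0])


@pytest.fixture(scope="session")
def chain_uniform():
    return build_chain(4, [1.0, 1.0, 1.0])


@pytest.fixture(scope="session")
def gnm_fixture():
    """GNM of the pinned 40-residue synthetic structure at cutoff 10."""
    return build_gnm(demo_structure(), 10.0)
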