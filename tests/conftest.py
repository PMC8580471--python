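import numpy as np
import pytest

import fibrinbd as fb


@pytest.fixture(scope="session")
def params():
    return fb.ModelParameters()


@pytest.fixture(scope="session")
def toys(params):
    return fb.toy_configurations(params)


def random_bent_chain(rng, n_nodes=8, n_fibres=1, box=3e-6, step=22e-9,
                      jitter=8e-9):
    """Random mildly-bent chains: bond lengths ~ step with 3D jitter.

    Dihedral-cusp configurations (phi ~ pi) are astronomically unlikely at
    this jitter level, keeping finite-difference checks well-conditioned.
    """
    steps = rng.normal(scale=jitter, size=(n_fibres, n_nodes, 3))
    steps[..., 0] += step
    pos = np.cumsum(steps, axis=1)
    pos += rng.random((n_fibres, 1, 3)) * box
    return fb.FibreNetwork(positions=pos, box_lengths=[box] * 3)


def finite_difference_forces(term, net, params, h=1e-12):
    """Central-difference gradient oracle for a potential term."""
    F = np.zeros_like(net.positions)
    for f in range(net.n_fibres):
        for n in range(net.nodes_per_fibre):
            for k in range(3):
                p = net.copy()
                p.positions[f, n, k] += h
                wp = term(p, params).energy.W_total
                p.positions[f, n, k] -= 2 * h
                wm = term(p, params).energy.W_total
                F[f, n, k] = -(wp - wm) / (2 * h)
    return F


def assert_forces_match(analytic, fd, rtol=1e-5, floor_frac=1e-7):
    """Relative comparison with a floor at a small fraction of the maximum
    force magnitude (finite differences lose precision for near-zero
    components)."""
    scale = max(np.abs(analytic).max(), np.abs(fd).max(), 1e-30)
    np.testing.assert_allclose(analytic, fd, rtol=rtol,
                               atol=floor_frac * scale)
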