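"""Shared hand-computed fixtures.

All expected values below were derived by hand (forward construction and
direct evaluation) before the implementation existed; see the individual
fixture docstrings.
"""

import numpy as np
import pytest

from typermat import DistanceMatrix


@pytest.fixture
def line4() -> DistanceMatrix:
    """Four points on a line at 1-unit spacing: an additive path-tree metric."""
    return DistanceMatrix.line_metric({"g1": 0, "g2": 1, "g3": 2, "g4": 3})


@pytest.fixture
def d3() -> DistanceMatrix:
    """3-point metric with d12=1, d13=2, d23=3.

    Undirected Hamiltonian paths and lengths (by enumeration):
    (1,2,3) -> 4, (2,1,3) -> 3, (1,3,2) -> 5.
    """
    return DistanceMatrix.from_dict(
        ["1", "2", "3"], {("1", "2"): 1.0, ("1", "3"): 2.0, ("2", "3"): 3.0}
    )


@pytest.fixture
def dbox() -> DistanceMatrix:
    """Box-graph metric on (p,q,r,s): pendant lengths 1, half-sides u=2, v=1.

    Shortest-path distances computed by hand on the box graph:
    d_pq=3, d_pr=4, d_ps=5, d_qr=5, d_qs=4, d_rs=3. Pairing sums 6, 8, 10,
    so the two largest differ and the 4-point condition fails.
    """
    return DistanceMatrix.from_dict(
        ["p", "q", "r", "s"],
        {
            ("p", "q"): 3.0, ("p", "r"): 4.0, ("p", "s"): 5.0,
            ("q", "r"): 5.0, ("q", "s"): 4.0, ("r", "s"): 3.0,
        },
    )


@pytest.fixture
def drec4() -> DistanceMatrix:
    """Recombinant insertion (a=0.5) of z into the 3-point metric on (x,y,u).

    Forward construction from d_xy=2, d_xu=3, d_yu=3: d_zx=d_zy=1, d_zu=3;
    genomic order (x, z, y, u). Kalmanson quadruple checked by hand:
    max(1+3, 3+1)=4 <= 2+3=5.
    """
    return DistanceMatrix.from_dict(
        ["x", "z", "y", "u"],
        {
            ("x", "z"): 1.0, ("x", "y"): 2.0, ("x", "u"): 3.0,
            ("z", "y"): 1.0, ("z", "u"): 3.0, ("y", "u"): 3.0,
        },
    )


@pytest.fixture
def w1() -> DistanceMatrix:
    """5-gene worked fixture with one recombinant event.

    Built forward from the line metric u=0, x=1, y=2, v=4 by inserting z
    between x and y with crossover fraction a=0.3, then adding divergence
    increments delta_z=0.5, delta_x=0.1, delta_y=0.2. Hand inversion:
    a = (4.4-5.0)/(3.3-5.3) = 0.3, delta_z = (1.3+1.0-1.3)/2 = 0.5,
    f(a) = 2.2 - 0.3*1.1 - 0.7*2.2 = 0.33, ancestral d_xy = 1,
    delta_x = 1.3 - 0.7 - 0.5 = 0.1, delta_y = 1.0 - 0.3 - 0.5 = 0.2.
    """
    return DistanceMatrix.from_dict(
        ["u", "x", "z", "y", "v"],
        {
            ("u", "x"): 1.1, ("u", "y"): 2.2, ("u", "v"): 4.0, ("u", "z"): 2.2,
            ("x", "y"): 1.3, ("x", "v"): 3.1, ("x", "z"): 1.3,
            ("y", "v"): 2.2, ("y", "z"): 1.0, ("z", "v"): 2.8,
        },
    )


def random_metric(n: int, rng: np.random.Generator) -> DistanceMatrix:
    """Random Euclidean (hence metric) distance matrix on n planar points."""
    pts = rng.random((n, 2)) * 3.0
    m = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(m, 0.0)
    m = 0.5 * (m + m.T)
    return DistanceMatrix([f"t{i}" for i in range(n)], m)
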