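import numpy as np
import pytest

from nemashell.shell import CellularShell
from nemashell.synthetic import generate_sphere_shell


@pytest.fixture(scope="session")
def cube_shell() -> CellularShell:
    """Unit cube as 6 square cells, outward winding."""
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                  [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float)
    cells = [
        [0, 3, 2, 1],  # bottom (z=0), outward = -z
        [4, 5, 6, 7],  # top (z=1), outward = +z
        [0, 1, 5, 4],  # front (y=0)
        [1, 2, 6, 5],  # right (x=1)
        [2, 3, 7, 6],  # back (y=1)
        [3, 0, 4, 7],  # left (x=0)
    ]
    return CellularShell(v, cells)


@pytest.fixture(scope="session")
def icosahedron_shell() -> CellularShell:
    """Regular icosahedron with unit circumradius (20 triangle cells)."""
    phi = (1 + np.sqrt(5)) / 2
    raw = []
    for a, b in [(1, phi), (-1, phi), (1, -phi), (-1, -phi)]:
        raw += [[0, a, b], [a, b, 0], [b, 0, a]]
    v = np.array(raw, dtype=float)
    v /= np.linalg.norm(v[0])
    # faces via convex hull, rewound outward
    from scipy.spatial import ConvexHull

    hull = ConvexHull(v)
    cells = []
    for simplex in hull.simplices:
        p = v[simplex]
        n = np.cross(p[1] - p[0], p[2] - p[0])
        if n @ p.mean(axis=0) < 0:
            simplex = simplex[::-1]
        cells.append(list(simplex))
    return CellularShell(v, cells)


@pytest.fixture(scope="session")
def sphere_shell_200() -> CellularShell:
    return generate_sphere_shell(200, seed=1)


@pytest.fixture(scope="session")
def sphere_shell_small() -> CellularShell:
    return generate_sphere_shell(60, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
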