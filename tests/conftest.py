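import numpy as np
import pytest

import spectrack as st


@pytest.fixture(scope="session")
def gyr_spectra():
    """12-channel lambda-mode reference spectra for the GFP/YFP/RFP palette."""
    return st.make_reference_spectra(st.DEFAULT_FLUOROPHORES[1:4])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def brute_force_object_count(pop):
    """Independent union-find oracle over all O(N^2) footprint pairs.

    Merges two cells iff their border-clipped square footprints intersect
    with positive area and their color subsets are identical; returns the
    number of merged groups.
    """
    n = pop.n_cells
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    def clipped(c):
        h = c.side / 2.0
        return (max(0.0, c.center_x - h), min(pop.region.width, c.center_x + h),
                max(0.0, c.center_y - h), min(pop.region.height, c.center_y + h))

    for i in range(n):
        x0i, x1i, y0i, y1i = clipped(pop.cells[i])
        for j in range(i + 1, n):
            if pop.colors[i] != pop.colors[j]:
                continue
            x0j, x1j, y0j, y1j = clipped(pop.cells[j])
            ox = min(x1i, x1j) - max(x0i, x0j)
            oy = min(y1i, y1j) - max(y0i, y0j)
            if ox > 0 and oy > 0:
                union(i, j)
    return len({find(i) for i in range(n)})
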