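import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from adjdiff import AdjacencyGraph, AreaUnit, CountyTable


def graph_from_edges(edges, roster=None):
    """Small in-memory graph builder for fixtures."""
    ids = list(roster) if roster else sorted({i for e in edges for i in e})
    nbrs = {i: set() for i in ids}
    for a, b in edges:
        nbrs[a].add(b)
        nbrs[b].add(a)
    return AdjacencyGraph(tuple(AreaUnit(i, i) for i in ids),
                          {i: frozenset(v) for i, v in nbrs.items()})


@pytest.fixture
def path3():
    """A - B - C."""
    return graph_from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def cycle4():
    """A - B - C - D - A."""
    return graph_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])


@pytest.fixture
def square_grid():
    """Polygons of a k x k grid of unit squares, as an id -> geometry dict."""
    def _make(k):
        return {f"r{r}c{c}": box(c, r, c + 1, r + 1)
                for r in range(k) for c in range(k)}
    return _make


@pytest.fixture
def small_table(path3):
    df = pd.DataFrame(
        {"outcome": [10.0, 7.0, 1.0], "povr": [4.0, 2.0, 8.0]},
        index=pd.Index(["A", "B", "C"], name="id"),
    )
    return CountyTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
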