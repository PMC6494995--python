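import numpy as np
import pandas as pd
import pytest

from ssngen import (
    GenotypeMatrix,
    NetworkPoint,
    build_network,
    hydrologic_distances,
)


@pytest.fixture
def y_network():
    """Two headwaters A (area 6) and B (area 4) joining into outlet C."""
    tab = pd.DataFrame(
        {
            "segment_id": ["A", "B", "C"],
            "downstream_id": ["C", "C", ""],
            "length": [1000.0, 1000.0, 1000.0],
            "area": [6.0, 4.0, 2.0],
            "precip": [1000.0, 1000.0, 1000.0],
        }
    )
    return build_network(tab)


@pytest.fixture
def y_points():
    return [
        NetworkPoint("a", "A", 500.0, 0.0, 1000.0),
        NetworkPoint("b", "B", 500.0, 800.0, 1000.0),
        NetworkPoint("c", "C", 500.0, 400.0, 0.0),
    ]


@pytest.fixture
def y_dset(y_network, y_points):
    return hydrologic_distances(y_network, y_points)


def random_tree_table(rng, n_segments, n_basins=1):
    """Edge table of a random rooted forest (independent of the simulator)."""
    rows = []
    sid = 0
    for b in range(n_basins):
        ids = []
        for k in range(max(1, n_segments // n_basins)):
            sid += 1
            me = f"s{sid}"
            down = ids[int(rng.integers(len(ids)))] if ids else ""
            ids.append(me)
            rows.append(
                {
                    "segment_id": me,
                    "downstream_id": down,
                    "length": float(rng.uniform(100, 5000)),
                    "area": float(rng.uniform(0.1, 20)),
                    "precip": float(rng.uniform(400, 1600)),
                }
            )
    return pd.DataFrame(rows)


def random_points(rng, net, n_points):
    segs = sorted(net.segments)
    pts = []
    for i in range(n_points):
        sid = segs[int(rng.integers(len(segs)))]
        pts.append(
            NetworkPoint(
                f"p{i}",
                sid,
                float(rng.uniform(0, net.segments[sid].length)),
                float(rng.uniform(0, 1e5)),
                float(rng.uniform(0, 1e5)),
            )
        )
    return pts


@pytest.fixture
def toy_genotypes():
    """Two populations, two loci; hand-checkable frequencies."""
    calls = np.array(
        [
            [[1, 1], [1, 2]],
            [[1, 2], [1, 2]],
            [[1, 2], [0, 0]],
            [[2, 2], [3, 3]],
            [[2, 2], [3, 4]],
        ]
    )
    return GenotypeMatrix(
        individuals=["i1", "i2", "i3", "i4", "i5"],
        populations=["P1", "P1", "P1", "P2", "P2"],
        loci=["L1", "L2"],
        calls=calls,
    )
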