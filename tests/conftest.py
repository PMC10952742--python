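import numpy as np
import pytest

from pemscope import synthdata
from pemscope.network import Segment, VesselNetwork


@pytest.fixture(scope="session")
def default_scene():
    """One default-condition scene shared by read-only tests."""
    return synthdata.generate_scene(synthdata.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def labeled_scene(default_scene):
    from pemscope import associate
    res = associate.classify(default_scene.cells, default_scene.network)
    return default_scene, res


@pytest.fixture()
def straight_capillary():
    """A single straight 4 μm capillary along x at y=z=50, length 200 μm."""
    xs = np.arange(0.0, 201.0, 2.0)
    pts = np.column_stack([xs, np.full_like(xs, 50.0), np.full_like(xs, 50.0)])
    seg = Segment(0, 0, 1, pts, np.full(len(xs), 4.0), order=1,
                  vessel_class="capillary")
    return VesselNetwork(nodes={0: pts[0], 1: pts[-1]}, segments=[seg])


def make_random_scene(rng, n_micro=60, n_peri=12, extent=(300.0, 300.0, 60.0),
                      dim=3):
    """Random point scene (no generator structure) plus a random polyline
    network; used by oracle-equivalence tests."""
    import pandas as pd

    ex, ey, ez = extent
    rows = []
    cid = 0
    for _ in range(n_peri):
        rows.append(dict(cell_id=cid, cell_type="pericyte",
                         x_um=rng.uniform(0, ex), y_um=rng.uniform(0, ey),
                         z_um=rng.uniform(0, ez) if dim == 3 else np.nan,
                         local_diameter_um=rng.uniform(3.0, 14.0)))
        cid += 1
    for _ in range(n_micro):
        rows.append(dict(cell_id=cid, cell_type="microglia",
                         x_um=rng.uniform(0, ex), y_um=rng.uniform(0, ey),
                         z_um=rng.uniform(0, ez) if dim == 3 else np.nan))
        cid += 1
    cells = pd.DataFrame(rows)
    for c in ("soma_x_um", "soma_y_um", "soma_z_um"):
        cells[c] = cells[c.replace("soma_", "")]

    net = VesselNetwork()
    nid = 0
    for k in range(4):
        n_pts = rng.integers(4, 10)
        pts = np.cumsum(rng.uniform(-25, 25, size=(n_pts, 3)), axis=0) + \
            [rng.uniform(0, ex), rng.uniform(0, ey), rng.uniform(0, ez)]
        diam = rng.uniform(3.0, 13.0, size=n_pts)
        net.nodes[nid] = pts[0]
        net.nodes[nid + 1] = pts[-1]
        net.segments.append(Segment(k, nid, nid + 1, pts, diam,
                                    order=None, vessel_class="capillary"))
        nid += 2
    return cells, net
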