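import numpy as np
import pandas as pd
import pytest

from pemscope import associate, synthdata, vasctree
from pemscope.network import Segment, VesselNetwork


def straight(seg_id, n0, n1, p0, p1, diameter=4.0, n=6, vclass="capillary"):
    pts = np.linspace(p0, p1, n)
    return Segment(seg_id, n0, n1, pts, np.full(n, float(diameter)),
                   vessel_class=vclass)


def y_network():
    """Root along x, two daughters."""
    net = VesselNetwork(nodes={
        0: np.array([0.0, 0, 0]), 1: np.array([60.0, 0, 0]),
        2: np.array([110.0, 40.0, 0]), 3: np.array([110.0, -40.0, 0])})
    net.segments = [
        straight(0, 0, 1, net.nodes[0], net.nodes[1], diameter=12.0,
                 vclass="arteriole"),
        straight(1, 1, 2, net.nodes[1], net.nodes[2]),
        straight(2, 1, 3, net.nodes[1], net.nodes[3]),
    ]
    return net


def bfs_depth_oracle(network, root_id):
    """Brute-force BFS depth over the segment adjacency graph."""
    adj = {}
    for a in network.segments:
        for b in network.segments:
            if b.segment_id == a.segment_id:
                continue
            if {a.start_node, a.end_node} & {b.start_node, b.end_node}:
                adj.setdefault(a.segment_id, set()).add(b.segment_id)
    depth = {root_id: 0}
    frontier = [root_id]
    while frontier:
        nxt = []
        for sid in frontier:
            for nb in adj.get(sid, ()):
                if nb not in depth:
                    depth[nb] = depth[sid] + 1
                    nxt.append(nb)
        frontier = nxt
    return depth


def random_tree(rng, max_segments=50):
    """Random tree by attaching segments to random existing endpoints."""
    net = VesselNetwork(nodes={0: rng.uniform(0, 100, 3)})
    open_nodes = [0]
    n_seg = int(rng.integers(1, max_segments))
    for sid in range(n_seg):
        parent = int(rng.choice(open_nodes))
        new = len(net.nodes)
        net.nodes[new] = net.nodes[parent] + rng.uniform(-40, 40, 3)
        net.segments.append(straight(sid, parent, new, net.nodes[parent],
                                     net.nodes[new],
                                     diameter=rng.uniform(3, 9)))
        open_nodes.append(new)
    return net


class TestBranchOrders:
    def test_single_y(self):
        net = vasctree.assign_branch_orders(y_network(), root_segment=0)
        orders = {s.segment_id: s.order for s in net.segments}
        assert orders == {0: 0, 1: 1, 2: 1}

    def test_default_root_is_largest_arteriole(self):
        net = vasctree.assign_branch_orders(y_network())
        assert net.segment(0).order == 0

    def test_generator_tree_reaches_order_8_at_venule(self):
        cfg = synthdata.GeneratorConfig(seed=4)
        net = synthdata.generate_vessel_network(cfg)
        truth = {s.segment_id: s.order for s in net.segments}
        for s in net.segments:
            s.order = None
        vasctree.assign_branch_orders(net)
        assert {s.segment_id: s.order for s in net.segments} == truth
        venule = [s for s in net.segments if s.vessel_class == "venule"]
        assert venule[0].order == 8 == max(s.order for s in net.segments)

    def test_random_trees_match_bfs_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            net = random_tree(rng)
            root = net.segments[0].segment_id
            vasctree.assign_branch_orders(net, root_segment=root)
            oracle = bfs_depth_oracle(net, root)
            assert {s.segment_id: s.order for s in net.segments} == oracle

    def test_cycle_refused_without_spanning_tree(self):
        net = y_network()
        # close a loop between the two daughter tips
        net.segments.append(straight(3, 2, 3, net.nodes[2], net.nodes[3]))
        with pytest.raises(vasctree.CyclicNetworkError):
            vasctree.assign_branch_orders(net, root_segment=0)
        vasctree.assign_branch_orders(net, root_segment=0,
                                      spanning_tree=True)
        assert all(s.order is not None for s in net.segments)


class TestLocateOnTree:
    def test_midpoint_and_junction_flags(self):
        net = vasctree.assign_branch_orders(y_network(), root_segment=0)
        cells = pd.DataFrame([
            dict(cell_id=0, cell_type="pericyte", x_um=30.0, y_um=2.0,
                 z_um=0.0, soma_x_um=30.0, soma_y_um=2.0, soma_z_um=0.0),
            dict(cell_id=1, cell_type="pericyte", x_um=57.0, y_um=3.0,
                 z_um=0.0, soma_x_um=57.0, soma_y_um=3.0, soma_z_um=0.0),
            dict(cell_id=2, cell_type="pericyte", x_um=500.0, y_um=500.0,
                 z_um=0.0, soma_x_um=500.0, soma_y_um=500.0, soma_z_um=0.0),
        ])
        loc = vasctree.locate_on_tree(cells, net)
        assert loc.branch_order.iloc[0] == 0
        assert not loc.at_junction.iloc[0]
        assert loc.at_junction.iloc[1]
        assert loc.unmapped.iloc[2]

    def test_generator_truth_orders_recovered(self, labeled_scene):
        scene, res = labeled_scene
        loc = vasctree.locate_on_tree(res.cells, scene.network)
        peri = loc[loc.cell_type == "pericyte"]
        seg_order = {s.segment_id: s.order for s in scene.network.segments}
        expected = peri.segment_id.map(seg_order)
        agree = (peri.branch_order == expected)
        assert agree.all()

    def test_order_distribution_counts_conserved(self, labeled_scene):
        scene, res = labeled_scene
        loc = vasctree.locate_on_tree(res.cells, scene.network)
        dist = vasctree.order_distribution(loc)
        peri_rows = dist[(dist.cell_class == "pericyte") &
                         (dist.branch_order >= 0)]
        assert peri_rows["count"].sum() == \
            (~loc.unmapped & (loc.cell_type == "pericyte")).sum()


class TestWidthMeasurement:
    def make_scene(self):
        xs = np.arange(0.0, 201.0, 1.0)
        pts = np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)])
        seg = Segment(0, 0, 1, pts, np.full(len(xs), 4.0),
                      order=1, vessel_class="capillary")
        return VesselNetwork(nodes={0: pts[0], 1: pts[-1]}, segments=[seg])

    def test_constant_diameter_all_location_types(self):
        net = self.make_scene()
        rules = vasctree.WidthRules(mode="fixed")
        for loc in ("VO", "P", "CAM", "PEM"):
            m = vasctree.measure_width_at(net, 0, 100.0, loc, rules)
            assert m["width_um"] == pytest.approx(4.0)

    def test_branchpoint_exclusion(self):
        net = self.make_scene()
        assert vasctree.measure_width_at(net, 0, 3.0, "VO",
                                         vasctree.WidthRules()) is None

    def test_wide_host_rejected(self):
        net = self.make_scene()
        net.segment(0).diameters[:] = 11.0
        assert vasctree.measure_width_at(net, 0, 100.0, "P",
                                         vasctree.WidthRules()) is None

    def test_two_line_average_versus_center_line(self):
        net = self.make_scene()
        seg = net.segment(0)
        seg.scale_diameters(100.0, 1.16, half_width=6.0)
        fixed = vasctree.measure_width_at(net, 0, 100.0, "P",
                                          vasctree.WidthRules(mode="fixed"))
        invivo = vasctree.measure_width_at(
            net, 0, 100.0, "P", vasctree.WidthRules(mode="invivo"))
        # flat bump: both rules see the dilated profile
        assert fixed["width_um"] == pytest.approx(4.0 * 1.16)
        assert invivo["width_um"] == pytest.approx(4.0 * 1.16)

    def test_dilated_pericyte_width_near_4_89(self):
        """Generator factor 1.16 over a 4.21 μm baseline → ≈ 4.89 μm."""
        xs = np.arange(0.0, 201.0, 1.0)
        pts = np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)])
        seg = Segment(0, 0, 1, pts, np.full(len(xs), 4.21),
                      order=1, vessel_class="capillary")
        net = VesselNetwork(nodes={0: pts[0], 1: pts[-1]}, segments=[seg])
        seg.scale_diameters(80.0, 1.16, half_width=6.0)
        m = vasctree.measure_width_at(net, 0, 80.0, "P",
                                      vasctree.WidthRules(mode="fixed"))
        assert m["width_um"] == pytest.approx(4.89, abs=0.01)

    def test_cam_near_pericyte_excluded_from_widths(self):
        net = self.make_scene()
        cells = pd.DataFrame([
            dict(cell_id=0, cell_type="pericyte", x_um=100.0, y_um=2.0,
                 z_um=0.0, soma_x_um=100.0, soma_y_um=2.0, soma_z_um=0.0,
                 segment_id=0, arclength_um=100.0, local_diameter_um=4.0,
                 is_cam=False, is_pem=False, has_pem=False),
            dict(cell_id=1, cell_type="microglia", x_um=106.0, y_um=3.0,
                 z_um=0.0, soma_x_um=106.0, soma_y_um=3.0, soma_z_um=0.0,
                 segment_id=-1, arclength_um=np.nan,
                 local_diameter_um=np.nan,
                 is_cam=True, is_pem=True, has_pem=False),
        ])
        meas = vasctree.measure_scene_widths(cells, net)
        assert "CAM" not in set(meas.location_type)

    def test_vo_requires_clearance(self):
        net = self.make_scene()
        # one pericyte in the middle: VO point must stay >10 μm away
        cells = pd.DataFrame([
            dict(cell_id=0, cell_type="pericyte", x_um=100.0, y_um=2.0,
                 z_um=0.0, soma_x_um=100.0, soma_y_um=2.0, soma_z_um=0.0,
                 segment_id=0, arclength_um=100.0, local_diameter_um=4.0,
                 is_cam=False, is_pem=False, has_pem=False)])
        meas = vasctree.measure_scene_widths(cells, net)
        vo = meas[meas.location_type == "VO"]
        assert len(vo) == 1
        assert abs(vo.arclength_um.iloc[0] - 100.0) > 10.0


class TestWidthContrast:
    def test_all_equal_widths_zero_differences(self):
        rows = []
        for loc in ("VO", "P", "CAM", "PEM"):
            for k in range(4):
                rows.append(dict(scene_id=0, location_type=loc,
                                 segment_id=0, arclength_um=k,
                                 width_um=4.0, day=None, cell_ids=""))
        out = vasctree.width_contrast_table(pd.DataFrame(rows))
        for loc in ("P", "CAM", "PEM"):
            assert out["table"][f"pct_diff_{loc}_vs_VO"].iloc[0] == \
                pytest.approx(0.0)

    def test_group_below_threshold_excluded(self):
        rows = [dict(scene_id=0, location_type="VO", segment_id=0,
                     arclength_um=k, width_um=4.0, day=None, cell_ids="")
                for k in range(3)]
        rows += [dict(scene_id=0, location_type="P", segment_id=0,
                      arclength_um=k, width_um=5.0, day=None, cell_ids="")
                 for k in range(4)]
        out = vasctree.width_contrast_table(pd.DataFrame(rows),
                                            min_per_group=4)
        assert np.isnan(out["table"]["VO"].iloc[0])
        assert out["table"]["P"].iloc[0] == pytest.approx(5.0)

    def test_generator_dilation_factors_recovered(self):
        """Percent differences vs VO recover the 16/15/21% dilations."""
        diffs = {"P": [], "CAM": [], "PEM": []}
        for seed in range(12):
            cfg = synthdata.GeneratorConfig(seed=seed)
            scene = synthdata.generate_scene(cfg)
            res = associate.classify(scene.cells, scene.network)
            meas = vasctree.measure_scene_widths(res.cells, scene.network,
                                                 scene_id=seed)
            out = vasctree.width_contrast_table(meas, min_per_group=1)
            for loc in diffs:
                v = out["table"][f"pct_diff_{loc}_vs_VO"].iloc[0]
                if np.isfinite(v):
                    diffs[loc].append(v)
        assert np.mean(diffs["P"]) == pytest.approx(16.0, abs=3.0)
        assert np.mean(diffs["CAM"]) == pytest.approx(15.0, abs=3.0)
        assert np.mean(diffs["PEM"]) == pytest.approx(21.0, abs=3.0)


def test_width_change_recovers_event_factors():
    cfg = synthdata.tracking_config(seed=3)
    scene = synthdata.generate_scene(cfg)
    series = synthdata.simulate_timepoints(scene, [0, 4, 7, 28], cfg)
    out = vasctree.width_change_on_gain_loss(series)
    ev = out["events"]
    losses = ev[ev.event == "loss"]
    gains = ev[ev.event == "gain"]
    assert (losses["pct_change"] < 0).all()
    assert (gains["pct_change"] > 0).all()
    assert losses["pct_change"].mean() == pytest.approx(-9.0, abs=3.0)


def test_width_change_empty_series():
    cfg = synthdata.tracking_config(seed=3, retention_per_visit=1.0,
                                    gain_rate=0.0)
    scene = synthdata.generate_scene(cfg)
    series = synthdata.simulate_timepoints(scene, [0, 4], cfg)
    out = vasctree.width_change_on_gain_loss(series)
    assert len(out["events"]) == 0
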