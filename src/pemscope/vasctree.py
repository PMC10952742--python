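"""Vascular-tree analysis: branch orders, cell positions on the tree, and
vessel width at cell landmarks.

Branch order follows the arteriole-rooted taxonomy: the penetrating
arteriole is order 0 and every daughter segment at a bifurcation takes its
parent's order plus one, so the ascending venule of the default synthetic
tree sits at order 8.  Width is measured on capillaries (< 10 μm diameter)
away from branchpoints, at four landmark types: VO (vessel only, no soma
nearby), P (lone pericyte), CAM (lone capillary-associated microglia more
than 10 μm from any pericyte) and PEM (pericyte with an adjacent
pericyte-associated microglia).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .associate import AssociationCriteria, reference_coords
from .network import VesselNetwork
from .synthdata import MICROGLIA, PERICYTE, TimeSeriesScene

logger = logging.getLogger("pemscope.vasctree")

LOCATION_TYPES = ("VO", "P", "CAM", "PEM", "gain", "loss")


class CyclicNetworkError(ValueError):
    """Branch ordering refused on a cyclic graph without spanning-tree mode."""


@dataclass
class WidthRules:
    """Parameters of the width-measurement protocol.

    ``mode`` selects the fixed-tissue rule for P/PEM (mean of two lines
    drawn at ``side_offset`` μm on either side of the pericyte soma) or the
    in-vivo rule (single line at the soma center).  Measurements are only
    made on host segments with local diameter < ``d_vessel_max``, at least
    ``branch_exclusion`` μm of arclength from any junction; VO points
    additionally require no soma of any type within ``vo_clearance`` μm.
    """

    mode: str = "fixed"            # "fixed" | "invivo"
    side_offset: float = 4.0
    branch_exclusion: float = 10.0
    vo_clearance: float = 10.0
    d_vessel_max: float = 10.0
    cam_pericyte_exclusion: float = 10.0
    min_per_group: int = 4

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "invivo"):
            raise ValueError("mode must be 'fixed' or 'invivo'")


# ---------------------------------------------------------------------------
# branch orders


def assign_branch_orders(network: VesselNetwork,
                         root_segment: int | None = None,
                         spanning_tree: bool = False) -> VesselNetwork:
    """Assign branch orders in place (and return the network).

    The root segment gets order 0; every segment reached across a shared
    node gets its parent's order + 1 (breadth-first).  The root defaults to
    the segment with the largest mean diameter of arteriole class if any
    such exists, else the largest mean diameter overall.  Cyclic graphs are
    refused unless ``spanning_tree`` is set, in which case the BFS tree
    defines the orders.
    """
    if not network.segments:
        return network
    g = network.graph()
    import networkx as nx
    if not spanning_tree and len(nx.cycle_basis(g)) > 0:
        raise CyclicNetworkError("network contains cycles; pass "
                                 "spanning_tree=True to order the BFS tree")

    if root_segment is None:
        pool = [s for s in network.segments if s.vessel_class == "arteriole"] \
            or network.segments
        root_segment = max(pool, key=lambda s: s.diameters.mean()).segment_id

    by_id = {s.segment_id: s for s in network.segments}
    adj: dict[int, list[int]] = {}
    node_segs: dict[int, list[int]] = {}
    for s in network.segments:
        node_segs.setdefault(s.start_node, []).append(s.segment_id)
        node_segs.setdefault(s.end_node, []).append(s.segment_id)
    for segs in node_segs.values():
        for a in segs:
            adj.setdefault(a, [])
            for b in segs:
                if b != a and b not in adj[a]:
                    adj[a].append(b)

    order = {root_segment: 0}
    queue = deque([root_segment])
    while queue:
        sid = queue.popleft()
        for nb in sorted(adj.get(sid, [])):
            if nb not in order:
                order[nb] = order[sid] + 1
                queue.append(nb)
    for sid, o in order.items():
        by_id[sid].order = o
    return network


# ---------------------------------------------------------------------------
# locating cells on the tree


def locate_on_tree(cells: pd.DataFrame, network: VesselNetwork,
                   d_junction: float = 10.0, max_snap: float = 20.0,
                   criteria: AssociationCriteria | None = None
                   ) -> pd.DataFrame:
    """Map each cell to the branch order of its nearest centerline point
    and flag junction residence (within ``d_junction`` μm of a node).

    Cells farther than ``max_snap`` from any centerline are flagged
    ``unmapped`` and excluded from distribution tallies.
    """
    criteria = criteria or AssociationCriteria()
    out = cells.copy()
    coords = reference_coords(out, criteria)
    res = network.nearest_points(coords)
    orders = {s.segment_id: s.order for s in network.segments}
    out["snap_distance_um"] = res["distance"]
    out["snap_segment_id"] = res["segment_id"]
    out["snap_arclength_um"] = res["arclength"]
    out["branch_order"] = [orders.get(int(s), None) if s >= 0 else None
                           for s in res["segment_id"]]
    out["unmapped"] = ~(np.isfinite(res["distance"]) &
                        (res["distance"] <= max_snap))

    node_xyz = np.array(list(network.nodes.values()))
    k = coords.shape[1]
    dmin = np.full(len(out), np.inf)
    if len(node_xyz):
        for lo in range(0, len(coords), 512):
            q = coords[lo:lo + 512]
            d = np.linalg.norm(q[:, None, :] - node_xyz[None, :, :k], axis=2)
            dmin[lo:lo + len(q)] = d.min(axis=1)
    out["at_junction"] = (dmin < d_junction) & ~out["unmapped"]
    n_un = int(out["unmapped"].sum())
    if n_un:
        logger.info("locate_on_tree: %d cells unmapped (> %g μm from any "
                    "centerline)", n_un, max_snap)
    return out


def order_distribution(located: pd.DataFrame,
                       classes: tuple = ("pericyte", "CAM", "PEM")) -> pd.DataFrame:
    """Fraction of each cell class per branch order, plus the fraction at
    junctions (mirrors the vascular-tree position figures)."""
    located = located[~located.unmapped]
    rows = []
    for cls in classes:
        if cls == "pericyte":
            sub = located[located.cell_type == PERICYTE]
        elif cls == "CAM":
            sub = located[(located.cell_type == MICROGLIA) &
                          located.get("is_cam", False)]
        elif cls == "PEM":
            sub = located[(located.cell_type == MICROGLIA) &
                          located.get("is_pem", False)]
        else:
            raise ValueError(f"unknown class {cls!r}")
        n = len(sub)
        for order, cnt in sub.branch_order.value_counts().sort_index().items():
            rows.append(dict(cell_class=cls, branch_order=int(order),
                             count=int(cnt),
                             fraction=cnt / n if n else np.nan))
        rows.append(dict(cell_class=cls, branch_order=-1,
                         count=int(sub.at_junction.sum()),
                         fraction=float(sub.at_junction.mean()) if n else np.nan))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# width measurement


def _arclength_ok(seg, s, rules: WidthRules, extra: float = 0.0) -> bool:
    lo = rules.branch_exclusion + extra
    return lo <= s <= seg.length - lo


def measure_width_at(network: VesselNetwork, segment_id: int, s: float,
                     location_type: str, rules: WidthRules | None = None,
                     day: int | None = None, cell_ids: tuple = ()) -> dict | None:
    """Width at one landmark; None (with a log entry) if the site violates
    the eligibility rules (host diameter, branchpoint exclusion)."""
    rules = rules or WidthRules()
    seg = network.segment(segment_id)
    extra = rules.side_offset if (
        rules.mode == "fixed" and location_type in ("P", "PEM", "gain", "loss")
    ) else 0.0
    if not _arclength_ok(seg, s, rules, extra):
        logger.info("width at %s on segment %d skipped: inside branchpoint "
                    "exclusion zone", location_type, segment_id)
        return None
    if seg.diameter_at(s) >= rules.d_vessel_max:
        logger.info("width at %s on segment %d skipped: host diameter >= "
                    "%g μm", location_type, segment_id, rules.d_vessel_max)
        return None
    if rules.mode == "fixed" and location_type in ("P", "PEM", "gain", "loss"):
        width = 0.5 * (seg.diameter_at(s - rules.side_offset) +
                       seg.diameter_at(s + rules.side_offset))
    else:
        width = seg.diameter_at(s)
    return dict(location_type=location_type, segment_id=segment_id,
                arclength_um=float(s), width_um=float(width), day=day,
                cell_ids=",".join(str(c) for c in cell_ids))


def measure_scene_widths(labeled_cells: pd.DataFrame, network: VesselNetwork,
                         rules: WidthRules | None = None,
                         scene_id=0, vo_step: float = 1.0) -> pd.DataFrame:
    """All VO / P / CAM / PEM width measurements for one labeled scene.

    P sites are pericytes without a PEM; PEM sites are pericytes with one.
    CAM sites are capillary-associated microglia farther than the
    CAM-pericyte exclusion distance (10 μm) from every pericyte.  VO sites
    are, per capillary segment, the centerline point maximizing clearance
    from every soma, provided that clearance exceeds ``vo_clearance``.
    """
    rules = rules or WidthRules()
    criteria = AssociationCriteria(d_vessel_max=rules.d_vessel_max,
                                   use_nucleus_center=(rules.mode == "fixed"))
    rows = []
    peri = labeled_cells[labeled_cells.cell_type == PERICYTE]
    micro = labeled_cells[labeled_cells.cell_type == MICROGLIA]
    peri_xyz = reference_coords(peri, criteria) if len(peri) else None

    # pericyte sites (P / PEM)
    for _, p in peri.iterrows():
        if "segment_id" in p and p.segment_id >= 0 and \
                np.isfinite(p.arclength_um):
            seg_id, s = int(p.segment_id), float(p.arclength_um)
        else:
            snap = network.nearest_points(
                reference_coords(p.to_frame().T, criteria))
            seg_id, s = int(snap["segment_id"][0]), float(snap["arclength"][0])
        loc = "PEM" if bool(p.get("has_pem", False)) else "P"
        m = measure_width_at(network, seg_id, s, loc, rules,
                             cell_ids=(int(p.cell_id),))
        if m:
            rows.append(m)

    # CAM sites: lone CAM only
    cam = micro[micro.is_cam.astype(bool)] if "is_cam" in micro \
        else micro.iloc[0:0]
    for _, c in cam.iterrows():
        pos = reference_coords(c.to_frame().T, criteria)[0]
        if peri_xyz is not None and len(peri_xyz) and np.min(
                np.linalg.norm(peri_xyz - pos, axis=1)
        ) <= rules.cam_pericyte_exclusion:
            continue  # too close to a pericyte: would contaminate with PEM
        snap = network.nearest_points(pos[None, :],
                                      max_diameter=rules.d_vessel_max)
        if not np.isfinite(snap["distance"][0]):
            continue
        m = measure_width_at(network, int(snap["segment_id"][0]),
                             float(snap["arclength"][0]), "CAM", rules,
                             cell_ids=(int(c.cell_id),))
        if m:
            rows.append(m)

    # VO sites: one per capillary segment, maximal soma clearance
    all_xyz = reference_coords(labeled_cells, criteria) \
        if len(labeled_cells) else np.empty((0, 2))
    for seg in network.capillary_segments():
        lo, hi = rules.branch_exclusion, seg.length - rules.branch_exclusion
        if hi - lo < vo_step:
            continue
        ss = np.arange(lo, hi, vo_step)
        pts = np.array([seg.point_at(s) for s in ss])[:, :all_xyz.shape[1]] \
            if len(all_xyz) else np.array([seg.point_at(s) for s in ss])
        if len(all_xyz):
            d = np.linalg.norm(pts[:, None, :] - all_xyz[None, :, :], axis=2)
            clearance = d.min(axis=1)
        else:
            clearance = np.full(len(ss), np.inf)
        best = int(np.argmax(clearance))
        if clearance[best] <= rules.vo_clearance:
            logger.info("no valid VO point on segment %d", seg.segment_id)
            continue
        m = measure_width_at(network, seg.segment_id, float(ss[best]),
                             "VO", rules)
        if m:
            rows.append(m)

    df = pd.DataFrame(rows, columns=["location_type", "segment_id",
                                     "arclength_um", "width_um", "day",
                                     "cell_ids"])
    df.insert(0, "scene_id", scene_id)
    return df


def width_contrast_table(measurements: pd.DataFrame,
                         min_per_group: int | None = None) -> dict:
    """Per-scene mean width by location type, percent differences vs VO,
    and the omnibus matched-samples comparison (Friedman test).

    Scenes contribute a location type only when they carry at least
    ``min_per_group`` measurements of it (default 4).
    """
    if min_per_group is None:
        min_per_group = WidthRules.min_per_group
    rows = []
    for scene_id, grp in measurements.groupby("scene_id"):
        row = {"scene_id": scene_id}
        for loc in ("VO", "P", "CAM", "PEM"):
            sub = grp[grp.location_type == loc]
            if len(sub) >= min_per_group:
                row[loc] = float(sub.width_um.mean())
            else:
                row[loc] = np.nan
                if len(sub):
                    logger.info("scene %s: %s group below threshold "
                                "(%d < %d), excluded", scene_id, loc,
                                len(sub), min_per_group)
        rows.append(row)
    table = pd.DataFrame(rows)
    for loc in ("P", "CAM", "PEM"):
        table[f"pct_diff_{loc}_vs_VO"] = 100.0 * (table[loc] - table["VO"]) \
            / table["VO"]

    complete = table.dropna(subset=["VO", "P", "CAM", "PEM"])
    friedman = None
    if len(complete) >= 3:
        st = stats.friedmanchisquare(complete["VO"], complete["P"],
                                     complete["CAM"], complete["PEM"])
        friedman = {"statistic": float(st.statistic),
                    "p_value": float(st.pvalue)}
    mean_diff = {}
    for loc in ("P", "CAM", "PEM"):
        vals = table[f"pct_diff_{loc}_vs_VO"].to_numpy(dtype=float)
        mean_diff[loc] = float(np.nanmean(vals)) \
            if np.isfinite(vals).any() else float("nan")
    return {"table": table, "friedman": friedman,
            "mean_pct_diff": mean_diff}


def width_change_on_gain_loss(series: TimeSeriesScene,
                              rules: WidthRules | None = None,
                              min_per_group: int = 2) -> dict:
    """Paired before/after widths at pericytes that gained or lost a PEM.

    For each logged event the width at the pericyte is measured on the
    imaging day preceding the event and on the event day, using the
    per-day network state.  Returns the event table, mean percent change
    per event type, and the paired t-test per type (scipy.stats.ttest_rel)
    where at least ``min_per_group`` pairs exist.
    """
    rules = rules or WidthRules(mode="invivo")
    day0 = series.cells_by_day[series.days[0]]
    peri = day0[day0.cell_type == PERICYTE]
    loc = {int(p.cell_id): (int(p.segment_id), float(p.arclength_um))
           for _, p in peri.iterrows()}

    rows = []
    for _, ev in series.events.iterrows():
        pid = int(ev.pericyte_id)
        if pid not in loc:
            continue
        seg_id, s = loc[pid]
        day_idx = series.days.index(int(ev.day))
        day_before = series.days[day_idx - 1]
        before = measure_width_at(series.networks_by_day[day_before],
                                  seg_id, s, ev.event, rules, day=day_before,
                                  cell_ids=(pid,))
        after = measure_width_at(series.networks_by_day[int(ev.day)],
                                 seg_id, s, ev.event, rules,
                                 day=int(ev.day), cell_ids=(pid,))
        if before is None or after is None:
            logger.info("event at pericyte %d dropped: width unmeasurable",
                        pid)
            continue
        rows.append(dict(pericyte_id=pid, event=ev.event,
                         day_before=day_before, day_after=int(ev.day),
                         width_before_um=before["width_um"],
                         width_after_um=after["width_um"],
                         pct_change=100.0 * (after["width_um"] -
                                             before["width_um"])
                         / before["width_um"]))
    events = pd.DataFrame(rows, columns=["pericyte_id", "event",
                                         "day_before", "day_after",
                                         "width_before_um", "width_after_um",
                                         "pct_change"])
    summary = {}
    for kind in ("gain", "loss"):
        sub = events[events.event == kind]
        entry = {"n_events": len(sub),
                 "mean_pct_change": float(sub["pct_change"].mean())
                 if len(sub) else None}
        if len(sub) >= min_per_group:
            t = stats.ttest_rel(sub.width_after_um, sub.width_before_um)
            entry["paired_t_p"] = float(t.pvalue)
        summary[kind] = entry
    return {"events": events, "summary": summary}
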