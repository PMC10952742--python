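"""Vessel centerline networks.

A :class:`VesselNetwork` is a graph of junction/terminal nodes joined by
polyline segments carrying a per-vertex diameter (all coordinates in μm).
The default topology produced by the synthetic generator is a tree rooted
at a penetrating arteriole (branch order 0) and terminating on an
ascending venule (order 8), with capillaries at orders 1-7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

ARTERIOLE = "arteriole"
CAPILLARY = "capillary"
VENULE = "venule"

#: SWC structure-type codes used for export (custom codes ≥5 are legal SWC).
_SWC_TYPE = {ARTERIOLE: 5, CAPILLARY: 6, VENULE: 7}
_SWC_TYPE_INV = {v: k for k, v in _SWC_TYPE.items()}


class NetworkValidationError(ValueError):
    """Topology or geometry of a network violates its invariants."""


@dataclass
class Segment:
    """Polyline between two nodes with per-vertex diameter.

    ``points`` is an (N, 3) array of vertex coordinates; ``diameters`` an
    (N,) array of local vessel diameters, both in μm.
    """

    segment_id: int
    start_node: int
    end_node: int
    points: np.ndarray
    diameters: np.ndarray
    order: int | None = None
    vessel_class: str = CAPILLARY

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise NetworkValidationError(
                f"segment {self.segment_id}: points must be (N, 3)"
            )
        if len(self.diameters) != len(self.points):
            raise NetworkValidationError(
                f"segment {self.segment_id}: diameters/points length mismatch"
            )
        if np.any(self.diameters <= 0):
            raise NetworkValidationError(
                f"segment {self.segment_id}: diameters must be positive"
            )

    @property
    def arclengths(self) -> np.ndarray:
        """Cumulative arclength at each vertex, starting at 0."""
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def length(self) -> float:
        return float(self.arclengths[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Interpolated coordinate at arclength ``s``."""
        cs = self.arclengths
        s = float(np.clip(s, 0.0, cs[-1]))
        out = np.empty(3)
        for k in range(3):
            out[k] = np.interp(s, cs, self.points[:, k])
        return out

    def diameter_at(self, s: float) -> float:
        """Linearly interpolated diameter at arclength ``s``."""
        cs = self.arclengths
        return float(np.interp(np.clip(s, 0.0, cs[-1]), cs, self.diameters))

    def scale_diameters(self, s_center: float, factor: float,
                        half_width: float) -> None:
        """Multiply diameters by ``factor`` within ``±half_width`` μm of
        arclength ``s_center`` (a flat local dilation/constriction)."""
        mask = np.abs(self.arclengths - s_center) <= half_width
        self.diameters = self.diameters.copy()
        self.diameters[mask] *= factor


@dataclass
class VesselNetwork:
    """Junction nodes plus polyline segments; the shared vascular container."""

    nodes: dict[int, np.ndarray] = field(default_factory=dict)
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nodes = {int(k): np.asarray(v, dtype=float) for k, v in self.nodes.items()}
        self._cache: dict | None = None

    # -- basic accessors -------------------------------------------------

    def segment(self, segment_id: int) -> Segment:
        for seg in self.segments:
            if seg.segment_id == segment_id:
                return seg
        raise KeyError(f"no segment {segment_id}")

    def graph(self) -> nx.Graph:
        """The node/segment adjacency as a networkx graph."""
        g = nx.Graph()
        for nid, xyz in self.nodes.items():
            g.add_node(nid, xyz=xyz)
        for seg in self.segments:
            g.add_edge(seg.start_node, seg.end_node, segment_id=seg.segment_id)
        return g

    def total_length(self, vessel_class: str | None = None) -> float:
        return float(sum(s.length for s in self.segments
                         if vessel_class is None or s.vessel_class == vessel_class))

    def capillary_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.vessel_class == CAPILLARY]

    def invalidate_cache(self) -> None:
        self._cache = None

    def copy(self) -> "VesselNetwork":
        return VesselNetwork(
            nodes={k: v.copy() for k, v in self.nodes.items()},
            segments=[Segment(s.segment_id, s.start_node, s.end_node,
                              s.points.copy(), s.diameters.copy(),
                              s.order, s.vessel_class)
                      for s in self.segments],
        )

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Check the container invariants; raise NetworkValidationError."""
        if not self.segments:
            raise NetworkValidationError("network has no segments")
        for seg in self.segments:
            for node, endpoint in ((seg.start_node, seg.points[0]),
                                   (seg.end_node, seg.points[-1])):
                if node not in self.nodes:
                    raise NetworkValidationError(
                        f"segment {seg.segment_id} references unknown node {node}")
                if not np.allclose(self.nodes[node], endpoint, atol=1e-6):
                    raise NetworkValidationError(
                        f"segment {seg.segment_id} endpoint does not coincide "
                        f"with node {node}")
        g = self.graph()
        if g.number_of_nodes() and not nx.is_connected(g):
            raise NetworkValidationError("network graph is not connected")

    # -- geometry queries ------------------------------------------------

    def _pieces(self) -> dict:
        """Flattened straight pieces of every polyline, cached for queries."""
        if self._cache is None:
            p0, p1, d0, d1, sid, s0 = [], [], [], [], [], []
            for seg in self.segments:
                cs = seg.arclengths
                p0.append(seg.points[:-1])
                p1.append(seg.points[1:])
                d0.append(seg.diameters[:-1])
                d1.append(seg.diameters[1:])
                sid.append(np.full(len(seg.points) - 1, seg.segment_id))
                s0.append(cs[:-1])
            self._cache = {
                "p0": np.concatenate(p0), "p1": np.concatenate(p1),
                "d0": np.concatenate(d0), "d1": np.concatenate(d1),
                "sid": np.concatenate(sid), "s0": np.concatenate(s0),
            }
        return self._cache

    def nearest_points(self, query: np.ndarray,
                       max_diameter: float | None = None) -> dict:
        """Project query points onto the centerline.

        Parameters
        ----------
        query : (K, 2) or (K, 3) array of coordinates in μm.  2-D queries
            are evaluated against the x/y coordinates of the centerline
            (appropriate for projected scenes where z has been dropped).
        max_diameter : if given, only centerline locations with local
            (interpolated) diameter strictly below this value are eligible;
            query points with no eligible location get distance = inf.

        Returns a dict of arrays: ``distance``, ``segment_id``,
        ``arclength``, ``diameter`` (local diameter at the foot point).
        """
        query = np.atleast_2d(np.asarray(query, dtype=float))
        k = query.shape[1]
        cache = self._pieces()
        a = cache["p0"][:, :k]
        b = cache["p1"][:, :k]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        denom[denom == 0] = 1.0

        n = len(query)
        out = {
            "distance": np.full(n, np.inf),
            "segment_id": np.full(n, -1, dtype=int),
            "arclength": np.full(n, np.nan),
            "diameter": np.full(n, np.nan),
        }
        piece_len = np.linalg.norm(cache["p1"] - cache["p0"], axis=1)
        # chunk over query points to bound memory
        for lo in range(0, n, 256):
            q = query[lo:lo + 256]
            t = np.einsum("kij,ij->ki", q[:, None, :] - a, ab) / denom
            t = np.clip(t, 0.0, 1.0)
            foot = a[None, :, :] + t[:, :, None] * ab[None, :, :]
            dist = np.linalg.norm(q[:, None, :] - foot, axis=2)
            diam = cache["d0"][None, :] + t * (cache["d1"] - cache["d0"])[None, :]
            if max_diameter is not None:
                dist = np.where(diam < max_diameter, dist, np.inf)
            best = np.argmin(dist, axis=1)
            rows = np.arange(len(q))
            sl = slice(lo, lo + len(q))
            out["distance"][sl] = dist[rows, best]
            out["segment_id"][sl] = cache["sid"][best]
            out["arclength"][sl] = cache["s0"][best] + t[rows, best] * piece_len[best]
            out["diameter"][sl] = diam[rows, best]
        finite = np.isfinite(out["distance"])
        out["segment_id"][~finite] = -1
        out["arclength"][~finite] = np.nan
        out["diameter"][~finite] = np.nan
        return out

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [{"node_id": nid, "xyz": list(map(float, xyz))}
                      for nid, xyz in sorted(self.nodes.items())],
            "segments": [
                {
                    "segment_id": s.segment_id,
                    "start_node": s.start_node,
                    "end_node": s.end_node,
                    "points": [[float(x), float(y), float(z), float(d)]
                               for (x, y, z), d in zip(s.points, s.diameters)],
                    "order": None if s.order is None else int(s.order),
                    "vessel_class": s.vessel_class,
                }
                for s in sorted(self.segments, key=lambda s: s.segment_id)
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "VesselNetwork":
        nodes = {int(n["node_id"]): np.asarray(n["xyz"], dtype=float)
                 for n in payload["nodes"]}
        segments = []
        for s in payload["segments"]:
            pts = np.asarray(s["points"], dtype=float)
            segments.append(Segment(
                segment_id=int(s["segment_id"]),
                start_node=int(s["start_node"]),
                end_node=int(s["end_node"]),
                points=pts[:, :3],
                diameters=pts[:, 3],
                order=None if s.get("order") is None else int(s["order"]),
                vessel_class=s.get("vessel_class", CAPILLARY),
            ))
        net = cls(nodes=nodes, segments=segments)
        net.validate()
        return net

    def to_swc(self) -> str:
        """SWC export: every polyline vertex becomes a sample; diameter is
        stored as radius (d/2) and vessel class in the type field
        (5 arteriole, 6 capillary, 7 venule).

        Each segment emits its own start vertex even at shared junctions
        (a duplicate-coordinate sample parented to the junction sample), so
        per-segment endpoint diameters survive a round trip.
        """
        lines = ["# pemscope vessel network export",
                 "# type codes: 5=arteriole 6=capillary 7=venule",
                 "# n type x y z radius parent"]
        sample = 0
        node_sample: dict[int, int] = {}
        for seg in sorted(self.segments, key=lambda s: s.segment_id):
            t = _SWC_TYPE[seg.vessel_class]
            prev = node_sample.get(seg.start_node, -1)
            for i in range(len(seg.points)):
                sample += 1
                x, y, z = seg.points[i]
                lines.append(f"{sample} {t} {x:.6f} {y:.6f} {z:.6f} "
                             f"{seg.diameters[i] / 2:.6f} {prev}")
                if i == 0 and prev == -1:
                    node_sample.setdefault(seg.start_node, sample)
                prev = sample
            node_sample[seg.end_node] = prev
        return "\n".join(lines) + "\n"
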