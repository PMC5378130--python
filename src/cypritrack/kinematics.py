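"""Point reduction and dwell-node extraction.

For classification, each tracked ellipse is reduced to three points: the
centre CE and the two terminal points TP1/TP2 at the ends of the major axis.
Because an ellipse's orientation is only defined modulo 180 degrees, the
terminal-point labels are made temporally consistent by choosing, each frame,
the labelling closest to the previous frame's points; this also yields a body
direction that is continuous modulo 360 degrees.

Nodes are temporal clusters of path points: a streaming pass keeps a running
cluster whose centre is the mean of its members; a point within ``dis_th`` of
the centre joins, a point beyond it finalises the cluster if it has more than
``Mn_th`` members (else the cluster is discarded) and restarts from the
current point. Members are therefore always temporally consecutive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import EllipseState

__all__ = ["PointTriplet", "Node", "terminal_points", "resolve_tp_identity",
           "extract_nodes", "triplet_series", "nodes_to_table"]


@dataclass(frozen=True)
class PointTriplet:
    """Centre + terminal points of one animal in one frame.

    ``theta_deg`` is the continuity-resolved body direction (the direction
    from CE to TP1), continuous modulo 360.
    """

    frame: int
    ce: tuple[float, float]
    tp1: tuple[float, float]
    tp2: tuple[float, float]
    theta_deg: float


@dataclass(frozen=True)
class Node:
    """A temporal cluster of trajectory points."""

    centre: tuple[float, float]
    members: tuple[int, ...]  # frame indices, strictly increasing, consecutive
    source: str = "centre"    # centre | TP1 | TP2

    @property
    def mn(self) -> int:
        return len(self.members)

    @property
    def first_frame(self) -> int:
        return self.members[0]

    @property
    def last_frame(self) -> int:
        return self.members[-1]


def terminal_points(ellipse: EllipseState) -> PointTriplet:
    """Place TP1/TP2 at the ends of the major axis.

    TP1 = CE + a*(cos theta, sin theta), TP2 = CE - a*(cos theta, sin theta).
    """
    t = math.radians(ellipse.theta_deg)
    ux, uy = math.cos(t), math.sin(t)
    xc, yc, a = ellipse.xc, ellipse.yc, ellipse.a
    return PointTriplet(frame=ellipse.frame, ce=(xc, yc),
                        tp1=(xc + a * ux, yc + a * uy),
                        tp2=(xc - a * ux, yc - a * uy),
                        theta_deg=ellipse.theta_deg % 360.0)


def _dist(p: tuple[float, float], q: tuple[float, float]) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def resolve_tp_identity(current: PointTriplet, previous: PointTriplet) -> PointTriplet:
    """Keep the terminal-point labelling consistent with the previous frame.

    Of the two possible labellings of the current frame's axis ends, keep the
    one minimising |TP1_t - TP1_{t-1}| + |TP2_t - TP2_{t-1}|; on a swap the
    body direction advances by 180 degrees. The returned direction is chosen
    within +-90 degrees of the previous one, so it is continuous mod 360.
    """
    keep = _dist(current.tp1, previous.tp1) + _dist(current.tp2, previous.tp2)
    swap = _dist(current.tp1, previous.tp2) + _dist(current.tp2, previous.tp1)
    if swap < keep:
        current = PointTriplet(frame=current.frame, ce=current.ce,
                               tp1=current.tp2, tp2=current.tp1,
                               theta_deg=(current.theta_deg + 180.0) % 360.0)
    # unwrap onto the previous direction (axis is mod 180; labelling fixes 360)
    d = current.theta_deg - previous.theta_deg
    d -= 360.0 * round(d / 360.0)
    return PointTriplet(frame=current.frame, ce=current.ce, tp1=current.tp1,
                        tp2=current.tp2, theta_deg=previous.theta_deg + d)


def triplet_series(track: pd.DataFrame) -> list[PointTriplet]:
    """Build the continuity-resolved triplet series for one animal's track.

    ``track`` is the tracker's per-animal table (frame, xc, yc, a, b,
    theta_deg, ...), sorted by frame. The first frame's labelling is
    arbitrary.
    """
    triplets: list[PointTriplet] = []
    prev: PointTriplet | None = None
    for row in track.itertuples(index=False):
        tp = terminal_points(EllipseState(
            cyprid_id=int(getattr(row, "cyprid_id", 0)), frame=int(row.frame),
            xc=float(row.xc), yc=float(row.yc), a=float(row.a), b=float(row.b),
            theta_deg=float(row.theta_deg), size=int(getattr(row, "size", 0))))
        if prev is not None:
            tp = resolve_tp_identity(tp, prev)
        triplets.append(tp)
        prev = tp
    return triplets


def extract_nodes(
    points,
    dis_th: float,
    mn_th: int,
    frames=None,
    source: str = "centre",
    strict: bool = True,
) -> list[Node]:
    """Streaming node extraction over a time-ordered path.

    ``points`` is an (n, 2) array-like of (x, y); ``frames`` optionally maps
    path positions to frame indices (defaults to 0..n-1). A trailing cluster
    at the end of the path is finalised under the same member-count test.
    With ``strict`` (default) a cluster becomes a node when Mn > mn_th;
    otherwise Mn >= mn_th.
    """
    if dis_th <= 0:
        raise ValueError("dis_th must be > 0")
    if mn_th < 1:
        raise ValueError("mn_th must be >= 1")
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        return []
    idx = np.arange(n) if frames is None else np.asarray(frames)

    def enough(count: int) -> bool:
        return count > mn_th if strict else count >= mn_th

    nodes: list[Node] = []
    cn = pts[0].copy()
    members = [0]
    for i in range(1, n):
        dis = math.hypot(pts[i, 0] - cn[0], pts[i, 1] - cn[1])
        if dis < dis_th:
            members.append(i)
            cn = pts[members].mean(axis=0)
        else:
            if enough(len(members)):
                nodes.append(Node(centre=(float(cn[0]), float(cn[1])),
                                  members=tuple(int(idx[m]) for m in members),
                                  source=source))
            cn = pts[i].copy()
            members = [i]
    if enough(len(members)):
        nodes.append(Node(centre=(float(cn[0]), float(cn[1])),
                          members=tuple(int(idx[m]) for m in members),
                          source=source))
    return nodes


def nodes_to_table(nodes_by_id: dict[int, dict[str, list[Node]]]) -> pd.DataFrame:
    """Flatten {cyprid_id: {source: nodes}} into the node CSV layout."""
    rows = []
    for cid, by_source in nodes_by_id.items():
        for source, nodes in by_source.items():
            for k, node in enumerate(nodes):
                rows.append((cid, source, k, node.centre[0], node.centre[1],
                             node.first_frame, node.last_frame, node.mn))
    return pd.DataFrame(rows, columns=["cyprid_id", "source", "node_index",
                                       "x", "y", "first_frame", "last_frame", "Mn"])
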