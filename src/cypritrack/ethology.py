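"""Rule-based classification of cyprid movement into four behaviours.

Walking cyprids pause between steps, so their paths condense into dwell
nodes. The classifier works on those nodes:

* **Wide search** — near-regular stepping. Over every window of four
  consecutive centre-node step lengths SL, walking requires St/m < 0.2
  (standard deviation over mean) and MC < 0.3, where MC is the maximum
  relative difference between a step length and 0.85 of the cyprid length CL.
  A passing window marks its five spanned nodes.
* **Inspection** — the animal stays attached at one terminal point and sweeps
  its body about it. A terminal-point node is an inspection node when the
  body direction over its member span covers more than 30 degrees (minimal
  circular arc containing the samples).
* **Close search** — tortuous stepping: a series of short inspection nodes.
  Consecutive inspection nodes closer than four steps (4 x 0.85 CL) whose
  member counts stay below a dwell cap chain into close search; chained nodes
  lose their inspection flag so the two labels never overlap.
* **Swimming** — everything not captured above.

Per-frame labels tile each track: frame spans of flagged nodes (extended over
stepped intervals for wide search and over whole chains for close search) are
painted with precedence close search > inspection > wide search, and
unlabelled frames are swimming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .kinematics import Node, extract_nodes, triplet_series

__all__ = [
    "BehaviourEvent",
    "walking_windows",
    "classify_wide_search",
    "classify_inspection",
    "classify_close_search",
    "assemble_ethogram",
    "summarize",
    "classify_track",
    "classify_tracks",
]

BEHAVIOURS = ("swimming", "wide_search", "close_search", "inspection")


@dataclass(frozen=True)
class BehaviourEvent:
    cyprid_id: int
    behaviour: str
    start_frame: int
    end_frame: int
    duration_s: float
    step_count: int | None = None  # wide search only


# ---------------------------------------------------------------------------
# Wide search


def walking_windows(
    centre_nodes: list[Node],
    cl: float,
    step_factor: float = 0.85,
    ratio_threshold: float = 0.2,
    mc_threshold: float = 0.3,
    max_step_frames: int | None = None,
) -> list[tuple[int, int]]:
    """Passing four-step windows, as (first node index, last node index).

    SL_i is the distance between consecutive node centres; CH_i the relative
    difference between SL_i and step_factor*CL. A window of four consecutive
    steps passes when St/m (standard deviation over mean of the four SL) is
    below ``ratio_threshold`` and the maximum |CH| is below ``mc_threshold``;
    it spans the five nodes i..i+4.

    A walking step is a brief relocation between pauses: when
    ``max_step_frames`` is given, an inter-node interval during which the
    animal travelled for longer than that many frames is not a step, however
    step-like its length, and no window may contain it. This keeps a long
    swimming excursion that happens to return near its origin, or a slow
    pivot, from counting as a step.
    """
    if cl <= 0:
        raise ValueError("cyprid length CL must be > 0")
    if len(centre_nodes) < 5:
        return []
    centres = np.array([nd.centre for nd in centre_nodes])
    sl = np.hypot(*(np.diff(centres, axis=0).T))
    expected = step_factor * cl
    ch = (sl - expected) / expected
    valid = np.ones(len(sl), dtype=bool)
    if max_step_frames is not None:
        gaps = np.array([centre_nodes[i + 1].first_frame - centre_nodes[i].last_frame
                         for i in range(len(sl))])
        valid = gaps <= max_step_frames
    windows = []
    for i in range(len(sl) - 3):
        if not valid[i:i + 4].all():
            continue
        window = sl[i:i + 4]
        m = window.mean()
        if m <= 0:
            continue
        if window.std() / m < ratio_threshold and np.abs(ch[i:i + 4]).max() < mc_threshold:
            windows.append((i, i + 4))
    return windows


def classify_wide_search(
    centre_nodes: list[Node],
    cl: float,
    step_factor: float = 0.85,
    ratio_threshold: float = 0.2,
    mc_threshold: float = 0.3,
) -> np.ndarray:
    """Per-centre-node walking weights W in {0, 1} (see walking_windows)."""
    w = np.zeros(len(centre_nodes), dtype=int)
    for i, j in walking_windows(centre_nodes, cl, step_factor,
                                ratio_threshold, mc_threshold):
        w[i:j + 1] = 1
    return w


# ---------------------------------------------------------------------------
# Inspection


def circular_range_deg(angles_deg) -> float:
    """Span of the minimal circular arc (mod 360) containing all samples."""
    a = np.asarray(angles_deg, dtype=np.float64) % 360.0
    if a.size <= 1:
        return 0.0
    a = np.sort(a)
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    return float(360.0 - gaps.max())


def classify_inspection(
    terminal_nodes: list[Node],
    theta_by_frame: pd.Series,
    angle_threshold_deg: float = 30.0,
) -> np.ndarray:
    """Per-terminal-node inspection weights IW in {0, 1}.

    A node is inspection when the body direction over its member span [S, E]
    sweeps strictly more than the threshold (circular minimal-arc range).
    """
    iw = np.zeros(len(terminal_nodes), dtype=int)
    for k, node in enumerate(terminal_nodes):
        s, e = node.first_frame, node.last_frame
        angles = theta_by_frame.loc[s:e].to_numpy()
        if circular_range_deg(angles) > angle_threshold_deg:
            iw[k] = 1
    return iw


# ---------------------------------------------------------------------------
# Close search


def classify_close_search(
    iw: np.ndarray,
    terminal_nodes: list[Node],
    cl: float,
    member_cap: int,
    step_factor: float = 0.85,
    chain_steps: float = 4.0,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Chain short inspection nodes into close search.

    ``terminal_nodes`` should hold the animal's inspection-classifiable
    nodes in time order -- pooled from both terminal-point paths, since the
    pinned end of successive pivots can fall on either path. Eligible nodes
    have IW = 1 and fewer than ``member_cap`` members (long dwells are
    genuine inspection and are skipped). Consecutive eligible nodes whose
    centres lie closer than ``chain_steps * step_factor * cl`` chain
    together; chains of at least two nodes become close search and their
    inspection weights are reset to 0.

    Returns (CSW, modified IW, chains) where each chain is a (first, last)
    pair of indices into ``terminal_nodes``.
    """
    iw = np.asarray(iw, dtype=int)
    csw = np.zeros_like(iw)
    eligible = [k for k in range(len(terminal_nodes))
                if iw[k] == 1 and terminal_nodes[k].mn < member_cap]
    gate = chain_steps * step_factor * cl
    chains: list[tuple[int, int]] = []
    run: list[int] = []

    def close_run() -> None:
        if len(run) >= 2:
            chains.append((run[0], run[-1]))
            for k in run:
                csw[k] = 1
                iw[k] = 0

    for k in eligible:
        if run and _node_dist(terminal_nodes[run[-1]], terminal_nodes[k]) < gate:
            run.append(k)
        else:
            close_run()
            run = [k]
    close_run()
    return csw, iw, chains


def _node_dist(n1: Node, n2: Node) -> float:
    return math.hypot(n1.centre[0] - n2.centre[0], n1.centre[1] - n2.centre[1])


# ---------------------------------------------------------------------------
# Ethogram assembly


def assemble_ethogram(
    cyprid_id: int,
    frames: np.ndarray,
    frame_rate: float,
    centre_nodes: list[Node],
    windows: list[tuple[int, int]],
    terminal_nodes: list[Node],
    iw: np.ndarray,
    chains: list[tuple[int, int]],
) -> tuple[list[BehaviourEvent], pd.Series]:
    """Map node-level weights to per-frame labels and merge into events.

    Each passing walking window paints wide search from the first member of
    its first node to the last member of its last node (overlapping windows
    merge; a window never bridges the time gap between two separate walking
    bouts). Inspection nodes (``iw`` after overlap removal) paint their
    member spans; close-search chains paint from their first node's first
    member to their last node's last member. Precedence inside a frame:
    close search > inspection > wide search; everything else is swimming.
    """
    frames = np.asarray(frames)
    labels = pd.Series("swimming", index=frames, dtype=object)

    for i, j in windows:
        labels.loc[centre_nodes[i].first_frame:centre_nodes[j].last_frame] = "wide_search"
    for k, node in enumerate(terminal_nodes):
        if iw[k] == 1:
            labels.loc[node.first_frame:node.last_frame] = "inspection"
    for first, last in chains:
        labels.loc[terminal_nodes[first].first_frame:
                   terminal_nodes[last].last_frame] = "close_search"

    events: list[BehaviourEvent] = []
    vals = labels.to_numpy()
    idx = labels.index.to_numpy()
    start = 0
    for i in range(1, len(vals) + 1):
        if i == len(vals) or vals[i] != vals[start]:
            s_f, e_f = int(idx[start]), int(idx[i - 1])
            behaviour = vals[start]
            step_count = None
            if behaviour == "wide_search":
                inside = [nd for nd in centre_nodes
                          if s_f <= nd.first_frame and nd.last_frame <= e_f]
                step_count = max(len(inside) - 1, 0)
            events.append(BehaviourEvent(
                cyprid_id=cyprid_id, behaviour=str(behaviour),
                start_frame=s_f, end_frame=e_f,
                duration_s=(e_f - s_f + 1) / frame_rate,
                step_count=step_count))
            start = i
    return events, labels


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (first, last) index pairs."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask) - 1))
    return out


# ---------------------------------------------------------------------------
# Summary


def summarize(events: list[BehaviourEvent] | pd.DataFrame,
              condition: str | None = None) -> pd.DataFrame:
    """Per-behaviour event counts, totals and truncated averages.

    Totals are seconds for close search, inspection and swimming, and steps
    for wide search. The average is total/count truncated toward zero
    (integer), matching how the published per-event averages round.
    Behaviours with no events report absent totals/averages (NaN, rendered
    as an em dash in the CSV).
    """
    if isinstance(events, pd.DataFrame):
        df = events
    else:
        df = events_to_table(events)
    rows = []
    for behaviour in BEHAVIOURS:
        sub = df[df["behaviour"] == behaviour]
        count = len(sub)
        if count == 0:
            rows.append((condition, behaviour, 0, np.nan, np.nan, ""))
            continue
        if behaviour == "wide_search":
            total = float(sub["step_count"].fillna(0).sum())
            unit = "step"
        else:
            total = float(sub["duration_s"].sum())
            unit = "s"
        avg = math.trunc(total / count)
        rows.append((condition, behaviour, count, total, avg, unit))
    out = pd.DataFrame(rows, columns=["condition", "behaviour", "event_number",
                                      "total", "average", "unit"])
    if condition is None:
        out = out.drop(columns=["condition"])
    return out


def events_to_table(events: list[BehaviourEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.cyprid_id, e.behaviour, e.start_frame, e.end_frame, e.duration_s,
          e.step_count) for e in events],
        columns=["cyprid_id", "behaviour", "start_frame", "end_frame",
                 "duration_s", "step_count"])


# ---------------------------------------------------------------------------
# Per-track orchestration


def classify_track(track: pd.DataFrame, config: RunConfig | None = None
                   ) -> tuple[list[BehaviourEvent], pd.Series]:
    """Full classification of one animal's track table.

    Builds the three point paths, extracts nodes from each, applies the four
    behaviour rules and returns (events, per-frame labels).
    """
    config = config or RunConfig()
    track = track.sort_values("frame")
    cid = int(track["cyprid_id"].iloc[0]) if "cyprid_id" in track else 0
    frames = track["frame"].to_numpy(dtype=int)
    triplets = triplet_series(track)

    cl = 2.0 * float(np.median(track["a"].to_numpy()))
    theta = pd.Series([t.theta_deg for t in triplets], index=frames)

    centre_path = np.array([t.ce for t in triplets])
    centre_nodes = extract_nodes(centre_path, config.dis_th, config.mn_th,
                                 frames=frames, source="centre",
                                 strict=config.strict_mn)
    windows = walking_windows(
        centre_nodes, cl, config.step_factor, config.ratio_threshold,
        config.mc_threshold,
        max_step_frames=int(round(config.max_step_duration_s * config.frame_rate)))

    # terminal nodes of both paths, pooled in time order: successive pivots
    # can pin either physical end, so the inspection-node sequence of one
    # animal spans both paths
    terminal_nodes: list[Node] = []
    for source, path in (("TP1", np.array([t.tp1 for t in triplets])),
                         ("TP2", np.array([t.tp2 for t in triplets]))):
        terminal_nodes.extend(extract_nodes(path, config.dis_th, config.mn_th,
                                            frames=frames, source=source,
                                            strict=config.strict_mn))
    terminal_nodes.sort(key=lambda n: (n.first_frame, n.source))
    iw = classify_inspection(terminal_nodes, theta, config.angle_threshold_deg)
    _, iw, chains = classify_close_search(
        iw, terminal_nodes, cl, config.member_cap(), config.step_factor,
        config.chain_steps)

    return assemble_ethogram(cid, frames, config.frame_rate, centre_nodes,
                             windows, terminal_nodes, iw, chains)


def classify_tracks(tracks: pd.DataFrame, config: RunConfig | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every animal in a tracker output table.

    Returns (ethogram table, per-frame label table).
    """
    config = config or RunConfig()
    all_events, label_rows = [], []
    for cid, sub in tracks.groupby("cyprid_id"):
        events, labels = classify_track(sub, config)
        all_events.extend(events)
        label_rows.append(pd.DataFrame({
            "cyprid_id": int(cid), "frame": labels.index, "behaviour": labels.values}))
    ethogram = events_to_table(all_events)
    frame_labels = (pd.concat(label_rows, ignore_index=True)
                    if label_rows else pd.DataFrame(columns=["cyprid_id", "frame", "behaviour"]))
    return ethogram, frame_labels
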