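"""Identity-preserving tracking of multiple cyprids across frames.

Each animal is represented per frame by an ellipse (centre, semi-axes,
orientation) fitted to its foreground segment. Across consecutive frames,
segments are associated by pixel overlap; the association graph decomposes
into one-to-one continuations, merges (several animals fusing into one blob),
splits (a shared blob separating), exits and entries.

Merged blobs are resolved by scoring candidate ellipses for each animal with
the cost ``W = a1*N_black + a2*N_white - a3*N_cyprid``, where ``N_black``
counts non-foreground pixels claimed inside a candidate, ``N_white`` counts
the animal's candidate-relevant pixels (its remaining pixels plus all free
pixels) the candidate fails to cover, and ``N_cyprid`` counts the animal's
carried-over ("remaining") pixels it does cover. Splitting blobs
are resolved by assigning each animal to the new segment minimising
``Et = w1*Es + w2*Ed + w3*Ep`` (relative size error, axial orientation error,
shared-pixel deficit), globally over all animals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .config import CostWeights, RunConfig
from .errors import DegenerateGeometryError, InvalidInputError
from .imaging import BackgroundModel, Segment, build_background, segment_frame

__all__ = [
    "EllipseState",
    "AssociationCase",
    "associate_segments",
    "fit_ellipse",
    "resolve_merge",
    "resolve_split",
    "split_costs",
    "track_sequence",
]


@dataclass(frozen=True)
class EllipseState:
    """One cyprid in one frame.

    ``provenance`` records how the geometry was obtained: a plain fit, a
    merge resolution, a split assignment, or carried over from the last seen
    frame (``missed``).
    """

    cyprid_id: int
    frame: int
    xc: float
    yc: float
    a: float
    b: float
    theta_deg: float  # normalised to [0, 180)
    size: int
    provenance: str = "fitted"

    @property
    def centre(self) -> tuple[float, float]:
        return (self.xc, self.yc)


@dataclass(frozen=True)
class AssociationCase:
    """One resolved situation of the segment-association step."""

    kind: str  # one_to_one | merge | split | exit | entry
    old_labels: tuple[int, ...]
    new_labels: tuple[int, ...]


# ---------------------------------------------------------------------------
# Ellipse fitting


def fit_ellipse(pixel_coords, method: str = "moments") -> tuple[float, float, float, float, float]:
    """Fit an ellipse to a filled pixel set; return (xc, yc, a, b, theta_deg).

    The default fit is the equivalent ellipse of the second-order central
    moments of the filled component; ``method="lsq"`` instead fits the
    component's boundary by direct least squares. ``a >= b`` is enforced and
    theta (degrees, from +x toward +y) is normalised to [0, 180).

    Raises :class:`DegenerateGeometryError` for < 5 pixels or (near-)collinear
    sets.
    """
    coords = np.asarray(sorted(pixel_coords) if isinstance(pixel_coords, (set, frozenset))
                        else list(pixel_coords), dtype=np.float64).reshape(-1, 2)
    if len(coords) < 5:
        raise DegenerateGeometryError(f"ellipse fit needs >= 5 pixels, got {len(coords)}")
    if method == "lsq":
        return _fit_ellipse_lsq(coords)
    x, y = coords[:, 0], coords[:, 1]
    xc, yc = float(x.mean()), float(y.mean())
    dx, dy = x - xc, y - yc
    mxx, myy, mxy = float((dx * dx).mean()), float((dy * dy).mean()), float((dx * dy).mean())
    common = math.sqrt(((mxx - myy) / 2.0) ** 2 + mxy ** 2)
    l1 = (mxx + myy) / 2.0 + common
    l2 = (mxx + myy) / 2.0 - common
    if l2 <= 1e-9:
        raise DegenerateGeometryError("pixel set is collinear; no ellipse defined")
    theta = math.degrees(0.5 * math.atan2(2.0 * mxy, mxx - myy)) % 180.0
    # eigenvalues of the covariance of a filled ellipse are (a/2)^2, (b/2)^2
    return xc, yc, 2.0 * math.sqrt(l1), 2.0 * math.sqrt(l2), theta


def _fit_ellipse_lsq(coords: np.ndarray) -> tuple[float, float, float, float, float]:
    """Boundary alternative: direct least-squares conic fit on hull pixels."""
    from skimage.measure import EllipseModel

    try:
        model = EllipseModel.from_estimate(coords)
        if not model:
            raise DegenerateGeometryError("least-squares ellipse fit failed")
        (xc, yc), (A, B), theta = model.center, model.axis_lengths, model.theta
    except AttributeError:  # older scikit-image
        model = EllipseModel()
        if not model.estimate(coords):
            raise DegenerateGeometryError("least-squares ellipse fit failed")
        xc, yc, A, B, theta = model.params
    if B > A:
        A, B = B, A
        theta += math.pi / 2.0
    if B <= 1e-9:
        raise DegenerateGeometryError("pixel set is collinear; no ellipse defined")
    return float(xc), float(yc), float(A), float(B), math.degrees(theta) % 180.0


def _ellipse_interior(xc: float, yc: float, a: float, b: float, theta_deg: float,
                      shape: tuple[int, int]) -> set[int]:
    """Integer pixels strictly inside an ellipse, as flat raster indices."""
    t = math.radians(theta_deg)
    ct, st = math.cos(t), math.sin(t)
    h, w = shape
    x0 = max(0, int(math.floor(xc - a - 1)))
    x1 = min(w - 1, int(math.ceil(xc + a + 1)))
    y0 = max(0, int(math.floor(yc - a - 1)))
    y1 = min(h - 1, int(math.ceil(yc + a + 1)))
    if x1 < x0 or y1 < y0:
        return set()
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    dx, dy = xs - xc, ys - yc
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / max(b, 1e-9)
    inside = (u * u + v * v) <= 1.0
    return set((ys[inside] * w + xs[inside]).tolist())


def _coords_from_flat(flat: set[int], width: int) -> np.ndarray:
    arr = np.fromiter(sorted(flat), dtype=np.int64, count=len(flat))
    return np.stack([arr % width, arr // width], axis=1)


# ---------------------------------------------------------------------------
# Segment association


def associate_segments(prev: Sequence[Segment], curr: Sequence[Segment]) -> list[AssociationCase]:
    """Group segments of consecutive frames by >= 1 px overlap.

    Every old and new segment appears in exactly one case. Connected
    components of the overlap graph map to the five situations: one-to-one
    continuation, merge (>= 2 old, 1 new), split (1 old, >= 2 new), exit
    (old with no new) and entry (new with no old). A component with several
    old and several new segments (outside the canonical five) is emitted as a
    single ``split`` case carrying all participants; the tracker resolves it
    with the split cost over every carried animal.
    """
    prev = sorted(prev, key=lambda s: s.label)
    curr = sorted(curr, key=lambda s: s.label)
    overlap: dict[int, set[int]] = {s.label: set() for s in prev}
    for o in prev:
        for n in curr:
            if o.flat & n.flat:
                overlap[o.label].add(n.label)

    # connected components over the bipartite overlap graph
    new_to_old: dict[int, set[int]] = {n.label: set() for n in curr}
    for o_label, ns in overlap.items():
        for n_label in ns:
            new_to_old[n_label].add(o_label)

    cases: list[AssociationCase] = []
    seen_old: set[int] = set()
    seen_new: set[int] = set()
    for o in prev:
        if o.label in seen_old:
            continue
        comp_old, comp_new = {o.label}, set()
        frontier_old = [o.label]
        while frontier_old:
            ol = frontier_old.pop()
            for nl in overlap[ol]:
                if nl not in comp_new:
                    comp_new.add(nl)
                    for ol2 in new_to_old[nl]:
                        if ol2 not in comp_old:
                            comp_old.add(ol2)
                            frontier_old.append(ol2)
        seen_old |= comp_old
        seen_new |= comp_new
        olds = tuple(sorted(comp_old))
        news = tuple(sorted(comp_new))
        if not news:
            cases.append(AssociationCase("exit", olds, ()))
        elif len(olds) == 1 and len(news) == 1:
            cases.append(AssociationCase("one_to_one", olds, news))
        elif len(news) == 1:
            cases.append(AssociationCase("merge", olds, news))
        else:
            cases.append(AssociationCase("split", olds, news))
    for n in curr:
        if n.label not in seen_new:
            cases.append(AssociationCase("entry", (), (n.label,)))
    return cases


# ---------------------------------------------------------------------------
# Merge resolution


def resolve_merge(
    new_segment: Segment,
    prev: Sequence[tuple[EllipseState, frozenset]],
    weights: CostWeights | None = None,
    method: str = "moments",
    velocities: dict[int, tuple[float, float]] | None = None,
    ref_shapes: dict[int, tuple[float, float]] | None = None,
) -> tuple[list[EllipseState], dict[int, frozenset]]:
    """Resolve one blob carrying several animals into per-animal ellipses.

    ``prev`` pairs each animal's last state with its last pixel support
    (flat raster indices). Pixels of the new segment overlapping an animal's
    previous support are its *remaining* pixels; pixels overlapping nobody are
    *free*. Four deterministic candidates are scored per animal with the
    merge cost ``W`` (see module docstring): an ellipse fitted to the
    remaining pixels only, to remaining plus all free pixels, to remaining
    plus the free pixels nearest to this animal's previous centre, and the
    previous ellipse carried forward rigidly along the track's velocity
    (``velocities``, px/frame per animal). The rigid candidate is what keeps
    an animal's full extent through sustained overlap, when its advancing
    edge lies inside another animal's old claim and is therefore neither
    remaining nor free; the cost accepts it only while it stays consistent
    with the foreground.

    Returns the resolved states (provenance ``merge-resolved``; an animal
    with no remaining pixels is returned as ``missed`` with its previous
    geometry) and each resolved animal's new pixel support: the segment
    pixels covered by its winning ellipse. Supports of overlapping animals
    may share pixels, but their union never exceeds the segment (no pixel is
    invented).
    """
    weights = weights or CostWeights()
    seg_flat = set(new_segment.flat)
    w = new_segment.shape[1]

    remaining: dict[int, set[int]] = {}
    for state, support in prev:
        remaining[state.cyprid_id] = seg_flat & set(support)
    claimed = set().union(*remaining.values()) if remaining else set()
    free = seg_flat - claimed

    # partition free pixels by nearest previous centre (deterministic)
    free_assign: dict[int, set[int]] = {state.cyprid_id: set() for state, _ in prev}
    if free:
        free_arr = np.fromiter(sorted(free), dtype=np.int64, count=len(free))
        fx, fy = free_arr % w, free_arr // w
        centres = np.array([[s.xc, s.yc] for s, _ in prev])
        d2 = (fx[:, None] - centres[None, :, 0]) ** 2 + (fy[:, None] - centres[None, :, 1]) ** 2
        owner = np.argmin(d2, axis=1)  # ties -> lowest index = lowest cyprid order
        ids = [s.cyprid_id for s, _ in prev]
        for pix, o in zip(free_arr.tolist(), owner.tolist()):
            free_assign[ids[o]].add(pix)

    states: list[EllipseState] = []
    supports: dict[int, frozenset] = {}
    for state, _ in prev:
        cid = state.cyprid_id
        rem = remaining[cid]
        if not rem:
            states.append(replace(state, frame=new_segment_frame_hint(state), provenance="missed"))
            continue
        vx, vy = (velocities or {}).get(cid, (0.0, 0.0))
        a_ref, b_ref = (ref_shapes or {}).get(cid, (state.a, state.b))
        geom_candidates: list[tuple] = []
        for cand in (rem, rem | free, rem | free_assign[cid]):
            try:
                geom = fit_ellipse(_coords_from_flat(cand, w), method=method)
            except DegenerateGeometryError:
                continue
            # the body is rigid: a candidate ellipse whose axes depart from
            # the animal's clean pre-merge shape is a blend of overlapping
            # bodies (or a truncation), not a plausible body; likewise a
            # whole-body rotation of > 15 degrees in one frame
            if not (0.8 <= geom[2] / max(a_ref, 1e-6) <= 1.15
                    and 0.8 <= geom[3] / max(b_ref, 1e-6) <= 1.15):
                continue
            if _axial_diff_deg(geom[4], state.theta_deg) > 15.0:
                continue
            geom_candidates.append((geom, cand))
        predicted = (state.xc + vx, state.yc + vy, state.a, state.b, state.theta_deg)
        pred_interior = _ellipse_interior(*predicted, new_segment.shape)
        relevant = rem | free  # pixels that could belong to this animal

        def score(geom, cand):
            interior = _ellipse_interior(*geom, new_segment.shape)
            n_black = len(interior - seg_flat)
            n_white = len(relevant - interior)
            n_cyprid = len(rem & interior)
            cost = weights.a1 * n_black + weights.a2 * n_white - weights.a3 * n_cyprid
            return (cost, *geom, cand, interior)

        best = None
        for geom, cand in geom_candidates:
            if not cand:
                continue
            scored = score(geom, cand)
            # ties favour the larger candidate: the cost is blind to free
            # pixels a candidate covers at no penalty, and dropping them
            # would starve the track of its advancing edge
            if best is None or scored[0] < best[0] - 1e-9 or \
                    (abs(scored[0] - best[0]) <= 1e-9 and len(cand) > len(best[6])):
                best = scored
        rigid_cand = seg_flat & pred_interior
        if rigid_cand:
            rigid = score(predicted, rigid_cand)
            # inertia: a fitted candidate replaces the velocity-carried body
            # only when decisively better. During near-total superposition the
            # blended fits win by a few pixels per frame and would walk both
            # claims onto the same geometry; a genuine pose change beats the
            # carried body by an amount that scales with the displaced area.
            margin = 0.1 * max(state.size, 20)
            if best is None or rigid[0] <= best[0] + margin:
                best = rigid
        if best is None:
            states.append(replace(state, frame=new_segment_frame_hint(state), provenance="missed"))
            continue
        _, xc, yc, a, b, theta, cand, interior = best
        # the winning ellipse defines the animal: its claim is every segment
        # pixel it covers, so claims of overlapping animals may share pixels
        # (their union never exceeds the segment)
        support = frozenset(seg_flat & interior) or frozenset(cand)
        supports[cid] = support
        states.append(EllipseState(cyprid_id=cid, frame=state.frame + 1, xc=xc, yc=yc,
                                   a=a, b=b, theta_deg=theta, size=len(support),
                                   provenance="merge-resolved"))
    return states, supports


def new_segment_frame_hint(state: EllipseState) -> int:
    return state.frame + 1


# ---------------------------------------------------------------------------
# Split resolution


def _axial_diff_deg(t1: float, t2: float) -> float:
    """Distance between two orientations defined modulo 180 degrees."""
    d = abs(t1 - t2) % 180.0
    return min(d, 180.0 - d)


def split_costs(
    cyprids: Sequence[tuple[EllipseState, frozenset]],
    segments: Sequence[Segment],
    weights: CostWeights | None = None,
    method: str = "moments",
) -> np.ndarray:
    """Pairwise assignment costs Et[i, j] between animals and new segments.

    Es = |s_i - s_j| / max(s_i, s_j); Ed = axial orientation distance / 90 so
    all three terms lie in [0, 1]; Ep = 1 - N_shared / min(s_i, s_j).
    """
    weights = weights or CostWeights()
    et = np.zeros((len(cyprids), len(segments)))
    seg_fits = []
    for seg in segments:
        try:
            seg_fits.append(fit_ellipse(seg.coords, method=method))
        except DegenerateGeometryError:
            seg_fits.append(None)
    for i, (state, support) in enumerate(cyprids):
        s_i = max(state.size, 1)
        for j, seg in enumerate(segments):
            s_j = seg.size
            es = abs(s_i - s_j) / max(s_i, s_j)
            fit = seg_fits[j]
            # unfit-table segment: neutral orientation term
            ed = _axial_diff_deg(state.theta_deg, fit[4]) / 90.0 if fit else 0.5
            n_shared = len(set(support) & seg.flat)
            ep = 1.0 - n_shared / min(s_i, s_j)
            et[i, j] = weights.w1 * es + weights.w2 * ed + weights.w3 * ep
    return et


def resolve_split(
    new_segments: Sequence[Segment],
    old_cyprids: Sequence[tuple[EllipseState, frozenset]],
    weights: CostWeights | None = None,
    method: str = "moments",
) -> dict[int, int]:
    """Assign animals from a splitting blob to the new segments.

    Returns a mapping cyprid_id -> segment label minimising the total
    ``Et`` cost, exhaustively for <= 4 animals and greedily beyond.
    Unassigned animals become missed and unassigned segments become entries
    (handled by the caller). Exact ties resolve with the lowest cyprid id
    taking the lowest segment label.
    """
    if not old_cyprids or not new_segments:
        return {}
    cyprids = sorted(old_cyprids, key=lambda p: p[0].cyprid_id)
    segments = sorted(new_segments, key=lambda s: s.label)
    et = split_costs(cyprids, segments, weights, method=method)
    n_c, n_s = et.shape
    r = min(n_c, n_s)

    if n_c <= 4:
        best_total, best_assign = None, None
        # choose which cyprids get a segment (all, if enough segments), then
        # enumerate injective segment choices in lexicographic order so that
        # ties resolve to lowest id -> lowest label
        for cyp_subset in itertools.combinations(range(n_c), r):
            for seg_perm in itertools.permutations(range(n_s), r):
                total = sum(et[i, j] for i, j in zip(cyp_subset, seg_perm))
                if best_total is None or total < best_total - 1e-12:
                    best_total = total
                    best_assign = dict(zip(cyp_subset, seg_perm))
        assign = best_assign or {}
    else:
        pairs = sorted(((et[i, j], i, j) for i in range(n_c) for j in range(n_s)),
                       key=lambda t: (t[0], t[1], t[2]))
        assign = {}
        used_segs: set[int] = set()
        for _, i, j in pairs:
            if i in assign or j in used_segs:
                continue
            assign[i] = j
            used_segs.add(j)
            if len(assign) == r:
                break
    return {cyprids[i][0].cyprid_id: segments[j].label for i, j in assign.items()}


# ---------------------------------------------------------------------------
# Whole-sequence tracking


@dataclass
class _Track:
    cyprid_id: int
    state: EllipseState
    support: frozenset
    missed_count: int = 0
    active: bool = True
    velocity: tuple[float, float] = (0.0, 0.0)
    ref_shape: tuple[float, float] | None = None  # clean (a, b), frozen in merges

    def advance(self, state: EllipseState, support: frozenset) -> None:
        self.velocity = (state.xc - self.state.xc, state.yc - self.state.yc)
        self.state = state
        self.support = support
        self.missed_count = 0
        if state.provenance != "merge-resolved":
            self.ref_shape = (state.a, state.b)


def track_sequence(
    frames: Sequence,
    config: RunConfig | None = None,
    bg: BackgroundModel | None = None,
) -> pd.DataFrame:
    """Track every animal through a frame sequence.

    Returns a table with one row per (frame, cyprid_id):
    frame, time_s, cyprid_id, xc, yc, a, b, theta_deg, size, provenance.
    New identities are minted only on entry; a vanished animal is carried as
    ``missed`` (last geometry) for ``miss_patience`` frames, then retired and
    never re-linked.
    """
    config = config or RunConfig()
    frames = list(frames)
    if not frames:
        raise InvalidInputError("empty frame sequence")
    if bg is None:
        bg = build_background(frames, config.diff_threshold, config.max_passes)

    rows: list[tuple] = []
    tracks: dict[int, _Track] = {}
    next_id = 1
    prev_segments: list[tuple[Segment, list[int]]] = []  # segment + carried ids
    shape = bg.pixels.shape

    def emit(state: EllipseState) -> None:
        rows.append((state.frame, state.frame / config.frame_rate, state.cyprid_id,
                     state.xc, state.yc, state.a, state.b, state.theta_deg,
                     state.size, state.provenance))

    for f_idx, frame in enumerate(frames):
        try:
            segments = segment_frame(frame, bg, config.bin_threshold, config.min_area)
        except InvalidInputError:
            raise
        seg_by_label = {s.label: s for s in segments}

        # previous "segments": real ones plus virtual supports of missed tracks
        assoc_prev: list[Segment] = []
        carried: dict[int, list[int]] = {}
        label = 1
        for seg, ids in prev_segments:
            virtual = Segment(label=label, coords=seg.coords, shape=seg.shape)
            assoc_prev.append(virtual)
            carried[label] = ids
            label += 1
        for tr in sorted(tracks.values(), key=lambda t: t.cyprid_id):
            if tr.active and tr.missed_count > 0 and tr.support:
                virtual = Segment(label=label,
                                  coords=_coords_from_flat(set(tr.support), shape[1]),
                                  shape=shape)
                assoc_prev.append(virtual)
                carried[label] = [tr.cyprid_id]
                label += 1

        cases = associate_segments(assoc_prev, segments)
        new_prev: list[tuple[Segment, list[int]]] = []
        updated: set[int] = set()

        def cyprids_of(old_labels) -> list[int]:
            ids: list[int] = []
            for ol in old_labels:
                for cid in carried[ol]:
                    if cid not in ids and tracks[cid].active:
                        ids.append(cid)
            return ids

        def mint_entry(seg: Segment) -> None:
            nonlocal next_id
            try:
                xc, yc, a, b, theta = fit_ellipse(seg.coords, method=config.ellipse_method)
            except DegenerateGeometryError:
                return  # unfit-table noise blob: no identity minted
            cid = next_id
            next_id += 1
            state = EllipseState(cid, f_idx, xc, yc, a, b, theta, seg.size, "fitted")
            tracks[cid] = _Track(cid, state, seg.flat)
            emit(state)
            updated.add(cid)
            new_prev.append((seg, [cid]))

        for case in cases:
            if case.kind != "entry" and case.new_labels and not cyprids_of(case.old_labels):
                for nl in case.new_labels:  # carried animals all retired meanwhile
                    mint_entry(seg_by_label[nl])
                continue
            if case.kind == "entry":
                mint_entry(seg_by_label[case.new_labels[0]])
            elif case.kind == "exit":
                for cid in cyprids_of(case.old_labels):
                    _mark_missed(tracks[cid], f_idx, config, emit)
                    updated.add(cid)
            elif case.kind == "one_to_one" and len(cyprids_of(case.old_labels)) == 1:
                seg = seg_by_label[case.new_labels[0]]
                cid = cyprids_of(case.old_labels)[0]
                tr = tracks[cid]
                try:
                    xc, yc, a, b, theta = fit_ellipse(seg.coords, method=config.ellipse_method)
                    state = EllipseState(cid, f_idx, xc, yc, a, b, theta, seg.size, "fitted")
                    tr.advance(state, seg.flat)
                    emit(state)
                except DegenerateGeometryError:
                    _mark_missed(tr, f_idx, config, emit)
                updated.add(cid)
                new_prev.append((seg, [cid]))
            elif case.kind in ("one_to_one", "merge") and len(case.new_labels) == 1:
                # one blob, several animals: merge resolution
                seg = seg_by_label[case.new_labels[0]]
                ids = cyprids_of(case.old_labels)
                prev_pairs = [(tracks[c].state, tracks[c].support) for c in ids]
                velocities = {c: tracks[c].velocity for c in ids}
                ref_shapes = {c: tracks[c].ref_shape or
                              (tracks[c].state.a, tracks[c].state.b) for c in ids}
                states, supports = resolve_merge(seg, prev_pairs, config.weights,
                                                 method=config.ellipse_method,
                                                 velocities=velocities,
                                                 ref_shapes=ref_shapes)
                kept: list[int] = []
                for st in states:
                    tr = tracks[st.cyprid_id]
                    if st.provenance == "missed":
                        _mark_missed(tr, f_idx, config, emit)
                    else:
                        st = replace(st, frame=f_idx)
                        tr.advance(st, supports[st.cyprid_id])
                        emit(st)
                        kept.append(st.cyprid_id)
                    updated.add(st.cyprid_id)
                if kept:
                    new_prev.append((seg, kept))
            else:  # split (including general many-to-many)
                segs = [seg_by_label[nl] for nl in case.new_labels]
                ids = cyprids_of(case.old_labels)
                prev_pairs = [(tracks[c].state, tracks[c].support) for c in ids]
                assign = resolve_split(segs, prev_pairs, config.weights,
                                       method=config.ellipse_method)
                assigned_labels = set(assign.values())
                for cid in ids:
                    tr = tracks[cid]
                    if cid in assign:
                        seg = seg_by_label[assign[cid]]
                        try:
                            xc, yc, a, b, theta = fit_ellipse(seg.coords,
                                                              method=config.ellipse_method)
                            state = EllipseState(cid, f_idx, xc, yc, a, b, theta,
                                                 seg.size, "split-assigned")
                            tr.advance(state, seg.flat)
                            emit(state)
                            new_prev.append((seg, [cid]))
                        except DegenerateGeometryError:
                            _mark_missed(tr, f_idx, config, emit)
                    else:
                        _mark_missed(tr, f_idx, config, emit)
                    updated.add(cid)
                for seg in segs:  # leftover fragments become entries
                    if seg.label in assigned_labels:
                        continue
                    try:
                        xc, yc, a, b, theta = fit_ellipse(seg.coords,
                                                          method=config.ellipse_method)
                    except DegenerateGeometryError:
                        continue
                    cid = next_id
                    next_id += 1
                    state = EllipseState(cid, f_idx, xc, yc, a, b, theta, seg.size, "fitted")
                    tracks[cid] = _Track(cid, state, seg.flat)
                    emit(state)
                    updated.add(cid)
                    new_prev.append((seg, [cid]))

        # tracks untouched by any case (e.g. already-missed, still unseen)
        for tr in sorted(tracks.values(), key=lambda t: t.cyprid_id):
            if tr.active and tr.cyprid_id not in updated:
                _mark_missed(tr, f_idx, config, emit)

        prev_segments = new_prev

    df = pd.DataFrame(rows, columns=["frame", "time_s", "cyprid_id", "xc", "yc",
                                     "a", "b", "theta_deg", "size", "provenance"])
    return df.sort_values(["frame", "cyprid_id"], kind="stable").reset_index(drop=True)


def _mark_missed(tr: _Track, f_idx: int, config: RunConfig, emit) -> None:
    tr.missed_count += 1
    if tr.missed_count > config.miss_patience:
        tr.active = False
        return
    tr.state = replace(tr.state, frame=f_idx, provenance="missed")
    emit(tr.state)
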