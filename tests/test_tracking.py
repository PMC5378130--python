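"""Segment association, ellipse fitting, merge/split resolution, tracking."""

import itertools
import math

import numpy as np
import pytest

from cypritrack.config import RunConfig
from cypritrack.errors import DegenerateGeometryError
from cypritrack.imaging import Segment
from cypritrack.synth import (ArenaSpec, crossing_trajectories, render_frames,
                              rasterize_ellipse)
from cypritrack.tracking import (EllipseState, associate_segments, fit_ellipse,
                                 resolve_merge, resolve_split, split_costs,
                                 track_sequence)

SHAPE = (120, 120)


def seg(label, coords):
    return Segment(label=label, coords=np.asarray(coords, dtype=int), shape=SHAPE)


def block(x0, y0, w, h):
    return [(x, y) for x in range(x0, x0 + w) for y in range(y0, y0 + h)]


def ellipse_segment(label, xc, yc, a, b, theta):
    rr, cc = rasterize_ellipse(xc, yc, a, b, theta, SHAPE)
    return seg(label, np.stack([cc, rr], axis=1))


def state_of(cyprid_id, segment, frame=0, provenance="fitted"):
    xc, yc, a, b, theta = fit_ellipse(segment.coords)
    return EllipseState(cyprid_id, frame, xc, yc, a, b, theta,
                        segment.size, provenance)


class TestAssociateSegments:
    def test_identical_sets_are_one_to_one(self):
        prev = [seg(1, block(10, 10, 4, 4)), seg(2, block(50, 50, 4, 4))]
        curr = [seg(1, block(10, 10, 4, 4)), seg(2, block(50, 50, 4, 4))]
        cases = associate_segments(prev, curr)
        assert sorted(c.kind for c in cases) == ["one_to_one", "one_to_one"]

    def test_two_old_overlapping_one_new_is_merge(self):
        prev = [seg(1, block(10, 10, 4, 4)), seg(2, block(16, 10, 4, 4))]
        curr = [seg(1, block(10, 10, 10, 4))]
        [case] = associate_segments(prev, curr)
        assert case.kind == "merge"
        assert case.old_labels == (1, 2)
        assert case.new_labels == (1,)

    def test_one_old_two_new_is_split(self):
        prev = [seg(1, block(10, 10, 10, 4))]
        curr = [seg(1, block(10, 10, 4, 4)), seg(2, block(16, 10, 4, 4))]
        [case] = associate_segments(prev, curr)
        assert case.kind == "split"

    def test_entry_and_exit(self):
        assert associate_segments([], [seg(1, block(5, 5, 3, 3))])[0].kind == "entry"
        assert associate_segments([seg(1, block(5, 5, 3, 3))], [])[0].kind == "exit"

    def test_every_segment_appears_exactly_once(self):
        prev = [seg(1, block(10, 10, 5, 5)), seg(2, block(40, 40, 5, 5)),
                seg(3, block(80, 80, 5, 5))]
        curr = [seg(1, block(12, 12, 5, 5)), seg(2, block(90, 90, 5, 5))]
        cases = associate_segments(prev, curr)
        olds = [l for c in cases for l in c.old_labels]
        news = [l for c in cases for l in c.new_labels]
        assert sorted(olds) == [1, 2, 3]
        assert sorted(news) == [1, 2]


class TestFitEllipse:
    def test_recovers_rendered_parameters(self):
        s = ellipse_segment(1, 50.0, 40.0, 10.0, 4.0, 30.0)
        xc, yc, a, b, theta = fit_ellipse(s.coords)
        assert (xc, yc) == pytest.approx((50.0, 40.0), abs=0.5)
        assert a == pytest.approx(10.0, abs=0.5)
        assert b == pytest.approx(4.0, abs=0.5)
        assert min(abs(theta - 30.0), 180 - abs(theta - 30.0)) < 3.0

    def test_circle_has_equal_axes(self):
        s = ellipse_segment(1, 60.0, 60.0, 6.0, 6.0, 0.0)
        _, _, a, b, _ = fit_ellipse(s.coords)
        assert a == pytest.approx(6.0, abs=0.5)
        assert b == pytest.approx(6.0, abs=0.5)

    def test_collinear_pixels_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_ellipse([(0, 0), (1, 0), (2, 0), (3, 0), (4, 0)])

    def test_too_few_pixels_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_ellipse([(0, 0), (1, 1), (2, 0)])

    def test_lsq_variant_agrees_on_clean_ellipse(self):
        s = ellipse_segment(1, 50.0, 40.0, 10.0, 4.0, 60.0)
        m = fit_ellipse(s.coords, method="moments")
        l = fit_ellipse(s.coords, method="lsq")
        assert m[0] == pytest.approx(l[0], abs=1.0)
        assert m[1] == pytest.approx(l[1], abs=1.0)


class TestResolveMerge:
    def test_degenerate_single_cyprid_equals_plain_fit(self):
        s = ellipse_segment(1, 50.0, 40.0, 9.0, 4.0, 20.0)
        prev = [(state_of(1, s), s.flat)]
        [resolved], supports = resolve_merge(s, prev)
        xc, yc, a, b, theta = fit_ellipse(s.coords)
        assert resolved.provenance == "merge-resolved"
        assert (resolved.xc, resolved.yc) == pytest.approx((xc, yc), abs=0.5)
        assert resolved.a == pytest.approx(a, abs=0.5)

    def test_touching_pair_resolved_to_own_sides(self):
        # two ellipses touching edge to edge; each resolved centre must stay
        # nearer its own previous centre than the other's
        s1 = ellipse_segment(1, 40.0, 40.0, 9.0, 4.0, 0.0)
        s2 = ellipse_segment(2, 57.0, 40.0, 9.0, 4.0, 0.0)
        merged = seg(1, np.concatenate([s1.coords, s2.coords]))
        prev = [(state_of(1, s1), s1.flat), (state_of(2, s2), s2.flat)]
        states, supports = resolve_merge(merged, prev)
        by_id = {s.cyprid_id: s for s in states}
        assert abs(by_id[1].xc - 40.0) < abs(by_id[1].xc - 57.0)
        assert abs(by_id[2].xc - 57.0) < abs(by_id[2].xc - 40.0)
        # no pixel invented: the union of claims stays inside the segment
        union = frozenset().union(*supports.values())
        assert union <= merged.flat

    def test_cyprid_without_remaining_pixels_goes_missed(self):
        s1 = ellipse_segment(1, 40.0, 40.0, 9.0, 4.0, 0.0)
        far = ellipse_segment(2, 100.0, 100.0, 9.0, 4.0, 0.0)
        prev = [(state_of(1, s1), s1.flat), (state_of(2, far), far.flat)]
        states, _ = resolve_merge(s1, prev)
        by_id = {s.cyprid_id: s for s in states}
        assert by_id[1].provenance == "merge-resolved"
        assert by_id[2].provenance == "missed"


def brute_force_assignment(costs):
    """Exhaustive-permutation minimiser, independent of the implementation."""
    n_c, n_s = costs.shape
    r = min(n_c, n_s)
    best, best_assign = None, None
    for rows in itertools.combinations(range(n_c), r):
        for cols in itertools.permutations(range(n_s), r):
            total = sum(costs[i, j] for i, j in zip(rows, cols))
            if best is None or total < best - 1e-12:
                best, best_assign = total, dict(zip(rows, cols))
    return best_assign


class TestResolveSplit:
    def _cyprids(self, sizes, thetas):
        out = []
        for k, (s, t) in enumerate(zip(sizes, thetas), start=1):
            # synthetic support pixels: a compact block of the wanted size
            side = max(2, int(math.isqrt(s)))
            coords = block(5 + 20 * k, 5, side, (s + side - 1) // side)[:s]
            segment = seg(k, coords)
            out.append((EllipseState(k, 0, *segment.centroid, 6.0, 3.0, t, s),
                        segment.flat))
        return out

    def test_size_driven_assignment(self):
        cyprids = self._cyprids([40, 90], [0.0, 0.0])
        segs = [seg(1, block(60, 60, 7, 6)[:42]), seg(2, block(80, 80, 8, 11))]
        assign = resolve_split(segs, cyprids)
        assert assign == {1: 1, 2: 2}  # 40->42 px and 90->88 px

    def test_symmetric_tie_breaks_to_lowest_id(self):
        cyprids = self._cyprids([36, 36], [0.0, 0.0])
        segs = [seg(1, block(60, 60, 6, 6)), seg(2, block(80, 80, 6, 6))]
        # force a perfect tie: identical sizes/orientations, zero sharing
        costs = split_costs(cyprids, segs)
        assert np.allclose(costs[0], costs[1])
        assign = resolve_split(segs, cyprids)
        assert assign == {1: 1, 2: 2}

    def test_extra_segment_left_unassigned(self):
        cyprids = self._cyprids([36, 36], [0.0, 90.0])
        segs = [seg(1, block(60, 60, 6, 6)), seg(2, block(80, 80, 6, 6)),
                seg(3, block(100, 100, 6, 6))]
        assign = resolve_split(segs, cyprids)
        assert len(assign) == 2
        assert set(assign) == {1, 2}

    def test_matches_exhaustive_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n_c = int(rng.integers(2, 5))
            n_s = int(rng.integers(2, 6))
            cyprids = self._cyprids(rng.integers(20, 120, n_c).tolist(),
                                    rng.uniform(0, 180, n_c).tolist())
            segs = []
            for j in range(n_s):
                w = int(rng.integers(3, 11))
                h = int(rng.integers(3, 11))
                segs.append(seg(j + 1, block(int(rng.integers(0, 100)),
                                             int(rng.integers(0, 100)), w, h)))
            costs = split_costs(cyprids, segs)
            want = brute_force_assignment(costs)
            got = resolve_split(segs, cyprids)
            got_idx = {cid - 1: assign_label - 1 for cid, assign_label in got.items()}
            want_cost = sum(costs[i, j] for i, j in want.items())
            got_cost = sum(costs[i, j] for i, j in got_idx.items())
            assert got_cost == pytest.approx(want_cost, abs=1e-9)


class TestTrackSequence:
    def test_single_moving_blob_keeps_one_identity(self):
        arena = ArenaSpec(width=160, height=160, noise_sd=0.0)
        rows = [(f, 30.0 + 2.0 * f, 80.0, 0.0, "swimming") for f in range(50)]
        import pandas as pd
        traj = pd.DataFrame(rows, columns=["frame", "xc", "yc", "theta_deg", "behaviour"])
        frames = render_frames([traj], arena, seed=0)
        tracks = track_sequence(frames)
        assert tracks["cyprid_id"].nunique() == 1
        assert len(tracks) == 50

    def test_crossing_preserves_both_identities(self):
        arena = ArenaSpec(width=240, height=240, noise_sd=0.0)
        t1, t2 = crossing_trajectories(arena, 90.0, speed=3.0, n_frames=60)
        frames = render_frames([t1, t2], arena, seed=0)
        tracks = track_sequence(frames)
        assert tracks["cyprid_id"].nunique() == 2
        last = tracks[tracks.frame == 59].set_index("cyprid_id")
        # raster order makes id 1 the animal moving +y along x=120 and id 2
        # the one moving +x along y=120; each must leave on its own path
        assert last.loc[1, "xc"] == pytest.approx(120.0, abs=2.0)
        assert last.loc[2, "yc"] == pytest.approx(120.0, abs=2.0)
        assert set(tracks["provenance"]) >= {"fitted", "merge-resolved", "split-assigned"}

    def test_departed_blob_retires_and_reentry_gets_new_id(self):
        import pandas as pd
        arena = ArenaSpec(width=160, height=160, noise_sd=0.0)
        rows = [(f, 30.0, 30.0, 0.0, "swimming") for f in range(20)]
        rows += [(f, 120.0, 120.0, 0.0, "swimming") for f in range(45, 60)]
        traj = pd.DataFrame(rows, columns=["frame", "xc", "yc", "theta_deg", "behaviour"])
        frames = render_frames([traj], arena, seed=0)
        tracks = track_sequence(frames, RunConfig(miss_patience=5))
        ids = sorted(tracks["cyprid_id"].unique())
        assert len(ids) == 2
        first, second = (tracks[tracks.cyprid_id == i] for i in ids)
        assert first["frame"].max() < 45   # retired during the absence
        assert second["frame"].min() == 45

    def test_identity_set_constant_without_exits(self):
        import pandas as pd
        arena = ArenaSpec(width=160, height=160, noise_sd=1.0)
        rows1 = [(f, 40.0 + f, 50.0, 10.0, "swimming") for f in range(40)]
        rows2 = [(f, 110.0 - f, 100.0, 170.0, "swimming") for f in range(40)]
        cols = ["frame", "xc", "yc", "theta_deg", "behaviour"]
        frames = render_frames([pd.DataFrame(rows1, columns=cols),
                                pd.DataFrame(rows2, columns=cols)], arena, seed=3)
        tracks = track_sequence(frames)
        per_frame_ids = tracks.groupby("frame")["cyprid_id"].agg(lambda s: tuple(sorted(s)))
        assert set(per_frame_ids) == {(1, 2)}
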