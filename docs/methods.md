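# Methods

`cypritrack` tracks settlement-stage barnacle larvae (cyprids) in fixed-camera
grayscale image sequences and classifies each animal's movement into four
canonical exploratory behaviours: swimming, wide search, close search and
inspection. This note documents the models, the parameters that matter, the
synthetic data the tests rely on, and the numerical and design choices made
where the procedure was genuinely open.

## Imaging model

The scene is a bright, static arena with dark animals (dark-on-bright polarity
is assumed throughout; a config switch inverts frames for the opposite case).
The background is estimated by a brighten-only fixed-point iteration: starting
from the first frame, any pixel of a later frame brighter than the current
background by more than `diff_threshold` (default 30 intensity units) replaces
it, and passes over the sequence repeat until one pass changes nothing. Because
an animal is strictly darker than the arena, a pixel is restored to the true
background as soon as the animal uncovers it in any frame; on sequences where
every pixel is uncovered at least once the reconstruction is exact (it equals
the per-pixel maximum over frames). A `max_passes` guard (default 50) bounds
the iteration when noise prevents convergence and flags the model unconverged.

Foreground is `background − frame > bin_threshold` (default 70, half the
nominal blob/background contrast of the synthetic renderer; the value is a
config-exposed guess because no canonical value exists). Connected components
are 8-connected — thin diagonal body outlines must not fragment — and
components under `min_area` = 5 px are discarded, following the requirement
that each animal's boundary span at least five pixels. Coordinates are 0-based,
x rightward, y downward; centroids are real-valued means of pixel coordinates.

## Tracking model

Each animal is an ellipse: centre `CE = (xc, yc)`, semi-axes `a ≥ b`,
orientation `θ ∈ [0°, 180°)` measured from +x toward +y. The default fit is the
equivalent ellipse of the second-order central moments of the filled component
(for a filled ellipse the covariance eigenvalues are `(a/2)²` and `(b/2)²`); a
direct least-squares boundary fit is available behind
`ellipse_method: "lsq"`. Moment fitting was chosen because segmentation yields
filled blobs and the fit is closed-form and deterministic.

Segments of consecutive frames associate by ≥ 1 px overlap. Connected
components of the overlap graph decompose into one-to-one continuations,
merges, splits, exits and entries; a component with several old **and**
several new segments (rare, outside the five canonical situations) is resolved
with the split cost over all carried animals.

### Merge resolution

When several animals fuse into one blob, each animal's *remaining* pixels are
the blob pixels overlapping its previous claim, and *free* pixels overlap
nobody's. Candidate ellipses per animal:

1. a fit of the remaining pixels alone,
2. a fit of remaining plus all free pixels,
3. a fit of remaining plus the free pixels nearest its previous centre,
4. the previous ellipse carried forward rigidly along the track's per-frame
   velocity.

Candidates are scored with `W = a1·N_black + a2·N_white − a3·N_cyprid`
(defaults `a1 = a2 = a3 = 1`, config-exposed): `N_black` counts non-foreground
pixels inside the candidate, `N_white` counts the animal's candidate-relevant
pixels — remaining ∪ free — left outside it, and `N_cyprid` counts remaining
pixels covered. Counting `N_white` over remaining ∪ free is essential: if
under-coverage went unpunished, the tight remaining-only fit would always win
and the claim would shed one body-advance of pixels per frame until the track
starved. The minimum-W candidate wins; exact ties prefer the larger claim.

The rigid candidate also carries a retention margin: a fitted candidate
replaces the velocity-carried body only when its cost is better by more than
10 % of the body size. During near-total superposition, blended fits win by
only a few pixels per frame, and accepting them walks both animals' claims
onto the same geometry just before separation; a genuine pose change displaces
enough area to clear the margin, so a turning animal is still re-fitted.

Two plausibility rules keep the candidates honest during deep overlap, where
a fit of blended pixel sets looks locally attractive but belongs to no single
body: fitted candidates are rejected when their semi-axes leave
`[0.8, 1.15]` of the animal's clean pre-merge shape (the body is rigid) or
when they imply a whole-body rotation above 15° in one frame. The rigid
velocity candidate is what carries an animal's identity through frames of
near-total superposition — its advancing edge lies inside the *other*
animal's old claim there, so it is neither remaining nor free and no fitted
candidate can recover it. The winning ellipse defines the animal: its claim is
every blob pixel it covers, so claims of overlapping animals may share pixels,
but their union never exceeds the blob (no pixel is invented).

An animal whose remaining set is empty is carried as `missed` with its last
geometry for `miss_patience` frames (default 10, ≈ 0.3 s at 33 fps), during
which its last claim re-enters association as a virtual segment (brief
detection dropouts re-link); after that the track is retired and never
re-linked, and a re-appearing animal gets a fresh identity.

### Split resolution

When a shared blob separates into segments, every (animal *i*, segment *j*)
pair is scored with `Et = w1·Es + w2·Ed + w3·Ep` (defaults `w1 = w2 = w3 = 1`):

- `Es = |s_i − s_j| / max(s_i, s_j)` — relative size discrepancy,
- `Ed = min(|Δθ|, 180° − |Δθ|) / 90°` — orientation discrepancy on the axial
  circle (θ is defined modulo 180°), divided by 90° so all three terms are
  dimensionless in [0, 1] and the weights comparable,
- `Ep = 1 − N_shared / min(s_i, s_j)` — shared-pixel deficit.

The assignment minimising `ΣEt` is found exhaustively for ≤ 4 animals and
greedily (ascending pair cost) beyond. Exact ties resolve with the lowest
animal id taking the lowest segment label. Unassigned animals become missed;
unassigned segments become entries.

## Kinematic reduction

Each ellipse reduces to three points: the centre and the terminal points
`TP1/2 = CE ± a·(cos θ, sin θ)` at the ends of the major axis. Because θ is
axial, terminal-point labels are made temporally consistent by keeping, per
frame, the labelling minimising `|TP1_t − TP1_{t−1}| + |TP2_t − TP2_{t−1}|`
(the first frame is labelled arbitrarily); the resolved labelling also yields
a body direction continuous modulo 360°.

Dwell nodes are extracted from each of the three point paths by a single
streaming pass: a running cluster whose centre is the mean of its members
absorbs any point within `dis_th` of it; a point beyond `dis_th` finalises the
cluster if it holds **more than** `Mn_th` members (strict by default, with an
inclusive config switch, since the original condition's strictness is
ambiguous) and restarts from the current point. The trailing cluster at the
path end is finalised under the same member test — not part of the original
description, but without it a terminal dwell immediately before settlement
would be lost. Members are therefore always temporally consecutive, and
membership is judged against the centre at insertion time (streaming
semantics; slight drift of the running mean is accepted). Defaults
`dis_th = 1.7 px` and `Mn_th = 14` members follow the published calibration at
33 fps; `Mn_th` is plausibly frame-rate-dependent (≈ 0.42 s) and both are
config-exposed.

## Behaviour rules

`CL`, the cyprid length, is estimated as twice the median fitted semimajor
axis over the track (the quantity is not otherwise defined).

**Wide search** works on centre-path nodes. For consecutive node distances
(step lengths) `SL`, every window of four steps is tested:
`St/m < 0.2` (standard deviation over mean) and
`MC = max |SL − 0.85·CL| / (0.85·CL) < 0.3`; a passing window paints the five
nodes it spans. The exact form of MC (normalised by `0.85·CL`, consistent with
the dimensionless 0.3 threshold) is a documented choice. Two artifact
decisions matter here: painting is per window — not per maximal run of
flagged nodes, which would bridge the minutes-long gap between two separate
walking bouts that happen to be adjacent in node index — and an inter-node
interval during which the animal travelled for longer than
`max_step_duration_s` (default 0.5 s) is not a step at all, however step-like
its length. Without the duration gate, a swimming excursion that returns near
its origin, or a slow anchored pivot, occasionally counts as a walking step.

**Inspection** works on terminal-path nodes: a node is an inspection event
when the body direction over its member span sweeps strictly more than 30°.
The sweep is the minimal circular arc containing the samples, so an
oscillation crossing 0°/360° is measured correctly and a sweep of exactly 30°
is not inspection.

**Close search** chains inspection nodes: consecutive eligible nodes closer
than four steps (`4 × 0.85·CL`) chain together, and chains of at least two
nodes become close search, resetting their inspection flags (the two labels
never overlap). Eligibility requires the node's member count to stay under a
dwell cap — implemented as a separate, larger threshold than the
node-extraction `Mn_th` (default: members equivalent to 20 s), because a
minutes-long dwell is genuine inspection even when flanked by close search,
and reusing 14 would erase nearly every inspection node from the chains.
Chaining runs over the pooled, time-ordered inspection nodes of **both**
terminal paths: successive pivots pin alternating physical ends of the body
(net rotation moves the pinned end across the fixed kinematic labels), so
chaining each path separately would fragment one close-search bout.

**Swimming** is the exact complement: any frame carrying none of the above.
Frame precedence is close search > inspection > wide search; adjacent
same-label frames merge into events, wide-search events also report their
step count (spanned centre nodes minus one — step counts are read as
inter-node intervals), and event durations are `(end − start + 1) /
frame_rate`. Per-behaviour summaries report event counts, totals (seconds,
or steps for wide search) and the total/count average truncated toward zero,
matching how the published per-event averages round (1949 s / 11 → 177 s;
45 s / 2 → 22 s).

## Synthetic data

The generator scripts motion per behaviour so ground truth is unambiguous;
transitions occur exactly at scripted times and a single integer seed drives
all randomness (bit-reproducible tables).

- *Swimming*: ballistic motion at 6 px/frame with 3°/frame heading noise,
  reflecting off arena walls.
- *Wide search*: dwell (20 frames) – step (`0.85·CL` over 3 frames) cycles
  with 8° heading noise per step and 0.2 px dwell jitter.
- *Close search*: the same stepped walking interrupted every 1–3 steps by a
  pivot about the leading terminal point. Turn magnitude is drawn from
  U(45°, 70°): above 45° so pivots register as direction changes (> 30°), and
  at most 70° so the pivot's centre-path chord `2a·sin(Δ/2)` stays far enough
  from `0.85·CL` that a walking window containing it fails the MC gate rather
  than mimicking a regular step.
- *Inspection*: the trailing terminal point is pinned and the body oscillates
  sinusoidally (default half-amplitude 30°, period 3 s).

Rendering rasterises hard-edged filled ellipses (no anti-aliasing, so segment
sizes are deterministic; semi-axes 9 × 4 px by default) on a uniform arena
(intensity 200, blobs 60) with additive Gaussian pixel noise (σ = 2).
Overlapping animals naturally fuse into one blob, which is what exercises the
merge/split machinery; `crossing_trajectories` builds two straight swimmers
whose paths intersect at the arena centre mid-sequence, a deliberately severe
fixture in which the two bodies pass through near-total superposition.

What the generator does **not** emulate: appendage-level shape change (a real
cyprid's antennules and thoracic limbs deform the blob), illumination drift,
water-column defocus, partial occlusion at arena walls, and stochastic
behaviour switching. Passing recovery tests therefore shows the pipeline's
rules are implemented coherently and are recoverable from pixels under the
stated imaging model — not that the thresholds are correct for any particular
laboratory setup.

## Study conditions and what the numbers mean

The recovery studies in `cypritrack.studies` fix their problem sizes: the
full-loop study runs 50 seeded scripts (swim 4 s / wide search 8 s / swim 4 s /
close search 12 s / swim 4 s / inspection 22 s, one animal, 160 × 160 px arena
at 33 fps) through generate → render → track → classify and reports aggregate
frame-level label accuracy and exact behaviour-sequence recovery; the crossing
study runs 100 two-animal crossings (angles U(20°, 160°), 3 px/frame, 60
frames, 240 × 240 px arena) and reports the identity-swap rate. Residual
swaps concentrate at near-exact head-on geometry (~155°), where two
antiparallel bodies superpose almost completely along one axis and no
pixel-support or orientation cue survives.

## Numerical choices and degenerate inputs

- Ellipse fits need ≥ 5 non-collinear pixels; degenerate sets raise a typed
  error and the tracker falls back to the previous state as `missed`.
- All iteration orders are deterministic; ties everywhere resolve to the
  lowest id / lowest label; candidate ties in merge resolution prefer the
  larger claim.
- Circular quantities: θ comparisons for split costs are axial (mod 180°);
  body-direction sweeps are mod 360° on the continuity-resolved series.
- An empty path yields no nodes; a track with fewer than five centre nodes
  can never be wide search; a track with no flagged nodes is one swimming
  event.
- Entry blobs that cannot be fitted (tiny or collinear, e.g. noise specks
  surviving `min_area`) mint no identity.

## Known limitations

- Identity through a merge rests on constant-velocity dead reckoning when
  overlap is near-total; animals that stop or turn sharply *while* fully
  superposed can swap (≈ 5 % of randomised crossings, concentrated near
  head-on geometry).
- Retired tracks are never re-linked; an animal that leaves the field of view
  and returns is a new individual, so per-individual statistics across long
  absences require downstream stitching.
- The classifier assumes the frame rate the thresholds were calibrated at
  (33 fps); at other rates `Mn_th`, `max_step_duration_s` and the
  inspection member cap should be rescaled in seconds.
- `CL` from the median fitted semimajor axis is biased slightly low when an
  animal spends much of the track partially occluded.
- Settlement (permanent attachment) is not a class; a settled animal reads as
  a long inspection event.
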