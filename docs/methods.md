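# Methods

## Scope and shape

The package implements the measurement chain of an automated egg-inspection
system at desk scale: geometry and IoU primitives, the SimAM attention and
Wise-IoU v3 loss numerics, temporal majority-voting fusion with its
binomial reliability model, a self-contained EAN-13 cage-label pipeline,
8-digit position codes, a classical reference detector behind a pluggable
provider contract, a seeded synthetic scene generator, and an append-only
record store. Training a neural detector, farm-scale accuracy studies and
deployment hardware are out of scope; the provider contract is the seam
where a trained detector would plug in.

## Voting fusion and its reliability model

A cycle is N frames (default 3) of one nest at `sample_interval` (default
10 s) spacing. Presence fusion votes at the nest level: present iff ≥ T
(default 2) frames contain a detection. The analytic reliability is the
binomial tail Σ_{k=T}^{N} C(N,k) P_d^k (1−P_d)^(N−k); it assumes per-frame
outcomes are independent, which the sampling interval is chosen to justify
(interference such as a pigeon standing over the nest is transient relative
to 10 s). `simulate_cycles` draws Bernoulli frames and converges to the
complement of this tail; the synthetic generator applies the same
Bernoulli model to whole images.

Count fusion generalises the vote to per-egg granularity, which the
nest-level statement underdetermines; the algorithm is a package design
choice: detections of all frames are processed in descending confidence
(ties: lower frame index, then input order) and greedily joined to the
nearest existing cluster within `match_radius` (default 40 px at
1920×1080) that has no member from the same frame, else they seed a new
cluster. Clusters with ≥ T distinct supporting frames each contribute one
egg. This is deterministic, O(k²) in the number of detections, and filters
single-frame spurious detections by construction. Frames whose processing
fails count as "no detection" votes rather than aborting the cycle.

Boundary: persistent occlusion (an interferer present in a majority of
frames) defeats any T-of-N vote; the generator reproduces it as
`p_occlude = 1`, and the chain then records a zero count.

## Wise-IoU v3

`wiou_v1 = exp(d²/D²)·L_IoU` with d the center distance of predicted and
target boxes and D the diagonal of their smallest enclosing box; D² is a
constant w.r.t. any differentiation. The v3 focusing coefficient is
r = β/(δ·α^(β−δ)) with β = L_IoU / mean L_IoU. The anchor property r = 1 at
β = δ fixes this algebraic form; the analytic maximum of r lies at
β = 1/ln α (about 1.56 for α = 1.9), which the property tests verify
numerically. Defaults α = 1.9, δ = 3, EMA decay 0.9 follow common usage of
the loss family and are fully configurable. The EMA is updated once per
batch with the batch mean; the first batch initialises the mean. As α → 1
the coefficient degenerates to the linear β/δ.

## SimAM

The per-neuron energy uses binary labels y_t = 1, y_o = −1 and an L2
regulariser λ (default 1e-4):
e_t(w,b) = (1−(wt+b))² + mean_{i≠t}(−1−(wx_i+b))² + λw². Its minimum has
the closed form e* = 4(σ²+λ)/((t−μ)²+2σ²+2λ). With mean and variance taken
over the *other* M−1 neurons (`exclude_target=True`) the closed form is the
exact minimiser, and the test suite checks it against Nelder-Mead
minimisation to 1e-5. The default weight path uses the over-all-M channel
statistics instead — the standard fast approximation, O(M) per channel —
because for realistic channel sizes the difference is negligible while the
exact form costs O(M²) naively (the vectorised leave-one-out form is
provided anyway). Weights are sigmoid(1/e*), strictly inside (0,1);
variance is biased (1/M), consistent with the over-all-mean convention.

## Barcode pipeline

All stages operate on 8-bit grayscale with 0-based, top-left-origin
coordinates and edge-replicating borders.

- **Grayscale**: Y = round(0.299R + 0.587G + 0.114B) (ITU-R BT.601). A
  variant with a 0.229 red weight circulates in print; it is selectable
  (`PRINTED_VARIANT`) but its weights sum to 0.93, so it darkens the image
  and is not the default.
- **Median filter**: 3×3 window, edge replication — removes impulse noise
  while preserving the bar/space step edges the decoder needs.
- **OTSU**: exhaustive scan of t ∈ [0,255] maximising w0·w1·(μ0−μ1)²;
  class 0 is "≤ t"; ties break to the smallest t. A second implementation
  computing class statistics from raw pixels serves as the test oracle.
- **Canny**: Gaussian smoothing (σ = 1.4), 3×3 Sobel gradients, 4-sector
  non-maximum suppression (ties broken by a strict comparison on one side
  so step edges thin to a single pixel), double threshold 50/150 on the
  0–255 scale, 8-connected hysteresis.
- **Contours**: Moore-neighbour boundary tracing with Jacob's stopping
  criterion, one external boundary per 8-connected component, oriented so
  the shoelace area in (x = col, y = row) coordinates is positive. Under
  this pixel-center vertex convention a filled w×h rectangle's boundary
  encloses (w−1)(h−1).
- **Screening**: minimum-area rotated rectangle per contour (via shapely's
  rotating-calipers `minimum_rotated_rectangle`), kept if the rectangle
  area is ≥ 0.1 % of the image and the long/short ratio is within ±25 % of
  2.0; candidates sorted by area, largest taken as the label.
- **EAN-13 decode**: the candidate region is rectified (axis-aligned crop,
  or rotation by the rectangle angle for in-plane-rotated labels), then ≥ 5
  evenly spaced scanlines across the central band are each re-binarised
  with OTSU on their own histogram, measured against the 95-module
  structure (3 guard + 42 + 5 center + 42 + 3 guard), and decoded — left
  six digits via L/G patterns whose parity sequence yields the implicit
  leading digit, right six via R patterns. Digits are majority-voted across
  scanlines and the weighted-sum check digit is verified. Failure modes are
  explicit: no guard structure on any scanline → `NoBarcodeError`; decoded
  digits failing the checksum → `CorruptCodeError`. Decoding is implemented
  from the symbology definition rather than delegated to a library decoder,
  so the chain is self-contained and each failure mode testable; the
  renderer is its exact inverse and the round trip is property-tested,
  including under 1 % salt-and-pepper noise after median filtering and
  under an exhaustive single-module corruption sweep.

## Position codes

8 digits, two per field: house 1–25, cage 1–4, group 1–99, nest 1–6 (cage
keeps two digits although its range needs one; the layout is preserved as
designed). The EAN-13 embedding uses a fixed 4-digit prefix, default
"2000" in the restricted-distribution numbering space so cage labels never
collide with retail articles; prefix mismatch on a checksum-valid code
raises a foreign-barcode error. parse/format are exhaustively inverse over
all 59,400 valid codes.

## Reference detector

Grayscale → OTSU → 8-connected components → per-component screening: pixel
area within [min_area, max_area], min-area-rectangle axis ratio ≤ 1.8,
fill ratio (area / rectangle area) ≥ 0.70. A perfect ellipse fills its
min-area rectangle at π/4 ≈ 0.785, so the fill floor sits below that value
with margin for rasterisation; confidence = fill × (short/long), threshold
0.25. `detector_config_for` derives the area band from a scene spec's egg
geometry so the same code runs at any scene scale. The detector is
deliberately simple plumbing — it exists so the fusion, positioning and
record stages can be exercised end to end, not as a detection-accuracy
contribution.

## Synthetic scenes

What is emulated: 1920×1080 frames; flat nest background (gray 90) with a
dark wire grid (pitch 120 px, 3 px, gray 40) drawn behind the eggs; 0–6
egg ellipses (long half-axis 26–40 px, axis ratio 1.1–1.6, albedo 205–235
with mild radial shading and a slight warm tint), placed with Chebyshev
separation so truth boxes are pairwise disjoint; the rendered cage label
top-right at ~2:1 backing aspect (module 4 px, quiet zone 11 modules);
optional salt-and-pepper noise; cycles of 3 frames with per-frame egg
jitter (≤ 8 px) and all-or-nothing nest occlusion by a large gray blob
with probability `p_occlude`. Occlusion, layout and noise draw from
independent sub-streams of one seed, so layouts are comparable across
occlusion settings and every render is bit-reproducible.

What is not emulated: lighting gradients and reflections, feathers, feed
and droppings, perspective and lens distortion, partial egg occlusion by
wires (eggs are drawn over the grid by default), motion blur (available as
an option in spirit but off, since transient blur is already covered by
the voting model), and the visual variety of real nests. Passing tests
therefore demonstrate the correctness and internal consistency of the
measurement chain under its stated assumptions — not field accuracy, which
depends on a trained detector and real imagery.

Problem sizes: tests and the acceptance checks run scenes at half scale
(960×540, geometry scaled proportionally, cluster match radius 20 px) —
100 full end-to-end cycles plus per-module suites complete in about a
minute; the 10⁴-cycle occlusion statistics run at the Bernoulli-flag level
(the same per-frame model the renderer draws from), where image content
adds nothing to the quantity being measured.

## Degenerate inputs and tie-breaks

Zero-area boxes are rejected at construction. Channels need ≥ 2 neurons.
Single-valued histograms raise rather than return an arbitrary threshold.
Empty detection batches raise; an uninitialised or zero EMA mean raises
before forming the anomaly ratio. OTSU ties go to the smallest threshold;
Canny NMS ties keep exactly one of two equal neighbours; cluster-assignment
ties in count fusion resolve by confidence, then frame index, then input
order. The record store is append-only: re-inspection of a nest adds a row
(id strictly increasing, gap-free) rather than updating, and zero counts
are stored.

## Known limitations

- The classical reference detector assumes bright eggs on a darker nest;
  it is not robust to textured backgrounds and is not meant to be.
- Barcode rectification handles in-plane rotation only; perspective
  distortion is out of scope.
- The binomial reliability model needs frame independence; correlated
  interference (persistent occlusion) is a documented failure boundary,
  not a solved case.
- The EAN-13 decoder requires the label to subtend ≥ 95 pixel columns
  after rectification (≥ 1 px per module).
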