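# Methods

This note records the models, conventions and numerical choices behind
`thermoroi`, and what the synthetic phantoms do and do not demonstrate.

## Conventions

Coordinates are (row, col), 0-based, origin at the top-left pixel
center; larger row = lower in the image. A positive rotation angle
turns the +col axis toward the +row axis. A pixel belongs to a
parametric shape iff its center lies inside or on the boundary
(`thermoroi.shapes`). Thermal TIFFs map integer counts to Celsius via
`°C = count × scale + offset` (defaults 0.01 / 0, sidecar-configurable);
CSVs are already Celsius. ROI sets persist as JSON (parametric
geometry) plus a 16-bit label-mask TIFF (pixel value = label, the
authoritative rasterisation), so write→read round-trips both exactly.

The 44 labels: right hand 1–8, left hand 9–16, right foot 17–21 (toes)
and 27–32 (ball-of-foot circle + 2 quads, heel circle + 2 quads), left
foot 22–26 and 33–38, right shin 39–41, left shin 42–44. Labels are
anatomical: the hallux is always `toe_1` and `*_quad_1` is the medial
quadrilateral, so identities survive left/right mirroring. Within one
image, ROI masks are made pairwise disjoint by label order (earlier
labels keep contested pixels) and clipped to the segmented foreground.

## Segmentation

Thermal images binarise by *local adaptive thresholding*: pixel is
foreground iff it exceeds the Gaussian-weighted mean of its
neighbourhood by more than a sensitivity offset. The neighbourhood
covers 1/16 of the image read as an **area** fraction — window side
`round(sqrt(H·W/16))`, forced odd (≈ 71 px at 320×256), σ = window/6,
kernel truncated at the window half-side, symmetric-reflection borders.
The linear reading (side = `round(max(H,W)/16)` ≈ 20 px) is selectable
(`segmentation.neighborhood_measure`) but degenerate for solid limbs: a
window much smaller than the limb makes the local mean equal the pixel
value, so interior classification reduces to a coin flip on sensor
noise and the uniform background splits ~50/50 into speckle that can
out-size the limb component. The area reading keeps enough background
in view from every interior pixel.

The sensitivity offset (default 0.1 °C ≈ 5× a 20 mK NETD) exists only
to absorb sensor noise on the uniform background; at offset 0 all ties
are background, so a constant image yields an empty mask, and adding a
constant to every pixel never changes the result. Visual images
binarise by Otsu's threshold on Rec.601 luminance (exhaustive 256-bin
between-class-variance scan; the brighter class is foreground unless
configured otherwise). `clean_mask` keeps the k largest 8-connected
components above `min_area` (default 100 px) and fills background
cavities smaller than `min_area`; it is idempotent.

## Hand cascade

`opening_profile` computes A(r), the foreground area after opening with
a disc SE of radius r (pixel (i,j) ∈ SE iff i²+j² ≤ r²), for
r = 1..r_max (default: half the shorter bounding-box side). Openings
are computed exactly through two squared Euclidean distance transforms
(verified pixel-identical to erosion∘dilation). Rasterised discs of
consecutive integer radii are not nested as operators, so the exact
opening area can transiently regain a pixel or two; the profile stores
the running-minimum envelope so A(r) is non-increasing, which the drop
detector assumes.

`finger_radius` evaluates the moving-window variance V(r) over windows
of N samples (N = 5 by default; the window spans r−N/2..r+N/2 and the
divisor is N−1; μ is the window mean of A). Starting from the midpoint
of the *non-zero support* of A(r) — the extinction tail past the
largest surviving structure carries no shape information and would drag
the midpoint off the plateau — and walking toward r = 0, the mean V of
the first three windows sets the reference; the first r with
V > reference × factor is the finger radius. The factor default is 20:
on the step-profile oracle (drops at 3–20, N ∈ {4,6}, 50 white-noise
seeds per case) a factor of 5 lands in the drop's window support only
~91% of the time, because window-variance ratios on a noisy plateau are
heavy-tailed; at 20 the rate is ~99.7%, while the drop-to-plateau
variance ratio (~10³) leaves detection untouched. The detector also
accepts plain arrays, since noisy test profiles cannot be represented
by the (correctly monotone) profile type.

Finger naming sorts blob angles at the palm centroid; the pair bounding
the largest circular gap subtends the widest angle (thumb + little
finger); for a right volar hand the thumb is the anticlockwise end of
the span, mirrored for the left; the rest follow in angular order. Ties
closer than 0.5° are rejected as degenerate. Palm anchors are the
major-axis ∩ blob-boundary intersections nearest the palm centroid
(second-moment eigenvector; isotropic blobs tie-break to vertical). The
palm template (anchors + three quadrilateral ROIs, shipped as a
versioned constant, user-replaceable via JSON) maps onto the image by
the unique 3-point affine.

Fingertip circles: circle Hough over radii 0.25–0.6× the blob's
minor-axis width on the blob's boundary edge map, using **raw** vote
counts (per-perimeter normalisation lets tiny circles nestled in the
base-cut corner outscore the fingertip cap). Candidates must lie ≥ 90%
inside the blob — a half-outside circle hugging the apex collects
spuriously many boundary votes — then candidates within 85% of the top
vote compete by distance to the fingertip (the boundary point farthest
from the palm centroid), ties to the larger radius.

## Shin cascade

The medial line takes the midpoint of the longest foreground run per
row (stays inside concave masks); the orientation is the least-squares
line col = a·row + b, with rows whose run is shorter than 0.7× the
median excluded from the fit (corner rows at the limb's ends have
midpoints off the axis and would bias the slope under rotation — the
invariant "rotating the limb by θ rotates the ROIs by θ" holds to ~1°
only with this trim). Reference points sit at arc lengths {half ROI
height, L/2, 3L/4}; rectangles use width 0.6× the local run width,
height 0.12× the line length, width axis perpendicular to the line, and
shrink in 3% steps (warned) if more than 1% of their raster falls
outside the limb. Left/right assignment is by centroid column in viewer
orientation (smaller column = right shin).

## Foot cascade

Registration: exact solve for 3 landmark pairs, least squares for more;
collinear or duplicate points are rejected, and the max residual is
recorded. Warping is inverse-mapped bilinear resampling. Vertical
alignment rotates the dominant covariance eigenvector to the row axis;
the 180° ambiguity puts the half of the width profile with the smaller
mean pixel-count width at the top (toes); masks rotate with order-0
interpolation and shapes map back to the original frame analytically
(rotations are similarities, so circles stay circles).

Toe delineation: LoG (σ = 2) zero crossings (sign change to a
4-neighbour with jump > 0.5 luma, keeping the smaller-|LoG| side),
restricted to the upper half of the foot, skeletonised, outer contour
band (±2 px) removed. Chains shorter than 10 px or with mean local-peak
|LoG| below 5 (the lobe amplitude next to the crossing — the response
at the crossing itself is ≈ 0) are dropped as illumination artefacts.
The outer contour is restored, endpoint edgels (exactly one 8-neighbour)
link by a straight line to the nearest edgel of a different chain
(lexicographic tie-break), and enclosed areas are flood-filled on the
upper-half crop, so the main foot interior (touching the crop boundary)
never counts as closed. Closed regions are labelled 4-connected —
regions bounded by 1-px 8-connected chains are only separated under the
dual connectivity. The five largest are the toes, opened with a disc of
radius 3, ordered so `toe_1` is the hallux.

Placement: β = 0.3, α = 0.25, τ = 0.35× the foot's row extent (all
config keys). The toe reference point is (mean toe bounding-box center
row, mean toe centroid column). The circle scan runs bottom-up and
stops at the first row where the Euclidean center-to-reference distance
is ≤ τ (exact equality is measure-zero on an integer grid). Initial
quadrilaterals are axis-aligned squares of side α·W<sub>r*</sub>; toe
overlap moves the top edge down 1 px per step, background overlap moves
the outer vertices diagonally toward the center; shrinking below 25% of
the initial area reports the quad missing; quad rasters also subtract
the circle so the set stays disjoint. The heel anchor is the
lowest-centered circle-Hough candidate (diameters 0.5–1.0× the median
foot width) on the Sobel edge map of the masked thermal image
(threshold: 90th percentile inside the mask); candidates below half the
top vote are not considered circles. Per-stage failures yield partial
results with a machine-readable report; a missing toe leaves the
remaining ROIs in place.

## Evaluation

Dice uses exact integer counting; empty∧empty ≡ 1, empty∧nonempty ≡ 0.
`pairwise_dice` strata are human–human and algorithm–human; labels
missing from one member of a pair are excluded and reported. The sign
test counts |dᵢ| > tolerance (default 0.55 °C), drops exact ties, and
returns the exact two-sided binomial p (one-sided variants by flag);
`scipy.stats.binomtest` is the engine, verified against full
enumeration for n ≤ 30. Success tallies compute 100·correct/total per
group and overall.

## Phantoms

Phantoms are parametric-geometry renders with exact ground truth, at
320×256 (the sensor aspect of a 20 mK NETD camera class), background
22 °C, additive Gaussian noise SD 0.02 °C, seeded end to end.

* **Hand**: palm ellipse (33 °C dome, −1.5 °C at the rim) + forearm
  stub + five capsule fingers (half-width 7 px) cooling toward the
  tips; left hands are exact mirrors. Truth fingertips are the capsule
  end-cap discs. Truth palm ROIs apply the anchor rule to the ideal
  noise-free silhouette (open at the finger scale, intersect each
  finger's major axis with its boundary) — the same definition the
  extraction uses, evaluated on exact geometry, because the
  opening-based split systematically places blob bases a few px outside
  the palm rim and that offset is a property of the method, not an
  error of the extraction.
* **Shin**: two tapering near-vertical trapezoids with a warm medial
  ridge; truth rectangles follow the placement rule on the analytic
  geometry, emulating the per-row horizontal-span width convention.
* **Foot**: a single foot, toes up, skin only ~2 °C above background
  (the poor contrast that forces the visual route) with a warmer heel
  pad disc for the thermal Hough stage. The pseudo-visual image lives
  on its own 400×320 camera grid related to the thermal grid by a known
  similarity (scale 0.64, rotation 2°), emitted as 4 landmark pairs.
  Groove and crease shadows render with a sharp edge on one side and a
  long linear fade on the other, so each skin fold yields a single edge
  chain as in photographs; the folds form a connected web (grooves run
  into the metatarsal creases, the outer creases dip steeply to the
  foot margin), and weak short streaks exercise the spurious-edge
  filter. The sole widens from the metatarsals toward the heel so the
  toe half of the width profile is the narrower one.

What phantom recovery shows: the full cascades re-derive all 44 ROIs
with per-label Dice ≥ 0.7 (hands, shins) / ≥ 0.6 (feet) across 20
seeds and sides, with zero ROI–ROI or ROI–background overlap. What it
does not show: robustness to clutter, pose far outside the acquisition
protocol, amputated digits, real skin texture, or real illumination —
the phantoms emulate protocol-compliant acquisitions with clutter-free
backgrounds, and the groove/crease shading is stylised.

## Problem sizes

The default test suite and acceptance script use 320×256 images, 20
phantom seeds per region, 300–1000 random mask pairs for the Dice
oracle, 500 random affines, and 1800 step profiles for the detector —
sizes chosen to exercise every code path at interactive runtimes.
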