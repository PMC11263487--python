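# Methods

This note documents the models, numerical choices and open design
decisions behind `odontomech`, and what the synthetic test bed does and
does not establish about real dentitions.

## Lever model and units

The jaw is modeled as a static lever in a single right-handed frame with
millimeter coordinates (medical-imaging inputs are normalized to RAS on
read; LPS is assumed for Slicer fiducial files without a coordinate-system
header, matching recent Slicer defaults). All lever arms are straight 3-D
Euclidean distances from the jaw joint: to the muscle insertion
(in-lever), the crown tip (out-lever), the crown base (tooth position) and
the jaw tip (jaw length). No along-jaw arc length is used anywhere.

Per tooth, `F_tooth = Σ F_in·sin(α)·(in/out)` summed over up to three
closing muscles, and `σ = F_tooth / SA_tooth` with the surface area the
exact sum of triangle areas. Angles are accepted in degrees at every
interface and converted once internally.

Defaults, chosen to make a bare run a pure mechanical-advantage model:

| parameter | default | meaning |
| --- | --- | --- |
| `input_force` | 1 N | static bite force per muscle |
| `insertion_angle_deg` | 90° | perpendicular pull, sin α = 1 |
| `pennation_angle_deg` | 0° | parallel-fibered muscle |
| `f_max` | 0.2 N/mm² | maximal isometric muscle stress |

The insertion angle is measured at the insertion point between the
muscle's line of action (insertion → origin) and the in-lever line
(insertion → jaw joint); this makes the 90° default the maximal-torque
configuration, which is the only reading consistent with sin(α) scaling.
When both a direct input force and volume parameters are given, the
volume-based (physiological cross-sectional area) estimate wins and a
notice is logged: explicit anatomy beats an assumed constant. The model is
static only — no gape angle, closing velocity, or lateral/antero-posterior
excursion — and single-cusped: multi-cuspid crowns get one consensus tip.

## Crown axis, tip and base

The crown's long axis is the eigenvector of the *surface-measure*
covariance (exact per-triangle area integrals) whose eigenvalue is most
isolated from the other two. For any surface of revolution the two
transverse eigenvalues coincide exactly, so the isolated eigenvalue marks
the symmetry axis regardless of aspect ratio; selecting the dominant
eigenvector instead fails for crowns wider than roughly 2.2× their height,
where the transverse spread exceeds the axial spread. Surface integrals
(rather than raw vertex scatter) make the axis independent of how the
surface happens to be triangulated. Isotropic meshes (all eigenvalues tie
within 1e-9 relative) warn and fall back to a deterministic tie-break:
the direction most aligned with the jaw frame's vertical (the normal of
the joint/jaw-tip/first-insertion plane), then the lowest eigen-index.

Orientation along the axis follows a proximity rule: of the two extreme
points of the vertex projections, the one nearer the jaw line — the
clamped orthogonal projection of the crown centroid onto the joint→tip
segment — is the base side. The base point is then the first ray–mesh
intersection walking along the axis from 10% of the axial extent outside
the crown ("slid until it contacts the tooth", landing at the center of
the base); the tip candidate is raised 10% of the axial extent beyond the
far end and snapped to the nearest surface point. The 10% raise is a free
parameter with no canonical value; it is large enough to clear flank
vertices and small enough to stay near the apex. If the base ray misses
(pathological concavity) the extreme vertex is used with a warning.
Recurved crowns whose apex leans toward the jaw line can defeat the
proximity rule; `flip_tip_base` (or per-tooth flip overrides) exchanges
tip and base, after which all downstream traits are recomputed.

Ray casting and nearest-surface-point queries are done with exact
vectorized per-triangle arithmetic (Möller–Trumbore; Ericson's closest
point on triangle) — tooth meshes are small enough that no spatial index
is warranted.

Height is the straight tip–base distance (not arc length). Width is the
maximum caliper diameter of the vertices in the basal 10% axial slab,
projected onto the plane normal to the tip–base direction; for a cone this
equals the basal diameter 2r. "Width" has no standard operational
definition for teeth; the basal-slab choice is robust for recurved crowns
(the slab fraction is an explicit argument). Aspect ratio is height/width
by construction.

## Labelmap surfaces

Labeled volumes are converted to one mesh per nonzero integer label by
extracting the exact voxel-boundary surface of the binary mask (cell faces
between the label and its complement, in physical coordinates via the
volume's spacing/origin/direction). This is deliberately not a smoothed
isosurface: the result is deterministic, watertight, and metrically exact
for voxel geometry (one unit voxel has area exactly 6), at the cost of
staircase artifacts that mildly inflate the area of smooth anatomy. Labels
producing an empty surface are skipped with a warning.

## Functional homodonty

Residuals are the ratio of each stress to the jaw median — a ratio, not a
difference, so the analysis is exactly invariant to rescaling all stresses
(units cancel). The null distribution subsamples ⌊n/2⌋ teeth without
replacement and renormalizes by the subsample median, 10 000 repetitions
per jaw (pool size reps·⌊n/2⌋); jaws with fewer than 4 teeth are skipped
because half-subsampling is degenerate there.

The threshold step runs 2-cluster k-medoids on 100 random 5000-residual
subsamples (without replacement, clipped to the pool size) and averages
the mean of the two cluster medoids. In one dimension the optimal
2-medoid partition is contiguous in sorted order and the best medoid of a
contiguous run is its lower median, so the solver sorts and scans all
split points with prefix sums — the *global* optimum of the k-medoids
objective, with none of PAM's seed sensitivity. The test suite retains an
exhaustive medoid-pair search as an independent oracle. "Cluster centers"
is read as the medoid values, since medoids are the centers of k-medoids.

Classification is two-sided: heterodont iff residual > upper or
< lower. The lower cutoff defaults to mirroring the upper on the log
scale (`lower = 1/upper`). An alternative `reciprocal` mode re-runs the
whole k-medoids procedure on the reciprocals of the pool and inverts the
cutoff; it is not the default because on jaws with the ordinary lever
stress gradient plus a strong high outlier it can invert to a lower
threshold at or above 1, which flags most of the jaw and breaks the
intended lower < 1 < upper ordering. `off` disables the lower cutoff.

The average squared residual is literally mean(residual²) (`center="none"`);
mean((residual−1)²) is available as `center="one"` for users who want a
divergence measure that is 0 for a perfectly homodont jaw.

Degenerate pools — all residuals identical up to a 1e-9 relative spread —
collapse both thresholds to the common value (padded by the same relative
tolerance so rounding-level scatter stays inside the band) and every tooth
is homodont. The tolerance exists because stresses that are equal in exact
arithmetic differ by a few ulps after the geometry pipeline.

Randomness: one master seed; each jaw group draws its own substream keyed
by (seed, CRC-32 of the group label), so adding or removing a jaw never
perturbs the others and the entire pipeline is bit-reproducible.

## Synthetic test bed

The generator builds a straight jaw (joint at the origin, tip on +x) with
conical teeth planted along it and a single insertion point near the joint
— the configuration of a simple lower-jaw bite model. Defaults describe a
small vertebrate jaw: 20 mm long, ten 2 mm cones of 0.5 mm basal radius,
insertion 3.35 mm from the joint; tests use 12–50 teeth and jaw lengths up
to 150 mm where a scenario needs more room. Every quantity the pipeline
measures is also computed here from closed forms (capped-cone area
πr√(r²+h²)+πr², straight-line levers, width = 2r), deliberately *not*
through the geometry/biomechanics modules, so ground truth is an
independent oracle. `inject_outlier` retunes one tooth's radius (height
and levers untouched) so its stress is a chosen multiple of the jaw's
unmodified median; `calibrate_homodont` does the same for every tooth to
produce an exactly stress-equalized jaw.

What passing these tests shows: the measurement chain recovers known
geometry to within mesh discretization error (≤2%), the lever identities
hold exactly, the classifier finds 5× stress outliers reliably and never
flags a stress-equalized jaw. What it does not show: performance on real
crowns — curved, asymmetric, worn, or multi-cuspid teeth, segmentation
noise, and non-straight jaw rami are all absent from the cone world, and
the tip/base proximity rule in particular is only exercised on cones with
modest (±20°) tilts.

## Problem sizes and runtime choices

Default test and acceptance runs use cones of 64–512 segments, jaws of
10–50 teeth, the reference analysis parameters (10 000 bootstrap reps,
5000-residual subsamples, 100 k-medoids repeats), 100-seed recovery
experiments, and a 100-cone random-pose suite; the bootstrap and k-medoids
steps are fully vectorized, so a complete dentition analysis takes well
under a second per jaw and the whole acceptance script under a minute on
one CPU.

## Known limitations

- Static, single-point bites; no dynamics, no multi-cusp stress sharing.
- The axis finder assumes a prolate or axially symmetric crown; thin
  blade-like teeth can yield the blade normal instead of the length axis.
- Voxel-boundary surfaces overestimate the area of smooth anatomy by a
  bounded staircase factor; meshes from proper surface reconstruction are
  preferred when available.
- The two-sided lower threshold is an interpretation (the classical
  procedure defines a single upper cutoff); its `mirror_log` default is a
  package choice, documented above.
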