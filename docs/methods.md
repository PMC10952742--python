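# Methods

## Spatial definitions

All coordinates are continuous μm, 0-based at the ROI corner, z
increasing with imaging depth. A microglia is **CAM** when its reference
center lies strictly within `r_assoc` (default 10 μm) of the centerline
of an eligible vessel — one whose locally interpolated diameter at the
nearest centerline point is strictly below `d_vessel_max` (default
10 μm). It is **PEM** when the center lies strictly within `r_assoc` of
the nucleus center of a pericyte residing on an eligible vessel. The two
labels are independent. The reference center is the nucleus center in
fixed-tissue mode and the soma center in in-vivo mode (a criteria flag);
the synthetic generator sets the two equal.

Boundary handling: the criterion is a strict inequality (`< 10 μm`), so
a distance of exactly 10 μm is not an association. Ties at the boundary
are measure-zero for continuous coordinates; an inclusive mode exists
behind `strict_inequality=False`. Equidistant pericytes are resolved
toward the lowest `cell_id` for reproducibility. Vessel distance is to
the centerline, not the wall; "local diameter" for eligibility is the
interpolated diameter at the foot point of the projection, since the
classification must work on networks whose diameter varies along a
segment.

Distances are full Euclidean in the dimensionality of the cell table:
3-D for in-vivo coordinates, 2-D for projected/fixed-tissue tables
(`z` column absent or NaN). Mixing dimensionalities in one table is an
error rather than a silent cast.

## Chance model

The null asks how many PEM would arise if microglia were positioned
independently of pericytes. Per iteration the observed number of
microglia is repositioned uniformly in the ROI box and classified
against the pericytes; the default conditions on the observed pericyte
pattern (`microglia-uniform`), which is the more conservative null
because it inherits any clustering of the real pericyte pattern. A
`both-uniform` mode also repositions pericytes (count preserved); it is
the variant with a closed-form oracle, P(PEM) = 1 − exp(−λ_p π r²) in
2-D, and is used for oracle tests. Edge handling defaults to `clipped`
(associations evaluated as-is inside the box, matching what a naive
per-ROI simulation does); `toroidal` (periodic distances, exact match to
the closed form) and `reflecting` (mirror-image pericytes across faces)
are available where edge effects must vanish. The pericyte-on-vessel
constraint is *not* imposed in the null: the observed pericyte positions
already encode vessel residence, and the null is about the microglia.
Default 1000 iterations; the standard error of a ~1.5% proportion over
~100 microglia is then far below reporting precision. The enrichment
report pools replicates as mean(observed)/mean(expected) and delegates
the paired comparison to the Wilcoxon signed-rank test (scipy).

## Vascular tree and widths

Branch order is breadth-first depth over the segment adjacency graph
from a root segment (largest-mean-diameter arteriole by default): the
root is order 0, every segment reached across a shared node gets its
parent's order + 1. Cyclic graphs are refused unless a spanning-tree
mode is requested.

Width is measured only on capillary-eligible hosts (< 10 μm), at least
10 μm of arclength from any junction (branchpoint exclusion; the
protocol excludes branchpoints without giving a distance, so 10 μm — the
one length scale the analysis uses throughout — is the default). P and
PEM widths use, in fixed-tissue mode, the mean of two diameters sampled
at ±4 μm on either side of the pericyte soma (soma diameter ~5–6 μm, so
4 μm clears the soma with margin); in in-vivo mode, a single diameter at
the soma center. Whether the in-vivo PEM rule should use one line or the
two-line average is ambiguous in the source protocols; both are
implemented and mode-selected rather than guessed. CAM width is the
diameter at the microglia's centerline projection and is only taken for
CAM more than 10 μm from every pericyte, to avoid contaminating the CAM
group with PEM sites. VO ("vessel only") sites are, per capillary
segment, the centerline point maximizing clearance from every soma,
accepted only if that clearance exceeds 10 μm. Group means require a
minimum of 4 measurements per location type per scene (2 for gain/loss
pairs); the omnibus contrast is a Friedman test, the gain/loss contrast
a paired t-test (both scipy).

## Tracking

Cells on consecutive days are matched greedily by ascending distance
(mutual nearest neighbor) within `max_displacement` (default 15 μm; the
tracking literature gives no tolerance, so the bound is exposed and the
generator's jitter keeps true displacements well under it). In the
regime displacement ≪ inter-cell spacing this equals the global optimal
assignment, which a test verifies against `linear_sum_assignment`.
Retention of a day-0 PEM means its tracked microglia is within
`r_assoc` of *any* pericyte on the later day (the definition used for
the published retention curve); the strict same-partner variant is
reported alongside and can never exceed it. A day-0 PEM whose microglia
cannot be followed counts as not retained — the conservative reading of
manual tracking. Gain/loss events are per-pericyte `has_pem` transitions
(gained / lost / stable / transient); per-day PEM-proportion curves can
be compared across days with repeated-measures ANOVA (statsmodels).

## Intensity

Quantification mirrors the marker-coverage protocol: select the focal
planes containing the pericyte, sum-project them (max projection for
tracing), subtract a rolling-ball background (radius 50 px,
scikit-image), expand the traced outline by 0.25 μm by Euclidean
buffering (shapely) — physical units, not pixel dilation — and take the
mean over pixels whose centers fall inside the expanded polygon. For
radii above ~12 px the background uses the classic shrink acceleration
(minimum-filter downscale, ball on the small image, bilinear upscale);
the contracts asserted are behavioral — a constant image maps to ~0 and
sub-radius blobs are preserved within 5% — not byte-equality with any
particular implementation. Images are treated as floating point
throughout.

## Synthetic scenes: what they emulate, and what they do not

The generator grows a vascular tree (penetrating arteriole descending
into the volume, bifurcating capillaries, one ascending venule), places
pericytes at random capillary arclengths with 25 μm minimum along-vessel
spacing (sparse "bump-on-log" somata), and places microglia as a mixture:
uniform, vessel-attracted (offset within 8 μm of a capillary point) and
pericyte-attracted (offset within 8 μm of a pericyte nucleus, hence
guaranteed PEM at the strict 10 μm criterion). Vessel-attracted microglia
are rejected out of pericyte neighborhoods so that PEM enrichment is
governed by the pericyte-attraction fraction alone. All randomness flows
from one seeded `numpy` generator per top-level call; identical
config + seed reproduces scenes byte-for-byte.

Default conditions were calibrated once so that a full-thickness 2-D
projection of an 800×600×60 μm slab reproduces the reference prevalence
regime: ~98 microglia and ~24 pericytes (2-D chance level ≈ 1.5%), CAM
≈ 40%, PEM ≈ 7% — i.e. roughly 5-fold above chance. Diameters: 4.21 μm
capillary baseline with multiplicative dilations 1.16 / 1.15 / 1.21
beneath P / CAM / PEM landmarks (flat bumps of ±6 μm arclength, wide
enough that both width rules read them); 15 μm arteriole, 12 μm venule.
Time series: per-visit retention (0.81, 0.963, 0.564), compounding to
81% / 78% / 44% at days 4 / 7 / 28; gains occur at PEM-free pericytes
(rate 0.08/visit) by recruiting a distant microglia; a gain multiplies
the local diameter by 1.195 and a loss by 0.91, applied when the last
adjacent microglia departs. Stable cells jitter with 3 μm SD (with
rejection so they never cross the association radius, keeping the event
log exact ground truth); losses walk away with 15 μm SD until
unambiguously beyond the criterion. The tracking preset uses a higher
pericyte-attracted fraction so one scene carries a day-0 PEM cohort of
~32, matching the size of the cohort followed in vivo.

What passing tests on these scenes show: the classifiers, null model,
tree statistics, width rules and trackers are correct against
independent oracles and recover known generated effects at realistic
densities. What they do not show: robustness to segmentation error,
registration drift between imaging days, chromatic offsets, process-level
(non-soma) contacts, inhomogeneous cell densities across cortical
layers, or morphologically realistic vasculature (no loops, no
hemodynamics, no diving venule trees). One structural consequence worth
noting: because pericytes live on a sparse tree, the *full* distribution
of microglia-to-pericyte distances in the null regime is dominated by
distance-to-tree and is not the homogeneous-Poisson nearest-neighbor
law; only its small-distance behavior (the chance level at r = 10 μm)
matches the closed form, and that is the regime the analysis uses. The
Poisson law holds exactly for the both-uniform null, where it is tested
at Kolmogorov–Smirnov distance < 0.05.

## Numerical choices and degenerate inputs

Point-to-polyline distance is exact for piecewise-linear centerlines
(vectorized projection onto every piece), verified against dense 0.1 μm
resampling. Zero denominators yield missing values, never 0 (e.g. %CAM
with no microglia). Empty slabs, zero-density configurations and
pericyte-free tables are valid inputs with empty-but-well-formed
outputs; infeasible geometry (ROI too small for an arteriole-to-venule
path) and infeasible density (pericytes cannot satisfy spacing) raise
dedicated errors. Networks serialize losslessly to JSON; SWC export
writes one sample per polyline vertex (radius = diameter/2, vessel class
in the type field, duplicate-coordinate boundary samples at junctions so
per-segment endpoint radii survive re-import) and is exact to the 1e-6
print precision. Counting protocols use half-open tile intervals
[x0, x1) × [y0, y1), which is the algorithmic form of the "count only on
top/left margins" rule; protocol A's edge exclusion tests the nucleus
disc (default radius 3 μm, a typical nucleus radius) against the box
edges.

## Problem sizes

Test and acceptance runs use 800×600×60 μm scenes (~120 cells, ~30
segments) pooled over tens of seeds, 200–5000 Monte-Carlo iterations,
and 40-replicate acceptance pools — sizes chosen to hold sampling error
comfortably below the tolerances being asserted while a full suite run
stays in the minutes range on one CPU.
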