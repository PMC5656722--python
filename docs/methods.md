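# Methods

## Problem

Intracoronary optical coherence tomography (OCT) resolves the layered
structure of the healthy arterial wall: a bright intima, a dark media and a
bright adventitia over decaying periadventitial tissue. Where the wall is
diseased, plaque or intimal thickening blocks the view and only a single
attenuating layer is visible. `octwall` implements a two-stage analysis of
polar OCT frames: (1) simultaneous extraction of the intima–media (IM),
media–adventitia (MA) and adventitia–periadventitia (AP) interfaces with a
globally optimal dynamic program, and (2) classification of each angular
position of the wall as healthy or diseased from features derived from those
tentative contours.

## Stage one: simultaneous three-contour segmentation

**Geometry.** The lumen–intima interface is segmented first (a
single-contour version of the same DP machinery, run on the negated axial
gradient of the native polar frame; a pre-computed lumen CSV may be supplied
instead). The guidewire shadow is masked by finding the single contiguous
circular run of A-lines whose pullback-averaged intensity falls below 0.5×
the median profile (minimum run length 3; among several candidate runs the
darkest mean wins, ties to the lower start index). A lumen-flattened
sub-image `I` is then sampled: 100 equiangular columns (column 0 at the
image +x axis, half-open 3.6° arcs), each holding the radial intensity
profile from the lumen boundary down to 1 mm (`depth_px = ceil(1000/pixel)`,
so 223 rows at 4.5 µm/px and 114 rows at 8.8 µm/px), bilinearly
interpolated and edge-padded past the frame bottom (clamped columns are
flagged).

**Cost maps.** Each column of `I` is correlated with a sampled first
derivative of a Gaussian (σ = 30 µm, truncated at ±4σ, sum-corrected to
zero, reflect padding in depth) giving the gradient image `I_G`: positive on
dark→bright transitions with increasing depth, so the MA interface is a
positive extremum and the IM/AP interfaces negative extrema. `I_G` is
replicated three times horizontally and min–max normalised into the cost
pair `C± = N[0,1](±I''' _G)`. Normalisation is global over the replicated
matrix — the two maps are then exact complements (`C+ + C- = 1`) and
relative edge strength between columns is preserved, which the gradient
features of stage two rely on. Guidewire columns carry no edge information;
their costs are replaced by the row-wise mean cost of the unmasked columns
so that the optimal path interpolates smoothly through the shadow.

**Front propagation.** A cumulative cost is built over the 4D space
`(x, y1, y2, y3)` by

```
C(x,y1,y2,y3) = min_{dy1,dy2,dy3} C(x-1, y+dy)
              + Σ_n ω_n (1 + κ·|dy_n|) (C^±(x, y_n) + C^±(x-1, y_n+dy_n))
```

with `C+` for interfaces 1 and 3 and `C-` for interface 2, weights
ω = (0.2, 1, 1), smoothness κ = 0.1, 2N+1 = 7 reachable neighbours per
column, and the admissibility constraint `y1 + g ≤ y2 ≤ y3 − g` with
g = 45 µm (`gap_px = max(1, round(g/pixel))`). The smoothness penalty uses
`|dy|`: penalising non-horizontal displacements is symmetric, and a signed
`dy` would reward downward drift. The first column is initialised to zero;
propagation is purely left-to-right, closure coming only from the
replication trick (the central third of the optimal path over `3W` columns
is kept). Backtracking starts at the cheapest admissible final state; all
ties resolve to the lexicographically smallest `(y1, y2, y3)` and then the
smallest `(dy1, dy2, dy3)`, making the output deterministic.

**Exactness and complexity.** The transition cost is separable per
interface, so each propagation step is computed exactly with three
sequential 1D relaxations (running minima over 2N+1 shifts of the state
cube) instead of a (2N+1)³ enumeration — verified against a brute-force
path enumeration on small instances. The dense state cube is O(depth³) per
column; at clinical depths this is reduced by a coarse-to-fine scheme:
block-mean depth-downsampling of the cost maps by `f = ceil(depth/32)`
(f = 4 at 8.8 µm/px, f = 7 at 4.5 µm/px), an exact DP on the coarse cube,
then a second, band-restricted run of the *same joint DP* at full resolution
within ±max(2f, N+1) rows of the (circularly smoothed) upsampled coarse
contours. Because the refinement is again a joint DP over admissible states,
the gap and per-step constraints hold by construction at full resolution; if
the band ever becomes infeasible it is doubled (this does not occur on
smooth anatomy). Small depths (≤ 32 rows) run the exact DP directly.

**Backtracking storage.** Rather than storing arg-min displacement tensors,
the per-column value cubes themselves are kept and the arg-min is re-derived
during backtracking by enumerating the (2N+1)³ candidate predecessors of the
single current state with the identical summation order — cheaper, and it
implements the lexicographic tie rule exactly.

## Stage two: healthy-region classification

**Region and features.** For each of the 100 columns, region `R` spans row
0 (the lumen) to the point 300 µm below the detected AP contour (clamped and
flagged at the image bottom). Seventeen features are computed per column:
five Haralick statistics (contrast, homogeneity, correlation, entropy,
energy) of a 16-level, symmetric, normalised grey-level co-occurrence matrix
taken at offset 1 along depth (a column is one-dimensional, so depth is the
only well-defined offset; levels are quantised over the fixed [0,1] range);
the mean squared residual of a degree-1 least-squares fit to the intensity
profile; the gradient values at the LI (row 0), IM and MA interfaces; a
monotony index (median |i − i′| where i′ is each sample's index after a
stable descending sort — 0 for a monotonically decaying profile, invariant
to monotone intensity rescaling); the sum of negative gradient values;
median intensities of the intima, media and adventitia bands; and the LI–IM,
LI–MA, LI–AP distances in µm. The rationale: a layered (healthy) wall
produces strong interface gradients, non-monotone profiles and coarse
texture, while a diseased wall attenuates smoothly. Features are min–max
normalised to [0,1] with training-set ranges (inference values clip;
zero-range features map to 0.5 with a warning). GLCM correlation of a
zero-variance region is defined as 0.

**Feature selection.** A Boruta-style procedure: on repeated random subsets
of 100 labelled A-lines, random-forest importances are compared against
column-shuffled shadow features; a feature's accumulated hit count is tested
against Binomial(n, ½) two-sided with Bonferroni correction at α = 0.01
(up to 1000 iterations per run, though decisions typically land within ~25).
A feature is *relevant* if confirmed in at least 26 of 51 repeats. The
classifier defaults to the eight relevant features (texture contrast /
homogeneity / correlation, the three interface gradients, the linear-fit
MSE and the monotony index); a switch enables all seventeen.

**Classifier.** Discrete AdaBoost (SAMME) over depth-1 decision stumps,
100 rounds, deterministic under a fixed seed (scikit-learn backend; the
fitted ensemble is exported to an explicit JSON stump list so prediction is
a plain weighted vote independent of the training backend). On separable
training data boosting terminates early, so a bundle may contain fewer than
100 stumps while recording `n_rounds = 100`. Per frame `k`, the classifier
is applied to frames `k−1, k, k+1` and each column takes the majority label;
at pullback ends the missing neighbour is dropped and a 1–1 tie keeps the
frame's own label. Finally the circular label sequence is cleaned by a flat
erosion of length K_E = 4 followed by a dilation of length K_D = 9
(anchors at floor(K/2), wraparound; guidewire columns take their nearest
unmasked neighbour's value during morphology and are restored afterwards).
Note the asymmetric kernels grow every surviving healthy run by
K_D − K_E = 5 columns.

## Evaluation metrics

Point-to-point contour error: per-column |y_auto − y_ref| × pixel size,
mean ± SD per interface, in µm, restricted to annotated columns. Layer
thickness (intima y1, media y2−y1, adventitia y3−y2): absolute error,
signed bias, 95 % limits of agreement (bias ± 1.96 SD) and error relative
to the reference thickness (zero-reference columns excluded and counted).
Healthy-arc agreement: Dice 2|A∩B|/(|A|+|B|) on angular columns (two empty
regions score 1 by convention), plus accuracy, sensitivity and specificity
with healthy as the positive class; zero-denominator metrics are NaN with
counts intact. Guidewire columns are excluded everywhere.

## Synthetic phantom

The generator renders polar pullbacks with known geometry: a lumen with
harmonic radius perturbation, healthy arcs carrying the bright/dark/bright
triple layer (defaults 130/95/105 µm — the reference thickness scale of
healthy coronary walls — with ±8 % smooth angular modulation and bounded
frame-to-frame drift so adjacent-frame voting is meaningful), diseased arcs
rendered as a single bright slab with exponential attenuation (length
constant 260 µm, ≥ 600 µm thick) and no layering, a zeroed guidewire sector,
and multiplicative gamma speckle of mean 1 and standard deviation 0.2 (the
standard surrogate for fully developed speckle). Cohorts randomise lumen
size/phase, thicknesses (±20 %), guidewire position and wall state
(20 % fully healthy, 20 % fully diseased, 60 % partial with a drifting arc
covering 30–85 % of the circumference). Healthy arcs always satisfy the
annotation rule intima+media < 500 µm. Ground truth (lumen, interfaces,
labels) is recorded before noise.

What the phantom does *not* emulate: catheter eccentricity and tangential
incidence, beam-profile and sheath artifacts, stents, bifurcations, thrombi,
calcium pools, or healthy walls with blurred, poorly visible layering.
Passing phantom tests therefore demonstrates correctness of the algorithms
under the stated image model, not clinical-grade robustness: in particular,
misclassification on the phantom is dominated by arc-boundary columns and
the asymmetric morphological kernels (which produce false positives, i.e.
sensitivity ≥ specificity), whereas on clinical data the dominant error
mode is missed healthy tissue with faint layering (false negatives, i.e.
specificity ≥ sensitivity). The per-frame tables produced by
`octwall evaluate` make this error budget explicit.

## Numerical choices and degenerate inputs

- Constant gradient image → both cost maps 0.5 with a warning (degenerate
  frame; the DP then returns a flat minimal-roughness solution).
- All-dark frame or edge-free frame → `LumenNotFoundError`.
- Depth must allow the gap constraint (`depth ≥ 2·gap_px + 1`), else an
  explicit error.
- Cumulative costs accumulate in float64; oracle-equivalence holds to 1e-9.
- Interface indices for feature lookup are rounded and clipped to the
  region; empty inter-interface bands fall back to the single boundary
  pixel.
- The replication trick guarantees approximate closure only; a wrap step
  exceeding N would indicate a DP defect and raises a warning.

## Problem sizes used in the shipped experiments

The reference experiments run at the 512×512 / 8.8 µm scanner preset:
single-frame phantoms for contour recovery (1 noise-free + 10 speckled
seeds), 100 random frames for the constraint invariants, and a 14-pullback
training / 26-pullback testing split with 10 frames per pullback (140/260
frames) for classifier recovery. Fifty random small instances
(replicated width ≤ 6, depth ≤ 10, N ≤ 2) are enumerated exhaustively for
the oracle-equivalence check.
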