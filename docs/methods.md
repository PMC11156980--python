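# Methods

`retinaos` analyzes how orientation selectivity is laid out across the
surface of the mouse retina. Its input is the kind of dataset produced by
population two-photon calcium imaging of the ganglion cell layer during a
moving-bar protocol: for every segmented cell, a ΔF/F response matrix per
motion direction, plus the retinal coordinates of each cell and imaging
field of view (FOV) relative to the optic nerve. Because such datasets are
large and rarely deposited, the package ships a first-class synthetic
generator that emulates their statistical structure, so every stage of the
pipeline is testable end to end without any downloads.

## Coordinate and angle conventions

All geometry lives in a retina-fixed plane: origin at the optic nerve
head, +x temporal, +y dorsal, angles counter-clockwise from +x in degrees.
Motion directions are angles in [0°, 360°); orientation (axial) preferences
are axes in [0°, 180°), and all axis arithmetic is done in double-angle
space (an axis φ is represented by the unit vector at 2φ) so that φ and
φ+180° coincide. The ventral cardinal axis is the vertical 90° axis;
`deviation_from_ventral` reports the signed smallest rotation from it,
in (−90°, +90°], positive toward temporal, with the horizontal axis mapped
to +90° by convention. The ventronasal (VN) and ventrotemporal (VT)
sampling rays run from the optic nerve at 225° and 315°. Preferred
orientation is reported in motion-axis space (half the double-angle phase
of the response-weighted vector sum); the long axis of the preferred bar
stimulus is orthogonal to it.

## Per-cell tuning statistics

For each cell, responses are first normalized to ΔF/F with the baseline F₀
taken as the mean fluorescence over non-stimulus frames. The peak response
R(θ_k) to direction θ_k is the mean over repetitions of each repetition's
maximum ΔF/F inside the response window (stimulus-on plus post-offset
frames; the mean-of-per-trial-maxima reading is robust to onset jitter).
Four statistics follow:

* L_dir = |Σ_k R(θ_k) e^{iθ_k}| / Σ_k R(θ_k), with the vector-sum phase as
  the preferred direction;
* L_ori = |Σ_k R(θ_k) e^{2iθ_k}| / Σ_k R(θ_k), with half the phase as the
  preferred orientation;
* DSI = (pref − null)/(pref + null), where pref is the sampled direction
  nearest the vector sum and null its 180° opposite;
* OSI = (pref − orthogonal)/(pref + orthogonal) on the four responses
  obtained by averaging opposite direction pairs, pref being the axis with
  the largest averaged response (which may differ from the vector-sum
  phase; both are stored).

Angle arithmetic always uses the two-argument arctangent on vector
components — no slopes, no infinities. Slightly negative noisy peaks are
clipped at zero before the resultant sums. A cell responding to exactly
one direction has L_dir = L_ori = 1; this degeneracy is why selectivity is
decided by the joint significance test rather than by thresholding either
index.

Trial-to-trial reliability is the variance-ratio quality index
QI = Var_t[⟨C⟩_r] / ⟨Var_t[C]⟩_r of a T×R response matrix C; QI = 1 when
all repetitions are identical. For a multi-direction recording the
cell-level QI concatenates the per-direction matrices along time (one
"repetition" = a full direction sweep). A matrix constant in time is a
0/0 case and returns QI = 0 with a degeneracy flag rather than raising, so
batch pipelines proceed. Cells with QI ≤ 0.6 (strict) are excluded.

## Permutation significance

Whether a cell is significantly direction- or orientation-tuned is decided
by a block-shuffled permutation test. A block is one trial — the full
T-frame trace of a single bar presentation — so within-trial
autocorrelation is preserved while the trial-to-direction assignment is
shuffled. Each of 1000 permutations reassigns whole trials to directions,
recomputes the per-direction mean peak responses, and recomputes both
L_dir and L_ori from the same shuffle. A statistic is significant when the
observed value strictly exceeds more than 95% of the permuted values; ties
count against significance, which is conservative for degenerate cells
(e.g. perfectly constant responses are never significant). Under the null
this procedure passes ≈ 50/1001 ≈ 5% of cells, which the acceptance suite
verifies by simulation. Per-cell RNG substreams are derived from (global
seed, cell id), so results do not depend on evaluation order. Cells are
classed OS / DS / both / none from the pair of flags; downstream OS
analyses include cells flagged "both" (their prevalence is below 1%).

## Functional subtyping

OS cells are grouped by k-means (best of 10 restarts, k = 2…10) followed
by silhouette analysis; the k with the highest mean silhouette value
SV(i) = (b(i) − a(i))/max(a(i), b(i)) is kept (Euclidean distances;
singleton clusters score 0). Two feature spaces are used. The ON-OFF
response shape is the trial- and direction-averaged trace cropped to the
stimulus-on and post-offset windows, resampled to 24 + 16 points and
peak-normalized; on synthetic data this recovers k = 3 and the clusters
are named by centroid kinetics: a post-offset-dominant centroid is OFF, an
ON centroid retaining ≥ 40% of its onset peak at stimulus end is ONs
(sustained), otherwise ONt (transient); centroids with no clear response
are labeled "unassigned" rather than silently misnamed. The preferred
orientation feature is the double-angle unit vector; because the dominant
axis drifts across the retina, the pipeline clusters orientations relative
to each FOV's local mean axis, which exposes the orthogonal-axes
bimodality (k = 2) of the overrepresented majority and underrepresented
minority. Group membership itself is assigned by a local rule: within each
FOV the double-angle circular mean axis (dominated by the majority, since
the orthogonal minority only shortens the resultant) is the local
overrepresented axis, and cells more than 45° from it form the
underrepresented group. A permuted-data control (each feature dimension
shuffled independently across cells) reports the silhouette curve expected
from structureless data; note it destroys correlation structure, not
marginal multimodality, so it is a reference curve rather than a zero
line.

## Map statistics

Preferred-orientation axes are summarized as 10°-bin histograms per
retinal region (duplicated at φ and φ+180° for polar display), per-FOV
deviation-from-ventral versus distance from the optic nerve (double-angle
circular mean per FOV; FOVs without qualifying cells are skipped with a
log entry), and a vector flow field: the circular mean axis and resultant
length on a 100 µm grid, masking bins with fewer than 5 cells and
reporting the axis as undefined when the resultant falls below 0.1.
Regional distributions are compared with a two-sample Kolmogorov–Smirnov
test plus a label-permutation test that uses the KS D statistic
(10 000 permutations by default, add-one-corrected p).

## The concentric-map model

The geometric model states that preferred orientations are tangents of a
family of concentric ellipses: common center (the anchor), common
horizontal-to-vertical radius ratio (the aspect). The tangent at an
on-ellipse point is computed from the direction vector
(−x_r²(y−y_c), y_r²(x−x_c)), equal to the implicit-differentiation slope
−y_r²(x−x_c)/(x_r²(y−y_c)) wherever that slope is finite but well defined
at vertical tangents too. Predicted deviation-versus-distance curves come
from intersecting the family with the VN/VT rays (exact quadratic roots;
radius sweep 100–2000 µm in 25 µm steps by default). Anchoring circles on
the optic nerve predicts a constant ±45° deviation along the diagonal
rays — the tangent is always orthogonal to the radius — while a ventral
anchor makes the deviation grow with distance from the nerve.

Model fitting is a deterministic grid search (reproducibility over speed:
the score surface is cheap) over anchor position (default x ∈ [−600, 600],
y ∈ [−1200, 0] µm, 100 µm steps) and aspect (0.95–1.25, step 0.01). Each
candidate is scored by the area between the quadratic fit of the measured
per-FOV deviation curve and the quadratic fit of the model curve,
integrated by trapezoid on a 1 µm grid over the shared distance range and
summed over the two axes. Two numerical details matter: curves are
unwrapped onto a continuous branch (period 180°) before fitting, and the
model quadratic is fit only over the measured distance range — the model
curve also contains a near-tangency branch close to the anchor, where the
ray grazes small ellipses, and including it corrupts the fit.

## The synthetic retina

The generator's defaults encode the study conditions: 425 × 425 µm² FOVs
with 590 ± 170 cells; 30% OS, 12% DS, 0.5% jointly selective; OS subtype
mix ONs/ONt/OFF = 70/20/10 with von Mises orientation-gain concentrations
κ = 1/2/3 (tuning inversely ordered to prevalence); 15% of OS cells in the
orthogonal underrepresented group; and true preferred orientations drawn
from the tangent field of an ellipse family with aspect 1.09 anchored at
(−100, −400) µm — a few hundred micrometers ventral and slightly nasal of
the optic nerve. The anchor magnitude matters: it must be small relative
to FOV distances for the VN/VT tangent field to sit near ∓45° and drift
with distance; a deep-ventral anchor would instead produce a field
orthogonal to that pattern over the sampled range. FOV centers are strung
along the named sampling rays (VN/VT at 600–2000 µm on-axis; ventral and
temporal bands allow ±300 µm perpendicular scatter), mirroring how the
imaging fields were laid out; keeping VN/VT centers on the rays is also
what makes the on-axis model curve a faithful summary of per-FOV data —
centers offset by ±250 µm would inject ~20° of systematic azimuthal error,
swamping the ~1° precision that ±0.02 aspect recovery requires.

Responses are built from unit-peak kinetic templates (piecewise double
exponentials; time constants in seconds): ONs rises at light onset
(τ 0.15), sags slowly during the bar (τ 8), and decays after offset
(τ 0.6); ONt is an onset transient (rise 0.10, decay 0.35); OFF is the
same transient after offset. Each trial trace is the template scaled by
the cell's tuning gain — von Mises in double-angle space for OS cells,
cosine modulation 1 − m(1 − cos Δ)/2 (depth m = 0.8) for DS cells, their
product for jointly selective cells, flat for untuned cells — plus i.i.d.
Gaussian noise (σ = 0.1 ΔF/F). The cosine DS gain is a deliberate choice:
it is a pure first harmonic, so direction tuning contributes nothing in
double-angle space and the measured rate of jointly significant cells
stays at the false-positive level (<1%), as observed. Trial count (R = 5),
frame rate (10 Hz), trial length (40 frames; bar on frames 5–24) are
unreported experimental details set to plausible values and fully
configurable. Map noise is von Mises in double-angle space (κ = 10 by
default, ≈ 9° angular s.d.). The condition tag (NR / B2KO / DR) changes
nothing by default, reflecting the finding that the map is
activity-independent; a `condition_effect` hook exists for power
analyses.

What the generator does not emulate: optical blur and neuropil
contamination, GCaMP indicator nonlinearity, segmentation errors,
correlated (shared) noise across cells, eye-specific flat-mount
distortion, or any spherical geometry — the model plane is the flattened
retina. Passing tests therefore demonstrate the correctness and
calibration of the analysis, not robustness to those real-data artifacts.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale sizes chosen to keep the suite
fast while leaving comfortable statistical margins: ~1500 OS cells for
subtype discovery, 2000 null cells × 1000 permutations for calibration
(binomial 99% interval), 40 FOVs × 125 cells (~5000 cells) for map
fitting. Determinism is end to end: one global seed feeds per-purpose
`SeedSequence` substreams (FOV/cell sampling, per-cell response noise,
per-cell permutations, clustering restarts), and rerunning any stage with
the same seed reproduces byte-identical tables.

Known limitations: with 8 stimulus directions the vector-sum preferred
orientation carries a small aliasing bias (≤ ~6° at the default tuning
widths, zero on average over uniformly placed axes); DSI can be negative
for adversarial peak patterns because "pref" is defined by proximity to
the vector sum, not by the largest response; the KS permutation comparison
is exchangeability-based and assumes independent cells; and the grid
search resolution bounds anchor recovery at 100 µm and aspect at 0.01.
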