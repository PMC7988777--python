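# Methods

This note documents the models and numerical choices behind `notoquant`:
what each stage computes, the parameters that matter, what the synthetic
generator does and does not emulate, and the design decisions taken where
the procedure it implements left details open.

## The severity pipeline

### Segmentation

Notochord pixels are `{(x, y) : I(x, y) ≥ T}` for a grey threshold `T`.
The reference procedure set `T` manually per imaging session, and manual
thresholds remain the default mode of operation; `auto_threshold` (Otsu's
between-class-variance criterion, shifted to the middle of the histogram gap
so it composes with the `≥` inclusion convention) is an optional fallback.
`largest_component` keeps the largest 8-connected component before fitting —
8-connectivity so a tube crossing pixels diagonally stays one component.
Whether the original analysis excluded off-notochord bright debris is not
documented; the largest-component step is this package's explicit answer and
can be disabled (`keep_largest=False`).

### Centerline

The centerline is a degree-6 polynomial `y(x)` fitted by unweighted ordinary
least squares over all mask pixels — the simplest reading of "fit the
pixels": no per-column skeletonisation, no intensity weighting. Internally
the fit runs on x rescaled to [−1, 1] (`numpy.polynomial.Polynomial.fit`)
for conditioning; coefficients are reported in pixel units. The fit refuses
masks with fewer than degree+1 distinct x values. Images whose mask bounding
box is taller than wide are transposed first (the convention is a roughly
horizontal notochord), and the transposition is flagged in the output row.

Rasterisation bounds the achievable accuracy: the column-wise pixel set of a
hard-edged tube has mean within 0.5 px of the true centerline, and the test
suite holds the fitted curve to that bound over 20 random geometries with
true polynomial centerlines of degree ≤ 6.

### Profile and severity

Points along the fitted curve are taken at uniform arc-length spacing
(default step 1 px). The arc-length map is built from cumulative chord
length over a dense table (16 subdivisions per pixel of x, i.e. chord error
far below the 1e-3 tolerance the tests enforce against adaptive quadrature)
and inverted linearly; tangents come from the analytic derivative.
Intensity at each point is bilinear interpolation (exact for affine fields);
`linewidth > 1` (odd) averages that many samples spaced 1 px along the local
normal, matching the straight-line profile-line convention the pipeline
generalises. Default linewidth is 1; whether the original adaptation
averaged across the tube is not stated, so the single-sample default is the
conservative choice with the option exposed. Samples outside the grid of
pixel centres are dropped, never clamped, and counted (`n_dropped`).

**Severity** is the arithmetic mean of the retained profile intensities —
deliberately simple, and exactly the tube intensity for a noiseless
lesion-free tube (the constant-field identity test holds this to 1e-6).

### Lesion calling

The reference criterion for a lesion is qualitative — higher pixel intensity
*and* broader area under the peak. The operational rule, all constants
exposed as configuration:

* baseline `b` = median of the profile, dispersion `s` = 1.4826·MAD —
  robust against the lesions themselves occupying part of the profile;
* candidates: local maxima with value ≥ `b + k·s`, default `k = 3`;
* merging: two candidates are one lesion unless they are at least
  `min_separation` apart (default 10 px) *and* the profile returns to the
  threshold (strictly: its valley dips to ≤ `b + k·s`) between them. The
  second clause is what stops a noise wiggle on the shoulder of one broad
  lesion from being counted as a second lesion; the strict inequality keeps
  two noiseless lesions — whose valley sits exactly at baseline — distinct;
* bounds and area: each call's bounds are where its excursion above the
  baseline ends (first sample at or below `b` walking out from the peak, or
  the valley minimum if a neighbouring call intervenes); the area is the
  trapezoidal integral of `max(I − b, 0)` between the bounds;
* area floor: calls with area below `min_area` are dropped. The default is
  adaptive, `40·s`: under the pipeline's operating conditions a noise
  excursion integrates to a few `s` while a real lesion (amplitude ≥ 8
  noise sigmas, width ≥ 4 px) integrates to hundreds of `s`, so the floor
  realises the "broader area" half of the criterion scale-freely and
  degrades to zero on noiseless profiles. A fixed `min_area` (including 0)
  can be passed instead.

Height alone cannot provide a false-positive-safe rule at `k = 3`: in a
profile of 2000 iid-noise samples, some sample exceeds `b + 3s` in most
realisations, so a pure height-above-threshold caller would call lesions in
lesion-free fish routinely. With the area floor the suite verifies zero
calls in ≥ 99 % of simulated lesion-free noisy profiles of length 2000, and
≥ 95 % exact lesion-count recovery on a 50-image cohort with three implanted
lesions per fish (in fact 100 % on both at the tested seeds).

Classification by count: more than 3 lesions = *affected*, more than 5 =
*severe*, both configurable; the boundaries are strict (3 lesions is still
unaffected).

## Group statistics

Kruskal–Wallis (tie-corrected H, chi-square upper tail, df = k−1) and
Mann–Whitney U (exact null for untied samples with `n_a·n_b ≤ 400`, normal
approximation with tie-corrected variance and continuity correction
otherwise) delegate to scipy, whose implementations match the standard
formulas; the suite pins them to a hand-evaluated H = 7.2 example, a
brute-force mid-rank oracle under ties, and a full-enumeration Mann–Whitney
oracle. Dunn's post hoc is implemented here (no maintained dependency
available) in the 1964 form with the pooled tie correction
`N(N+1)/12 − Σ(t³−t)/(12(N−1))`, two-sided normal p-values and Bonferroni
adjustment `min(1, m·p)` over all m pairs. All observations identical is
treated as a well-defined degenerate case (H = 0, p = 1) rather than an
error. One-way ANOVA is a thin delegation to `scipy.stats.f_oneway` — it is
exposed because two-way reporting is common, but the rank tests are the
default for severity data.

Calibration: over 10,000 simulated null cohorts (3 groups × 10, one
continuous distribution) the test suite requires the Kruskal–Wallis
rejection rate at α = 0.05 to be within 0.01 of nominal — a band covering
both Monte-Carlo error (s.e. ≈ 0.0022) and the known slight conservatism of
the chi-square approximation at n = 10 per group (the observed rate at the
tested seed is 0.046).

## Skeletal and histological quantifications

**Vertebral severity rubric.** Score 0 for `n = 0`, 1 for `n ≤ 3`, 2 for
`3 < n < 5`, 3 for `n ≥ 5`, with `n` a fusion or cleft count. Counts are
integers, which makes the printed intervals exhaustive and non-overlapping
(score 2 is exactly `n = 4`; `n = 0` takes precedence over `n ≤ 3`).
Fusions and clefts are scored independently (the reference procedure's
wording); because it does not state how the two categories combined into a
per-fish score, `score_fish` reports both per-category scores plus their
maximum by default and offers a `combined` mode (rubric of the summed
count) — neither presented as the original's ground truth.

**TMD calibration.** An affine map `d(g) = 0.25 + (g − g_lo)·0.5/(g_hi −
g_lo)` g/cm³ HA anchored at the mean grey values of two phantoms of known
density (0.25 and 0.75 g/cm³ HA; other phantom densities can be supplied).
Values outside the phantom range are extrapolated by the same line and
flagged, never clamped — a negative density is a visible data problem, not
something to correct silently.

**Channel means.** Per-channel arithmetic means over a rectangle or mask
ROI of an RGB image. Display-time transforms in the original staining
protocols (LUT application/inversion) are treated as display transforms:
quantification operates on raw channel values.

## The synthetic generator

`generate_notochord_image` renders: a hard-edged tube (`|y − f(x)| ≤ r`
in-tube) at `tube_intensity` over `background_intensity`, plus per-lesion
Gaussian bumps `A·exp(−(x−c)²/2σ_w²)` added inside the tube only (a lesion
is a notochord feature); optional Gaussian blur (`edge_softness`) for soft
edges; iid Gaussian noise; rounding and clipping to the bit depth (8 or 16;
default 16) — a simple camera model that keeps noiseless test images
integer-exact. Geometry is validated on a dense grid: the centerline must
keep `r ≤ f(x) ≤ H − r` over the full width. Pixel coordinates are
x = column, y = row, origin top-left, centres at integers, everywhere.

Cohort generation draws, per fish: a centerline (image midline plus a
Chebyshev wiggle whose coefficient magnitudes sum to ≤ `curve_max_amplitude`,
guaranteeing validity by construction, degree ≤ 6 so the fitted model class
contains the truth), a lesion count from the group's distribution, lesion
amplitudes and widths, and center positions uniform on the feasible set with
a minimum spacing (default 60 px) enforced by the gap construction — no
rejection loops, so generation is deterministic and cheap. Per-fish streams
are derived by hashing (cohort seed, group index, fish index) through
`numpy.random.SeedSequence`, so extending a cohort never reshuffles existing
fish.

Default conditions (`study_cohort_spec`) emulate the study design the
pipeline was built around: four arms — untransformed control, a
RAS-transformed arm, and two immune-depletion rescue arms (strong and
partial) — sized 52/140/41/105 fish, with Poisson lesion counts of mean
0/5/1/3 and amplitudes uniform on 40–80 grey at noise σ = 4 (i.e. 10–20
noise sigmas, comfortably above the ≥ 8σ recovery regime). Tube intensity
120 over background 20 at 16-bit depth is a nominal choice: the original
stereomicroscope bit depth and magnification are unpublished, so the
generator is a statistical emulation, not a calibration. Tests and the
reproducibility checks run scaled-down cohorts (typically 3–8 fish per
group on 120×400 px images, 50 fish for the recovery check on 150×700 px);
these sizes are the package's test-design choice and are stated here so the
numbers in the suite are interpretable.

What the generator does *not* emulate — and therefore what passing tests do
not certify about real data: uneven illumination and background gradients,
autofluorescence and off-target bright structures (beyond what
`largest_component` handles), optical blur anisotropy, depth effects from
maximum projections, pigment occlusion, fish-to-fish variation in tube
brightness, and lesions that change tube geometry rather than intensity.
On real images the manual threshold and the peak constants should be
reviewed against a few hand-annotated fish before batch use.

## Known limitations

* Severity conflates lesion load with overall reporter brightness; it is a
  within-experiment comparison statistic, not an absolute measure.
* The polynomial centerline cannot follow a notochord that folds back on
  itself in x (y must be a function of x after the auto-transpose).
* Lesion calls are 1-D: two lesions at the same x but different depths are
  one peak.
* The exact Mann–Whitney path requires untied data; heavily tied small
  samples fall back to the corrected normal approximation.
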