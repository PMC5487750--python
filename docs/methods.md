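# Methods

This note documents the model behind `breastsym`, the choices made where a
design question was genuinely open, and what the synthetic test bed does and
does not establish about real photographs.

## Coordinate and orientation conventions

All geometry lives in image pixel space: `x` grows rightward along columns,
`y` grows **downward** along rows, and "left"/"right" are viewer-relative —
exactly what an annotator sees on screen.  "Clockwise" is clockwise on the
displayed image; with y pointing down this means ray direction
`(sin θ, −cos θ)` for a sweep starting at 12 o'clock.  Coordinates are
stored as 0-based floating-point pixels.

## The symmetry model

The BSI treats asymmetry as a weighted mean of six bilateral discrepancy
terms.  Each paired measurement `(a, b)` is reduced to the scale-free ratio
`f = min(a,b)/max(a,b)`; the discrepancy is the linear deviation
`d = 1 − f`, and

```
BSI = scale_max · Σ_k w_k d_k ,   Σ_k w_k = 1,  scale_max = 15 .
```

Consequences that the test suite verifies as theorems of the construction:

* **Mirror zero** — an exactly mirror-symmetric annotation has every
  `f_k = 1` and scores 0.
* **Saturation** — all factors 0 (one-sided degeneracy in every component)
  scores exactly 15.
* **Similarity invariance** — ratios are unchanged by translating or
  uniformly rescaling the scene, so the score is a shape property,
  independent of camera distance and image resolution.
* **Side exchange invariance** — `min/max` is symmetric in its arguments.
* **Decomposition** — the mammilla sub-score (direct, horizontal, vertical,
  radial components) and the area sub-score (area, circumference) sum to
  the BSI exactly.

Degenerate pairs: `(0, 0)` is defined as `f = 1` (both sides identically
null is perfect agreement — e.g. both nipples exactly on the jugulum
vertical), a one-sided zero as `f = 0`.  The linear transform `d = 1 − f`
is the minimal monotone choice; nothing in the construction requires a
nonlinearity, and linearity keeps the sub-score decomposition exact.

## The radial profile

The radial component casts `n = 24` rays (a 15° grid) from each nipple to
its breast border, left breast clockwise, right breast counter-clockwise,
both starting at 12 o'clock.  The opposed sweep directions implement mirror
correspondence: cut *i* on one breast faces cut *i* anatomically, and a
perfectly mirrored scene gives 24 unit ratios.  The 24 per-cut ratios are
combined by arithmetic mean *before* weighting (per-cut ratio, then mean —
not mean length, then one ratio), so a local bulge is penalised even when
total lengths balance.

Two decisions here were open and are fixed by convention, not by anatomy:

* **Anchor** — the sweep starts at 12 o'clock.  Any fixed anchor works,
  because both sides use the same anchor and mirrored directions; only the
  pairing of cuts matters.
* **Nearest crossing** — a ray stops at its nearest boundary intersection.
  Manually traced borders are near-star-shaped around the nipple; the
  nearest-crossing rule is robust to tracing wiggles that briefly make a
  ray cross the ring more than once.  Ray/segment intersection is solved
  directly (vectorised 2-D cross products) rather than through a geometry
  library so this rule — and exact mirror symmetry of the result — is
  under local control.

A nipple exactly on its border is rejected at construction time: a zero
radial distance would make the ratio factors undefined.

## Weights

The published questionnaire (10 surgeons, 8 students; importance scale
1 = very important … 4 = not important) gives pooled means of 1.407
(nipple position), 2.130 (area), 2.241 (circumference).  Inverting the
scale (`r = 5 − m`) and normalizing over the three BSI-relevant items
yields group weights 0.3896 / 0.3112 / 0.2992 — the intended emphasis of
nipple position over either size measure.  The scars item is surveyed but
never enters the score.  Two decisions were open:

* the within-group split of the nipple weight across its four components
  is equal (no finer preference data exists);
* weights are fully user-overridable through a `key = value` config file
  (renormalized on load), since the exact production weights of the
  original clinical software were never published.  The derived defaults
  reproduce the published ordering from the published questionnaire data,
  which is the strongest statement the available inputs support.

## Harris banding

The published BSI→Harris table enumerates half-unit grid points only
(group 1: ≤2.5, group 2: 3–6.5, group 3: 7–10, group 4: 10.5–15).  Off-grid
values (e.g. 2.6–2.9) fall between rows; they are resolved by rounding to
the nearest 0.5 first, ties away from zero, with rounded values below 1
mapping to group 1.  This makes the banding total on [0, 15] while agreeing
with the table at every printed point.

## Synthetic shapes and rater jitter

`make_symmetric_pair` builds one breast contour from a star-shaped radial
function

```
r(φ) = r_ellipse(φ) · (1 + droop · max(0, sin φ)) · wiggle(φ)
```

(`sin φ > 0` points inferiorly in image coordinates; `wiggle` is an
optional seeded sum of low-order cosine harmonics with relative amplitude
≤ `contour_wiggle`), places the nipple, and mirrors everything exactly
about the torso midline.  Defaults — semi-axes 120 × 100 px, droop 0.2,
nipple 10 px below the contour center, on an ~800 px-wide virtual image —
are in the range of breast contours annotated on clinical frontal photos.
`apply_asymmetry` then perturbs one side: nipple displacement, isotropic
border scaling about the nipple (linear factor `s`, hence area × `s²`,
perimeter and radial distances × `s`), and whole-side vertical shift.

`simulate_rater_panel` emulates k annotators re-annotating one image.
Landmark clicks receive independent isotropic Gaussian jitter of
`jitter_sd` pixels.  Border jitter has the same per-vertex marginal sd but
is smoothly correlated along the ring (Gaussian kernel, correlation length
≈ 30° of arc): a human tracing a border wanders smoothly, it does not
flicker vertex-by-vertex — and uncorrelated noise at realistic amplitudes
(tens of pixels against a ~15 px vertex spacing) would almost surely
self-intersect the ring, describing digitisation noise rather than
annotator behaviour.  Draws that still violate an invariant are resampled
a bounded number of times.  With this model, 2 px jitter on ~500 px shapes
keeps the BSI's ICC(A,k) above 0.95 (the high-reliability regime reported
for objective scoring), and increasing jitter degrades the median ICC
monotonically.

What the simulator does **not** emulate: photographic segmentation
ambiguity (where the breast border "is" on a real photo), pose and
illumination effects, correlated errors between raters trained together,
or the tail behaviour of human misclicks.  Green tests therefore establish
the *arithmetic* of the score and the *direction* of its response to
controlled asymmetry and noise — not field inter-rater reliability, which
requires photographs.

## Agreement statistics

ICC(A,1) and ICC(A,k) are computed from the two-way ANOVA mean squares of
a complete subjects × raters grid, absolute-agreement definition (rater
offsets count against agreement), with confidence bounds via the
F-distribution method and Satterthwaite degrees of freedom.  Panel data
are assumed complete; missing-data ICC estimation is out of scope.  The
implementation is cross-checked in the tests against an independent
loop-written ANOVA oracle and against `pingouin.intraclass_corr`.  A grid
with zero between-subject variance raises an explicit "undefined" error
instead of returning 0 — constant subjects give rater agreement no scale.
When the residual mean square is exactly 0 the F-method interval is
degenerate and the bounds are reported equal to the point value.  The
average-measures form ICC(A,k) is the default, with single-measures
exposed alongside, since reports of "average ICC" in panel studies refer
to the k-rater mean.  Pearson correlation (with the t-transform p-value
and `r²`) delegates to `scipy.stats.pearsonr`.

## Numerical choices and problem sizes

* Mirror-zero and swap-invariance assertions use an absolute tolerance of
  1e-9 BSI points; exact mirroring is reproduced by reflection arithmetic
  to ~1e-12 relative error.
* Polygon validity (simplicity, positive area) is enforced by shapely at
  construction; degenerate (collinear) rings are rejected.
* Containment is strict interiority: boundary points count as outside,
  so a nipple on its border is invalid rather than silently zero.
* Property suites run at moderate contour resolutions (48–120 vertices)
  and the ICC-degradation study at 10 subjects × 5 raters × 20 seeds ×
  4 jitter levels — sizes chosen to exercise every code path while keeping
  the default test run under a minute.
* Monte-Carlo oracles (10⁶-point area estimate) and closed forms (circle
  perimeter, ellipse polar radius) bound the geometric primitives to 1%
  and 0.1% respectively.

## Known limitations

* The score is 2-D: projection of a 3-D anatomy onto one frontal view.
  Volume asymmetry with symmetric silhouettes is invisible to it (3-D
  surface capture is a different instrument class, deliberately out of
  scope).
* The default weights inherit the questionnaire's small panel (n = 18);
  they are defaults, not dogma, and the config file exists precisely so
  studies can pre-register their own weighting.
* The equal within-group split of the nipple weight is a convention; no
  data distinguishes the four nipple components' importance.
* Harris banding compresses a continuous score; adjacent BSI values can
  straddle a band edge by rounding.
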