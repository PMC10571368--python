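# Methods

## Problem and model

An isolated tooth scanned in air in a cone-beam CT volume is, after
binarization, a single 26-connected component of "tooth" voxels. Its surface
is taken to be the set of *edge pixels*: tooth pixels with at least one
background pixel among their 8 neighbours **within the same axial slice**
(pixels on the image border count as edges). The root/crown distinction is
made on the surface only, from intensity: enamel (crown surface) is markedly
more radiodense than cementum (root surface), so the histogram of edge-pixel
intensities is bimodal, and a per-tooth threshold *X* placed in the valley
between the two modes classifies each edge pixel as root (< *X*) or crown
(≥ *X*).

Root surface area is the pixel-count rule: each root edge pixel contributes
one in-plane pixel width of circumference, each slice's circumference is
multiplied by the slice spacing, and slices are summed —

    RSA = N_root_edge_pixels × pixel_size_mm × slice_spacing_mm.

Two properties are inherent to this estimator and are reproduced
deliberately, not corrected:

* **Diagonal bias.** Perimeter is a pixel count, not a geometric contour
  length, so obliquely oriented boundaries are under-measured relative to
  their true arc length. Validation phantoms therefore use axis-aligned
  prisms, where the rule is exact.
* **No axial caps.** Only laterally exposed surface is accumulated; the
  apex (and any occlusally facing surface) contributes nothing.

Both closed-form and per-slice summation are computed and cross-checked to
1e-9 on every call; the closed form (exact in integer pixel counts) is the
reported value.

## The dynamic threshold

The surface histogram is searched after a centred moving average
(`smoothing_window`, default 5 bins, reflected boundaries; width 1 disables
smoothing). Peak candidates must have

* prominence ≥ `min_prominence_fraction` (default 0.10) of the smoothed
  curve's peak-to-trough range — a *relative* criterion, so adding a
  constant to every bin changes nothing; and
* separation ≥ `min_peak_separation` (default 20 bins) from any higher
  peak — the cementum and enamel modes sit tens of gray levels apart, so
  closer twin peaks are one noisily sampled mode, of which only the higher
  is kept.

*P* is the first (lowest-bin) surviving peak; on a flat peak plateau the
smallest bin is reported, matching "first". If fewer than two peaks survive,
the surface is unimodal (no detectable enamel/cementum contrast) and a
`NoPeakError` is raised rather than guessing a threshold.

*X* is the location of the **minimum value between the first two peaks**.
Between well-separated modes the valley floor is a long stretch of (nearly)
empty bins, so the exact argmin is meaningless noise; ties are resolved as a
plateau. Starting from the minimal bin nearest *P*, the plateau extends over
contiguous bins within `plateau_tolerance_fraction` (default 0.02) of the
range above the floor, and the **midpoint** bin is reported. Rationale for
the midpoint rather than the plateau's left edge: the left edge of the empty
stretch is an extreme order statistic of the cementum mode — it hugs that
mode, is biased by roughly half the inter-mode gap, and fluctuates with
sample extremes — whereas the midpoint is deterministic, reduces to the same
answer when the valley is a single bin, and coincides with the analytic
valley of a symmetric two-mode mixture. The tolerance converts the plateau
endpoints from sample extremes into quantile-like level crossings, which is
what makes threshold recovery reproducible to a few bins.

A literal "first local minimum after P" on a noisy curve pins *X* to shallow
dips just after the peak top; restricting the search to the inter-peak
interval is the faithful reading of the method's intent (the premise is two
clearly separated peaks) and is what the error contract of the threshold
requires.

## Binarization and components

The air/tooth cut is automatic by between-class-variance maximisation
(Otsu) over the whole-volume histogram, with a manual `air_threshold`
override. Isolated teeth in air give a strongly bimodal whole-volume
histogram, which is the regime where Otsu is reliable; the override exists
for volumes that violate that assumption. A degenerate result (all air or
all tooth) raises a warning, not an error.

Connected components use 26-connectivity (the most inclusive standard 3-D
choice); components smaller than `min_component_voxels` (default 27, a
3×3×3 cube) are dropped as noise. Thresholds are computed **per component**:
the central point of the method is that no global gray cut works across
teeth.

## Volume I/O

DICOM series are read one directory = one series, slices ordered by spatial
position along the scan axis (filename order is untrusted). Volumes stored
deeper than 8 bits are min–max rescaled to 0–255 with round-half-up — the
vendor's detector-to-display mapping is unknown, so the package makes the
simplest monotone choice and documents it. Missing spacing metadata falls
back to 0.3 mm (the isotropic voxel size of the reference acquisition) with
a warning. A minimal raw fixture format (`.rsavol`: ASCII header + uint8
payload) provides bit-exact round-trips for tests and artifacts.

## Phantoms

The generator emulates exactly the features the pipeline depends on and
nothing more: a solid (square prism, digitized cylinder, or a coaxial
two-part tooth with the crown prism overhanging the root by 2 px per side)
in air, with region intensities `round(Normal(mean, noise_sd))` clipped to
[0, 255]. The two-part tooth marks the root/crown junction **by intensity
only** — like the real CEJ, nothing in the geometry signals it on the root
side. Ground truth (root edge count, RSA, analytic mixture valley — the
integer bin minimising the log mixture density between the modes, the
midpoint when `noise_sd = 0`) is computed from the clean geometry before
noise.

Defaults are a plausible isolated tooth at 0.3 mm voxels: root 20 px
(6 mm) wide and 40 slices (12 mm) tall, crown 12 slices, cementum/enamel
surface modes 90/190, air 0, noise sd 4. Intensity modes must be separated
by at least 4 noise standard deviations — phantoms are meant to be solvable;
the generator refuses specs where the modes blur together. What the phantoms
do **not** emulate: real root anatomy (curvature, furcations), alveolar
bone, beam hardening, scatter, and intensity nonuniformity. Passing the
phantom suite therefore shows the algorithm implements its definition
exactly and tolerates additive noise; it does not certify accuracy on
clinical scans, where the reference comparison (below) is the evidence.

Problem sizes in the test-suite and acceptance runs — prisms of side
3–20 px over 10 root slices, and 20 noisy phantoms at the default geometry —
were chosen so each simulation still has thousands of surface pixels while
the whole suite stays interactive.

## Behaviour under noise

At noise sd 8 (modes 12.5 sd apart) the recovered *X* stays within 2 bins of
the analytic valley and RSA within ~2% of truth across hundreds of seeds.
The residual RSA error is a small *positive* bias with a known mechanism: a
few root-surface voxels in the far left intensity tail fall below the air
cut, denting the binarized surface and adding perimeter pixels. Across 300
seeds the worst observed error was 2.07% (exactly one seed above 2%); error
is zero at sd ≤ 4 and grows monotonically with noise.

## Agreement statistics

Differences are method A − method B. The paired *t*-test uses the sample SD
(n−1); the mean's 95% CI uses the t quantile with n−1 df; the Bland–Altman
limits of agreement use the conventional fixed 1.96 multiplier (not a t
quantile). Cronbach's α is the standard item-variance form. The ICC is
ICC(2,1) — two-way random effects, absolute agreement, single measure,
computed from the two-way ANOVA mean squares — chosen because inter-rater
agreement of continuous measurements should charge systematic rater offsets
against the coefficient; a `model="consistency"` alternative is exposed.
Degenerate inputs (zero-variance differences or totals) return flagged
NaN/degenerate results rather than infinities.

The packaged 24-tooth table reproduces its own summary statistics: mean
difference 0.73 mm², SD 5.42 mm², 95% CI upper bound 3.01 mm², Bland–Altman
mean 0.7 mm², t = 0.656, p = 0.519. Note that the *t* statistic printed in
the original report of these data (1.005) is not consistent with the table's
own difference column, and two different p-values appear there for the same
test; this package always reports values recomputed from the pairs, and the
recomputed p (0.519) matches one of the printed ones. The published
reliability coefficients (α = 0.998, ICC = 0.988) cannot be recomputed —
the rater-level raw data are not available — so the coefficients are
validated on constructed matrices (duplicated raters, hand-computed toy
ANOVA tables) instead.

## Known limitations

* Isolated teeth only: touching teeth, or roots against alveolar bone of
  similar intensity, are out of scope by construction.
* The pixel-count perimeter systematically under-measures oblique
  boundaries (see above); do not compare its absolute values against
  mesh-based surface areas without accounting for that.
* A tooth whose surface shows no enamel/cementum contrast (e.g. a root
  fragment) yields `NoPeakError`; callers that know the specimen is
  root-only can pass a `threshold_override`.
* 8-bit intensities are assumed throughout; deeper data are rescaled
  min–max, which is a choice, not a calibration.
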