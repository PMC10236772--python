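# Methods

## The quantity being computed

`avcalc` quantifies aortic valve calcification (AVC) on non-contrast,
ECG-gated cardiac CT with the Agatston method, restricted to an
annulus-referenced region of interest. The Agatston score is a
dimensionless calcium burden: on each axial slice, every connected
supra-threshold lesion contributes

```
score_lesion = area_mm2 x w(peak HU) x thickness_factor
```

where `w` is 1 for peak attenuation in [130, 200) HU, 2 for [200, 300),
3 for [300, 400) and 4 for >= 400 HU, and the total is the sum over all
lesions in the region of interest. Calcium is defined by the fixed
attenuation threshold of 130 HU, inclusive. A calcium *volume* score
(mask voxel count x voxel volume, mm^3) is reported alongside.

## Region of interest

The aortic annulus plane is constructed from three user-supplied
landmarks at the nadirs (lowest insertion points) of the three valve
cusps, with a fourth landmark on the ascending-aorta side fixing the
normal's sign. The ROI is the slab of voxels whose **centers** have
signed plane distance in the closed interval [-5.0 mm, +20.0 mm]
(configurable). Distances are measured along the plane normal — a true
3D point-plane distance — not along the scanner axis, so oblique annuli
are handled correctly. The slab, rather than anatomical segmentation,
is what excludes left-ventricular-outflow-tract and mitral calcium
below the annulus; calcium in contact across the slab face is cut at
the face, and residual extra-valvular calcium (aortic sinus, coronary
ostia) is removed with manual exclude masks, mirroring the manual
reading workflow. Include edits can add voxels, but never sub-threshold
ones: the 130 HU requirement is not overridable.

## Lesion definition and numerical choices

- Lesions are **per axial slice**, maximal in-plane 8-connected
  components (4-connectivity available). The score sums weighted areas,
  a per-slice quantity; 3D region growing (26- or 6-connectivity) is
  provided for interactive-style selection but is not the scoring path.
- The density weight uses the lesion's **peak** HU (classical rule).
- Exactly 400 HU maps to weight 4 (the classical >= 400 convention);
  the traditional integer bin definitions leave 400 itself unassigned, so the
  boundary is configurable (`hi_bin_inclusive=False` gives the strict
  reading, under which 400 falls to weight 3).
- Lesions smaller than 1 mm^2 are dropped before scoring (classical
  minimum-lesion convention, configurable); they still count toward the
  volume score.
- `thickness_factor = slice_thickness_mm / 3.0`, so the standard 3 mm
  calcium-scoring protocol scores with factor 1 and thinner
  reconstructions remain comparable; both the reference thickness and
  the factor rule are configurable.
- Slab membership is a closed interval on voxel centers: deterministic,
  and pinned by phantom tests. Per-lesion score terms are accumulated
  with `math.fsum`, so totals are independent of lesion enumeration
  order and exactly rounded.
- DICOM series are sorted by the projection of ImagePositionPatient on
  the slice normal (not InstanceNumber); rescale slope/intercept are
  applied so voxel values are calibrated HU.

## Agreement statistics

The validation protocol for paired per-subject scores (two software
tools, two observers, or repeat reads):

- **ICC**: two-way random-effects, absolute-agreement, single-measure
  (ICC(2,1)) by default, computed from the mean squares of the
  subjects x methods layout with the standard F-based 95% CI. Absolute
  agreement is the defensible default for method comparison because a
  systematic offset must count against agreement; consistency and
  average-measure forms are selectable. With zero residual variance the
  F-based interval is undefined and degenerates to the point estimate.
- **Bland-Altman**: differences d = a - b; limits of agreement
  mean(d) +/- 1.96 x sample SD(d); the CI of the mean difference
  mean(d) +/- 1.96 x SD(d)/sqrt(n). Both intervals are reported
  separately (published summaries sometimes conflate them). Per-subject
  (mean, difference) pairs are emitted for plotting; no plots are drawn.
- **Discordance**: per subject, relative difference
  |a - b| / ((a+b)/2) x 100, counted when *strictly* exceeding each
  threshold (default 5% and 10%). The pair-mean denominator is
  configurable to method-A-as-reference. Undefined when a + b = 0.
- **Summaries**: median and 25th-75th percentiles (linear-interpolation,
  type-7 percentiles — reported values depend on this choice) and
  Shapiro-Wilk W/p per method; constant input is flagged degenerate.

## Phantoms and what the tests show

The phantom generator emulates the geometry of the scoring problem, not
CT physics: a uniform soft-tissue background (-50 HU), box/ellipsoid
calcium plateaus placed in patient space with voxel-center membership
(later lesions overwrite earlier), optional additive Gaussian noise,
and annulus landmarks. Lesions carry anatomical tags (aortic, mitral,
coronary, sinus) so decoy calcium outside the slab — including mitral
calcium touching aortic calcium across the ROI face — can be staged.
There is **no** partial-volume averaging, beam hardening, motion, or
contrast simulation; ground truth stays analytically exact, which is
the point. Consequently the passing tests demonstrate that the
geometry, segmentation and scoring arithmetic are correct, not that
scores on real, noisy, partial-volume-blurred patient scans will match
another workstation's reading.

`expected_agatston` is a deliberately independent oracle: its own
rasterisation, explicit per-voxel slab test, BFS flood fill, and
if-chain weighting, kept separate from the production pipeline. In
exact mode (no noise) pipeline totals must equal it bit-for-bit; in
robust mode (noise present) it refuses unless every plateau and the
background keep >= 5 x noise SD from the 130 HU threshold and every
weight boundary, in which case the noise-free expectation is still the
correct score with overwhelming probability.

`simulate_paired_scores` draws per-subject true scores from
Normal(3400, between_sd^2) truncated at zero — the default mean
reflects a severely calcified pre-TAVR population — and adds
independent per-method Gaussian reading error plus an optional method-B
bias. With between-subject SD 100 and error SD 10 the population ICC is
10000/10100 ~ 0.990, which the estimator recovers in the calibration
suite (200 replicates at n = 500, mean within +/-0.005). Bland-Altman
limits are checked to contain ~95% +/- 1% of simulated Normal
differences over 1000 replicates of 50 pairs.

Problem sizes in the test and acceptance suites — randomized phantoms
up to 48 x 48 x 19 voxels, 100-phantom oracle sweeps, 200-replicate ICC
recovery, 1000-replicate coverage — were chosen as the smallest scales
at which each property is sharply testable.

## Per-leaflet split

The three nadirs are projected onto the annulus plane; directions from
their in-plane centroid to each projected nadir bound three angular
sectors, and each lesion is assigned whole, by its centroid projection,
to one sector. Sector scores sum to the total by construction. This is
one reasonable geometry for a per-leaflet breakdown; lesions straddling
a sector boundary are not split, and a lesion centroid coinciding with
the nadir centroid is an error.

## Known limitations

- No registration: landmarks must be given in the scored scan's frame.
- No automatic detection of coronary/sinus/mitral calcium; exclusion is
  geometric (slab) plus manual edit masks.
- No calcium mass score (mg hydroxyapatite), no DICOM writing, no GUI.
- Exact reproduction of any particular workstation's ICC/CI values
  requires the per-patient data; the statistics module reproduces the
  protocol, not a specific cohort's numbers.
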