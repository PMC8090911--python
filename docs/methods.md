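# Methods

This note records what the package computes, the assumptions behind the
synthetic data, the defaults that matter, and the choices made where the
published pipeline description leaves the design open.

## Ring construction and the PNLA score

Nuclei are segmented as thresholded connected components (8-connectivity
throughout) kept when their equivalent circular diameter lies in a
configured band and their roundness 4πA/P² is at least 0.6. Each nucleus
label is eroded by a Euclidean disk of radius `shrink_px` (default 2 px =
0.325 µm at the default calibration of 0.1625 µm/px), expanded by
`grow_px` (default 25 px = 4.0625 µm) with a collision-free growth in which
every background pixel within reach takes the label of the *nearest*
labelled pixel — equidistant ties go to the smallest label id, a rule chosen
because it is deterministic and exactly checkable against a brute-force
oracle. Labels touching the image border are removed, and the ring is the
expansion minus the shrunken nucleus. The effective ring band therefore
spans from 2 px inside the original nuclear boundary to 23 px outside it.

A punctum belongs to a ring when its centroid pixel lies in the ring
(`membership="overlap"` switches to an any-pixel rule). The PNLA score of a
field is the mean area (px², with µm² companions) of member puncta pooled
across the field; wells average their fields. Fields with no member puncta
score 0 and carry a `no_ring_puncta` flag instead of being dropped, so
cytotoxic wells cannot silently bias a plate.

Distances are Euclidean everywhere (disk structuring elements rasterised as
`{p : ‖p‖ ≤ r}`), matching the micrometre calibrations; the pixel size is
carried on every raster and never hard-coded.

## Plate statistics

Z′ uses sample standard deviations (ddof = 1). Plates are included iff
Z′ > 0; the (0, 0.5) band for complex phenotypic assays is annotated but not
enforced. `robust_z_scores` implements (x − median)/MAD with the raw MAD by
default, exactly as the formula is written; the screening workflow calls it
with the σ-consistent MAD (×1.4826), the standard robust Z of the HTS
literature, because with the raw MAD a fixed threshold of 2 sits at only
~1.35 Gaussian σ and would flag ~9 % of inert wells — no screen would run
at that operating point. Hit calling is `robust_z ≥ 2`, boundary inclusive;
the normalisation population is the compound wells of the plate (controls
excluded), and no multiple-testing correction is applied (the cut-off is a
fixed effect-size rule, not an inference).

The two-sample comparison defaults to Welch's t-test (a pooled-variance
option exists): when only "a t-test" is specified, the unequal-variance form
is the safer default.

One marker threshold is fixed per plate — the median of the per-field
automatic thresholds over the negative-control wells — mirroring how a
screening module runs with a single configured "appropriate threshold".
Re-estimating the threshold on every field injects a common-mode shift into
all puncta areas of that field and visibly fattens the inert tail of the
plate distribution.

## Puncta detection

Both nucleus- and punctum-scale detection share the round-objects filter;
puncta use a permissive roundness minimum (0.2) because coalesced multi-spot
blobs *are* the accumulation signal, and a diameter band of 2–20 px so those
blobs are retained. The default punctum threshold is Otsu floored at
`median + 6 × 1.4826 MAD` of the image: on sparse-spot fields Otsu alone
collapses into the noise band.

## Synthetic data: what it emulates, and what it does not

The generator renders what the analysis needs to be well-posed, not camera
physics:

- **Nuclei** are non-overlapping smoothed disks (rejection sampling, ≤1000
  retries per cell, with an explicit density error) with radius 12–16 px,
  placed ≥25 px from the image edge so their expanded territories survive
  border removal. Dead cells render at half radius and double intensity.
- **Puncta** are Gaussian spots (σ = 1.2 px, ≈0.46 µm FWHM at the default
  calibration). Each punctum is perinuclear with probability
  `perinuclear_bias`; perinuclear puncta scatter (σ = 2.5 px) around 2
  per-cell cluster centres inside a 0–23 px band outside the nuclear
  boundary — the band mirrors the analysis ring so the phenotype is
  geometrically well-posed — while peripheral puncta are dispersed in a
  28–63 px annulus with a 6-px field-wide minimum spacing. Clustering is the
  physical basis of the area readout: accumulation merges spots into larger
  detected blobs, which is also why detection recall intentionally degrades
  at high bias (coalesced lysosomes are not resolvable, and are not meant to
  be counted).
- **Plates** assign DMSO-like negative controls bias 0.1, lapatinib-like
  positive controls bias 0.9, and compounds their planted effects; defaults
  are 4 fields per well and 8 cells per 256×256 field. All randomness flows
  from one seed through `SeedSequence` spawning (per well, then per field),
  so identical specs are bit-identical.
- **Time courses** draw per-cell puncta counts from a logistic
  expected-rate profile (baseline 0.4, plateau 6 puncta/cell, half-rise at
  6 h for early-LMP and 20 h for late-LMP drug classes, width 2 h) and
  linear death ramps; timepoints are rendered independently because the
  analysis scores each timepoint without tracking.
- **Organoids** are dark disks (default 7000 px² at day 1) on a bright
  background with a growth factor and optional thin protrusions at day 3.

Not modelled: optics/PSF, 3-D stacks, illumination gradients, bleaching,
autofluorescence and spectral crosstalk. Passing tests therefore demonstrate
correctness of the *computational* pipeline under the stated statistical
structure, not robustness to real-instrument artefacts.

Noise is additive Gaussian (σ = 8 intensity units on a background of 100;
nucleus amplitude 900, punctum amplitude 600) — the simplest model that
exercises thresholding.

## LMP, death and flux classification

A cell is puncta-positive at ≥3 puncta (configurable). Dead-cell detection
is the conjunction *area < 0.5 × field-median nucleus area* AND *mean
intensity > 1.5 × field-median*; the factors are package defaults for a
criterion that is only described qualitatively (shrunken, brightly stained
nuclei), and the conjunction prevents merely-small or merely-bright nuclei
from being flagged. Percent positive is computed over live cells; percent
dead over all detected cells per site. Kinetics are classified from the
first timepoint at which percent-positive reaches
max(2 × baseline, 10 %): before 12 h → *early*, at/after → *late*, never →
*none*; a series that does not span 12 h is refused. Flux puncta are *red*
when mean GFP / mean RFP < 0.5 within the punctum (zero RFP →
unclassifiable).

## Organoid pipeline

Stage order is fixed: bottom-hat (closing by a Euclidean disk minus the
image) → Otsu threshold → dilate (3 px) → fill holes → minimum area
(500 px²). Two numerical guards are documented: (1) the closing only fills
dark objects *smaller* than the structuring element, so the default radius
(80 px) exceeds the largest expected organoid radius; (2) on a blank field
Otsu splits the noise in half, so thresholding additionally requires the
enhancement to clear the robust noise band of the bottom-hat image. The
bottom-hat uses scikit-image's exact "crosses" disk decomposition (verified
bit-equal to the direct closing). Dilation inflates both days by the same
rim, so the percent change is approximately bias-free; the residual bias is
documented rather than corrected. Inverted-contrast input (bright objects
on dark) raises a `ContrastDirectionWarning`.

## Problem sizes used in the test suite

Simulation-backed tests run at desk scale: 20 fields per bias level for the
discrimination grid; ten 68-well plates (64 compounds, 4 fields/well) for
hit recovery; ten seeds per drug class over 0–24 h at 2-h steps for kinetic
classification; one organoid pair per growth factor in {0.5, 1, 1.5, 2};
100 random 64×64 instances per morphological oracle.

## Known limitations

- The exact algorithms behind the commercial "Find Round Objects" and
  "Auto Threshold" modules are unpublished; this package reproduces the
  documented pipeline structure, not instrument output byte-for-byte.
- Peripheral puncta of one cell can fall inside a neighbour's ring in
  crowded fields, so the measured in-ring fraction sits above the planted
  bias at low bias; the readout remains strictly monotone in the bias.
- Spheroid protrusion *counting* is out of scope (no algorithm is
  described for it); the generator can render protrusions for segmentation
  tests.
- The dead-cell rule uses field medians; fields that are mostly dead would
  shift the reference and under-flag.
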