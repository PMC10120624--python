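# Methods

This package re-implements, as a tested pipeline over synthetic data, a
terminal-type-specific quantification of cannabinoid receptor 1 (CB1R) in
human prefrontal cortex: segmentation of excitatory (vGlut1-positive) and
inhibitory (vGAT-positive) presynaptic boutons in 3-D confocal stacks,
measurement of CB1R immunofluorescence under the bouton masks, and a blocked
ANCOVA comparison of schizophrenia (SZ) subjects against matched
non-psychiatric comparisons (Ctrl). No raw images from the original cohort
are publicly deposited, so every stage is exercised on synthetic stacks whose
ground truth emulates the cohort's statistical structure.

## Measurement chain

**Acquisition model.** Stacks are 4-channel (vGlut1, CB1R, vGAT, lipofuscin)
3-D arrays in camera ADU; the full-size field is 512×512 pixels covering
55×55 μm (pixel 55/512 ≈ 0.1074 μm) with 0.25 μm z-steps. Plane 0 is the
tissue surface. Sections cut at 40 μm shrink during immunohistochemistry;
raw depths are corrected back to the 40 μm scale by
`corrected = raw × 40 / measured`.

**Exposure normalization** (`imgproc.normalize_exposure`): camera response is
linear in exposure time, so each channel is rescaled by
`reference / exposure`; the lipofuscin channel is acquired at a constant
exposure. The reference defaults to the largest exposure in the cohort.

**Spot enhancement** (`imgproc.difference_of_gaussians`): each channel is
band-passed by a difference of Gaussians with σ = 0.7 and 2.0 pixels, applied
per z-slice in XY (the historical channel operation is two-dimensional; a 3-D
mode is available as a config switch), and clipped at zero so downstream
thresholds act on one-sided data. The 0.7/2.0-px band passes puncta of
roughly 1–3 px σ — the bouton scale at this calibration.

**Segmentation** (`segment.segment_channel`): thresholds sweep upward from
the Otsu value of the enhanced channel's integer histogram in increments of
50 gray levels. At each threshold the binarized stack is labeled in 3-D
(26-connectivity) and components with physical volume inside 0.03–2.0 μm³
(11–693 voxels at the default calibration; ceil/floor conversion so true
volumes at the bounds are kept) are accumulated as a voxelwise union. After
the sweep, the union is relabeled and the size gate re-applied; final masks
are copied back onto the *unenhanced* channel for intensity measurement.
Because thresholded masks are nested, the largest component size is
non-increasing in the threshold, and the sweep stops early once no component
can reach the minimum gate — an exact shortcut, not an approximation. The
stopping threshold defaults to the channel maximum.

Merging across iterations is a voxelwise union followed by one final
relabel. A consequence worth knowing: two puncta whose masks touch at the
lowest threshold can never be split by later iterations. This drove the
choice of synthetic densities (below).

**Lipofuscin exclusion** (`segment.segment_lipofuscin`): the same sweep on
the unenhanced lipofuscin channel — aggregates are much larger than the DoG
pass-band — without the upper size gate, since autofluorescent aggregates may
exceed 2 μm³. Because the upper gate is absent, the starting threshold is
floored at `median + 5 robust SD` of the channel; otherwise a section with no
lipofuscin would have its entire field masked when Otsu splits pure noise.

**Acceptance filters** (`measure.apply_filters`), evaluated independently per
object so their order cannot matter: (a) shrinkage-corrected centroid depth
within 10–14 μm of the tissue surface (the antibody-penetrance window);
(b) centroid X and Y inside the virtual counting frame (pixels 10–502 of a
512 field, i.e. the outer 2% excluded; scaled equivalently for reduced
fields); (c) no voxel overlapping the lipofuscin mask; (d) not overlapping
both the vGlut1 and the vGAT mask (dual-labeled objects are ambiguous).
Centroids, not extreme voxels, are used for the geometric filters — robust to
single-voxel protrusions. Overlap means ≥ 1 shared voxel, the strictest
reading.

**Typing and measures** (`measure`): every accepted vGlut1/vGAT object
yields a bouton record whose `cb1r_mean` is the mean of the unenhanced CB1R
channel under the object's mask. Inhibitory records are split into high/low
CB1R expressors at the median of the *control* subjects' vGAT bouton values
(pooled over boutons by default; a subject-level variant is provided —
which pooling the original analysis used is ambiguous). Ties at the median
are low (`> median` defines high). Per-site summaries are unweighted bouton
means per class plus a "sum CB1R" measure: total CB1R ADU under accepted
CB1R-channel object masks (frame- and lipofuscin-filtered) restricted to a
single z-plane, by default the middle plane of the accepted depth window (the
original measurement's plane is not specified). Site values average to one
value per subject × layer — the dependent measures of the models. Empty
cells propagate as missing, never as zero.

## Statistical models (`stats`)

All models are ordinary least squares with sum-to-zero contrasts and
Type III (joint Wald) F tests per term.

* Sum measure: group + layer + group×layer, with subject **pair as a fixed
  blocking factor** (paired variant) or with the cohort covariates — sex,
  race, age, postmortem interval, storage time — replacing the block
  (unpaired variant). Categorical covariates are indicator-coded with the
  most frequent level as reference.
* Terminal-type measure: group + layer + terminal class + group×class +
  group×layer×class, paired and unpaired variants as above. A term listed as
  an interaction absorbs any sub-interaction of its factors that is not
  itself listed (the convention of classic GLM custom models); the
  "three-way" term therefore spans group×layer, layer×class and
  group×layer×class (25 df), reproducing the F(2, 315) / F(25, 315)
  degree-of-freedom layout of a blocked 10-pair × 6-layer × 3-class design,
  and 319 residual df in the covariate variant.
* Post hoc pairwise group contrasts within each class use the model residual
  variance and Bonferroni adjustment `min(1, k·p)`.
* Within-pair Ctrl/SZ intensity ratios are compared between exposure-history
  groups by a pooled-variance (Student) two-tailed t test; demographics use
  Fisher's exact test (categorical) and the pooled t (continuous).
* Rank-deficient designs raise an error naming the aliased term; a constant
  response reports F = 0 rather than NaN.

**Calibration caveat.** The null-calibration check (rejection rate at
α = 0.05 within [0.03, 0.08] over 200 replicates) simulates errors that are
exchangeable given the modelled factors. When a subject-level random effect
is shared across that subject's layers — as is surely true of real tissue —
the fixed-effects ANCOVA treats correlated cells as independent and is
anticonservative (we measure ≈ 0.38 rejection under a subject SD comparable
to the residual SD). This is a property of the original analysis design that
the package reproduces faithfully; it is why the power checks here should
not be read as type-I-calibrated under clustering.

## Synthetic cohorts (`synthgen`)

Each cohort has `n_pairs` matched pairs (one Ctrl and one SZ subject each),
with covariates drawn from the reference cohort's demographic summaries, and
`sites_per_layer` stacks per cortical layer per subject. Stacks are rendered
lazily and deterministically from the cohort seed.

**Scene model.** Boutons are anisotropic 3-D Gaussians (σ_xy ~ U(0.12, 0.26)
μm, σ_z = 1.5 σ_xy, reflecting substantial axial restoration by
deconvolution; the stacks represent already-deconvolved images). Marker
amplitudes are lognormal (mean 1500 ADU, CV 0.25). Each bouton carries a
co-localized CB1R signal; a non-synaptic CB1R-only population and large
multi-channel lipofuscin blobs (σ 0.4–1.0 μm, bleeding 20–50% of their
amplitude into every channel) complete the scene. Antibody-derived signal
decays with depth as `exp(−0.01 × depth)` (penetrance); lipofuscin
autofluorescence does not. Voxels get Poisson-Gaussian noise
(`var = 15² + 0.5·signal`) and 16-bit quantization.

**CB1R intensity structure.** Bouton CB1R targets draw from lognormal
distributions around per-class group means — by default the reference
cohort's published values (Ctrl/SZ): excitatory 770.5/1042.2 ADU, high
inhibitory 2510.1/2137.3, low inhibitory 435.5/460.4 — scaled by per-subject
× class lognormal factors (CV 0.10) and bouton-level CV 0.12. 45% of
inhibitory boutons are high-expressors; slightly below one half, so the
control-median split point falls in the upper tail of the low mode (≈500–700
ADU, like the reference cohort's 712 ADU) rather than in the empty inter-mode
gap, where a median is an unstable order statistic.

**Making "measured mean" a meaningful target.** Two design elements keep the
measured mean CB1R of a bouton interpretable as its configured target:

1. the CB1R co-label is a compact flat-top profile
   `exp(−(u/2.4)⁸)` in punctum-scaled radius `u`, nearly constant over any
   plausible object mask, so the measured mean is insensitive to the exact
   mask extent (a plain Gaussian co-label makes the measured mean drop
   20–30% for masks only slightly wider than the truth mask);
2. amplitudes are calibrated per object so that, at the analysis-window
   depth, the expected measured value — own signal plus the diffuse
   background contributed by all neighbours' profile mass (a mean-field
   computation in `background_compensation`) — equals the drawn target.

`cb1r_mean_truth` records the mean of the complete noise-free CB1R scene
under the object's truth mask (`u ≤ 1.8`): exactly what a perfect mask would
measure, including neighbour contributions. Matched detections reproduce
these truths within ≈2% across cohorts.

**Densities** (boutons per 1000 μm³: 30 vGlut1, 30 vGAT, 10 CB1R-only, 5
lipofuscin) were chosen once for testability, not tissue fidelity — the
source material reports no densities or SNR. The binding constraint is the
union-then-relabel merge: at these densities and punctum sizes, noise-free
detection of interior puncta reaches ≥95% recall with ≤5% false discoveries
(centroid matching at 0.3 μm); substantially denser scenes merge neighbours
that the algorithm cannot split.

**What passing tests do and do not show.** The generator produces isolated,
approximately Gaussian puncta with known intensities and a stationary
background; real deconvolved tissue has structured neuropil, variable
antibody penetration, and bouton morphologies no Gaussian captures. Passing
recovery tests therefore demonstrates the *pipeline's* fidelity under a
known-truth model of the data, not the biological accuracy of any real-tissue
estimate.

## The median-split estimand

One property discovered during validation deserves emphasis. The high/low
expressor classification thresholds at the control-group median. Under the
reference group means the SZ low mode (460 ADU) sits above the Ctrl low mode
(435 ADU), so a threshold in the low-mode tail admits more SZ than Ctrl low
boutons into the "high" class, deflating the SZ high-class mean. A
bouton-level Monte Carlo with *perfect* measurement shows the asymptotic
high-class group contrast is ≈ −19 to −21% against the generating −14.9%.
The split-defined class contrast is thus a biased estimand of the underlying
mode contrast — a property of the median-split method itself, present in any
analysis of this design, not an artifact of segmentation or measurement
(which are verified unbiased to ≈2% on matched boutons). The test suite
asserts measurement fidelity on matched boutons under the pipeline's own
classification, the split-independent excitatory contrast against its
generating value, and the directional behaviour of the split statistic
(sign preservation, inflation of the high-class contrast, shrinkage of the
low-class contrast).

## Problem sizes

Simulation studies run at a reduced field (64×64×32 voxels at full voxel
calibration, measured thickness 20 μm so the corrected 10–14 μm window sits
at raw 5–7 μm): the parameter-recovery study uses 20 cohorts of 10 pairs ×
2 layers × 2 sites; the noise-free detection study 3 cohorts of 2 pairs ×
3 sites; the image-level null study 20 cohorts of 3 pairs. The analysis
drivers under `analysis/` use a 4-pair cohort of the same geometry. All
sizes are the package's own choices and are set in one place per study.

## Known limitations

* Union-then-relabel cannot split touching puncta; whether the original
  implementation allowed higher-threshold fragments to replace merged
  objects is unknown, and this is the main fidelity risk of the
  re-implementation.
* Blind deconvolution is not modelled; stacks represent its output.
* The fixed-effects ANCOVA ignores subject-level clustering (above).
* Laminar boundaries come from the cohort manifest, not from images.
* The 2-D plane for the sum measure and the bouton- vs subject-level median
  pooling are documented choices where the original procedure is ambiguous.
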