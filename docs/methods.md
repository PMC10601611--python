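# Methods

`cyanofish` quantifies where fluorescent signals sit inside rod-shaped
cyanobacterial cells — specifically, where mRNA-FISH foci and GFP-tagged
ribosome signals lie relative to the thylakoid membrane system — and ships a
synthetic-image generator with exact ground truth so that every measurement
in the pipeline can be validated end to end.

## The measurement problem

Cyanobacteria such as *Synechococcus elongatus* carry two distinct membrane
systems: concentric thylakoid shells near the cell periphery (strongly
autofluorescent via chlorophyll and phycocyanin) and the plasma membrane
outside them. Whether an mRNA or a ribosome sits in the central cytoplasm,
at the inner thylakoid surface, or out at the plasma membrane is the
biological question; at confocal resolution (pixels of 24 nm, PSF of
~200 nm FWHM) the distances involved are a handful of pixels, so the
quantification has to be careful and reproducible. The pipeline implements
five measurements:

1. **Segmentation.** Cell outlines come from the pigment channel: a 2×2-pixel
   uniform blur (below optical resolution, noise suppression only), a global
   Otsu threshold, hole filling (pigment fluorescence is a peripheral shell,
   so thresholding yields annuli), watershed splitting of touching cells on
   the negated Euclidean distance transform, and removal of objects smaller
   than 0.3 µm². Cells touching the image border are flagged and excluded
   from measurements. Watershed markers are the regional maxima of an
   h-suppressed (h = 2 px), Gaussian-smoothed (σ = 3 px) distance transform:
   smoothing is needed because pixel-scale outline wobble fragments the flat
   axial EDT ridge of a rod into many spurious maxima, and taking maxima on
   the morphological reconstruction (rather than the raw h-maxima output)
   keeps each merged maximum a single connected marker.

2. **Radial (short-axis) profiling.** For each cell, an 8-pixel-wide line
   across the short axis through the centroid gives per-channel profiles; the
   two thylakoid peaks (highest local maximum per side of the centroid, ties
   broken outward, parabolic sub-pixel refinement) define the normalized
   coordinate u, affine in position with u = −0.5 and +0.5 at the peaks.
   This normalization compensates for variable cell width and makes radial
   positions comparable across cells. Profiles are linearly interpolated onto
   a common grid with 101 points between the peaks (the count is a package
   choice; only "the same number for all cells" is essential). Punctate
   signals are 2-D local maxima inside the mask exceeding the in-cell median
   by 5 median absolute deviations, localized with intensity-weighted 3×3
   sub-pixel refinement and projected onto the cell's short-axis coordinate.
   Detection runs on the blurred, *unsubtracted* channel: per-cell median
   subtraction floors roughly half the in-cell pixels at zero, which
   collapses the MAD and with it any robust detection threshold, whereas the
   median/MAD pair on the raw channel is robust as long as punctate signal
   occupies less than half the mask. Compartment calls use a configurable
   thylakoid-zone half-width (default 0.1 in u): central (|u| < 0.4),
   thylakoid (0.4–0.6), beyond (> 0.6, the plasma-membrane side).

3. **Colocalization.** Per cell, the Pearson correlation of two channels'
   in-mask pixels, with the signal/background split chosen by Costes'
   automatic procedure: regress b on a (ordinary least squares by default,
   total least squares behind a flag), scan the candidate threshold T_A
   downward over the distinct observed intensities of a with T_B = m·T_A + c,
   and stop at the highest pair for which the pixels below both thresholds
   are no longer positively correlated. The correlation is then computed over
   pixels above either threshold (an `all` pixel-set option computes it over
   all in-mask pixels instead; both choices are logged because the original
   analysis does not state which was used). An undefined below-set
   correlation is treated as inadmissible and the scan continues; if no
   candidate qualifies, or the regression slope is non-positive, all pixels
   are retained and the result flagged.

4. **Scalar intensity metrics.** Mean in-mask intensity; *patchiness*, the
   sample SD of in-mask intensities divided by the summed in-mask intensity —
   deliberately not a coefficient of variation. Patchiness highlights sharp
   foci against diffuse background and is the right readout when a
   transcript's total FISH signal is small compared to cellular
   autofluorescence; because the sum grows with cell area the metric is not
   dimensionless across cell sizes, so it is reported alongside cell area
   and compared only within identical acquisition settings. The
   *membrane band* statistic thresholds the pigment channel inside the mask
   (Otsu) to select the thylakoid region, fills its holes, and takes every
   pixel within 0.2 µm outward of it (8 px at 24 nm, rounded half-up) as the
   plasma-membrane zone; the hole-filling matters, since a band grown inward
   as well would be contaminated by central-cytoplasm signal. Reported as the
   band mean and the band share of the whole-cell-plus-band total. The
   *polar:equatorial ratio* splits the mask by projection onto the long axis
   into two polar caps (outer 20 % of the projected extent each, a package
   definition — no standard one exists) and the equatorial remainder, and
   reports the ratio of mean intensities.

5. **Probe design.** FISH probe sets are built by a deterministic greedy scan
   of the target mRNA: accept the first 20-nt window with GC in 45–55 %
   (the tolerance encodes "about 50 %"), jump 22 nt (probe plus the 2-nt
   minimum gap), repeat; cap at 48 probes. Probes are emitted 5′→3′ as
   synthesized (reverse complement of the target window) with the 3′
   fluorophore recorded as metadata. Fewer than 40 probes triggers a warning
   rather than an error — small sets hybridize too little label for reliable
   detection. No melting-temperature or off-target screening is attempted.

6. **Reporting.** Two-sample comparisons use the pooled-variance two-tailed
   Student's t-test (Welch behind a flag); summaries use inclusive
   (linear-interpolation) quantiles; box plots draw whiskers at the full
   range, the box at the IQR and the line at the median; violin plots carry
   guide lines at u = ±0.5. P-values are reported raw; Benjamini–Hochberg
   is an explicit opt-in.

## The synthetic-data generator

Cells are 2-D spherocylinders (the imaging is a thin confocal section of a
rod, so no 3-D rendering), placed without overlap by rejection sampling,
with lengths 2.5–3.5 µm and widths 0.9–1.1 µm. Per channel the generator
renders:

* a **pigment channel**: a Gaussian ridge in the distance-to-centerline
  coordinate, peaking at 0.7 of the cell half-width (this ridge defines
  |u| = 0.5), width σ = 0.06 u-units, total flux 2×10⁶ counts per cell,
  plus a diffuse interior pigment level of 60 counts/px — real pigment
  fluorescence is not strictly membrane-confined, and the interior level is
  also what lets a single global threshold recover the full cell outline;
* **focus channels**: isotropic 2-D Gaussian foci (σ = 60 nm) with
  log-normal fluxes (median 9×10⁴ counts, giving post-blur peaks roughly
  5× the background SD), positions drawn from configurable u-distributions
  (central: truncated normal, σ = 0.12, |u| ≤ 0.3; membrane: |u| uniform on
  0.5–0.68 with random sign), uniform longitudinal placement with a minimum
  inter-focus spacing of 14 px so that rendered foci remain individually
  resolvable, plus a diffuse in-cell background of 80 counts/px with an
  optional polar-cap enrichment factor.

Rendering is flux-preserving (every component is normalized to its
configured total on the pixel grid) before a Gaussian PSF (σ = 100 nm,
appropriate for NA 1.4 and far-red emission) and noise (Poisson at unit gain
plus Gaussian read noise, σ = 3 counts) are applied; all randomness hangs
off a single seed, and identical configurations are bit-identical. Ground
truth records cell poses, per-focus true u and flux, and per-cell,
per-channel fractions of pre-blur signal in the central (|u| < 0.4), shell
(0.4–0.6) and beyond-shell (> 0.6) compartments.

The generator emulates the signal classes the pipeline measures, not the
full physics of acquisition: no 3-D structure or defocus, no photobleaching,
no spectral bleed-through beyond one optional crosstalk coefficient, no
structured autofluorescence. Passing recovery tests therefore demonstrates
that the *measurement code* is correct and calibrated on scenes with known
answers — not that real micrographs are free of segmentation or background
pathologies the simulator does not model. One consequence worth keeping in
mind on real data: optical blur moves flux across compartment boundaries, so
band fractions and compartment calls near boundaries are blur-biased; the
blur-free recovery tests isolate the measurement geometry from that bias.

## Numerical and design choices

* Coordinates are 0-based (row, col) pixel indices; physical distances come
  from the 24 nm pixel pitch; orientations are axial angles in [0, π).
* Degenerate inputs are errors or flags, never silent: constant channels
  (Pearson, Costes), zero total fluorescence (patchiness), fewer than two
  thylakoid peaks (profile), empty band or caps (region metrics).
* Background subtraction (per-cell median, floored at zero) is a logged
  strategy switch (`median`/`none`); patchiness is computed on whichever
  image it is handed (before subtraction by default in the CLI).
* Thylakoid-peak ties take the outermost candidate; focus detection ties are
  resolved by `skimage.feature.peak_local_max` ordering, which is
  deterministic.
* Test and benchmark problem sizes (fields of 512–768 px with 10–16 cells,
  200-focus recovery runs, 2,000-replicate type-I calibration) were chosen
  as the smallest scenes at which the measured quantities stabilize.

## Known limitations

* The u coordinate is built from one short-axis profile per cell and applied
  to all foci via the cell-local frame; cells with bent axes or asymmetric
  shells would need per-focus profiling.
* Costes thresholds on channels with no true correlation are well-defined
  but not meaningful — the scan stops wherever the below-set correlation
  first dips to zero; the `all_retained`/`anticorrelated` flags mark cells
  where the threshold carries no information.
* Focus counting, molecule counting per focus, and 3-D localization are out
  of scope.
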