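# Methods

This note documents the models behind `ramanmsi`: what the simulator
assumes, which parameters matter, the numerical choices made where the
design was genuinely open, and what the passing tests do and do not show
about real instruments and real tissue.

## Spectral library

Each tissue class is a sum of Gaussian bands on a shared 1 cm⁻¹ grid from
260 to 1900 cm⁻¹. Band *positions* follow skin Raman biochemistry: BCC
carries the nucleic-acid bands (788 cm⁻¹ O–P–O, 1098 cm⁻¹ PO₂⁻), dermis
the collagen bands (851, 950 cm⁻¹ proline/hydroxyproline, amide III around
1245–1271 cm⁻¹), lipid-rich tissue the CH₂/C–C/C=C set (850, 1070, 1267,
1301, 1450, 1660, 1745 cm⁻¹); phenylalanine (1004 cm⁻¹) and the CH₂
deformation (1450 cm⁻¹) appear in every tissue class, and every class has
a CH₂-twist band inside 1279–1327 cm⁻¹ — without it the A₇ denominator of
the A₆/A₇ ratio hovers near zero and that feature becomes numerically
meaningless, which is not what real tissue does. Band *widths* default to
8–20 cm⁻¹ FWHM and relative amplitudes to order-one values; the
literature gives positions, not a quantitative per-class intensity table,
so the amplitudes are a modelling choice made once. Each class also has a
smooth 4th-order-polynomial fluorescence baseline with a class-specific
scale; the surgical marking dye is modelled as a very strong broad
baseline (6× the tissue scale) plus two very broad humps, which is what a
fluorescent dye looks like through a Raman spectrograph.

The grid extends down to 260 cm⁻¹ so that the MgF₂ substrate band at
320 cm⁻¹ survives the dispersion offsets of off-axis beams.

## Tissue phantom

The phantom is a label image plus an AF image plus a dye mask. AF
intensities are drawn per class from Gaussian distributions chosen so
that BCC (13000 ± 2500), epidermis (12000 ± 2500) and fat (11500 ± 2500)
overlap heavily — AF detects these structures but cannot separate them —
while dermis (3000 ± 700) and bare substrate (300 ± 60) are clearly
darker. This encodes the working premise of the whole method: AF has high
sensitivity and low specificity, and Raman supplies the specificity. Dye
contamination is placed on a configurable fraction (default 25%) of
pixels within a 20 µm halo of the tumour, where marking dyes bleed in
practice.

What the phantom does **not** model: 3-D tissue structure and
depth-of-field mixing, spatial texture within a class, hair follicles and
other rare confounders, inter-patient spectral variability. A classifier
that is perfect here can therefore only be said to be *consistent*; the
printed clinical sensitivity/specificity of the original patient study is
out of reach of any simulation and is not claimed.

## Instrument forward model

One exposure = one batch. For each beam the emission (class basis +
fluorescence baseline + dye term + MgF₂ band) is convolved with a
Gaussian pseudo-slit kernel (default 6 cm⁻¹ FWHM), evaluated at the
wavenumber each detector column disperses to (ground-truth cubic
ν(c) = 260 + 1.72c − 10⁻⁴c² + 2·10⁻⁸c³ over 1024 columns), scaled by
`gain × weight × t_int`, and written to two adjacent rows of the
256 × 1024 CCD (256 rows / 60 µm ≈ 4.3 rows/µm; column offset
0.1 col/µm of in-FOV x-offset, plus a per-beam uniform ±2 cm⁻¹
dispersion jitter that the MgF₂ correction later removes). Detector
noise: Poisson shot noise, 5 counts RMS Gaussian read noise, 100-count
bias, Poisson-count cosmic rays (single-pixel spikes, amplitude up to
full well, 2 per frame), clipping at the 16-bit full well.

Power sharing: the 0th order carries 10× the throughput of the strongest
1st order; 1st-order throughput falls off quadratically to 0.1 at the FOV
edge (hologram efficiency plus vignetting). For ≤ 10 beams the blazing
level can be optimized so all beams receive similar power;
`equalize_beam_weights` models that operating point by redistributing the
batch total evenly.

The photon gain (800 counts per basis unit per second for the two-track
sum at unit weight) was fixed once so that a weight-1 beam at 2 s lands in
the SNR regime the method is reported to operate in (SNR tens at the
1450 cm⁻¹ band; edge beams near the diagnostic floor). The per-beam power
arithmetic (3.6 W × 33% / 10 ≈ 119 mW) is kept separate from the
throughput weights; the simulator does not attempt a radiometric
counts-per-milliwatt calibration, and it deliberately does not reproduce
the inconsistent printed power-density figure.

## Holograms

The far field is a single centred FFT of the unit-amplitude phase field —
no aberrations, no device look-up table. `gratings_and_lenses` takes the
argument of the complex sum of per-spot linear ramps (the constant term
of the always-present 0th-order spot breaks the binary-phase degeneracy,
so an origin peak always exists). Spot power is the summed intensity in a
3 × 3 window. Blazing scales the phase-modulation depth about the
circular mean: b = 1 leaves the pattern, b = 0 sends all power
undiffracted, intermediate b transfers power monotonically into the 0th
order; `optimize_uniformity` scans b on a grid (1.0 → 0.05, step 0.05) and
keeps the max/min spot-power ratio minimizer.

Gerchberg–Saxton alternates amplitude constraints in the two planes from
a seeded random far-field phase. The error it reports is the normalized
far-field amplitude mismatch — the error-reduction distance, which is
provably non-increasing; intensity correlation on the target support
(used for quality checks, ≥ 0.9 after 30 iterations on a 5-spot target)
is monotone only in practice, not in theory, and is exposed separately.

## AF segmentation and sampling points

"Maximum homogeneity" thresholding is implemented as multi-level Otsu
(thresholds minimizing pooled within-class variance, verified in tests
against an exhaustive scan), followed by connected-component splitting of
every intensity band and merging of components below a minimum area into
their surroundings. All bands become segments — bare substrate simply
yields dim segments; `generate_sampling_points` skips segments whose mean
AF falls below 10% of the image mean (configurable), since there is
nothing to diagnose on glass.

Per-segment point count = max(min_per_segment, area × density ×
priority), priority = (segment mean AF / global mean)^γ with γ = 1, so
AF-bright structures are sampled more densely; the exact priority rule of
the original instrument software is not public, and γ is configurable,
not canonical. Points are placed by seeded best-candidate blue-noise
sampling inside the segment mask; a singleton lands on the segment's
interior pole (deepest-inside pixel). The AF→Raman stage mapping is a
6-parameter affine least-squares fit to landmark pairs (affine rather
than similarity, because stitched mosaics can shear slightly).

## Batch planning

k-means on the stage coordinates with k starting at ⌈N/6⌉ and growing by
1 (with a few deterministic re-seedings per k — more when the partition
is nearly feasible) until every cluster (a) has ≤ 6 members, (b) fits in
one 180 × 60 µm FOV *centred on its 0th-order member* (the member closest
to the cluster centroid; stage target = that member), (c) has pairwise
vertical gaps ≥ 10 µm, and (d) leaves enough vertical slots to pad to 6.
Infeasible groups are split: first by greedy first-fit interval grouping
on the vertical axis, then by halving. Padding draws fills uniformly in
the FOV, rejection-sampled against the separation constraint *and*
against destroying the remaining packing capacity; when rejection fails,
fills snap to canonical slots packed outward from existing members (any
subset of which is mutually separated). Fills are excluded from the
0th-order centroid so padding never moves the measurement anchor. The
vertical axis of the separation constraint is the 60 µm FOV dimension
(the CCD row direction); the minimum separation is configurable because
tighter spacings are physical for strongly scattering samples.

Acquisition time = batches × integration time × overhead multiplier
(default 1; stage moves, readout and hologram computation roughly double
it in practice).

## Readout and preprocessing

Per beam: sum the two tracks (despiking by track disagreement: where
|a − b| exceeds 6× the expected shot+read noise of the difference, the
sum becomes twice the lower track; coincident double hits fall back to a
5-point rolling median), subtract the constant bias, assign wavenumbers
with the cubic fitted to the five polystyrene fingerprint peaks (620.9,
1001.4, 1031.8, 1155.3, 1583.1 cm⁻¹ — conventional values, configurable),
translate the axis on the MgF₂ substrate band (quadratic sub-bin peak
interpolation), crop to 520–1830 cm⁻¹ and resample to the shared 1 cm⁻¹
grid (1311 points for every beam), and SNV-normalize. Classification
re-crops to 600–1800 cm⁻¹; both ranges are honoured.

One design point deserves emphasis: the MgF₂ correction aligns every beam
to the **apparent** substrate-peak position of the calibrated 0th-order
polystyrene reference, not to the absolute 320 cm⁻¹. The fitted cubic
extrapolates below its lowest anchor (620 cm⁻¹) with seed-dependent
errors of several cm⁻¹ at 320 cm⁻¹; aligning to the absolute value would
turn that extrapolation error into a global axis shift that moves the
narrow A₄ window off the phenylalanine band. Aligning to the shared
apparent position removes exactly what the correction exists to remove —
per-beam dispersion offsets — and leaves all spectra on one mutually
consistent axis. For the same reason, classifier training spectra are
analyzed with the *run's fitted* calibration and MgF₂ reference, exactly
as the measurements are; in the real workflow this consistency is
automatic because reference raster scans pass through the same
instrument.

SNR follows the stated definition: signal = baseline-subtracted maximum
in 1440–1460 cm⁻¹ (local linear baseline through the 3-sample edge
means), noise = RMS of the linearly detrended 1490–1510 cm⁻¹ region.
Height rather than area is used for the signal because the noise is an
RMS and a height/RMS ratio is dimensionally natural.

## Classifier

Band areas use the windows as printed, including the A₂ ⊂ A₃ overlap
(implemented literally). Local baselines anchor on the mean of 3 samples
at each window edge. Features are the five stated ratios; A₄ = 0 or
A₇ = 0 flags the spectrum unclassifiable.

The dye/fat screen: principal-component scores 2 and 3 are always
computed (sign-fixed so each loading's largest element is positive). When
the spectral library is available — always, in this simulated workflow —
each spectrum is compared by normalized correlation against the dye and
lipid signatures and the three tissue-class signatures, and removed only
when a contamination template is its nearest match. A pure
PC2/PC3-threshold rule proved structurally brittle in simulation: which
component carries the lipid contrast rotates from run to run, a
20%-abundance fat population can sit just inside a 4-MAD cut, and whole
tissue classes can sit outside it. Without a library the PC-threshold
rule (3 robust SDs from the component median) is the fallback, labelling
outliers as unknown contamination.

The 3-class multinomial logistic regression runs on robustly standardized
features (median/MAD — the ratio features are heavy-tailed).
Regularization C is chosen on a grid {0.01…100} by stratified 5-fold CV
maximizing mean fold specificity subject to mean fold sensitivity ≥ the
95% target; the BCC threshold is tuned on each training fold as the
largest threshold keeping training sensitivity ≥ target (a quantile of
the BCC class's P(BCC)), so held-out sensitivity concentrates at the
target by exchangeability. "Specificity" counts all non-BCC model classes
together. Fat and dye never reach the model: segments whose surviving
spectra are majority-screened as fat or dye are called that class
directly; segments with no surviving spectra (e.g. all saturated) are
marked unmeasured.

## Problem sizes used in tests and benchmarks

The default end-to-end phantom is 256 × 256 px at 4 µm (≈ 1 mm², ~60 AF
points, ~60 batches, ~6 s wall time). The canonical batch-accounting
scenario uses 794 points in 318 clusters on a 500 µm grid. SNR benchmarks
use 20 seeded replicates of 6- and 10-beam batches; the sensitivity
benchmark 500 spectra per class, 10 seeds in the acceptance script and 3
in the test suite. These sizes keep the full suite under two minutes
while leaving every statistical margin wide (SNR margins ≥ 2×, accuracy
margins several points).

## Known limitations

- The simulator's class separability is set by the hand-chosen band
  amplitudes; end-to-end accuracy numbers certify pipeline correctness,
  not clinical performance.
- The hologram model is aberration-free and LUT-free; absolute
  diffraction efficiencies are not predicted, only relative power
  distribution behaviour.
- The planner reproduces the padding invariants and totals of the
  canonical scenario, but the AF-point-to-batch ratio of a real section
  depends on its geometry.
- No dark/flat-field detector correction beyond constant bias; no
  travelling-salesman ordering of stage moves; batch order is
  construction order.
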