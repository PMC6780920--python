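# Methods

## Problem setting

A multiplexed DIA (all-ion-fragmentation) LC-HRMS injection interleaves
full-scan spectra at several collision energies.  Because AIF applies no
precursor isolation, each MS/MS spectrum is a mixture of every co-eluting
compound's fragments; annotation therefore relies on chromatographic
co-elution between a precursor peak (0-energy MS¹ channel) and candidate
fragment peaks (one channel per collision energy), backed by targeted
libraries and peak-shape statistics.

## Pipeline

**Demultiplexing.** Scans are partitioned by (ms level, collision energy)
read from the per-spectrum metadata (mzML `collision energy` cvParam;
mzXML `collisionEnergy` attribute).  Energy 0 at any ms level is treated
as the MS¹ channel — converters disagree on whether stepped-CE full scans
are recorded as level 1 or 2.  Files lacking energy metadata can be
assigned a user-stated cycle (e.g. `0,5,10,20`) by scan order.  Retention
times are normalized to minutes whatever the file's unit, because all RT
tolerances are stated in minutes.  Polarity filtering (for
fast-polarity-switching runs) happens before the split.

**EIC extraction.** For a target m/z the per-scan match window is the
tighter of a relative ppm tolerance (default 5 ppm) and an absolute window
(default 0.005 Da, binding only above m/z 1000 at these defaults).  The
most intense centroid inside the window is kept per scan; scans without a
match get zero-intensity placeholders so the RT grid is preserved, and the
per-scan signed ppm deviation is recorded for QC plotting.

**Peak detection.** The pipeline is targeted, so untargeted feature
finding is unnecessary: peaks are maximal runs of consecutive
above-threshold EIC points, recursively split at interior local minima
that fall below a valley fraction (default 0.5) of the smaller flanking
maximum.  Runs shorter than `min_scans` (default 3) are dropped.  Area is
trapezoidal on the raw trace.  When several peaks match one target all
are reported ranked by apex intensity; annotation keeps rank 1 and logs
the alternates.

**Asymmetry factor.** f = (t_Rf − t_Rmax)/(t_Rmax − t_Ri) on the detected
span — deliberately the whole-edge ratio, not the conventional 10 %-height
tailing factor.  f = 0 flags degenerate peaks (< 3 scans, or apex on an
edge scan, where a numerator or denominator vanishes).  On a uniform grid
a mirror-symmetric peak has f = 1 exactly.

**Smoothing.** Matched peaks are spline-smoothed before correlation
scoring only; detection, areas, f, IPIR and F/P ratios always use the raw
trace.  `smoothing-spline` (default) is `scipy` `UnivariateSpline` with
the residual budget set from the noise variance estimated by second
differences (var ≈ mean(Δ²y)²/6), so a noiseless trace passes through
unchanged; `cubic-spline` interpolates exactly.  Peaks under 4 scans pass
through unsmoothed; fitted negatives clamp to 0.

**Scores and decision rule.** PPC is the standard Pearson correlation
(`scipy.stats.pearsonr`, two-sided p-value) of two smoothed traces over
shared scans — matched by scan id on a common channel, else by nearest RT
within half the median scan period; fewer than 3 shared scans makes PPC
undefined, which rejects with reason "insufficient scans".  PPS = f₁/f₂
on raw-peak asymmetry factors (0 when either f is degenerate).  IPIR uses
apex intensities of the monoisotopic and +1 peaks; its >1 pass rule is
suppressed when the formula contains S or Br, whose natural isotope
patterns legitimately invert the ratio.  Accept iff PPC ≥ 0.7 and
0.3 ≤ PPS ≤ 3, both bounds inclusive; the F/P ratio is reported without a
cutoff.  The inclusive upper PPS bound matters: a pair scoring PPS
exactly 3.00 fails only if its PPC is also below the cutoff.

**MS¹ annotation.** Theoretical m/z per (entry × adduct × isotopologue
0/+1) from a bundled monoisotopic atomic-mass table (≥ 6 decimals);
adduct registry [M+H]⁺ +1.007276, [M+NH₄]⁺ +18.033823, [M+Na]⁺
+22.989218, [M−H]⁻ −1.007276, user-extensible since real libraries vary;
the +1 isotopologue offset is fixed at +1.003355 Da (¹³C−¹²C), the
dominant channel for CHNO metabolites.  Fragment cation m/z subtracts the
electron mass — needed to match 4-decimal printed values (e.g. C₄H₆NO⁺ →
84.0444).  The +1 isotopologue is only annotated when the monoisotopic
ion was found and co-elutes within 0.08 min.

**AIF annotation.** The precursor anchor always comes from the MS¹
channel; a precursor ion surviving inside the MS/MS spectra is handled as
an ordinary library fragment.  Fragment matches require the mass window
and apex-to-apex |ΔRT| ≤ 0.08 min; among several candidates the smallest
ΔRT wins, ties broken by intensity.  The minimum-fragment constraint
(≥ 1 … all) controls group retention, and by construction the "all
fragments" annotation set is a subset of the "≥ 1 fragment" set.

## Key parameters

| parameter | default | unit | note |
|---|---|---|---|
| ppm tolerance | 5 | ppm | MS¹ and MS/MS matching |
| m/z window | 0.005 | Da | absolute cap alongside the ppm tolerance |
| RT tolerance | 0.08 | min | precursor–fragment apex alignment |
| PPC cutoff | 0.7 | – | inclusive |
| PPS band | 0.3 – 3 | – | inclusive both ends |
| min scans per peak | 3 | scans | below → no peak / f = 0 |
| valley split fraction | 0.5 | – | interior-minimum split rule |
| ubiquity threshold K | 5 | entries | library validation |

## Synthetic runs

The simulator emulates a stepped-CE acquisition: four channels (CID
0/5/10/20 eV) cycling at 4 spectra/s, i.e. a 1-s per-channel scan period;
Gaussian peaks with σ = 0.04 min (≈ 14 s FWHM, typical for short
reversed-phase gradients), or exponentially-modified Gaussians when a
tailing constant τ is set (EMG gives controllable asymmetry with a smooth
apex).  Per-centroid m/z jitter is uniform within a ppm bound (default
2 ppm); noise centroids are uniform in m/z with exponentially distributed
intensity at the floor.  The +1 isotopologue renders at the stated
intensity ratio on the MS¹ channel, fragments only in their collision
energy channel at the stated F/P ratio.  Identical seeds give
byte-identical mzML.

It does **not** emulate isotope fine structure, adduct-formation
equilibria, detector saturation, ion suppression, or RT drift between
channels.  Passing recovery tests therefore demonstrates the correctness
of the extraction/alignment/scoring machinery, not robustness to matrix
effects in real biological runs.

Test and acceptance problem sizes were chosen to keep the whole suite in
the seconds range while leaving every statistic well determined: runs of
~0.75 min RT span (≈ 45 scans/channel), 3 spiked metabolites, 20–50
seeded replicates per recovery statistic, 1000 random pairs for the
Pearson-oracle comparison.

## I/O

mzML 1.1 and mzXML 3.x are parsed with a compact lxml implementation
(centroid spectra; base64 little-endian 32/64-bit floats, optional zlib;
mzXML's network-order interleaved peak pairs), and a deterministic mzML
writer supports the simulator and round-trip tests.  Profile-mode spectra
are rejected with a clear error — centroiding belongs upstream in the
converter.  Libraries are RFC-4180 CSV; the MS/MS dialect stores both
precursor m/z and (optionally) neutral mass and cross-checks them through
the adduct registry at load time.

## Library curation checks

`validate_library` flags AIF entries whose every fragment lies below m/z
50 (unusable when acquisition starts at m/z 50) and single-fragment
entries whose only ion is shared within 5 ppm by more than K other
entries (no specificity, e.g. the 72.0444 alanine immonium ion).  The
20 %-relative-abundance curation guideline for selecting library
fragments is documented here but not executed, because reference spectra
intensities are not part of the library format.  Validation never mutates
the library unless `strict` is set.

## Known limitations

- Only |z| = 1 adducts and the +1 isotope channel; no isotope-pattern
  simulation beyond that.
- No spectral dot-product/cosine matching, SWATH-style window
  deconvolution, or decoy-based FDR — annotations are tolerance- and
  score-gated only.
- HCD "%" and CID "eV" energy labels are opaque strings; no
  cross-instrument conversion.
- The nearest-RT scan pairing assumes channels sample the same gradient;
  runs with per-channel RT offsets larger than half a scan period would
  need alignment first.
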