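# Methods

## The measurement and its model

A mass photometer records, for every particle that lands on the
glass–water interface during a 60-s acquisition, one dimensionless
*ratiometric contrast* value. Within one material class the contrast
magnitude is proportional to particle mass; by the sign convention used
throughout this package mass-binding events are negative, so heavier
particles land further left in the event histogram. `mpsize` works on
event lists only — video processing and landing-event detection are the
instrument's job and out of scope.

Genome length in an AAV sample is inferred by one of three routes:

1. **Approach 1 — filled minus empty, external calibration.** The contrast
   difference between the filled- and empty-capsid peaks, Δc = c_filled −
   c_empty, isolates the genome's contribution. A linear calibration built
   from protein standards converts Δc to a mass difference ΔM (kDa), then
   to bases via the conversion factor 309 kDa per 1,000 bases (the mean
   chain-residue mass of the four dNMPs, ≈308.9 Da/base). dsDNA-ladder
   calibrations convert Δc to base pairs and double (1 bp = 2 bases); RNA
   and circular-ssDNA-plasmid calibrations convert directly to bases.
2. **Approach 2 — AAV-based calibration.** AAVs of known genome length are
   themselves the calibrants. The Δ-contrast variant regresses
   filled-minus-reference contrast differences on genome length (reference:
   empty capsid or, equivalently, a 3,643 kDa high-molecular-weight
   standard); the absolute variant regresses filled-peak contrasts directly,
   optionally including the empty capsid as a 0-base point.
3. **Approach 3 — genome release.** The capsid is disassembled (heat, or
   heat in 1 % SDS followed by surfactant removal) and the free ssDNA
   genome's own peak is sized on a single-stranded nucleic acid
   calibration. Sizing is refused if any intact-AAV peak remains
   (incomplete disassembly).

## Peak analysis

Events are smoothed by Gaussian kernel density estimation rather than
binned histograms. The bandwidth is declared in calibrated units — 40 kDa
(or 120 bases / 120 bp) for intact-AAV analysis, 50 bases for released
genomes — and converted to contrast units through a provisional
contrast-per-unit slope. Before any calibration exists the provisional
slope comes from the package's anchor coefficients (below); after a first
calibration its `slope_per_base` supersedes the guess. The grid spans the
event range ±3 bandwidths with at least 8 nodes per bandwidth (2,048 nodes
minimum, 65,536 cap), so narrow kernels stay resolved even when stray
aggregate events stretch the range.

Candidate peaks are local density maxima with prominence ≥ 10 % of the
global maximum, expanded to windows of ±2 bandwidths and truncated at the
density minimum between neighbours. Each window receives a least-squares
single-Gaussian fit to the smoothed density, initialised at the windowed
mode with the sample SD of the windowed events, followed by one refit on
the window recentred to μ̂ ± 2.5 σ̂ (the first window can clip a peak's
flanks when the declared bandwidth is narrower than the population width;
the refit repairs that). Windows whose raw event count falls below 50 are
flagged low-confidence, not rejected; ~300 events per population is the
design target. A window whose events are all identical (a possibility in
noiseless simulations) short-circuits to an exact delta fit with the sigma
pinned at a 10⁻⁶ floor and a `degenerate` flag.

Fitted peaks are classified by contrast magnitude: fragments below 0.030,
released genomes in 0.030–0.07, intact AAVs in 0.10–0.20, aggregates above
0.5 (all configurable). The fragment bound is read as a magnitude — the
fragment region is the *low*-mass side — although the band edges are the
one place where large drifts can push a population out of its band. With
two peaks in the AAV band the lower-magnitude one is the empty capsid (or
spiked HMW standard) and the higher the filled capsid; a third candidate
raises an ambiguity error for the caller to resolve from the sample sheet;
when two filled candidates survive elsewhere the more populous peak wins.

## Calibration and inversion

All families fit contrast as a linear function of response (OLS, intercept
always estimated), matching the convention in which slopes are quoted in
contrast per base; prediction inverts the line analytically, response =
(c − intercept)/slope. The fitted-line orientation is documented rather
than argued over: for well-conditioned calibrations the two orientations
agree to well below the measurement noise. Contrast *differences* are
converted through the slope alone, so the intercept cancels — except for
the Δ-contrast AAV family, whose regressed quantity is itself a
difference and therefore uses its full line. The circular-ssDNA plasmid
family always contains the (0, 0) point as an ordinary datum (appended
automatically if absent), never as a constraint. Urease contributes two
points (272 and 545 kDa oligomers).

Leverage diagnostics use the hat-matrix diagonal of simple linear
regression, h_i = 1/n + (x_i − x̄)²/Σ(x_j − x̄)². For the absolute AAV
calibration with responses {0, 3793, 4142, 4504, 4596, 4658} bases the
0-base empty point carries h ≈ 0.973 — nearly saturated — which is why
including or excluding it changes the slope substantially and why the
Δ-contrast variant is preferred whenever a reference can be spiked.

## Study aggregation and resolution

Replicate estimates are averaged within each measurement day first; mean,
SD (ddof = 1) and %CV = 100·SD/mean are computed across the day means
(n = days, typically 3, with 3–4 replicates per day). Accuracy is
100·mean/expected and is omitted — not reported against zero — when the
expected length is unknown; an expected length of 0 means an empty capsid
and is a legitimate value. A single day reports SD/%CV as not applicable
rather than zero. Display rounding is fixed (integer bases and accuracy,
one-decimal %CV) so table-style output is reproducible; full precision is
retained internally and in report JSON.

The within-sample resolution limit uses the separation at which two equal
Gaussian peaks stop being bimodal, taken as the full width at half
maximum: Δbases_min = k·σ/|slope per base| with k = 2.355 (configurable).
With σ = 0.0015 contrast and slope 8.8×10⁻⁶ per base this gives ≈400
bases; k is a declared criterion choice, since bimodality thresholds
between 2σ (merged) and 4σ (clearly split) are all defensible.

## The simulator

The generative model is linear contrast-vs-size with per-class
coefficients plus Gaussian event noise (σ = 0.002 contrast) and one
additive offset per acquisition (drift, SD 0.001) — chosen as plausible
instrument-scale values; no peak widths are published for these
populations, so σ is a stated assumption rather than a fitted one.

Anchors and coefficients:

* `alpha_free_ss` = 0.041/4,658 ≈ 8.80×10⁻⁶ contrast per base of free
  linear ssDNA, anchoring the released 4,658-base genome at −0.041.
* `alpha_capsid` = `alpha_free_ss`/0.309 ≈ 2.85×10⁻⁵ contrast per kDa for
  protein-class particles (proteins, capsids, HMW standard). Tying the
  mass route to the ssDNA anchor keeps one contrast-per-base scale across
  routes and places the 3,700 kDa empty capsid at ≈ −0.105, inside the
  −0.1…−0.2 intact-AAV band.
* `class_ratio` encodes the empirical material-class biases as
  configuration, not optics: free RNA, circular ssDNA and dsDNA scatter
  per base at `alpha_free_ss` divided by 1.10, 1.19 and 1.47 respectively
  (dsDNA per bp = 2 bases' worth), so sizing an encapsidated genome
  against those ladders overestimates by the ratio. The
  `protein_mass_route` ratio (1.03) is implemented as an encapsidation
  factor: the genome inside a capsid contributes 1.03 × 0.309 kDa/base of
  apparent optical mass, so even the mass route is slightly biased while
  the protein calibration itself stays perfectly collinear (the empty
  capsid is both a calibrant and the sample's reference, so it cannot
  carry two different coefficients).

Intact samples are empty/filled multinomial mixtures (masses 3,700 and
3,700 + ratio×0.309×L kDa), optionally spiked with the HMW standard.
Release runs put the genome at −`alpha_free_ss`·L and add artifact events:
fragments uniform in magnitude below 0.030 and aggregates uniform in
0.5–1.0, with shares 25 %/5 % for the heat-only workflow and 5 %/0.5 %
for heat+SDS — invented magnitudes that reproduce the qualitative
contrast between the workflows, not measured rates. Identical seeds give
bit-identical output.

What the simulator deliberately does **not** emulate: iSCAT optics and
refractive-index physics (the class ratios stand in for them), partially
filled capsids, landing-rate/titer kinetics, focus drift within an
acquisition, non-Gaussian peak shapes, and correlated noise. Passing
recovery tests therefore demonstrates that the analysis chain is correct
and self-consistent under the stated noise model — not that an instrument
will achieve the same accuracy on real material.

## Validation studies and problem sizes

`mpsize.validation` (driven by `scripts/acceptance.py`) runs three seeded
recovery studies sized like the underlying measurement design — 3 days ×
3 replicates, 300 events per population — which keeps each study in the
seconds range on one CPU:

* **Approach 1**: per day, one protein calibrant set plus three intact
  acquisitions of a 4,658-base sample (50 % empty spike); the mass-route
  ratio is set to 1.0 so the reported error isolates measurement noise.
  Error = mean over days of |day-mean − truth|/truth.
* **Approach 2 (Δ contrast)**: per replicate, all five study samples
  (3,793–4,658 bases); the 4,658-base sample is sized leave-one-out on
  the line built from the other four. Drift cancels in the differences,
  so the error is dominated by peak-position noise ≈ σ/√n.
* **Approach 3**: three replicate SDS-workflow releases sized on a
  noiseless plasmid calibration whose circular-ssDNA coefficient is
  matched to the released genome; the surviving error is peak noise plus
  the per-measurement drift that this route, lacking an internal
  reference, cannot cancel — the documented cost of approach 3.

## Known limitations

* Single-Gaussian fits per window; overlapping sub-populations within one
  peak (e.g. partial filling) are reported as one population.
* Classification bands are fixed magnitudes; gross drift can move a
  population across a band edge.
* The filled/empty event-count ratio is exposed but not validated as a
  quantitation feature.
* The simulator's class ratios are configuration derived from observed
  accuracies; they carry no optical meaning and should be recalibrated
  per instrument and material batch.
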