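# Methods

## Problem and signal model

Diffuse in vivo flow cytometry (DiFC) counts fluorescent circulating
tumor cells (CTCs) non-invasively: two fiber-optic probes, separated by
3 mm along a superficial blood vessel, excite fluorescence with a 488 nm
laser and collect diffuse emitted light onto photomultiplier tubes.  In
the two-color instrument each probe feeds a green (GFP-band) and an
orange (tdTomato-band) channel, giving four uniformly sampled mV time
series per scan (P1-G, P1-O, P2-G, P2-O).  A cell or cell cluster
transiting a probe's sensing region appears as a transient unimodal spike
on the channels of the fluorophores it carries; the same event reappears
on the second probe after the transit time over the probe separation,
which also reveals the flow direction (forward = arterial, reverse =
venous).

## Processing chain

1. **Background subtraction** — subtract the median of a moving 5 s
   window (tissue autofluorescence drifts on many-second timescales;
   transit spikes last tens of milliseconds, so the median ignores them).
2. **Noise estimation** — standard deviation (ddof = 0) of the
   background-subtracted signal in a moving 1 min window.
3. **Candidate peaks** — local maxima with amplitude ≥ k·σ(t), k = 5,
   i.e. a minimum peak SNR of 20·log₁₀(5) ≈ 13.9 dB.  Candidates closer
   than half a peak width are merged (one transit, one peak).
4. **Artifact rejection** — candidates co-occurring on all four channels
   within 10 ms are discarded: animal/probe motion hits every channel
   simultaneously, whereas a real transit reaches the probes ≥ 20 ms
   apart.
5. **Cross-probe matching** — per color, candidate pairs whose
   inter-probe delay corresponds to 5–150 mm/s and whose amplitude and
   width agree within a factor of 2 are scored by
   |log amplitude ratio| + |log width ratio| + |delay − median delay|
   (each term normalized) and accepted greedily, each candidate at most
   once.  Unmatched candidates are discarded.
6. **Two-fluorophore classification** — coincident green + orange
   matched detections (2λ peaks) are split into true two-fluorophore
   (2FP) clusters versus bright one-fluorophore (1FP) events with
   spectral bleed, using the bleed threshold below.
7. **Sizing and scan statistics** — amplitude-based cell counts, cluster
   definitions, 2-minute moving detection rates, Pearson correlation of
   the paired color rates, the ≥ 0.5 detections/min scan-inclusion rule,
   and a flow-normalized concentration estimate.

## The bleed threshold

With amplitudes expressed in local-noise-σ units (so the detection limit
is the constant 5), the largest secondary-channel amplitude attributable
to spectral bleed from a primary peak of amplitude `I_pr` is

    max(I_sec) = I_pr (T_R I_pr + 5) / (I_pr − 5)

where `T_R` is the bleed ratio of the primary color's fluorophore into
the other filter band.  A measured `I_sec` above this threshold cannot be
bleed alone, so the detection contains cells of both colors (2FP);
otherwise it is attributed to the primary fluorophore (1FP).  The
threshold diverges as `I_pr → 5⁺` (near the detection limit the
classification is maximally conservative) and behaves as `T_R·I_pr + 5 +
O(1/I_pr)` for bright peaks — the +5 is the worst-case noise headroom on
the secondary channel.

`T_R` is calibrated from single-fluorophore runs, where every coincident
secondary peak is known to be bleed.  Inverting the threshold per
calibration point gives

    T_R,i = [I*_sec (I*_pr − 5) − 5 I*_pr] / I*_pr²

and the calibration takes the maximum over points, clamped at 0.  This is
the smallest `T_R` for which zero calibration points classify as 2FP — a
guarantee that holds for *any* calibration set by construction, at the
price of conservatism (false-negative 2FP near the threshold).  The
classifier applies a 10⁻⁹ relative tolerance at the threshold so the
calibration point that set `T_R` never flips to 2FP through round-off.

**Units.**  The equations are applied in local-noise-σ units, so the
constant 5 coincides with the 5σ detection threshold, which is where a
detection-limit term belongs.  A mV reading of the same equations is
possible but would make the constant depend on the noise level; the σ
convention is adopted throughout.

**Calibration bias.**  Writing the measured secondary amplitude as
`I_sec = T_R I_pr + ε` with noise ε, a point contributes
`T_R,i ≈ T_R + (ε − 5(1 + T_R))/I_pr`.  Since |ε| stays below ~5σ even as
the worst case over hundreds of points, the estimate approaches the true
ratio *from below* as calibration brightness grows; the worst-case band
used by the recovery test is `[T_R − 11/max(I_pr), T_R + 6/min(I_pr)]`
(|ε| ≤ 6 allowance).  Calibration should therefore use the brightest
available 1FP material (cultured clusters), as the recovery checks do.

## Saturation

Detections whose peak amplitude exceeds 1500 mV saturate a PMT and
misreport the relative channel intensities; they are flagged and excluded
from 1FP/2FP classification and cluster statistics.  Two sufficient
conditions are checked: background-subtracted amplitude > 1500 mV, or the
raw signal at the peak reaching the detector rail (`raw ≥ limit`) — a
rail-clipped peak reports an amplitude *below* the limit while its
intensity ratio is badly wrong, and unflagged clipped peaks would inflate
the calibrated bleed ratio several-fold.  Automated flags replace manual
curation for reproducibility; flagged detections stay in the record table
marked `saturated`/`indeterminate` for review.

## Cluster sizing

Amplitudes are modeled as additive over member cells, so
`n = round(amplitude / per-cell reference amplitude)` (at least 1 for a
detected color), with the per-cell reference taken as the median
amplitude of single-cell calibration detections per color (configurable;
by default the median single-color detection amplitude of the scan at
hand).  For 2FP detections the secondary amplitude is first
bleed-corrected by subtracting `T_R ×` the primary amplitude so bleed does
not inflate the minority-color count.  A 1FP detection is a cluster only
at ≥ 3 nuclei (excluding a single cell in mitosis); every 2FP detection
contains cells of both colors and is a cluster by definition.

## Scan statistics

Detection rates use 2-minute moving windows stepped every 1 s (windows
truncated and renormalized at the scan edges).  The Pearson correlation
of the paired green/orange rate series is reported with a two-sided
t-test whose degrees of freedom use the number of effectively independent
windows, `n_eff = duration / window length`, not the raw (heavily
overlapping, serially correlated) window count — using the raw count
would overstate significance by orders of magnitude.  Scans below
0.5 detections/min overall are excluded from correlation analyses.  The
peripheral-blood concentration estimate is `rate / sampled flow` with a
default sampled flow of 0.1 mL/min (the order of blood volume per minute
carried by a mouse ventral tail artery) and assumes every cell passing
the probed vessel is detected; the assumption is recorded in the output
metadata.

## Synthetic scans

The generator's defaults encode the standard study conditions:

| parameter | default | meaning |
|---|---|---|
| sampling_rate | 2000 /s | kHz-class PMT digitization; window lengths are in seconds so results are rate-robust |
| probe_separation_mm | 3 | instrument geometry |
| flow_rate_ul_min | 25 (phantom) / 100 (in vivo) | syringe-pump flow / tail-artery blood flow |
| concentration_per_ml | 10³ per color (singles); 10³ clusters/mL (mean size 10 ≈ 10⁴ cells/mL) | phantom suspensions |
| speed_mean_mm_s | 30, log-normal jitter gsd 1.15 | transit speed in the probed vessel |
| sensing_length_mm | 1 | probe field of view; transit FWHM = length/speed |
| cell_amp_median_mv | 80 per color, log-normal gsd 2.0 | per-cell brightness ≈ 40σ (≈ 32 dB SNR) with heavy bright tail |
| tr_true | green 0.04, orange 0.06 | generative bleed ratios |
| noise_sigma_mv | 2.0 | channel noise |
| background | 50 mV + 10 mV drift, 120 s period | autofluorescence baseline |
| saturation_limit_mv | 1500 | detector rail (clips the noisy signal) |

Arrivals are Poisson with mean `concentration × flow × duration`;
cluster sizes are shifted-geometric; a mixed cluster (probability
`two_fp_mixing` for size ≥ 2) splits its cells binomially with both
colors guaranteed present.  Events render as Gaussian pulses on both
probes of each expressed color, the probe-2 center offset by
±separation/speed, with bleed `T_R ×` the opposite-color total added
before noise; motion artifacts render simultaneously on all four
channels.  Identical (config, seed) gives identical output.

The in vivo scenario modulates the Poisson intensity with a log-Gaussian
Ornstein–Uhlenbeck process (σ = 0.7, correlation time 120 s), with a
`modulation_shared` coefficient interpolating between independent
(shedding-driven) and fully shared (perfusion-driven) rate fluctuation —
the knob that makes the rate-correlation analysis testable in both
regimes.

What the generator does **not** model: depth-dependent optical
sensitivity and scattering (absorbed into the amplitude distributions),
non-Gaussian pulse shapes from vessel geometry, probe repositioning
drift, heart-rate pulsatility, and real autofluorescence statistics.
Passing tests therefore demonstrate correctness of the *algorithms* under
the stated generative model, not instrument-level performance on animal
data.

## Numerical choices

- Moving windows are centered and truncated at trace edges (no phase
  lag); window lengths in samples are forced odd for symmetry.
- Rolling median/std are computed with pandas; the tests pin them against
  naive O(n·w) per-sample oracles exactly.
- Noise σ is floored at 10⁻⁶ mV when normalizing amplitudes so noiseless
  synthetic traces do not divide by zero.
- Peak width is FWHM by linear interpolation between samples, floored at
  one sample period.
- Local maxima come from plateau-aware peak finding (plateau midpoint);
  candidates closer than half a width merge, keeping the taller.
- The noise window can optionally be re-estimated with detected peaks
  masked out (`mask_peaks_for_noise`), iterated to a fixed point (≤ 5
  passes).  At high event rates (the 25/min phantom), the pulses
  themselves otherwise inflate the rolling σ by several-fold and suppress
  dim detections; the default remains off, and the phantom-condition
  analyses enable it.
- Cell counts round half away from zero.
- Scan/detection tables serialize floats at `%.17g` and parse with
  round-trip precision, so text round trips are bit-exact.

## Problem sizes in the checks

The acceptance checks run a 6 h noise-only scan at 1 kHz (the false-alarm
condition) inside the test suite, and the standalone acceptance script
uses a 1 h noise-only scan, 10-minute phantom scans at 2 kHz, and
20-seed, 40-minute event-level replicates for the correlation contrast.

## Known limitations

- The concentration estimator assumes complete detection within the
  sampled vessel; in vivo it is a lower-bound-style estimate whose
  systematic error tracks detection efficiency.
- The greedy matcher can mispair candidates when two events of similar
  amplitude arrive within one delay window; at phantom rates this
  produces rare speed outliers (the recovery checks use medians).
- The calibrated `T_R` is conservative by construction; 2FP clusters
  whose minority color sits near the bleed bound are under-called.
- Overlap-corrected degrees of freedom for the rate-correlation p-value
  are an interpretation; alternatives (block bootstrap) would be
  stricter but are out of scope.
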