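# Methods

This note records the model assumptions, parameter choices, numerical
details and known limitations of `slfomap`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model

The systemic low-frequency oscillation (sLFO) is modeled as a single
band-limited driving signal s(t) carried with the blood: voxel v sees

    y_v(t) = offset + a_v · s(t − τ_v) + Σ_k c_kv · n_k(t) + ε_v(t)

with a spatially smooth delay field τ_v (seconds), nonnegative coupling
amplitudes a_v, optional *stationary* network timecourses n_k(t) shared by
voxel sets (standing in for neuronal connectivity signals), and additive
noise ε. Two simplifications are deliberate: delays are stationary over
the record (no within-run lag dynamics), and the neuronal signal is
band-limited noise rather than an HRF-convolved point process.

Sign convention throughout: **positive lag = later arrival** (venous
side); negative lag = early (arterial side). Reported lag maps are
recentered so the mode of the delay histogram is zero, since arrival time
is intrinsically relative.

## Phantom generator (`slfomap.phantom`)

The generator is first-class, tested code — it defines the study
conditions under which every downstream claim is verified.

* **Defaults** describe the standard healthy-circulation case: 20³ voxel
  grid, TR 0.72 s, 1200 timepoints (HCP-like sampling), radial delay
  field spanning 6.5 s (the in-vivo blood-transit spread), unit sLFO
  amplitude, unit white noise (SNR 1), constant offset 100.
* **Driving signals**: `bandlimited-noise` (white Gaussian noise with
  FFT bins outside the band zeroed — zero-phase, so ground-truth delays
  are uncorrupted, and spectral containment is exact); `sum-of-sinusoids`
  (seeded random phases); `pseudoperiodic(peak_freq, peak_fraction)`
  (band-limited noise with `peak_fraction` of the band power concentrated
  within ±0.005 Hz of `peak_freq` — the hazard case).
* **Fractional delays** are realized exactly: the driving signal is
  generated on an extended, circularly periodic record
  (n + ⌈max delay/TR⌉ + 8 samples), delayed with a frequency-domain
  phase ramp (exact for the periodic band-limited record), and trimmed.
* **Noise** is white Gaussian per voxel (AR(1) optional via `ar1_coef`).
* **Two-block preset**: two 8×8×4 blocks in a 32×16×4 grid, a
  sum-of-sinusoids driver delayed 0→6 s along the first axis, identical
  between blocks; background is offset + noise only. These dimensions are
  a package choice, recorded in `phantom.TWO_BLOCK_PRESET`.
* **Reproducibility**: all randomness flows from one integer seed through
  spawned `numpy.random.SeedSequence` children (driving / networks /
  noise); identical specs give bit-identical phantoms.

What the phantom does *not* emulate: motion, scanner drift beyond a
linear trend, spatial noise correlations, HRF dynamics,
cardiac/respiratory aliasing, and within-run delay variation. Passing
tests therefore demonstrate correctness of the estimation machinery under
the stated model, not robustness to all properties of real data.

## Filtering (`slfomap.prep`)

Default: linear detrend, then a 2nd-order Butterworth band-pass
(0.01–0.15 Hz) applied forward–backward (`sosfiltfilt`) — zero phase, so
no group delay enters the lag estimates. An FFT brick-wall filter is
available (`filter_type="brickwall"`); it is exactly idempotent and gives
perfect spectral containment, at the cost of Gibbs ringing on
non-stationary inputs. Records must be at least three time constants of
the high-pass pole (3/(2π·0.01 Hz) ≈ 48 s) long.

The zero-phase IIR filter has edge transients driven by the slow 0.01 Hz
pole. Consequences handled explicitly: refinement convergence (and
probe-fidelity comparisons in the tests) are computed over the record
interior, trimming three high-pass time constants from each end
(`refine.interior_corr`).

## Lagged correlation (`slfomap.lagcorr`)

* Pearson correlation over the **overlapping samples** at each
  integer-sample shift — no zero padding, no circular wraparound (which
  fabricates correlation for traveling signals). Implemented with one FFT
  cross-correlation plus prefix sums per lag; a naive shift-and-Pearson
  loop serves as the independent oracle in the tests (agreement 1e-10).
  Lags whose overlap falls below 0.8 of the record are NaN; windows wider
  than half the record are rejected.
* When mapping a volume, voxels **and probe** are detrended and
  band-passed identically before correlation. This mirrors the null
  procedure exactly; without it the null (which filters both its inputs)
  systematically over-estimates the threshold and the significance mask
  is badly conservative.
* Sub-sample peak: 3-point parabolic interpolation around the discrete
  argmax (δ clipped to ±½ sample). Ties break toward the smallest |lag|;
  an argmax on the window boundary marks the voxel `failed`.
* Amplitude and r² come from a least-squares fit of the lag-shifted probe
  (plus intercept) to the filtered voxel timecourse. Both are reported
  separately because "strength" is ambiguous: `amplitude` is in signal
  units per unit probe, `r2` is the variance fraction.
* GCC mode flattens cross-spectral magnitudes (floored at 10⁻³ of the
  maximum to avoid inflating empty bins) and rescales so a pure delay
  peaks at 1; its values are *not* Pearson correlations and are labeled
  `normalization="gcc"`.
* Zero-time recentering uses a 0.25 s histogram bin anchored at multiples
  of the bin width, making the operation exactly idempotent; mode ties
  break toward zero.
* Sidelobe scan: positive local maxima of the probe autocorrelation at
  nonzero lag with r ≥ 0.3 inside the search window (only positive lobes
  can capture a voxel's argmax one period away); a warning is emitted
  when any are found.

## Fractional shifts of finite records

The phantom's circular phase-ramp shift is exact only on its extended
periodic record. For *finite* records (shifting the probe in dynamic GSR,
realigning voxels in refinement, building the amplitude regressor) the
record is mirror-extended before the frequency-domain shift and trimmed
after (`_corr.fracshift_reflect`). The even extension removes the
wrap-around discontinuity that otherwise rings across the record; samples
shifted in from beyond the edge are genuinely unobserved and are filled
with the reflection. Residual error is confined to ~|lag| worth of edge
samples (<1% of variance in the noiseless removal test).

## Significance (`slfomap.significance`)

Why empirical: band-pass filtering removes degrees of freedom and the
peak-pick over lags inflates the statistic; both are captured by running
the full procedure on signals with no shared temporal structure.

* **Shuffle null** (default): permute the probe's time indices, then
  band-pass both the surrogate and the reference and take the peak within
  the window. Full random permutation (not block permutation) is valid
  here because the post-shuffle filter dominates the autocorrelation of
  the inputs. Default 10⁴ iterations; <100 triggers a warning.
* **Peak statistic**: signed maximum of r (one-sided) by default, with
  the same parabolic refinement as the voxel peak finder so null and map
  statistics are exchangeable; `two_sided=True` uses max |r| (and is what
  reproduces the classical 1.96/√n threshold when the window is collapsed
  and filtering disabled).
* **Reference**: defaults to the unpermuted probe itself (self-null),
  which is the calibrated choice for thresholding that probe's own lag
  map. An independent reference can be passed explicitly — required when
  comparing against the **phase-randomization null**: phase surrogates
  preserve the probe's bin-level magnitude spectrum, so in a *self*-null
  they share magnitudes with the reference and the maximum statistic is
  inflated by ~√2. With an independent reference the shuffle and phase
  nulls agree closely (verified within 10% in the tests).
* **Mismatch null**: peak correlations over all ordered pairs of
  independent records; deterministic; warns if the resulting threshold
  exceeds 0.9 (records were probably not independent).
* **Threshold**: empirical (1−p) quantile; requires n_iter·p ≥ 5. The
  null is recomputed at the start of every refinement pass, since
  refinement changes the probe's spectrum.

## Refinement and despeckling (`slfomap.refine`)

* Voxel selection: significant ∧ not failed ∧ lag at least 1 s inside
  the window edge (edge fits are unreliable). At least 100 voxels are
  required (configurable); fewer raises with advice to use a seed ROI.
* Weighting: maxcorr² (reliability-proportional); an unweighted mean is
  available. Order of operations: average the realigned raw timecourses,
  then filter, then z-normalize (configurable via the function's
  arguments; averaging first minimizes per-voxel filter transients).
* Convergence: interior Pearson correlation between consecutive probes at
  lag 0; default tolerance 0.999, default 3 passes. Non-convergence
  returns the best pass with a warning. By default the final state's maps
  are recomputed with the final probe so downstream denoising uses
  consistent lags.
* Despeckle: 3×3×3 in-mask neighborhood, median of ≥6 valid neighbors
  required (fewer → voxel flagged isolated, left unchanged). A voxel is
  re-fit when |lag − median| matches a sidelobe period within 1 s; the
  stored correlation function is re-searched within median ± period/2.
  Iterates to a fixed point (≤10 passes). Lag, maxcorr and r² (set to
  maxcorr²) are refreshed; the amplitude map would require the voxel data
  again and keeps its original fit. Despeckling greatly attenuates but
  does not fully eliminate sidelobe errors — the efficacy test requires
  ≥90% restoration, not 100%.

## Denoising (`slfomap.denoise`)

Per voxel, dynamic GSR fits intercept + linear trend + the lag-shifted
probe and subtracts the full fitted model, making the residual *exactly*
orthogonal to the removed regressor (the trend term prevents drift from
being absorbed into the sLFO coefficient). `r2_map` reports only the
regressor-attributable fraction. Voxels with failed or window-edge lags
pass through unchanged and are flagged; non-significant voxels are still
denoised by default (their coefficient is small), with
`restrict_to_sigmask` to override. Static GSR uses the same fit with one
unshifted global-mean regressor, and `seed_connectivity` provides the
zero-lag seed correlation map used to demonstrate the
anticorrelation-artifact contrast between the two.

## Problem sizes used in the validation suite

Unit tests use small grids (≈6³–10³ voxels, 400–800 timepoints) chosen so
each scenario still has the statistical resolution its assertion needs;
the end-to-end suite (`tests/test_acceptance.py`) uses the full default
conditions: 20³ voxels × 1200 timepoints at TR 0.72 s for pipeline
recovery, null calibration, despeckling (delay span 3 s there, so the
+10 s speckle stays inside the ±15 s window; driver noise SD 0.5 keeps
injected speckle the dominant error source) and the GSR contrast
(linear-gradient span 6.5 s), and 10⁴ null iterations for the threshold.
The whole suite runs in well under five minutes on one CPU;
`scripts/acceptance.py` in seconds.

## Known limitations

* Stationary-delay assumption; no windowed/dynamic lag analysis.
* No echo cancellation for probes contaminated by multi-delay seed
  regions (the package detects the echo via autocorrelation sidelobes and
  warns; the remedy is a homogeneous-delay seed ROI).
* The first/last ~max|lag| seconds of a record cannot be fully denoised —
  the probe is unobserved beyond the record; the mirror fill is a
  least-wrong guess.
* Significance uses a single empirical threshold (p<0.05 by default); no
  voxelwise multiple-comparison correction beyond it, and no spatial
  smoothing.
* GCC-mode peak heights are not comparable to Pearson r and are not used
  for significance.
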