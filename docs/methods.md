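# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a methods appendix: what is computed, under what
assumptions, and what the synthetic conditions do and do not establish
about real recordings.

## Direction tuning model and fit

A neuron's mean evoked response as a function of grating motion direction
θ (degrees) is modelled as a baseline plus two Gaussian lobes sharing one
width:

R(θ) = a₀ + a₁ exp(−d(θ, θ₀)²/2σ²) + a₂ exp(−d(θ, θ₁)²/2σ²)

with d(·,·) the angular difference wrapped to (−180°, 180°], θ₀ the
preferred direction and, by default, θ₁ constrained to θ₀ + 180° (the null
direction); a flag frees θ₁. Conventions:

- **Normalization.** Responses are divided by the curve maximum before
  fitting, so the mean-squared-error acceptance threshold of 0.5 and the
  reported fit errors live on a dimensionless [0, 1]-ish scale regardless
  of firing rate. This makes the filter scale-equivariant (tested).
- **Baseline.** a₀ is fixed to the mean of the four lowest normalized
  points rather than fitted — the literal reading of the model's baseline
  definition. Consequence: for broad tuning (σ ≳ 18° sampled at 15°
  spacing) the Gaussian tails leak into those four points and a₀ absorbs
  part of the lobes, slightly biasing the remaining parameters. The
  noiseless-refit benchmark therefore uses widths of 8–15°, where the
  lobes are fully resolved by the 24-direction design and refit errors are
  below 10⁻⁴; at σ = 25° the measured bias is ~3×10⁻³ in the amplitudes
  and ~0.1° in σ (θ₀ stays exact by symmetry). This is an identifiability
  property of the baseline convention, not an optimizer artifact.
- **Optimization.** Bounded trust-region least squares (a₁, a₂ ≥ 0,
  σ ∈ [3°, 180°]), multi-start over the two highest response peaks and
  σ starts {15°, 30°, 60°}; lowest mse wins, ties broken toward smaller σ.
  After fitting, the lobes are canonicalized so a₁ ≥ a₂ (the preferred
  direction is the larger lobe). Flat, nonpositive, or non-converged
  curves are flagged `accepted=False`, never raised.

## Selectivity indices and response summaries

OSI/DSI = (R_opt − R_null)/(R_opt − R_spon), evaluated on the fitted,
denormalized curve (raw-bin evaluation available via flag): R_opt at θ₀,
R_null at θ₀ + 180° for DSI, and the mean of θ₀ ± 90° for OSI ("orthogonal"
is read as the average of both orthogonal directions; they coincide under
the constrained model). R_spon is the measured pre-stimulus rate. Indices
are clipped to [0, 1], matching the bounded reported distributions;
neurons whose R_opt does not exceed R_spon, or whose fit fails the 0.5
filter, carry no indices and are flagged.

OR is the maximum and AR the mean of the 24 spontaneous-subtracted
per-direction means (a flag reports them on the raw scale; subtraction is
the package default because it is how the per-trial response is defined).
SNR = OR / max(SA, 1 spike/s); the floor prevents near-silent cells from
producing unbounded ratios.

F1/F0: spikes at the preferred direction are folded at the stimulus
temporal period into a 32-bin cycle histogram, discarding each repeat's
final partial cycle. F0 is the histogram mean minus the spontaneous rate
(subtraction is a flag; applying it keeps F0 consistent with the package's
response definition), F1 is the amplitude of the first Fourier harmonic.
Ratio > 1 ⇒ simple; a ratio of exactly 1 is complex.

## Synthetic-data generator

The generator defines the study conditions; its defaults are the published
group statistics (young: OSI 0.71 ± 0.18, DSI 0.48 ± 0.25, OR 47.1 ± 27.9,
SA 3.4 ± 2.6 spikes/s, n = 79; old: 0.48 ± 0.18, 0.33 ± 0.17, 99.1 ± 29.5,
24.7 ± 11.7, n = 83), the per-layer densities and proportions of the
published table, and the published intensity and blot summaries.

- **Index-targeted neurons.** Per neuron, targets (OSI, DSI, peak evoked
  rate, SA) are drawn and the tuning shape (a₁, a₂, σ) is solved so the
  noiseless curve hits them exactly: given σ, the index equations are
  linear in a₁ ± a₂; σ is found by 1-D root bracketing. Draws with no
  admissible solution (e.g. peak ≤ SA) are redrawn with a bounded retry
  count. OSI/DSI targets come from normals truncated to [0, 1] located at
  the published mean/SD (so the realized mean sits slightly below the
  located mean — the truncated-normal moment is the calibration oracle);
  SA and peak rate come from nonnegative distributions whose
  *post-truncation* moments match the published ones exactly
  (truncated-at-zero normal for young SA and both peaks, a moment-matched
  lognormal for old SA whose coefficient of variation exceeds the
  truncated-normal family's range).
- **Spiking.** Inhomogeneous Poisson with rate
  max(0, SA + evoked(θ)·(1 + m·cos 2πft)), sampled by thinning; the
  pre-stimulus epoch is homogeneous at SA. Defaults: 3 s stimulus (the
  protocol only bounds it above by 5 s), 1 s pre-stimulus, 5 repeats,
  2 Hz drift — a typical optimal temporal frequency for rat V1 and six
  full cycles per trial. Simulated cells carry no refractory period.
- **Modulation depth** m is drawn uniformly in [0.7, 1] for ground-truth
  simple cells and [0, 0.3] for complex cells. Because a sinusoidally
  modulated (non-rectified) rate has F1/F0 ≤ 1 in expectation, recovered
  ratios for simple cells cluster just below 1 and only noise carries them
  above the boundary: the generator's class labels are *not* faithfully
  recovered by the F1/F0 classifier, and the simulated simple fraction
  under-reports the configured one. Class-count comparisons on synthetic
  data are therefore qualitative; the classifier itself is validated on
  constructed trains (phase-locked vs uniform) instead.
- **Histology.** Homogeneous spatial Poisson cell placement per AOI
  (default 0.05 mm², 61 AOIs per layer and group, giving the ~600 residual
  degrees of freedom of the reported ANOVA) with i.i.d. Bernoulli GABA
  marks. Ground truth is always returned with the data.
- **Voltage traces.** Gaussian noise plus a biphasic template (200 µV,
  ~1 ms) at each planted spike time; overlapping templates sum.
- **Blots.** Lognormal optical densities, moment-matched per group;
  GAPDH defaults to a constant 1.0 so the lane ratio is the target draw.

What the synthetic conditions do **not** emulate: correlations between a
neuron's tuning fields (independence is assumed — the published summaries
carry no joint information), bursting/refractoriness, rectified simple-cell
dynamics (above), receptive-field structure, realistic confocal optics,
and between-AOI overdispersion of cell density. The last point means
Poisson counting noise is far smaller than the published between-AOI SDs;
as a result the total-neuron (NeuN) density comparison, reported as
non-significant in the original data, can reach nominal significance on
synthetic maps. Passing tests establish that the analysis chain recovers
what the generator planted, not that real tissue behaves this way.

## Statistics

Pearson chi-square without continuity correction (validated exhaustively
against the closed-form statistic on small tables); Welch t-test by
default ("Student's t-test" in the source leaves the variant open; pooled
available), with the one-tailed p defined as half the two-tailed p in the
observed direction; fixed-effects two-way ANOVA with interaction on
balanced designs only (unbalanced input is rejected, not re-weighted; a
single-level second factor reduces to one-way ANOVA). Group summaries use
the n−1 sample SD; percentages and percent changes round to 1 decimal
except the SA change, reported to the nearest integer as in the source.
Bin edges follow the printed definitions exactly; the two boundary values
the text leaves unassigned (AR = 30, SNR = 10) go to the upper bin.

## Problem sizes and reproducibility

Every generator is a pure function of (spec, seed); the end-to-end
pipeline derives stage seeds from one master seed and embeds a config hash
in its outputs. The benchmark sizes used by the test suite and the
reproduction script — a 100-point noiseless refit grid, 200 neurons per
group for index recovery, 100 replicates for group separation, 200 AOIs
for histology calibration, and one full study at the published sample
sizes — were chosen to keep Monte-Carlo error well below the tolerances
they are judged against while the whole suite runs in well under a minute
per component.

## Known limitations

- The F1/F0 classifier cannot exceed 1 in expectation under the
  generator's non-rectified rate model (see above).
- AR and SNR are emergent (not index-targeted), so their simulated group
  means track but do not exactly match the published ones; DSI inherits a
  small upward recovery bias (~0.05 at the young preset) from the a₀
  convention on broad curves.
- Two-way ANOVA requires balance by design; missing AOIs must be handled
  upstream.
- The fluorescence-intensity group comparison simulates per-slice summary
  draws; image-based intensity extraction is validated separately on
  planted blobs.
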