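# Methods

This note documents the models, conventions and numerical choices behind
`eegsel`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where genuinely open choices were fixed.

## Synthetic cohorts

Each channel is Gaussian noise with a 1/f^β amplitude spectrum (β = 1 by
default, DC removed, RMS 15 µV) plus a shared 10 Hz alpha source of
default amplitude 10 µV, amplitude-modulated by a ~1 Hz positive envelope
and projected with a posterior-dominant gain (0.4-1.0 across the scalp).
The modulation gives realistic epoch-to-epoch variance, so the std and
quartile summary statistics carry information; the posterior gradient
gives GFP peaks a consistent topography for the microstate stage.

Group effects:

- **Band-power multipliers** are applied per channel in the frequency
  domain (rFFT amplitudes in the band scaled by √m), so a multiplier m
  scales band power by exactly m in expectation.
- **Complexity shifts** mix an AR(1) component (φ = 0.95, matched
  variance) into the channel for negative shifts, lowering Lempel-Ziv
  complexity monotonically; positive shifts mix white noise instead.
  Mixing slightly reshapes the channel spectrum; this is accepted and
  documented rather than compensated.

Default profiles: PSF — ×3 power at CP5 52-64 Hz, ×2.5 at Fp1 0.5-4 Hz;
CTF — ×3 at CP5 30-56 Hz, ×1.8 at Fp1 0.5-4 Hz, complexity shift −0.5 at
FC5 and T7. These magnitudes are a fixed package choice (the placement
mirrors where the group differences localise; the real study reports no
effect sizes on a scale transferable to a generator): large enough that a
~40-subject binary task is clearly solvable, i.e. "strong" effects.
`default_profiles(effect_scale=0)` yields a null cohort. Default group
sizes are 21/20/17 (control/PSF/CTF). Per-subject seeds derive from the
cohort seed via `numpy.random.SeedSequence.spawn`, so cohorts are a pure
function of their configuration.

The generator does **not** emulate: eye-blink or muscle artifacts,
electrode impedance drift, inter-channel noise correlation beyond the
alpha source, the eyes-open condition, or realistic microstate syntax.
Passing tests therefore demonstrate correctness of the pipeline's
machinery and its sensitivity/calibration on clean, stationary signals —
not performance on artifact-laden clinical EEG.

## Containers

The lossless container is a numpy `.npz` archive (samples, rate, channel
names, positions, subject id, group). EDF (16-bit) writing and EDF/BDF
(24-bit BioSemi) reading are implemented directly on the fixed-layout
header; physical range is ±⌈max |x|⌉ µV, so the quantisation step is
(2·pmax)/65535 for EDF. Durations that are not whole seconds are
zero-padded into the final record and trimmed on read using a sample
count stored in the recording-id field. Malformed files raise a parse
error carrying the byte offset of the failure.

## Preprocessing

Order: resample → notch → bandpass → interpolation → average reference →
edge trim. The notch and bandpass are designed at the target rate
(post-resample). Choices the source protocol leaves open, fixed here:

- Resampling: `scipy.signal.resample_poly` (polyphase FIR anti-aliasing).
- Notch: IIR biquad, quality factor 30, applied with `filtfilt`
  (zero-phase; ≥ 40 dB rejection at 50 Hz, < 1 dB at ±10 Hz).
- Bandpass: order-8 Butterworth SOS, `sosfiltfilt`. Cutoffs are
  pre-warped by (√2−1)^(1/16) so that the −3 dB points of the combined
  forward-backward response land on the stated edges (upper edge clipped
  below Nyquist when needed).
- Edge handling: the first and last second are discarded after the full
  chain to remove filter transients.
- Epoch rejection (optional, off by default): drops 1-s windows whose
  peak-to-peak amplitude exceeds a threshold on any channel — a hook for
  real data replacing manual/ICA cleaning, which is out of scope.

The chain is linear (scalar homogeneity holds exactly) when
interpolation and rejection are not triggered.

## Features

Epochs are contiguous, non-overlapping 1-s windows (trailing partial
window dropped), giving 1 Hz native spectral resolution.

- **PSD bins**: rectangular-window periodogram per epoch
  (`scaling="spectrum"`, constant detrend), summed into 2-Hz bins
  [0-2), [2-4), …, the Nyquist folded into the last bin. Bin values are
  powers (µV²), not densities; Parseval holds against the detrended
  epoch variance.
- **Band powers**: delta (<4 Hz, DC excluded by detrending), theta
  [4-8), alpha [8-13), beta [14-30), gamma (>30 Hz up to Nyquist). The
  13-14 Hz gap follows the conventional printed band edges; at 1 Hz
  resolution the 13 Hz line falls outside both alpha and beta.
- **Lempel-Ziv complexity**: strict median binarisation (value > median
  → 1, ties → 0), LZ76 exhaustive parsing (Kaspar-Schuster), normalised
  as c(n)·log₂(n)/n. A strict median split requires continuous
  amplitudes to be informative: on a two-valued signal the median equals
  the majority value and the binarised string collapses.
- **Hjorth**: activity = population variance; mobility =
  √(var(Δx·fs)/var(x)) in rad/s (≈ 2πf for a tone), defined as 0 for a
  constant epoch.
- **Sample entropy**: SampEn(m=2, r=0.2σ), Chebyshev distance, strict
  `< r`, self-matches excluded; a constant epoch (r = 0) or an epoch with
  no m-template matches raises a degenerate-signal error, and such epochs
  are dropped from the secondary series (infinite values likewise).
- **Summaries**: mean, population standard deviation, and quartiles by
  the linear-interpolation scheme (numpy's "linear"/Hazen-type method) —
  fixed here and asserted in tests.

Normalisation: every column is z-scored with the population std;
columns with std < 1e-4 are first shifted to strict positivity and
log-transformed (the log path is recorded in the column metadata);
constant columns map to zeros and are flagged.

## Microstates

Maps are taken at strict local maxima of the GFP (std across channels),
thinned to a 10 ms minimum separation keeping the larger peak. The
modified K-means ignores polarity: assignment maximises squared spatial
correlation; the template update is the dominant eigenvector of the
cluster's outer-product sum; iteration stops when assignments are stable
(≤ 100 iterations); the best of n restarts by GEV (GFP²-weighted squared
correlation of each map with its template) is kept. Backfitting labels
every time point the same way, ties resolving to the lowest class index
(a zero map therefore gets class 0). No temporal smoothing is applied.
Classes are reordered by descending coverage for stable reporting; no
claim is made that they match the canonical A-D archetypes. Subjects
whose fitted GEV falls below 0.5 are flagged, not dropped — the original
discard rule for improper topographies has no published criterion.

Statistics come from run-length encoding: mean duration (ms), occurrence
(segments/s), coverage (time fraction; sums to 1), and segment-to-segment
transition probabilities (row-normalised, zero diagonal; all-zero rows
flag absent classes). Flattened names: `MS_<class>_<metric>` and
`MSTRANS_<i>to<j>` (24 columns at k = 4).

## AHFS

Mutual information is the plug-in estimate on an equal-frequency
discretisation with ⌈√n⌉ bins (labels used as-is). Criterion formulas,
with S the selected set, f the candidate, Y the labels:

- mRMR: I(f;Y) − mean_{s∈S} I(f;s)
- JMIM: min_{s∈S} I(f,s;Y)
- MMIFS (implemented variant): I(f;Y) − mean_{s∈S} [I(s;Y)/H(s)]·I(f;s)
- LCFS (implemented variant): |r(f,Y)| − mean_{s∈S} |r(f,s)|
- CORR: |r(f,Y)| / (1 + mean_{s∈S} |r(f,s)|)

The exact MMIFS/LCFS definitions used by the original selector are not
published in a recoverable form; the variants above are documented and
isolated behind the criterion registry so substitutions are one-line.
With S empty every criterion reduces to its relevance term. At each step
each criterion nominates its top candidate (ties lexicographic); each
nominated augmented set is scored by pooled 3-fold stratified CV accuracy
of the evaluation model (default: one hidden layer of 8 logistic units,
fixed iteration budget); the best nominee is kept (ties → accuracy, then
lexicographic name). Runs stop at 20 steps by default. Stability = 20
runs with seeds derived from a base seed; the prefilter passed to CFFS is
the union of final sets (appearance count ≥ 1).

## CFFS

The feature graph connects pairs with |Pearson r| ≤ τ on the normalised
table (τ = 0.4 for the PSF tasks, 0.35 for C-CTF); constant features get
correlation 0 and a flag. "Cliques" means *all* fully connected subgraphs
within the size bounds (3-9 by default), enumerated by networkx's
ascending-size clique walk (equivalent to maximal-clique search plus
subset expansion); a maximal-only mode exists behind a flag. If more than
the cap (600) exist, a without-replacement sample stratified by size
(largest-remainder allocation proportional to availability) is drawn.
Candidates are trained per (clique, algorithm) — L2 logistic regression
(C = 1), random forest (100 trees), ANN (8 logistic hidden units) — under
one shared stratified 3-fold split; every subject is predicted exactly
once per model and train/test disjointness is asserted. Top 20 models per
algorithm by pooled accuracy (ties → smaller set, then names).

## Shapley explanation

Interventional value function: v(S) = mean over background rows of
f(x with features in S from the subject, remainder from the background).
Feature sets are ≤ 9, so the 2ⁿ coalitions are enumerated exactly;
efficiency (Σφ + base = f(x)), symmetry and dummy hold to numerical
precision and are tested. Each subject is explained by the fold model
that held it out, background = that fold's training rows (optionally
subsampled for scaled runs). The explained quantity is the predicted
probability of the positive class; for the CTF-PSF task the positive
class is PSF, so positive values indicate schizotypal susceptibility and
negative ones latent bipolarity.

Aggregation (the original procedure names no formula; this one is fixed
and isolated in one function): a feature's raw score is the **sum** over
top models containing it of the mean absolute Shapley value across
subjects — i.e. features appearing in more models accrue proportionally
more mass — then scores are normalised to sum to one. Breakdowns by
metric type, 2-Hz frequency bin (non-PSD features pooled) and electrode
each partition the unit total.

## Orchestration and scaling

The three tasks are C-PSF (control vs schizotypal-featured, positive
class PSF, τ = 0.4), C-CTF (positive CTF, τ = 0.35) and CTF-PSF
(positive PSF, τ = 0.4); a microstate-only feature mode re-runs any task
on the 24 microstate columns alone. A run manifest (JSON-serialisable)
records the configuration, seeds, per-algorithm top-model accuracies and
their maxima, the normalised importance table and its breakdowns; reruns
from the same configuration are bit-identical.

`PipelineConfig` defaults are the full-scale settings (20 AHFS runs × 20
steps, 600 cliques of 3-9 features, top 20 per algorithm). Replicated
tests and the acceptance script use the package's desk-scale sizes —
cohorts at 256 Hz for 12 s, 4 AHFS runs × 5 steps, ≤ 80 cliques of 3-6
features, top 5 per algorithm, 50-tree forests, Shapley background capped
at 16 rows — chosen so a complete task run takes tens of seconds while
exercising every stage; all conclusions drawn from them (planted-effect
recovery, null calibration) are scale-robust properties, not headline
numbers.

## Known limitations

- The synthetic generator's simplifications listed above; in particular
  microstate features on synthetic data have weak group information, so
  the microstate-only mode demonstrates plumbing, not discriminative
  power.
- MMIFS/LCFS are documented reconstructions, not verified reproductions
  of the original selector's formulas.
- Selection optimism: any accuracy attached to a greedily selected
  feature set (AHFS traces, CFFS top models) is biased upward on null
  data; the calibration tests therefore measure the mean over candidates
  under a label-independent prefilter.
- Spectral features above the 60 Hz bandpass edge (bins up to the 64 Hz
  Nyquist) are computed but carry attenuated signal; planted effects are
  kept at or below 64 Hz.
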