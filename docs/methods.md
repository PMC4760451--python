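# Methods

This note documents the models, numerical choices and deliberately open
design decisions behind slicephys, and states what the synthetic-data
generators do and do not emulate.

## Containers and units

All signals live in a `Trace` (uniformly sampled, dt in seconds) with
canonical units mV (current clamp, field) and pA (voltage clamp); time is
seconds internally, milliseconds in feature values where the field
conventionally uses ms (FWHM, latency, rise/decay). CSV files store
samples with 17 significant digits, which round-trips IEEE-754 doubles
exactly; HDF5 round-trips are bit-exact. ABF/NWB ingestion is an optional
adapter (requires pyabf / pynwb) behind the same `SweepSet` contract.

## Up-state detection

Field signals are band-passed 3–300 Hz with a 4th-order Butterworth
applied forward–backward (zero phase, preserving onset timing) and
rectified. The binned statistic is the sample SD of the raw samples inside
each non-overlapping 10-ms bin; a partial trailing bin is ignored. The
alternative reading of the 10-ms rule — a 10-ms-stepped running SD over a
longer window — is not used; the per-bin SD is the simpler literal reading
and is exposed through the config. Event extent runs from the first to the
last supra-threshold bin; sub-threshold runs of ≤ 100 ms inside an event
are bridged (a *longer* return below threshold terminates it); candidates
shorter than 300 ms are dropped before events within 1 s of each other are
merged. Events touching either trace boundary are flagged truncated and
excluded from duration statistics (they still count toward event rates).

The baseline "quiet period" is found automatically as the 1-s sliding
window (100-ms step) of minimal SD, replacing a by-eye selection with a
reproducible rule; an explicit window can be supplied instead. For
intracellular traces the Down-state level is the mode of a 0.5-mV-bin
histogram of the membrane potential — robust to the fraction of time the
cell spends depolarized — and the same bin-SD rule is then applied to the
level-subtracted trace.

The detector is deliberately scale-equivariant: scaling the trace and the
baseline SD together leaves detections unchanged, which the tests assert,
and its output is checked verbatim against an exhaustive bin-labeling
oracle.

## Intrinsic properties

Derivatives are central differences on raw samples (no smoothing by
default; optional 3-point Savitzky–Golay for noisy data). The
phase-plane threshold criterion is dV/dt ≥ 20 V/s, configurable; the
"first trough" search window for the AHP is 20 ms after the peak, which
bounds the trough without capturing sag. FWHM uses linear interpolation at
the half level on both flanks. Firing rate at 2× rheobase is
(count − 1)/(last − first spike time), robust to onset latency. A "spike
doublet" is operationalized as a first ISI < 10 ms. The membrane-test fit
is nonlinear least squares on `Iss + (I0 − Iss)e^{−t/τ}`, seeded from the
sampled peak, the tail mean, and the integral-based time constant; a
noiseless transient is inverted exactly and the suite checks < 2% bias at
5 pA noise over 100 seeds.

## Spontaneous PSC detection

The named shape criteria of trace-by-trace mini analysis are re-specified
with explicit, configurable values: detection polarity, threshold 3× noise
SD, 10–90% rise within [0.1, 5] ms, single-exponential decay constant
within [1, 50] ms, minimum separation 2 ms (closer events collapse to the
larger). Noise SD is the minimum over 100-ms sliding windows of the raw
trace — short enough that some windows are event-free even at tens of Hz.

Candidates are local maxima of a lightly smoothed copy (0.5-ms boxcar)
whose prominence within an 8-ms window exceeds the threshold. Prominence
against the pre-event valley generalizes "deviation from the preceding
5-ms baseline" to events riding on a predecessor's decay, which a
threshold-crossing trigger cannot re-arm for; at ~11 events/s roughly one
event in seven arrives within 15 ms of another, so this matters for the
frequency statistics. The event reference level is the preceding-5-ms mean
on quiet stretches and the valley when riding on a tail; amplitudes are
read from a more strongly smoothed copy (1-ms boxcar) to suppress the
upward bias of reading a noisy maximum. When a following event truncates
the decay window, the fitted τ is biased upward and unreliable, so only
the lower decay bound (which rejects fast noise blobs) is enforced there.
Smoothing at 0.5 ms is a deliberate operating point: lighter smoothing
floods the detector with false positives, heavier smoothing merges close
events.

Two resolution limits remain and are inherent to the criteria themselves:
the 2-ms minimum separation is a dead time (for a Poisson train whose
median instantaneous frequency is 16 Hz it alone biases the recovered
median about −3%), and pairs closer than roughly one rise time are
detected as a single event. Recovered medians in the tests sit within 5%
of the generator's calibration with these effects included.

Events inside detected Up states can be flagged and are excluded from
"spontaneous" statistics by default (a switch restores them); frequency
distributions pool events across cells by default, with per-cell analysis
available.

## Evoked responses

The onset rule scans away from the stimulus after a 1-ms blanking window
per pulse (samples under the blank are linearly interpolated, since a
stimulation artifact would trivially trip any SD rule). The 5-ms
reference window slides with the candidate sample (the fixed pre-stimulus
variant is a config choice). Two consecutive supra-threshold samples are
required and the first is reported — over a scan of tens of samples a
single-sample 3-SD excursion is overwhelmingly likely to be noise, and
without this guard the latency estimate is biased early. The reported
latency is the sub-sample interpolated crossing of the 3-SD level, which
removes the half-sample quantization bias; the estimator's residual bias
at SNR 10 is below 0.05 ms with jitter SD recovered within 20%. With
4-pulse 40-Hz trains the latency is measured from the first pulse only.
The latency CV uses the sample SD; at least five trials are required for
any monosynaptic/polysynaptic call. The most effective stimulation
intensity for the evoked-duration curve is the argmax of the mean evoked
duration, ties resolved to the lowest intensity; durations are averaged at
trial level within a slice, then across slices.

## Synthetic generators

All generators are pure functions of (parameters, seed) through a single
`numpy` Generator per call; identical inputs give bit-identical traces.
Default sampling is 10 kHz (resolves 0.1-ms latency differences), with two
protocol-specific exceptions chosen for the quantity each trace carries:
current steps at 50 kHz, because central-difference recovery of ~230 V/s
maximal slopes at 10 kHz carries a ~5% discretization error against a 2%
recovery contract, and field Up-state traces at 2 kHz, since their signal
band ends at 300 Hz and 20-minute corpora are generated in bulk.

**Genotype presets** are plain-text key/value bundles (euploid, trisomic)
holding the passive circuit (Cm 70/94 pF, Rm/Cm 4.6/2.6 MΩ/pF, Ra 10 MΩ),
resting potential (−66/−64.8 mV), Up-state medians (duration 2.2/1.9 s,
rate 0.048/0.038 events/s), spontaneous-frequency medians (EPSC 16.2/8.7,
IPSC 13.7/7.4 Hz), evoked latencies (EPSC 4.1/4.6 ms, IPSC 4.6/6.3 ms;
per-trial jitter SD = published SEM·√n) and the action-potential bundle
(rheobase 55/73 pA, amplitude 112/115 mV, AHP −12.0/−11.7 mV, FWHM
1.32/1.27 ms, threshold −40.6/−38.9 mV, SFA 1.27/1.29, max rise 231/237,
max decay −113/−122 V/s).

**PSC trains** are homogeneous Poisson processes convolved with a
difference-of-exponentials kernel (0.5/5 ms rise/decay, 20 pA, noise SD
2 pA) plus white Gaussian noise. Since the per-event frequency convention
is 1/interval and the median of 1/interval for a Poisson process is
rate/ln 2, a generator asked for a target median uses rate = median·ln 2,
making the calibrated medians recoverable without bias.

**Up/Down traces** are a semi-Markov two-state process: Up durations
log-normal (median-parameterized, σ_log = 0.35 — only medians are
calibrated, so any right-skewed positive law matching the median is
admissible and the skew parameter is configurable); Down durations a
1.5-s-shifted exponential tuned so that events per second of recording
match the preset rate. The "rate" preset is interpreted as events per
second of recording (not inverse median inter-event interval); the preset
files flag this. The Down floor guarantees ground-truth intervals already
satisfy the 1-s merge rule. Field traces are noise whose SD is 10× the
Down-state SD during Up states, band-limited by the 3–300 Hz filter;
intracellular traces add a 10-mV depolarization with 2-mV barrage
fluctuation over 0.25-mV resting noise.

**Action potentials** are a parameterized waveform template stitched onto
a leaky subthreshold trajectory at prescribed spike times — feature
recoverability, not conductance-based realism, is the contract (the
steady state of the leaky model against threshold also gives the
closed-form rheobase the grid recovery relies on). The template rise has
slope max_rise·sin(u) with the sine phase entered at 60 V/s (a sharp
sodium-activation knee, so the first template sample is the detected
phase-plane threshold); the fall has slope −|max_decay|·sin(πs/t_f)^p,
with (t_f, p) solved numerically (Brent) so the total drop equals
amplitude − AHP and the half-amplitude level is re-crossed exactly at
FWHM. All Table-style kinematics are thereby encoded to < 0.2%. Spike
trains at or above rheobase are prescribed: first-spike latency shrinks
with drive, ISIs progress geometrically with ratio g chosen so that the
adaptation ratio equals the preset SFA, and the inter-spike membrane path
is a time-warped exponential approach to threshold (slope everywhere below
the 20 V/s criterion).

**Evoked trials** place a fast kernel (0.2/2 ms rise/decay — an AMPA-like
monosynaptic current; a slow-rising event under a 3-SD onset rule would
carry an intrinsic late bias incompatible with sub-0.1-ms recovery) at
stimulus + N(mean, sd) with optional biphasic artifact and Up-state-like
tail.

### What the generators do not emulate

Amplitude heterogeneity across synapses (optional log-normal jitter is
off by default), bursty/non-Poisson event statistics, electrode drift and
line noise, conductance-based Up-state mechanisms, series-resistance
artifacts, and spike-shape variability within a cell. Passing tests
therefore demonstrate that each analysis stage recovers the parameters of
data satisfying its own statistical assumptions — they bound algorithmic
bias, not robustness to every pathology of real recordings.

## Statistics

Student's t is pooled-variance by default (Welch by flag). Zero-variance
t-tests are defined as (0, p=1) for equal means and (±∞, p=0) otherwise.
Kruskal–Wallis uses rank sums with tie correction; KS is the two-sample
statistic with exact small-sample p where applicable. The Holm–Šidák
step-down is 1−(1−p_(k))^(m−k+1) on sorted p-values with a running
maximum, cross-checked against statsmodels. The factorial design (area by
genotype × recording mode) uses a type-II two-way ANOVA with Holm–Šidák
post hoc genotype contrasts within each mode; `group_compare` covers the
two-sample tests, and the factorial test has its own entry point since it
is not a two-sample comparison. No correction is applied across the
report's many measures — mirroring the single-comparison workflow it
reproduces — and this caveat is deliberate. Significance is fixed at 0.05;
everything is reported as mean ± SEM.

## Problem sizes

The recovery suites use 20 × 1200-s field corpora, 20 × 600-s PSC trains,
100 × 10 evoked trials and 100-seed noise-bias loops — sizes at which the
median estimators' sampling error is several times smaller than the
tolerances being checked, while the whole suite runs in about a minute.

## Known limitations

Overlapping PSCs within ~1 rise time are counted once; Up-state boundary
placement is quantized to 10-ms bins; the evoked-onset rule assumes the
5-ms pre-window is stationary (a slow pre-stimulus drift inflates its SD
and delays detection); firing classification assumes the 2×-rheobase sweep
exists in the step protocol; and the pipeline's factorial area analysis
mixes field (a.u.) and intracellular (mV·s) areas, which is meaningful for
the genotype contrast within each mode but not between modes.
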