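# Methods

## Scope and data model

The package classifies per-channel clinical EEG into six event classes
(SPSW, PLED, GPED, EYEM, ARTF, BCKG — this member order is the
canonical class axis everywhere).  Signals enter as EDF, are
resampled to the canonical 250 Hz by polyphase rational resampling
(zero-phase anti-alias FIR; sub-250 Hz sources are upsampled with a
warning), and are re-referenced to the 22-channel
temporal-central-parasagittal (TCP) bipolar montage.  The exact pair
list of the TCP montage varies slightly across vendors; the packaged
default follows the ACNS/TUH convention (`STANDARD_TCP_MONTAGE`) and
can be overridden by a YAML pair list.  All intervals are half-open
`[start, stop)` seconds from record start; amplitudes are microvolts.
Annotations are CSV rows `channel_index, start, stop, label` with
0-based channel indices — a deliberately minimal dialect of the
per-channel label files used by public EEG event corpora.

EDF is read through `mne`; the writer is implemented natively against
the EDF header layout (16-bit samples, per-channel symmetric physical
bounds), since the scientific stack targeted here ships no EDF writer.
Round trips are accurate to one least-significant bit of the 16-bit
range, and records are zero-padded to whole 1 s data records.

## Front end

Features are computed every 0.1 s from a 0.2 s Hamming-tapered window:
64-point FFT power spectrum; 24 triangular filters linearly spaced
over 0–125 Hz with 50% overlap; log compression and an orthonormal
DCT-II; cepstra 1..7 kept (the 0th, an overall level term, is
replaced by the frequency-domain log energy).  The differential
energy `E_d` is the max-minus-min of `E_f` over a 9-frame (0.9 s)
centered window — a cheap transient detector that separates impulsive
events from stationary background.  Regression derivatives use
half-window 9 (delta) and 3 (delta-delta); the delta-delta of `E_d`
is excluded, for a total dimension of 26.

Numerical choices: logs are floored at `1e-10` so silent frames stay
finite; delta edges replicate boundary values; the `E_d` window is
clipped at record edges; the final analysis frame is completed by
zero-padding, keeping frame count exactly `duration / frame_step`.
Whether `E_f` sums raw FFT bins or filter-bank outputs is a config
switch (`energy_from_filterbank`, default on — the oversampled filter
bank is what the rest of the cepstral chain consumes).  No
pre-emphasis is applied: EEG lacks the spectral-tilt convention that
motivates it in speech.  The whole front end is deterministic:
identical record and config give bit-identical features.

## Pass 1 — GMM-HMM sequential decoding

One left-to-right HMM per class, 3 emitting states by default (the
state count is not critical at 10 frames per epoch; it is
configurable), each state an L-component diagonal-covariance Gaussian
mixture, grown by binary splitting 1→2→4→8 with a few Baum-Welch
iterations per stage.  Training pools 1 s epochs from all channels
(channel-independent models); epochs spanning several labels take the
majority-coverage label, ties resolved toward the clinically
higher-priority class.  Initialization is a flat start from global
mean/variance with small seeded perturbations; variances are floored
at `1e-3` of the global per-dimension variance.  The forward-backward
recursions are scaled per frame (with a per-frame emission offset so
extreme log-densities cannot underflow); a frame whose density
underflows under every state raises an explicit error naming the
variance floor as the remedy.  Equal-length segments are batched, so
the E-step is vectorized across all segments of a class.

Decoding scores each channel epoch under all six models and converts
log-likelihoods to a posterior 6-vector by log-sum-exp normalization;
no class priors are applied (the corpus priors are heavily imbalanced,
and the later passes supply context).  Viterbi is provided for state
alignment; ties break toward the lower state index.

## Pass 2 — stacked denoising autoencoders

The 132-dimensional epoch supervector (22 channels × 6 scores,
channel-major) is reduced by global PCA and min-max scaled into
[0, 1] — the scaling makes sigmoid reconstruction with a
cross-entropy loss well-posed.  Three networks:

| role      | PCA | window | inputs | outputs | hidden (reference) |
|-----------|-----|--------|--------|---------|--------------------|
| SPSW 2-way| 13  | 3      | 39     | 2       | 100/100/100        |
| EYEM 2-way| 13  | 3      | 39     | 2       | 100/100/100        |
| six-way   | 20  | 41     | 820    | 6       | 800/500/300        |

The 13-dimensional branch is additionally smoothed by a sliding
3-epoch average before windowing; the six-way branch windows the PCA
outputs directly.  Window edges replicate the boundary epoch.
Corruption is masking-to-zero at level 0.3 per layer.  Pre-training
is greedy layer-wise minibatch SGD on reconstruction cross-entropy
(labels are never read); fine-tuning backpropagates a softmax head
through the encoder stack.  The reference hyperparameters (learning
rates 0.5 / 0.1–0.2, 150–800 epochs, batch 100–300) are the package
defaults; the `fast` profile used by the test suite and the
acceptance script keeps the published geometry but shrinks hidden
layers and epoch counts so a full pipeline trains in under a minute
per corpus on one CPU core.

Two pieces of training hygiene proved necessary at desk scale and are
part of the design: fine-tuning holds out 10% of the training windows
and restores the best-validation-accuracy parameters (plain SGD on
these small corpora occasionally drifts late in training), and the
pipeline trains two independently initialized candidates per network,
keeping the better validation accuracy (the loss surface has
occasional poor basins that no learning-rate choice avoids reliably).
Both mechanisms read only training data.

Class imbalance is addressed by interpolation augmentation: minority
classes are oversampled toward the majority count (capped at a
configurable multiple, default 3×) by convex combinations of
same-class nearest neighbours plus Gaussian jitter at 0.05 of the
class standard deviation.  Originals are never modified.

The enhancer starts from the six-way posterior.  When a binary
detector exceeds 0.5 while its class block ({SPSW, GPED, PLED} or
{EYEM}) does not hold the strict maximum of the six-way vector, the
block is rescaled to the detector's probability mass with internal
ratios preserved, the complement to the remainder, and the vector is
renormalized.  Ties count as disagreement, so a maximally uncertain
six-way output defers to a confident detector.

## Pass 3 — bigram grammar smoothing

The packaged 6×6 transition table encodes clinical priors (periodic
discharges persist; spikes do not follow PLEDs; two rows sum to 1.02
as printed in the source table due to rounding and are stored
verbatim, with an optional row-renormalization flag at load).  Each
iteration computes a file-level prior
`(Σ_i P_i + ε_prior · M) / (L + M)` (ε_prior = 0.1, M = 1), left and
right context distributions as exponentially decayed sums over up to
N = 10 neighbours (λ = 0.2, out-of-range neighbours skipped — no
phantom context is invented at record edges) blended with the file
prior at weight α = 0.1, and multiplies each class posterior by the
grammar factor raised to `γ/n` (γ = 1, n the iteration number).  The
annealed `γ/n` exponent is an interpretation choice: a `γ·n` exponent
grows without bound and prevents the intended label convergence; a
config switch (`anneal=False`) restores the literal product.  All
epochs update simultaneously from the iteration's snapshot, and
iteration stops when argmax labels are unchanged (cap 20).  All
normalization constants are normalize-to-unit-sum.

## Scoring

Event-based scoring counts every (channel, epoch) pair; epoch-based
scoring counts each epoch once, with the epoch reference label reduced
from per-channel annotations by the clinical priority vote
SPSW > PLED > GPED > EYEM > ARTF > BCKG (the highest-priority class
present on any channel wins, so rare focal events stay visible).
Collapses: four-way merges {EYEM, ARTF, BCKG} into BCKG; two-way pits
TARG = {SPSW, GPED, PLED} against BCKG.  Clinical detection tables
often print a "specificity" that is actually the fraction of
background units flagged as targets; this package computes that
false-alarm rate and the conventional specificity under separate,
explicit names.  DET curves sweep a penalty subtracted from the
target score before thresholding at 0.5; the zero-penalty point is
flagged and coincides with the two-way confusion-matrix rates.

## Synthetic corpora

The generator emits 22-channel TCP-montage records at 250 Hz: pink
(1/f) background noise at 10 µV RMS (the "easy" profile; a hard
profile raises noise to 35 µV and lowers event amplitudes), with
stylized events on class-appropriate channel subsets — biphasic
20–70 ms transients for SPSW (focal, 2–4 channels), periodic spike
trains for PLED (1.5–3 s intervals, one hemisphere's derivations) and
GPED (0.5–1 s intervals, all channels, synchronized), slow frontal
deflections for EYEM, broadband bursts for ARTF.  Event intervals are
aligned to the 1 s epoch grid; per-channel annotations exactly cover
the injected intervals and BCKG fills the complement.  The default
class mix is background-dominated (BCKG 64%, PLED 13%, GPED 7.5%,
ARTF 13%, EYEM 1.5%, SPSW 1%), emulating the strong imbalance of
clinical event corpora; fractional per-record shares are realized by
probabilistic rounding so the corpus-level mix is unbiased.  Records
never mix PLED and GPED.  Record-level attributes — lateralization
side and the periodic pattern type — follow stratified low-discrepancy
assignment rather than iid draws, so even a handful of records covers
both hemispheres and both periodic patterns at the intended marginal
rates.

What the corpus does *not* emulate: true EEG biophysics (no volume
conduction, no realistic spectra per state), inter-rater ambiguity,
electrode artifacts correlated across channels, or patient
demographics.  Passing tests on it demonstrates that the pipeline's
machinery — features, sequential decoding, context integration,
grammar smoothing, scoring — behaves as specified on data with the
right temporal and spatial signatures; it says nothing about absolute
performance on clinical recordings.

## Problem sizes used by the test suite and acceptance script

Synthetic corpora of 16–20 records × 60 s (train/eval split 80/20),
HMMs with 3 states × 2 mixture components, and the `fast` SdA profile
(hidden 80/50 or 40/30, 20 pre-training and 150–400 fine-tuning
epochs).  These sizes were chosen so a complete train + decode cycle
runs in tens of seconds on a single core while leaving the published
architecture geometry (feature dimension, PCA dimensions, window
lengths, network input sizes) untouched.  The HMM brute-force
equivalence checks run on instances of up to 3 states and 6 frames,
where exhaustive path enumeration is exact and fast.

## Known limitations

* The per-record EDF writer requires integer sampling rates and whole
  data-record seconds (tails are zero-padded).
* SPSW recall at epoch level is weak in heavily imbalanced corpora —
  the same behaviour the architecture exhibits on clinical data; the
  enhancer recovers some of it at the cost of occasional
  within-block misattribution between SPSW and GPED/PLED.
* The six-way network's 41-epoch window deliberately trades temporal
  resolution for context: short ARTF bursts are systematically
  absorbed into BCKG, which is visible in every confusion matrix the
  pipeline produces.
* Channel-dependent models, full-covariance Gaussians, learned (as
  opposed to packaged) grammars, and time-aligned overlap scoring are
  out of scope.
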