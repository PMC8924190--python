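# Methods

`evoseizure` builds patient-specific seizure-prediction models for scalp EEG
by evolutionary search.  This note documents the model, its parameters, the
synthetic data the package is validated on, and the numerical and design
choices a maintainer should know about.

## The prediction model

A model is an *individual*: five **hyper-features** plus one **pre-ictal
period** parameter.  Each hyper-feature is a second-level feature built from
one of 24 first-level EEG features on one electrode: at each step of a
1-minute sliding-window analysis, a reducing operator (mean, median,
variance, max or min) is applied to the 5-second-resolution first-level
feature over a look-back window of `window_length` minutes, shifted into the
past by `delay` minutes.  The value at grid time *t* therefore summarises
the interval `[t − delay − window_length, t − delay)`.  Delays let a model
read a *sequence* of epochs rather than a single interval.

The five hyper-feature series feed a class-weighted logistic regression
(weights `n / (2 n_c)`, inversely proportional to class frequency) after
column z-scoring with training-set parameters.  Samples in
`[onset − preictal, onset)` are labelled pre-ictal; samples within 30 min
after an onset are excluded from both classes (post-ictal guard — the
literature names this period but rarely quantifies it; 30 min is this
package's choice).

For alarm generation the binary classifier output is smoothed with the
**Firing Power** — a trailing moving average whose window equals the
pre-ictal duration — and an alarm is raised at an upward crossing of 0.7,
followed by a refractory period equal to the pre-ictal duration.  Partial
windows at stream start average over the available samples rather than
emitting undefined values.

### Fitness

Three objectives, all maximised:

* **S_ss** — sample sensitivity: fraction of pre-ictal samples classified
  pre-ictal;
* **S_sp** — sample specificity: fraction of inter-ictal samples classified
  inter-ictal;
* **Pcf** — patient comfort, computed from the genotype alone:

  `Pcf = 1.25 · (1 − (N_electrodes · N_lobes) / (N_electrodes · 5))`

  which is 1 for a single electrode in a single lobe and 0 for five
  electrodes across five lobes.  As printed, the electrode count cancels
  and Pcf depends only on the lobe count; the formula is implemented
  exactly as printed and the cancellation is asserted in a property test.

S_ss and S_sp are evaluated by *iterative retraining*: for training
seizures 1…K (first three chronological seizures, last 4 h before each
onset), the classifier is trained on seizures 1…k−1 and scored on seizure
k's segment; scores are averaged over the K−1 validation seizures.

S_ss/S_sp are computed on the **raw** classifier outputs, not after Firing
Power smoothing.  A trailing average of pre-ictal length crosses 0.7 only
after ~70 % of the window, so post-smoothing sample sensitivity is bounded
near 0.3 even for a perfect classifier — incompatible with sensitivity
objectives thresholded at 0.9.  Firing Power is an alarm regulariser, not a
sample-score transform.

### Search

NSGA-II with a fixed population of 100 over 50 generations (reference
settings; both are parameters).  Ranking is fast non-dominated sorting plus
crowding distance (boundary members +∞; objectives with zero range
contribute 0 to interior distances).  Parents come from binary tournaments
(rank, then crowding, then a fair coin); offspring are produced by
recombination with rate 0.90 and mutation with rate 0.015 per gene
(≈ 1/66, one expected mutation per individual).  Mutation is a unitary
step: ordered gene domains step ±1 with reflecting boundaries; the
electrode gene steps along the physical scalp adjacency of the 19-electrode
10–20 montage.  Recombination pairs the two parents' five hyper-features
greedily by genotypic similarity (number of equal genes, ties to the lowest
index) and then mixes genes uniformly within each pair; the spec of the
within-pair rule is this package's choice.  Environmental selection is the
standard (μ+λ) truncation on (rank, crowding).

The post-run **Decision Maker** keeps non-dominated individuals with
S_ss ≥ 0.9 and S_sp ≥ 0.9, relaxing both to 0.8 if none qualify.  Two
additions are this package's own: (i) the returned selection is
deduplicated to distinct genotypes, since NSGA-II populations accumulate
clones of good lineages and a Pareto-optimal solution *set* contains each
solution once; (ii) if even 0.8 selects nothing, the single individual
maximising min(S_ss, S_sp) is returned with a `below_threshold` flag, so
the pipeline always yields a deployable model.

### Testing and statistical validation

Testing is pseudoprospective: the stream after the third training seizure
is replayed chronologically; before each test seizure the classifier is
retrained on the 4-h segments of all seizures seen so far.  A seizure
counts as predicted iff at least one alarm falls inside its pre-ictal
interval.  FPR/h divides false alarms by *eligible* hours: inter-ictal time
excluding pre-ictal windows, refractory periods and the post-ictal guard.

Chance level comes from a surrogate analysis: keeping the real alarm train
fixed, seizure onsets are re-placed uniformly at random in the test span
(no onset earlier than `start + preictal`, consecutive onsets ≥ 4.5 h
apart, sampled exactly via the order-statistics construction) and
sensitivity is re-scored; 30 surrogates per model by default.  The
published descriptions of this procedure do not fix its details; the
re-placement rules above are this package's reconstruction.  A model
performs above chance when a one-tailed Welch t-test (variant unspecified in
the source literature; Welch chosen) rejects at α = 0.01 with
mean(real) > mean(surrogate).  With several stochastic search executions
per patient (30 by default), each run's selected individuals are tested and
the run-level mean sensitivities form the "real" sample.  Population-level
significance of *i* validated models among *I* uses the binomial tail
`P = Σ_{j=i}^{I} C(I,j) α^j (1−α)^{I−j}` (α = 0.05).

### Phenotype mining

Each selected individual becomes one transaction of canonical items — the
decoded (active-branch) feature, electrode, operator, window and delay of
its five hyper-features plus the pre-ictal value; silent genes carry no
phenotypic meaning and are excluded.  Gene presence is the fraction of
transactions containing an item.  Association rules come from level-wise
apriori mining with minimum support 0.07, confidence 0.10 and lift 1.00.
Rule mining defaults to pairwise itemsets (`max_len=2`): interaction
strengths and electrode connectivity aggregate *pairwise* lifts, and
unbounded mining is exponential as soon as two selected individuals share a
transaction (every subset of a shared ~26-item transaction is frequent at
support 0.07).  Exhaustive mining remains available for small item
universes and is cross-checked against brute-force enumeration in the
tests.  Pairwise interaction strengths sum rule lifts per item pair and
normalise by the maximum pair sum; electrode connectivity exports
electrode–electrode rules with lift > 1 as an edge list.

## First-level features

Signals are brought to 256 Hz (polyphase resampling), then filtered
zero-phase (forward–backward, phase handling unstated in the source
literature) with a 4th-order 50 Hz notch and a 4th-order 0.5 Hz Butterworth
high-pass, and cut into non-overlapping 5-s windows (1280 samples).  Per
window and electrode, 24 features:

* first four statistical moments (population definitions; kurtosis
  non-excess, so a Gaussian scores 3);
* Hjorth mobility and complexity via first differences (Hjorth *activity*
  equals the variance and shares its feature id; the genotype still exposes
  "activity" as a selectable value that decodes to variance — this
  deduplication is what reconciles the printed count of 24);
* relative spectral power in delta 0.5–4, theta 4–8, alpha 8–12, beta
  13–30, low-gamma 30–79 and high-gamma 79–128 Hz, normalised by the sum
  of the six band powers so the fractions sum to 1 by construction (the
  12–13 Hz gap between alpha and beta is kept as printed);
* spectral edge frequencies SEF50/75/90 over 0.5–128 Hz with linear
  interpolation between spectral bins (a relative epsilon of 1e-9 absorbs
  round-off when the target falls exactly on a bin boundary);
* db4 wavelet sub-band energies D1…D8, A8 (absolute energies; whether the
  source used absolute or relative is unstated).

Spectral estimates use a one-sided Hann-tapered periodogram without
detrending (estimator unstated in the source; the high-pass already removes
the mean).  The wavelet transform uses **periodization** boundaries: 1280 =
2^8·5, so the 8-level db4 decomposition is exactly orthogonal and sub-band
energies conserve window energy to round-off — a symmetric-extension
variant would break that Parseval property.  Zero-variance windows are
flagged degenerate: higher moments, Hjorth ratios and SEF are set to 0 and
band fractions to 1/6.

## Synthetic data

Real long-term annotated scalp EEG is access-restricted, so the package
ships a generator that emulates the study conditions: 19 channels of
stationary 1/f ("pink") noise at 20 µV RMS (white noise available for unit
tests), seizure onsets placed uniformly at random with ≥ 4.5 h spacing
(order-statistics construction), and — in a configurable pre-ictal window
before each onset — a drift of one first-level feature on a chosen
electrode set, calibrated numerically so that full drift strength moves the
window-level feature mean by `drift_magnitude` baseline standard
deviations.  Drift shapes: step, linear ramp, exponential.  The default
conditions are a 45-min, 3-SD **step** drift of the **variance** feature on
**C3** with four seizures: the method models the pre-ictal state as a
distinct class with a sharp boundary, and the step plant realises exactly
that hypothesis.  Plant mechanisms: an amplitude gain for variance (which
also co-drifts the absolute wavelet energies, as amplitude scaling must), a
DC offset for the mean (visible only without the high-pass; intended for
unfiltered unit tests), and a band-centre sinusoid with
bisection-calibrated amplitude for the relative band powers.  Other
features are not plantable and are refused.

Pink noise is synthesised in power-of-two FFT blocks (2^20 samples ≈ 68 min
at 256 Hz), which bounds memory and keeps transforms fast; spectral content
below ~2.4·10⁻⁴ Hz is not represented, far below the 0.5 Hz analysis
high-pass.  Fixed seeds give bit-identical recordings.

What the generator does **not** emulate: real EEG nonstationarity beyond
1/f wander (sleep–wake cycles, medication effects), artefacts (muscle, eye,
electrode pops), spatial correlation between channels, and ictal
discharges themselves.  Passing tests on this data show that the search
recovers planted, well-separated structure under the stated noise model —
not that the method attains any particular performance on clinical
recordings.

### A known recovery bias

Because a hyper-feature at time *t* summarises
`[t − delay − window, t − delay)`, its response to a drift beginning at
`onset − preictal` is smeared over roughly `delay + window` minutes.
Labels therefore align best with the fully-drifted *tail* of the plant
window, and the evolved pre-ictal period is biased low by about the
look-back length: with a 45-min plant, selected models frequently settle on
a 30-min pre-ictal with S_ss = 1 and S_sp ≈ 0.92–0.95, which passes the
0.9 Decision-Maker threshold and is non-dominated (such models also tend to
maximise comfort).  The electrode, by contrast, is recovered reliably.
This mirrors the built-in bias in searched pre-ictal periods discussed in
the seizure-prediction literature and is left as a documented property
rather than compensated for.

## Problem sizes in the test suite

The suite validates at reduced scale, chosen so the whole run completes
comfortably on one CPU: the end-to-end recovery study uses one synthetic
patient (the generator defaults above), five search executions with
population 20 over 10 generations; surrogate calibration uses 1000
repetitions of 30-vs-30 samples at α = 0.05; oracle equivalences use 200
random 3-objective points over 20 seeds (sorting) and ≤ 12-item transaction
sets (apriori).  Unit fixtures use 1–4 channels and two to three seizures.
Reference settings (population 100, 50 generations, 30 runs) remain the
defaults of the library and CLI.

## I/O and formats

Signals travel as EDF; annotations as CSV (`onset_s`, optional free-text
`classification` — the on-disk format of the original database is not
public, so EDF+CSV is this package's choice).  Reading goes through `mne`;
writing uses a minimal 16-bit EDF encoder (one-second records, physical
range ±2000 µV ⇒ ~0.06 µV quantisation) sufficient for round-tripping
synthetic recordings.  Channels whose labels are not in the 19-electrode
10–20 set are dropped with a warning.  Feature tensors export as long-form
CSV; individuals and populations as JSON / JSON-lines; run artifacts
include a manifest with a config hash and all run seeds for provenance.

## Limitations

* The comfort formula is implemented exactly as printed even though its
  electrode count cancels algebraically; if the cancellation is a
  typographical artefact of the source, the objective under-penalises
  multi-electrode single-lobe montages.
* Gene domains for delay, window length and operator are reconstructions
  (the source's main text does not list them), as is the electrode
  adjacency used for mutation.
* The fitness pipeline assumes training segments free of recording gaps;
  patients with > 1 h of missing data per seizure are out of scope.
* Recovered pre-ictal periods carry the look-back bias described above.
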