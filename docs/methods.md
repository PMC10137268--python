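# Methods

## Model

Vigilance is modelled as a first-order Markov chain over three hidden
states — S1 low, S2 medium, S3 high — observed only through quantized HRV.
Each analysis window emits one symbol from {1, 2, 3}, the SDNN level of that
window, so the full model is a discrete-emission HMM λ = (π, A, B) with
N = M = 3: π the initial state distribution, A the 3×3 state-transition
matrix (a<sub>ij</sub> = P(next = j | current = i); self- and
cross-transitions all allowed), B the 3×3 emission matrix
(b<sub>ij</sub> = P(symbol j | state i)).

The assumptions this encodes: vigilance changes slowly relative to the
1-minute window (first-order Markov dynamics at the window scale are
adequate); within a window, SDNN depends only on the current vigilance
level; and higher SDNN corresponds to higher vigilance — the orientation
follows the boxplot geometry of the calibration data, in which the low
vigilance level occupies the lowest SDNN range. Quantizing SDNN to three
levels discards amplitude information beyond the level boundaries but makes
the emission model a small multinomial that can be estimated supervisedly
from very short paired records.

## Pipeline stages and parameters

**ECG cleaning** (`ecg_preprocess.denoise`). A zero-phase Butterworth
band-pass, default 0.5–40 Hz, order 2 per pass (the forward–backward pass
squares the response). The high-pass corner removes DC and baseline drift
(≥ 40 dB per pass at 0.05 Hz); the low-pass suppresses broadband noise
while leaving QRS energy (≲ 40 Hz) intact. An optional IIR notch
(default Q = 30) targets mains interference and is applied *before* the
band-pass so the slow-settling high-pass never sees the mains component.
Zero-phase filtering of a finite record necessarily leaves edge transients
of roughly the filter settling time (~2 s for the 0.5 Hz corner); beats
inside those margins are still detected but their amplitudes are less
reliable. EMD-style decomposition and accelerometer-based motion-artifact
removal are out of scope: they are device-specific and add nothing to the
model under test.

**R-peak detection** (`detect_r_peaks`). A differential-threshold detector:
the absolute first difference of the cleaned signal is compared against
`threshold_frac` (default 0.3) times its rolling maximum over a sliding
window (default 2 s — the window must span at least one cardiac cycle, so
every neighbourhood contains a QRS slope and the threshold adapts to local
amplitude). Contiguous supra-threshold runs straddle a QRS complex; each is
collapsed to the local maximum of the signal it spans, and a 200 ms
refractory period (the physiological minimum between ventricular
depolarizations) keeps only the taller of two candidates closer than that.
A flat record yields no peaks rather than an error.

**HRV features** (`hrv_features`). Per window of cumulative RR time
(default 60 s; an interval belongs to the window containing its onset;
windows with < 4 beats and trailing partial windows are dropped with a
warning):

* `hr_mean` — mean of instantaneous HR(n) = 60000 / RR(n) ms, in bpm;
* `sdnn` — sample standard deviation (N−1 divisor) of the RR intervals, ms;
* `rmssd` — root mean square of successive RR differences, ms;
* `lfp`, `hfp` — integrated tachogram power over (0.04, 0.15] Hz and
  (0.15, 0.40] Hz, ms²; `lf_hf` their ratio.

Spectral estimation resamples the irregular tachogram at 4 Hz by cubic
interpolation, mean-centres it, and applies Welch's averaged periodogram
(Hann segments of ≤ 256 samples, 50% overlap), integrating the density over
each band by trapezoid. 4 Hz comfortably oversamples the ≤ 0.4 Hz band of
interest; band edges are half-open (lo, hi] so the shared 0.15 Hz edge is
counted once. A 60 s window resolves 0.017 Hz, below the 0.04 Hz LF edge;
shorter windows trigger a resolution warning.

A `literal` switch computes the alternative difference-based formulation
(dispersion statistics over δ(n) = RR(n) − RR(n−1) rather than over the
intervals, with N−1 / N−2 divisors) for comparison; the default is the
universal SDNN/RMSSD definition, which is also what the quantization
thresholds presuppose.

**Quantization** (`quantize_labels`). Symbols: SDNN ≤ t_low → 1,
t_low < SDNN ≤ t_high → 2, above → 3. Values exactly on a threshold go to
the lower class — the convention had to be fixed somewhere and is tested.
The packaged defaults are t_low = 155 ms, t_high = 182 ms. The derivation
rule takes labelled SDNN samples per level and returns midpoints of the
adjacent-level quartile pairs (Q3 of the lower level, Q1 of the upper),
with quartiles by linear interpolation (type 7, the numpy default — the
most widespread convention). Note the packaged defaults are not exactly the
midpoints of the reference quartile pairs ((153 + 156)/2 = 154.5 and
(186 + 179)/2 = 182.5): the defaults reproduce the reference configuration,
the midpoint rule is what the package recommends for new data. Overlapping
quartile pairs (Q3 of the lower ≥ Q1 of the upper) still yield a midpoint
but are flagged non-separable and warned about. PVT fastest-10% reaction
times label states as < 400 ms → 3, 400–500 ms → 2, > 500 ms → 1
(boundaries inclusive to the middle class).

**HMM estimation and decoding** (`hmm_core`). Initialization follows the
left-right convention, π = (1, 0, …, 0), and a uniform A (every state has
three outgoing paths, each 1/3); both wash out during training, which is
why they can be fixed without estimation. B is initialized supervisedly
from a paired (O, Q) record by event counting, with an optional Laplace
`smoothing` pseudo-count (default 0, matching the plain count convention)
and a uniform row for states never observed.

Baum–Welch uses per-time-step scaling constants (the sum of the unscaled
forward variables at each step), giving the log-likelihood as the sum of
log scales without underflow; the backward pass is scaled by the same
constants. Re-estimated rows are floored at 1e-12 before renormalization so
a finite sample cannot create absorbing zeros. Convergence: change in total
log-likelihood < 1e-6 (tol), max 500 iterations. Multiple sequences train
per-sequence by default (sufficient statistics summed, π re-estimated as
the average posterior at t = 0); a `concat` mode joins them into one stream
first, reproducing the reference configuration in which ten 30-long records
were concatenated to length 300. The EM log-likelihood is non-decreasing by
construction and the implementation verifies against a hand-evaluated EM
step and exhaustive path enumeration in the tests.

Viterbi decodes in log space (log 0 = −inf is safe under max), breaking
ties toward the lowest state index at every step — deterministic output on
exactly tied paths. Decoding uses the trained π by default; a
`leftright_pi` flag substitutes (1, 0, 0). The trained initial distribution
of the reference model was never published, and its validation sequences
start in states 2 and 3 — impossible under a strict left-right start — so
the package treats π at decode time as configuration rather than dogma.

**Evaluation** (`evaluation`). Accuracy, Hamming distance and MAE over
integer state labels. MAE treats the ordinal labels as integers; reports
round percentages to 2 decimals and MAE to 4.

## Synthetic study conditions

The generators emulate the structure of the calibration recordings, not
their content:

* `sample_hmm` draws (state, symbol) paths from a generating chain. The
  default (`DEFAULT_GENERATOR`) has sticky transitions (0.70 self, split
  0.20/0.10 toward neighbours) — vigilance persists across minutes — and
  emissions that put 0.80 on the own symbol, 0.15 on the adjacent level and
  0.05 on the distant one, mirroring how SDNN quantization confuses
  neighbouring levels far more often than distant ones.
* `synth_rr` renders a state path as RR intervals: per state, i.i.d. normal
  draws with mean 900 ms for all states and SD (80, 170, 220) ms for states
  1–3, redrawn at or below a 300 ms floor. The common mean isolates the
  observation channel in SDNN: states differ in spread, not rate, so the
  expected window SDNN (~80 / ~170 / ~220 ms) brackets the (155, 182)
  thresholds the way the calibration boxplot does, with state 2 genuinely
  ambiguous. Each state segment is filled with beats until it spans one
  60 s analysis window and then rescaled to exactly that duration, keeping
  generator labels aligned with `window_features` windows indefinitely (the
  rescale factor is ~1 ± 2% and perturbs the segment SD negligibly).
* `synth_ecg` places a narrow positive Gaussian QRS template (σ = 10 ms,
  peak 1) at each cumulative beat time on a flat baseline and adds white
  noise at a requested SNR, returning the true peak indices.
* `WELL_SEPARATED_GENERATOR` is the chain used for parameter-recovery
  simulations: emissions put 0.95 on the own symbol, so the hidden states
  are nearly observed and the recovery error of Baum–Welch is dominated by
  transition-count sampling noise (≈ 0.02–0.05 max row L1 at T = 10 000)
  rather than by state ambiguity. With the deliberately confusable default
  emissions the same study measures estimator efficiency under overlap, a
  different and harder question (~0.08 at the same T).

What the generators do **not** model — and hence what passing tests cannot
certify about real recordings: P/T-wave morphology and realistic QRS shapes,
motion artifacts and electrode noise, ectopic beats, respiratory sinus
arrhythmia structure beyond broadband spread, circadian drift, and
inter-individual differences in dynamics (one shared chain generates all
records). Results on synthetic data bound implementation correctness, not
field performance.

## Numerical choices and degenerate inputs

* Scaled forward/backward rather than pure log-space: one normalization per
  step, exact log-likelihood, no `logsumexp` in the inner loop.
* Impossible observations: `forward_loglik` returns −inf (a sentinel, not
  an error); `viterbi` raises, since no best path exists.
* Row-stochasticity is validated to 1e-9; the published trained matrices
  carry printed rounding of up to 1e-4 per row and are renormalized before
  use as a live model (`PaperFixtures.hat_params`). The published *initial*
  emission matrix is shipped verbatim but row 1 sums to 1.10 as printed, so
  it is excluded from stochastic validation and from decoding use.
* `detect_r_peaks` on a flat signal: the adaptive threshold is zero and
  strictly-greater comparison yields no candidates — empty output.
* `peaks_to_rr` with < 2 peaks returns an empty series rather than erroring;
  SDNN/RMSSD require ≥ 2 intervals and band power ≥ 4 beats, and raise
  otherwise.
* Sequences are 1-based everywhere a user sees them (files, reports, API
  arrays); the 0-based shift happens privately inside the algorithms.

## Problem sizes

The packaged studies are sized to run comfortably on one CPU: exhaustive
HMM oracles enumerate N ≤ 3, T ≤ 7 (≤ 2 187 paths); the synthetic
quantization loop uses 120 one-minute windows (~2 h of simulated
recording); supervised-plus-EM training studies use records of length 300,
matching the reference corpus layout; parameter recovery uses one
10 000-symbol sequence. These sizes put Monte-Carlo fluctuations well
inside the asserted margins.

## Known limitations

* The R-peak detector assumes the sliding threshold window contains at
  least one QRS slope; recordings with pauses longer than the window
  (default 2 s) can produce noise-driven detections inside the pause.
* The SDNN thresholds (155, 182 ms) are high for 1-minute windows by
  general HRV standards; they are shipped as the reference configuration
  and treated as given, in ms, without rescaling. For new populations the
  quartile-midpoint derivation should be re-run on labelled data.
* Baum–Welch finds local optima; for unsupervised fits from flat starts,
  multiple restarts with the best final likelihood are advisable (the
  supervised emission initialization largely removes the issue in the
  intended workflow).
* MAE on ordinal labels assumes unit spacing between adjacent vigilance
  levels; it is reported for comparability, not as a calibrated loss.
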