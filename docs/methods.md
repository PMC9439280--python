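# Methods

This note documents the model choices, defaults, and numerical decisions
behind the package, and what the synthetic study does and does not show.

## Matching model

A recording is assumed to hold exactly three cardiac cycles. Cycles are
delimited as equal thirds of the sample axis (`floor(n/3)` samples each, up
to two trailing samples discarded): the recordings this method targets are
hand-edited to three cycles, and avoiding segmentation is the method's point,
so no beat detector is used. Cycle-to-cycle differences (length jitter,
murmur stochasticity) are exactly what the fuzzy matching is meant to
absorb.

**Templates.** The time-domain self template is the elementwise mean of the
three cycles; frequency-domain templates average the one-sided DFT moduli
(bins `0 … floor(n/2)`; the symmetric half would double-count energy in
matching). The mutual template is the frequency template of one designated
normal recording — by convention the shortest normal recording of the
dataset, or the generator's dedicated `NHS-reference` signal — shared by all
signals so that pathological spectra are scored against a common normal
pattern.

**Filter bank.** The initial bank stacks the 1st–8th derivatives of
`exp(-t²/2)`, generated by the probabilists' Hermite recurrence and sampled
on a uniform grid over `[-2.5σ, +2.5σ]` (endpoints included), each row
scaled to unit Euclidean norm. The 2.5σ support covers >98% of the Gaussian
mass while keeping very short filters non-degenerate. At `L = 2` the grid
collapses to the two endpoints: odd-order rows become `±(√2/2, −√2/2)` and
even-order rows `(√2/2, √2/2)` up to sign — accepted as the two-point limit
of the construction. Rows are not orthogonal and no orthogonality is
claimed.

**Eigen optimization.** `X = m ⊛ W` (full convolution per row);
`U = (β₁ … β_O)` holds the eigenvectors of the `O` largest eigenvalues of
`X Xᵀ`; `W′ = Uᵀ W`. Zero eigenvalues are legitimate (rank-deficient `X`).
Determinism decisions:

* eigenvalues sorted non-increasing with a stable sort; ties keep the
  decomposition's output order;
* each eigenvector's sign is fixed so its largest-magnitude entry is
  positive;
* eigenvectors whose eigenvalue is numerically null (≤ 1e-9 of the largest)
  are replaced by a deterministic orthonormal completion of the retained
  basis (Gram–Schmidt over canonical basis vectors, smallest index first
  among tied residuals). LAPACK's null-space vectors are otherwise
  arbitrary, which made repeated runs and amplitude-scaled inputs disagree.

With the frequency-domain defaults (`N = 8, L = 2, O = 3`) the bank's row
space is only two-dimensional, so the third eigen direction is always
numerically null. Its optimized filter is snapped to exactly zero, and
matching treats a zero template row as a *neutral* trace (`y ≡ 1`, energy 0,
flagged in the result); only a template whose rows are all zero is an error.
This keeps the documented defaults usable while being explicit that the
third frequency-domain filter carries no information.

**Matching degree.** Per filter, the cross-correlation of the trimmed target
feature `x′_si` with the trimmed template feature `x′_mi` is divided by the
sliding window norm of `x′_si` (window = template length, computed by
cumulative sums) times a template norm term. Two normalizations exist:

* `ncc` (default): divide by `‖x′_mi‖` — true normalized cross-correlation,
  bounded by 1 (Cauchy–Schwarz) and invariant to amplitude scaling;
* `literal`: divide by `‖x′_mi‖²` — row-wise proportional to `ncc`, so all
  best-match lags agree, but scale-dependent and unbounded.

Lag axes differ by dimension:

* **Time domain (self):** the template (one averaged cycle) slides over the
  whole three-cycle signal in complete-overlap (valid) lags; the lag axis is
  partitioned into three equal contiguous thirds and each third contributes
  its own maximum degree and energies. This reconciles "three matching
  features per dimension" with a single continuous matching curve.
* **Frequency domain (self and mutual):** each cycle spectrum is matched
  separately against the template, which starts at every spectral position
  and is allowed to run off the upper end ("slide" mode; the truncated
  window norms fall out of convolving the squared signal with an all-ones
  vector). A frequency offset between a pathological spectrum and the
  normal template therefore appears as a shifted best-match lag rather than
  being invisible. For mutual matching, cycle spectra are linearly
  resampled to the reference template's length first so bins are
  commensurate.

Endpoint trimming defaults to `L−1` samples per end (removes every partial-
overlap sample of the full convolution). Zero-energy windows (silence) give
`y = 0` at that lag, flagged, never an exception — silence is legitimate in
a PCG.

**Matching energy.** `ME_i` is the windowed Euclidean norm of `x′_si` at the
best-match lag — the correlation energy the i-th optimized wavelet captures
where the signals align. Energies scale linearly with signal amplitude
(degrees, in `ncc` mode, not at all), so the degree/energy split separates
shape information from level information.

**Feature vector.** Fixed block order TD.S.MD, TD.S.ME, FD.S.MD, FD.S.ME,
FD.M.MD, FD.M.ME → `9·(O+1)` values (36 at the defaults), named
`<block>.<cycle>` and `<block>.<cycle>.<filter>`. Defaults follow the
tabulated hyperparameters: time `N=8, L=6, O=3`; frequency `N=8, L=2, O=3`.

## MFCC fusion

Standard speech defaults, all configurable: 25 ms Hamming frames, 10 ms hop,
FFT size = next power of two, 26 triangular Mel filters spanning
0–`sr/2` with edges uniform on the Mel scale, natural-log energies floored
at 1e-10 (silent frames are not an error), orthonormal DCT-II, coefficients
1–13 kept (c₀ dropped), mean-aggregated over frames. The Mel constant
defaults to the conventional 2595 (base-10 log); 2585 is available as a
configuration switch for literal reproducibility of sources printing that
value. Fusion concatenates matching features first, then MFCCs (49 values
at the defaults).

## Evaluation harness

Metrics are computed by hand from the pooled confusion matrix, one-vs-rest:
recall (= sensitivity) `TP/(TP+FN)`, precision `TP/(TP+FP)`, specificity
`TN/(FP+TN)`; macro values are unweighted class means; accuracy is
trace/total. A never-predicted class gets precision 0 and is flagged.
Cross-validation is stratified ten-fold with a fixed seed; grid search, when
enabled, runs nested (3-fold) inside each training fold over conventional
grids (SVM: C ∈ {0.1,1,10,100}, γ ∈ {scale,0.01,0.001}; KNN: k ∈ {1,3,5,7,9};
RF: 100–500 trees, depth {∞,10,20}; MLP: (50),(100),(100,50)), with the
winning parameters recorded per fold. Features are z-scored inside each
training fold for SVM/KNN/MLP; random forests run unscaled. One-vs-rest AUC
uses cross-validated continuous scores (probabilities where available,
decision function otherwise) and the trapezoidal rule. Per-feature tests are
Welch's two-sided t-tests with per-class means and standard errors; two
constant equal groups return `t=0, p=1`, flagged degenerate.

## Synthetic data: what it emulates, and what it does not

The generator emulates the target dataset's format: 8 kHz mono, 0.8 s
nominal cycles, three cycles per recording (2.4 s), five balanced classes,
plus one dedicated normal reference recording. Each cycle contains:

* S1: 40 Hz tone, Gaussian envelope (σ = 12 ms) near the cycle start,
  amplitude 1.0;
* S2: 60 Hz tone, σ = 10 ms, at 35% of the cycle, amplitude 0.7;
* a class-specific murmur: band-passed white noise (4th-order Butterworth,
  zero-phase) in the auscultatory window — AR: diastolic decrescendo
  80–250 Hz; MR: holosystolic 100–400 Hz; MS: diastolic crescendo ("rumble")
  40–150 Hz; MVP: late-systolic 120–350 Hz plus a 300 Hz mid-systolic click;
* textbook changes to the sounds themselves: accentuated S1 (×1.4) in MS,
  soft S1 (×0.6) in MR, soft S2 (×0.65) in AR. Without these the classes
  would differ only in noise statistics, which no real PCG dataset does;
* broadband measurement noise.

Murmurs sit 10 dB and noise 20 dB below the S1+S2 energy by default; burst
amplitudes jitter by 5% and cycle lengths by ±2% (then padded/truncated to
nominal length). Everything is driven by one `numpy` Generator, so a seed
fixes the dataset bit for bit.

What the synthetic study does **not** show: inter-patient variability,
recording-chain differences, background sounds, arrhythmic cycle spacing,
or murmur morphologies beyond stationary band-limited noise. The synthetic
classes are stereotyped, so classifiers reach near-perfect tenfold accuracy
at 60 recordings per class — evidence that the pipeline extracts the class
structure that is present, not a claim about accuracy on clinical data.

## Problem sizes and numerics

The default study uses 60 recordings per class (300 total, plus the
reference); extraction of the full study takes a few seconds. Correlations
use FFT-based convolution where faster (agreement with direct-loop oracles
is tested to 1e-9); sliding window energies use cumulative sums, clipped at
zero, with exact-zero windows flagged as silent. Feature CSVs are written
with 12 significant digits and round-trip to better than 1e-10.

## Known limitations

* Equal-thirds cycle splitting misaligns recordings whose cycles differ
  strongly in length; the matching degree absorbs small jitter only.
* The frequency-domain defaults carry a structurally null third filter (see
  above); its energy features are identically zero.
* The mutual dimension depends on the choice of reference recording;
  results are only comparable across runs that share it.
* MFCC deltas, cepstral mean normalization, and adaptive selection of `O`
  are out of scope.
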