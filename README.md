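# fmfe — fuzzy matching feature extraction for phonocardiograms

`fmfe` turns a short heart-sound recording (a phonocardiogram, PCG) into a
compact, interpretable feature vector for diagnosing valvular heart disease,
without any heart-sound segmentation. It targets the common five-class
setting — normal heart sound (NHS), aortic regurgitation (AR), mitral
regurgitation (MR), mitral stenosis (MS), mitral valve prolapse (MVP) — on
mono 8 kHz recordings that each contain three cardiac cycles.

It is aimed at biomedical-signal researchers who want a feature-engineering
alternative to deep models: every feature has a physical reading (how well,
where, and with how much energy a recording matches a cardiac-cycle
template), and a classical classifier on top of them is cheap to train and
easy to audit.

## The method

For a target signal `s` with cycles `h1, h2, h3`:

1. **Templates.** Time domain: `m = (h1 + h2 + h3)/3`. Frequency domain:
   `m = (|FFT(h1)| + |FFT(h2)| + |FFT(h3)|)/3` (one-sided moduli). *Self*
   templates come from the signal itself; the *mutual* template is built once
   from a designated normal recording and shared by all signals.
2. **Filter bank.** `W` stacks the 1st–8th Gaussian-derivative wavelets
   (Hermite recurrence, unit-norm rows, length `L`).
3. **Eigen optimization.** `X = m ⊛ W` row-wise; `U` holds the eigenvectors
   of the top `O` eigenvalues of `X Xᵀ`; the optimized bank is `W′ = Uᵀ W` —
   the `O` filter combinations that capture the template's correlation
   energy.
4. **Fuzzy features.** `X_m = m ⊛ W′`, `X_s = s ⊛ W′`, endpoints trimmed to
   kill convolution edge effects.
5. **Matching degree.** Per filter, the normalized cross-correlation trace
   `y_i(k)` of `x′_si` against `x′_mi` over lags `k` (sliding window norm in
   the denominator); the degree is `d = y_1 ⊙ y_2 ⊙ … ⊙ y_O`, and `mmd =
   max d` with its lag.
6. **Matching energy.** `ME_i` is the windowed norm of `x′_si` at the
   best-match lag — the correlation energy each optimized wavelet captures
   where the signals align.

Three matching dimensions are extracted — time-domain self (TD.S), frequency-
domain self (FD.S), frequency-domain mutual (FD.M) — each contributing three
`mmd` values (one per cycle region) and `3·O` energies, for `9·(O+1)` = 36
features at the defaults (N=8, L=6, O=3 in time; N=8, L=2, O=3 in
frequency). Optionally 13 MFCCs (25 ms / 10 ms frames, 26 triangular Mel
filters, `Mel(f) = 2595·log10(1 + f/700)`) are fused for 49 features total.

The package also ships a seeded synthetic five-class PCG generator (S1/S2
bursts plus class-specific murmur bands and textbook auscultation
signatures), so the whole pipeline is testable without any data download,
and an evaluation harness (SVM / KNN / random forest / MLP, stratified
tenfold cross-validation, optional nested grid search, macro metrics,
one-vs-rest ROC, per-feature Welch t-tests).

## Worked example

```python
import numpy as np
from fmfe import (FmfeConfig, cross_validate, extract_fmfe,
                  extract_feature_table, generate_dataset, mutual_template)

signals, reference = generate_dataset(n_per_class=10, seed=0)
vec = extract_fmfe(signals[0], FmfeConfig(), mutual=mutual_template(reference))
for name in ("TD.S.MD", "FD.S.MD", "FD.M.MD"):
    print(f"{name} = {np.round(vec.blocks[name], 3)}")

table = extract_feature_table(signals, reference=reference)
report = cross_validate(table, classifier="rf", n_folds=10, seed=0)
print(f"tenfold RF accuracy: {report.accuracy:.3f}")
```

prints

```
TD.S.MD = [0.406 0.318 0.432]
FD.S.MD = [0.982 0.915 0.968]
FD.M.MD = [0.861 0.964 0.885]
tenfold RF accuracy: 1.000
```

The normal recording matches its own averaged-cycle template only moderately
in the time domain (cycle-to-cycle jitter and noise), matches its own
averaged spectrum almost perfectly (FD.S.MD near 1), and matches the shared
normal reference spectrum well (FD.M.MD high — as a normal recording
should). A random forest separates the five synthetic classes perfectly
under tenfold cross-validation.

The same pipeline is available from the shell:

```sh
fmfe simulate --n-per-class 50 --seed 0 --out-dir data/
fmfe extract  --input data/ --reference NHS-reference --out features.csv
fmfe evaluate --features features.csv --classifier rf --folds 10 --seed 0 --out report.json
fmfe report   --report report.json
```

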