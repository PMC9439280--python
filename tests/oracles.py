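"""Independent loop-based oracles used to cross-check the vectorized code.

Everything here is deliberately written with explicit Python loops and no
convolution/FFT shortcuts, so agreement with the package is a genuine
two-route check.
"""

from __future__ import annotations

import math


def conv_full(x, w):
    """Full discrete convolution by double loop."""
    n, m = len(x), len(w)
    out = [0.0] * (n + m - 1)
    for i in range(n):
        for j in range(m):
            out[i + j] += x[i] * w[j]
    return out


def dft_modulus(x):
    """One-sided DFT modulus by direct O(n^2) summation."""
    n = len(x)
    out = []
    for k in range(n // 2 + 1):
        re = sum(x[t] * math.cos(2 * math.pi * k * t / n) for t in range(n))
        im = -sum(x[t] * math.sin(2 * math.pi * k * t / n) for t in range(n))
        out.append(math.hypot(re, im))
    return out


def elementwise_mean(rows):
    length = len(rows[0])
    return [sum(row[i] for row in rows) / len(rows) for i in range(length)]


def fuzzy_rows(values, filters, trim):
    rows = []
    for w in filters:
        conv = conv_full(list(values), list(w))
        rows.append(conv[trim:len(conv) - trim] if trim else conv)
    return rows


def match_pipeline(signal_values, template_values, filters, trim,
                   mode="valid", normalization="ncc"):
    """Loop reimplementation of the fuzzy-matching pipeline.

    Returns (traces, degree, mmd, mmd_index, energies); energies are the
    windowed norms of the target's fuzzy features at the best-match lag.
    """
    xs_rows = fuzzy_rows(signal_values, filters, trim)
    xm_rows = fuzzy_rows(template_values, filters, trim)
    ls, lm = len(xs_rows[0]), len(xm_rows[0])
    n_lags = ls - lm + 1 if mode == "valid" else ls
    traces, all_norms = [], []
    for xs, xm in zip(xs_rows, xm_rows):
        tnorm_sq = sum(v * v for v in xm)
        tnorm = math.sqrt(tnorm_sq) if normalization == "ncc" else tnorm_sq
        ys, norms = [], []
        for k in range(n_lags):
            window = xs[k:k + lm]       # truncated at the right in slide mode
            wsq = sum(v * v for v in window)
            norms.append(math.sqrt(wsq))
            if tnorm_sq == 0.0:         # eigen-null filter: neutral trace
                ys.append(1.0)
            elif wsq == 0.0:
                ys.append(0.0)
            else:
                num = sum(a * b for a, b in zip(window, xm))
                ys.append(num / (math.sqrt(wsq) * tnorm))
        traces.append(ys)
        all_norms.append(norms)
    degree = [math.prod(col) for col in zip(*traces)]
    mmd = max(degree)
    mmd_index = degree.index(mmd)
    energies = [norms[mmd_index] for norms in all_norms]
    return traces, degree, mmd, mmd_index, energies


def eig_sym_2x2(a, b, c):
    """Eigenvalues of [[a, b], [b, c]] by the quadratic formula, descending."""
    mean = (a + c) / 2.0
    disc = math.sqrt(((a - c) / 2.0) ** 2 + b * b)
    return mean + disc, mean - disc


def mfcc_toy(samples, sample_rate, n_fft, n_filters, n_coeff, mel_constant):
    """From-scratch one-frame MFCC: DFT -> mel filterbank -> log -> DCT-II.

    Mirrors the documented pipeline (Hamming window, triangular filters with
    edges uniform on the mel scale, energies floored at 1e-10, orthonormal
    DCT, coefficient 0 dropped) with none of the package's code.
    """
    m = len(samples)
    window = [0.54 - 0.46 * math.cos(2 * math.pi * i / (m - 1)) for i in range(m)]
    frame = [s * w for s, w in zip(samples, window)] + [0.0] * (n_fft - m)
    mags = []
    for k in range(n_fft // 2 + 1):
        re = sum(frame[t] * math.cos(2 * math.pi * k * t / n_fft)
                 for t in range(n_fft))
        im = -sum(frame[t] * math.sin(2 * math.pi * k * t / n_fft)
                  for t in range(n_fft))
        mags.append(math.hypot(re, im))

    def mel(f):
        return mel_constant * math.log10(1.0 + f / 700.0)

    def mel_inv(v):
        return 700.0 * (10.0 ** (v / mel_constant) - 1.0)

    top = mel(sample_rate / 2.0)
    edges = [mel_inv(top * i / (n_filters + 1)) for i in range(n_filters + 2)]
    bin_freqs = [k * sample_rate / n_fft for k in range(n_fft // 2 + 1)]
    log_energies = []
    for f in range(n_filters):
        lo, mid, hi = edges[f], edges[f + 1], edges[f + 2]
        energy = 0.0
        for freq, mag in zip(bin_freqs, mags):
            weight = min((freq - lo) / (mid - lo), (hi - freq) / (hi - mid))
            energy += max(weight, 0.0) * mag
        log_energies.append(math.log(max(energy, 1e-10)))
    coeffs = []
    for k in range(1, n_coeff + 1):
        total = sum(log_energies[j]
                    * math.cos(math.pi * k * (2 * j + 1) / (2 * n_filters))
                    for j in range(n_filters))
        coeffs.append(total * math.sqrt(2.0 / n_filters))
    return coeffs
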