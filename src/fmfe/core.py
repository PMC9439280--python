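"""The fuzzy matching feature extraction (FMFE) algorithm.

Pipeline, per matching dimension:

1. template features      X  = m (*) W          (full convolution, row-wise)
2. eigen mask             U  = top-O eigenvectors of X X^T
3. optimized filters      W' = U^T W
4. fuzzy features         X_m = m (*) W',  X_s = s (*) W'  (endpoints trimmed)
5. matching degree        y_i = ncc trace of x'_si against x'_mi over lags,
                          d = y_1 . y_2 ... y_O (elementwise product),
                          mmd = max(d) with its first-attaining lag
6. matching energy        ME_i = windowed norm of x'_si at the best-match lag

Three dimensions are extracted: time-domain self matching (one continuous lag
axis over the whole three-cycle signal, partitioned into thirds), frequency-
domain self matching (each cycle spectrum against the averaged spectrum), and
frequency-domain mutual matching (each cycle spectrum against a shared normal
reference template).  The six feature blocks concatenate to 9*(O+1) values.

Normalization modes: "ncc" divides the correlation by the sliding window norm
times ||x'_mi|| (true normalized cross-correlation, bounded by 1, scale
invariant); "literal" divides by the sliding window norm times ||x'_mi||^2.
The two traces are proportional row-wise, so best-match lags agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import correlate

from .errors import ValidationError
from .signal_io import PcgSignal
from .templating import (Template, freq_template, magnitude_spectrum,
                         resample_spectrum, split_cycles, time_template)
from .wavelets import WaveletBank, build_wavelet_bank

BLOCK_ORDER = ("TD.S.MD", "TD.S.ME", "FD.S.MD", "FD.S.ME", "FD.M.MD", "FD.M.ME")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class MatchSettings:
    """Hyperparameters of one matching dimension.

    ``trim=None`` means the default symmetric trim of L-1 samples per end,
    which removes every partial-overlap lag of the full convolution.
    """

    n_filters: int = 8
    length: int = 6
    n_components: int = 3
    trim: int | None = None
    normalization: str = "ncc"
    mode: str = "valid"              # lag axis: valid | slide
    support_sigmas: float = 2.5

    @property
    def trim_amount(self) -> int:
        return self.length - 1 if self.trim is None else self.trim

    def validate(self) -> None:
        if self.normalization not in ("ncc", "literal"):
            raise ValidationError(
                f"unknown normalization {self.normalization!r}")
        if self.mode not in ("valid", "slide"):
            raise ValidationError(f"unknown matching mode {self.mode!r}")
        if not 1 <= self.n_components <= self.n_filters:
            raise ValidationError("need 1 <= O <= N")
        if self.trim_amount < 0:
            raise ValidationError("trim must be nonnegative")


def _default_time() -> MatchSettings:
    return MatchSettings(n_filters=8, length=6, n_components=3)


def _default_freq() -> MatchSettings:
    # per-cycle spectra are matched by sliding the template across the
    # frequency axis (partial overlap at the upper end), so a frequency shift
    # between main spectral distributions is visible in the lag of the max
    return MatchSettings(n_filters=8, length=2, n_components=3, mode="slide")


@dataclass
class FmfeConfig:
    """Per-dimension settings; defaults are N=8, L=6, O=3 (time) and
    N=8, L=2, O=3 (frequency)."""

    time: MatchSettings = field(default_factory=_default_time)
    freq: MatchSettings = field(default_factory=_default_freq)

    def validate(self) -> None:
        self.time.validate()
        self.freq.validate()


# ---------------------------------------------------------------------------
# matrices

@dataclass
class TemplateFeatureMatrix:
    """X = m (*) W: one full-convolution row per initial filter."""

    rows: np.ndarray                     # (N, len(m)+L-1)

    def __post_init__(self) -> None:
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=np.float64))


@dataclass
class EigenMask:
    """Top-O eigenvectors (columns) of X X^T with their eigenvalues."""

    columns: np.ndarray                  # (N, O)
    eigenvalues: np.ndarray              # (O,) non-increasing
    trace: float                         # trace of X X^T (total energy)

    @property
    def energy_fraction(self) -> float:
        return float(self.eigenvalues.sum() / self.trace) if self.trace > 0 else 1.0


@dataclass
class OptimizedFilterBank:
    """W' = U^T W: the O eigen-combined filters."""

    filters: np.ndarray                  # (O, L)

    def __post_init__(self) -> None:
        self.filters = np.atleast_2d(np.asarray(self.filters, dtype=np.float64))

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    @property
    def length(self) -> int:
        return self.filters.shape[1]


@dataclass
class FuzzyFeatureMatrix:
    """Convolution of a signal with the optimized bank, endpoint-trimmed.

    ``raw`` keeps the untrimmed rows for inspection and plotting.
    """

    rows: np.ndarray                     # (O, T) trimmed
    raw: np.ndarray                      # (O, T + 2*trim)
    trim_amount: int

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def row_length(self) -> int:
        return self.rows.shape[1]


@dataclass
class MatchResult:
    """Per-filter correlation traces, their product, and the best match.

    ``window_norms[i, k]`` is the Euclidean norm of the target's fuzzy
    feature x'_si over the template-length window starting at lag k — the
    correlation energy axis from which the matching energies are read.
    """

    traces: np.ndarray                   # (O, Q)
    degree: np.ndarray                   # (Q,) elementwise product
    mmd: float
    mmd_index: int                       # first lag attaining the max
    energies: np.ndarray                 # (O,) windowed norms at the best lag
    window_norms: np.ndarray             # (O, Q)
    zero_norm_lags: np.ndarray           # bool (Q,), lags with silent windows
    null_rows: np.ndarray = None         # bool (O,), zero-template rows


# ---------------------------------------------------------------------------
# operations

def template_features(template: Template | np.ndarray,
                      bank: WaveletBank) -> TemplateFeatureMatrix:
    """X = m (*) W: full discrete convolution of the template with each row."""
    m = template.values if isinstance(template, Template) else np.asarray(template, float)
    if m.size < bank.length:
        raise ValidationError("template shorter than the filters")
    rows = np.stack([np.convolve(m, w) for w in bank.filters])
    return TemplateFeatureMatrix(rows)


def optimize_filters(X: TemplateFeatureMatrix, bank: WaveletBank,
                     n_components: int) -> tuple[EigenMask, OptimizedFilterBank]:
    """Eigen-reduce the bank: U = top-O eigenvectors of X X^T, W' = U^T W.

    The symmetric eigendecomposition may yield zero eigenvalues (rank-deficient
    X is allowed; with L = 2 the bank's row space is two-dimensional, so any
    third component is numerically null).  Numerically-null directions
    (eigenvalue below 1e-9 of the largest) are replaced by a deterministic
    orthonormal completion of the retained basis — LAPACK's null-space vectors
    are otherwise arbitrary, which would break run-to-run and scale
    reproducibility.  Each eigenvector's sign is fixed so its
    largest-magnitude entry is positive; eigenvalue ties keep the
    decomposition's output order.
    """
    n = X.rows.shape[0]
    if not 1 <= n_components <= n:
        raise ValidationError(f"n_components must be in 1..{n}")
    if n != bank.n_filters:
        raise ValidationError("feature matrix and bank row counts differ")
    gram = X.rows @ X.rows.T
    eigenvalues, eigenvectors = np.linalg.eigh(gram)
    order = np.argsort(eigenvalues, kind="stable")[::-1]
    eigenvalues = eigenvalues[order][:n_components]
    columns = eigenvectors[:, order][:, :n_components]
    tol = max(float(eigenvalues[0]), 0.0) * 1e-9
    null_start = int(np.searchsorted(-eigenvalues, -tol, side="right"))
    if null_start < n_components:
        basis = columns[:, :null_start]
        for j in range(null_start, n_components):
            residuals = np.eye(n) - basis @ basis.T
            norms = np.linalg.norm(residuals, axis=0)
            # smallest canonical index among the (possibly tied) best residuals
            pick = int(np.flatnonzero(norms >= norms.max() - 1e-6)[0])
            vec = residuals[:, pick]
            vec /= np.linalg.norm(vec)
            basis = np.column_stack([basis, vec])
        columns = basis
    for j in range(columns.shape[1]):
        peak = np.argmax(np.abs(columns[:, j]))
        if columns[peak, j] < 0:
            columns[:, j] = -columns[:, j]
    mask = EigenMask(columns, eigenvalues, float(np.trace(gram)))
    filters = columns.T @ bank.filters
    # a null direction maps to the zero filter in exact arithmetic; snap the
    # rounding residue away so downstream matching sees it as such
    filters[eigenvalues <= tol] = 0.0
    return mask, OptimizedFilterBank(filters)


def fuzzy_features(signal_values: np.ndarray, filters: OptimizedFilterBank,
                   trim_amount: int | None = None) -> FuzzyFeatureMatrix:
    """Convolve a signal with each optimized filter, then trim both ends.

    The default trim of L-1 per end removes all partial-overlap lags of the
    full convolution (equivalent to keeping the valid part).
    """
    x = np.asarray(signal_values, dtype=np.float64)
    length = filters.length
    trim = length - 1 if trim_amount is None else int(trim_amount)
    if trim < 0:
        raise ValidationError("trim must be nonnegative")
    if x.size < length:
        raise ValidationError("signal shorter than the filters")
    raw = np.stack([np.convolve(x, w) for w in filters.filters])
    if raw.shape[1] - 2 * trim < 1:
        raise ValidationError("signal too short after endpoint trimming")
    rows = raw[:, trim:raw.shape[1] - trim] if trim else raw.copy()
    return FuzzyFeatureMatrix(rows, raw, trim)


def _sliding_sumsq(x: np.ndarray, window: int, mode: str) -> np.ndarray:
    """Windowed sum of squares per lag (cumulative-sum method).

    ``valid``: full windows only; ``slide``: one lag per template start
    position 0..len(x)-1, windows truncated at the right end (the convolution
    of the squared signal with an all-ones vector, right half).
    """
    csum = np.concatenate(([0.0], np.cumsum(x * x)))
    if mode == "valid":
        out = csum[window:] - csum[:-window]
    else:
        stops = np.minimum(np.arange(x.size) + window, x.size)
        out = csum[stops] - csum[:-1]
    return np.maximum(out, 0.0)


def matching_degree(Xs: FuzzyFeatureMatrix, Xm: FuzzyFeatureMatrix,
                    normalization: str = "ncc", mode: str = "valid") -> MatchResult:
    """Slide each template row over the target row and combine the traces.

    Per row i, the cross-correlation of x'_si with x'_mi is divided by the
    sliding window norm of x'_si (window = len(x'_mi)) times the template
    norm term (||x'_mi|| in "ncc" mode, ||x'_mi||^2 in "literal" mode).
    ``mode`` sets the lag axis: "valid" keeps complete-overlap lags only
    (len(x'_si) - len(x'_mi) + 1 of them); "slide" starts the template at
    every target position 0..len(x'_si)-1 and lets it run off the right end,
    the truncated window norms coming from the all-ones convolution.  Lags
    whose window has zero energy yield y_i = 0 and are flagged.  A template
    row with zero norm (an eigen-null filter) contributes a neutral trace
    y_i = 1 and zero energy, and is flagged in ``null_rows``; only a template
    whose rows are ALL zero is an error.  The degree d
    is the elementwise product of the O traces; the matching energy of filter
    i is the windowed norm of x'_si at the best-match lag (the correlation
    energy the optimized wavelet captures where the signals match best).
    """
    if normalization not in ("ncc", "literal"):
        raise ValidationError(f"unknown normalization {normalization!r}")
    if mode not in ("valid", "slide"):
        raise ValidationError(f"unknown matching mode {mode!r}")
    if Xs.n_rows != Xm.n_rows:
        raise ValidationError("Xs and Xm must have the same number of rows")
    ls, lm = Xs.row_length, Xm.row_length
    if ls < lm:
        raise ValidationError("target rows must be at least as long as template rows")
    n_lags = ls - lm + 1 if mode == "valid" else ls
    traces = np.empty((Xs.n_rows, n_lags))
    window_norms = np.empty((Xs.n_rows, n_lags))
    zero_mask = np.zeros(n_lags, dtype=bool)
    null_rows = np.zeros(Xs.n_rows, dtype=bool)
    if not np.any(Xm.rows):
        raise ValidationError("every template row is zero")
    for i in range(Xs.n_rows):
        xs, xm = Xs.rows[i], Xm.rows[i]
        template_sumsq = float(np.dot(xm, xm))
        if template_sumsq == 0.0:
            null_rows[i] = True
            traces[i] = 1.0
            window_norms[i] = np.sqrt(_sliding_sumsq(xs, lm, mode))
            continue
        full = correlate(xs, xm, mode="full", method="auto")
        num = full[lm - 1:lm - 1 + n_lags]
        win = _sliding_sumsq(xs, lm, mode)
        window_norms[i] = np.sqrt(win)
        tnorm = np.sqrt(template_sumsq) if normalization == "ncc" else template_sumsq
        silent = win == 0.0
        zero_mask |= silent
        denom = np.where(silent, 1.0, window_norms[i] * tnorm)
        traces[i] = np.where(silent, 0.0, num / denom)
    degree = traces.prod(axis=0)
    mmd_index = int(np.argmax(degree))
    return MatchResult(traces, degree, float(degree[mmd_index]), mmd_index,
                       window_norms[:, mmd_index].copy(), window_norms,
                       zero_mask, null_rows)


def _optimized_bank_for(template: Template,
                        settings: MatchSettings) -> OptimizedFilterBank:
    bank = build_wavelet_bank(settings.n_filters, settings.length,
                              settings.support_sigmas)
    X = template_features(template, bank)
    _, optimized = optimize_filters(X, bank, settings.n_components)
    return optimized


def match_time_domain_self(signal: PcgSignal,
                           settings: MatchSettings) -> tuple[np.ndarray, np.ndarray]:
    """Time-domain self matching over the whole three-cycle signal.

    The template is the average cycle; the lag axis spans the full signal and
    is partitioned into three equal contiguous thirds, each contributing its
    own maximum matching degree and the matching energies at that lag.
    Returns (md, me) with shapes (3,) and (3, O).
    """
    settings.validate()
    cycles = split_cycles(signal)
    template = time_template(cycles, origin_id=signal.id)
    optimized = _optimized_bank_for(template, settings)
    trim = settings.trim_amount
    Xm = fuzzy_features(template.values, optimized, trim)
    Xs = fuzzy_features(signal.samples, optimized, trim)
    result = matching_degree(Xs, Xm, settings.normalization, settings.mode)
    md = np.empty(3)
    me = np.empty((3, optimized.n_filters))
    for k, lags in enumerate(np.array_split(np.arange(result.degree.size), 3)):
        if lags.size == 0:
            raise ValidationError("too few lags to partition into thirds")
        local = int(np.argmax(result.degree[lags]))
        idx = int(lags[local])
        md[k] = result.degree[idx]
        me[k] = result.window_norms[:, idx]
    return md, me


def match_frequency_domain(signal: PcgSignal, template: Template,
                           settings: MatchSettings) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-domain matching of each cycle spectrum against a template.

    Self matching passes the signal's own averaged-spectrum template; mutual
    matching passes the shared normal reference template, and cycle spectra
    are linearly resampled to its length first.  Returns (md, me) with shapes
    (3,) and (3, O).
    """
    settings.validate()
    if template.domain_tag != "frequency":
        raise ValidationError("frequency-domain matching needs a frequency template")
    optimized = _optimized_bank_for(template, settings)
    trim = settings.trim_amount
    Xm = fuzzy_features(template.values, optimized, trim)
    cycles = split_cycles(signal)
    md = np.empty(3)
    me = np.empty((3, optimized.n_filters))
    for k, cycle in enumerate(cycles.cycles):
        spectrum = magnitude_spectrum(cycle)
        if spectrum.size != len(template):
            spectrum = resample_spectrum(spectrum, len(template))
        Xs = fuzzy_features(spectrum, optimized, trim)
        result = matching_degree(Xs, Xm, settings.normalization, settings.mode)
        md[k] = result.mmd
        me[k] = result.energies
    return md, me


# ---------------------------------------------------------------------------
# feature vector assembly

@dataclass
class FmfeFeatureVector:
    """The six concatenated blocks of one signal's matching features."""

    blocks: dict[str, np.ndarray]
    signal_id: str = ""
    label: str = "UNKNOWN"

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.blocks[name] for name in BLOCK_ORDER])

    @property
    def names(self) -> list[str]:
        out: list[str] = []
        for name in BLOCK_ORDER:
            block = self.blocks[name]
            if name.endswith("MD"):
                out.extend(f"{name}.{k + 1}" for k in range(block.size))
            else:
                n_comp = block.size // 3
                out.extend(f"{name}.{k + 1}.{i + 1}"
                           for k in range(3) for i in range(n_comp))
        return out

    def __len__(self) -> int:
        return sum(b.size for b in self.blocks.values())


def extract_fmfe(signal: PcgSignal, config: FmfeConfig | None = None,
                 mutual: Template | None = None) -> FmfeFeatureVector:
    """Extract the full FMFE vector for one signal.

    ``mutual`` is the shared frequency-domain reference template; when omitted
    the signal's own frequency template stands in (mutual matching then
    coincides with self matching).  Block order is fixed: TD.S.MD, TD.S.ME,
    FD.S.MD, FD.S.ME, FD.M.MD, FD.M.ME; total length is 9*(O+1) when both
    dimensions share O.
    """
    config = config or FmfeConfig()
    config.validate()
    td_md, td_me = match_time_domain_self(signal, config.time)
    self_template = freq_template(split_cycles(signal), origin_id=signal.id)
    fd_md, fd_me = match_frequency_domain(signal, self_template, config.freq)
    mutual_tpl = mutual if mutual is not None else replace(
        self_template, source_tag="mutual")
    fm_md, fm_me = match_frequency_domain(signal, mutual_tpl, config.freq)
    blocks = {
        "TD.S.MD": td_md, "TD.S.ME": td_me.ravel(),
        "FD.S.MD": fd_md, "FD.S.ME": fd_me.ravel(),
        "FD.M.MD": fm_md, "FD.M.ME": fm_me.ravel(),
    }
    return FmfeFeatureVector(blocks, signal_id=signal.id, label=signal.label)
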