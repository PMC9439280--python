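"""Gaussian-derivative wavelet filter banks.

The initial matched-filter bank ``W`` stacks the 1st..Nth derivatives of the
Gaussian ``exp(-t^2/2)``, each sampled on a uniform grid over
``[-support_sigmas, +support_sigmas]`` and scaled to unit Euclidean norm.
Derivatives are generated through the probabilists' Hermite recurrence

    He_{n+1}(t) = t He_n(t) - n He_{n-1}(t),
    d^n/dt^n exp(-t^2/2) = (-1)^n He_n(t) exp(-t^2/2),

so no symbolic differentiation is needed.  Rows of odd derivative order are
antisymmetric about the grid centre; even orders are symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError

MAX_ORDER = 8


@dataclass
class WaveletBank:
    """``N x L`` bank of unit-norm Gaussian-derivative filters."""

    filters: np.ndarray            # shape (N, L)
    orders: tuple[int, ...]        # derivative order of each row, 1..8
    support_sigmas: float

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=np.float64)
        if self.filters.ndim != 2:
            raise ValidationError("filter bank must be a 2-D array")
        n, length = self.filters.shape
        if n < 1 or length < 2:
            raise ValidationError("bank needs N >= 1 rows of length L >= 2")
        if len(self.orders) != n:
            raise ValidationError("orders must match the number of rows")

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    @property
    def length(self) -> int:
        return self.filters.shape[1]


def hermite_he(order: int, t: np.ndarray) -> np.ndarray:
    """Probabilists' Hermite polynomial He_n evaluated by the recurrence."""
    t = np.asarray(t, dtype=np.float64)
    if order < 0:
        raise ValidationError("Hermite order must be nonnegative")
    h_prev = np.ones_like(t)
    if order == 0:
        return h_prev
    h = t.copy()
    for n in range(1, order):
        h, h_prev = t * h - n * h_prev, h
    return h


def gaussian_derivative(order: int, t: np.ndarray) -> np.ndarray:
    """The order-th derivative of exp(-t^2/2), unnormalized."""
    t = np.asarray(t, dtype=np.float64)
    return (-1.0) ** order * hermite_he(order, t) * np.exp(-0.5 * t * t)


def build_wavelet_bank(n_filters: int = 8, length: int = 6,
                       support_sigmas: float = 2.5) -> WaveletBank:
    """Build the initial bank of 1st..n-th Gaussian-derivative filters.

    Row ``k`` (1-based) is the k-th derivative of the Gaussian sampled at
    ``length`` uniform points on ``[-support_sigmas, +support_sigmas]``
    (endpoints included), then scaled to unit Euclidean norm.
    """
    if n_filters < 1:
        raise ValidationError("n_filters must be >= 1")
    if n_filters > MAX_ORDER:
        raise ValidationError(f"n_filters must be <= {MAX_ORDER} "
                              "(derivative orders 1..8)")
    if length < 2:
        raise ValidationError("length must be >= 2")
    if support_sigmas <= 0:
        raise ValidationError("support_sigmas must be positive")
    grid = np.linspace(-support_sigmas, support_sigmas, length)
    rows = np.empty((n_filters, length))
    orders = tuple(range(1, n_filters + 1))
    for i, order in enumerate(orders):
        row = gaussian_derivative(order, grid)
        norm = np.linalg.norm(row)
        if norm == 0.0 or not np.isfinite(norm):
            raise ValidationError(
                f"derivative-order-{order} row is degenerate at L={length}; "
                "increase length or support_sigmas")
        rows[i] = row / norm
    return WaveletBank(rows, orders, float(support_sigmas))


def save_bank_csv(bank: WaveletBank, path: str | Path) -> None:
    """Export a bank (rows = filters) for inspection."""
    header = f"orders={','.join(map(str, bank.orders))};" \
             f"support_sigmas={bank.support_sigmas}"
    np.savetxt(Path(path), bank.filters, delimiter=",", header=header)


def load_bank_csv(path: str | Path) -> WaveletBank:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    meta = dict(item.split("=") for item in header.split(";") if "=" in item)
    filters = np.atleast_2d(np.loadtxt(path, delimiter=","))
    orders = tuple(int(o) for o in meta["orders"].split(","))
    return WaveletBank(filters, orders, float(meta["support_sigmas"]))
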