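"""Spherical-spline surface Laplacian (current source density).

The scalp potential is interpolated with spherical splines built from a
truncated Legendre series; the surface Laplacian of that interpolant is
evaluated at the electrodes themselves.  With ``x = cos θ`` between two
electrode positions:

    g(x) = (1/4π) Σ_{n=1..N} (2n+1) / (n(n+1))^m · P_n(x)
    h(x) = (1/4π) Σ_{n=1..N} (2n+1) / (n(n+1))^(m−1) · P_n(x)

The spline coefficients ``c`` solve the regularized system
``(G + λI) c + c0·1 = v`` under the zero-sum constraint ``Σ c = 0``; the
output is the *negative* surface Laplacian ``H c / r²`` (CSD-positive =
current source).  λ is added to the diagonal of G only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre

from .epochs import EpochArray
from .montage import Montage


@dataclass(frozen=True)
class CsdParams:
    """Spline order m, Legendre series degree N, regularization λ."""

    spline_order: int = 4
    legendre_degree: int = 10
    lam: float = 1e-5
    head_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.spline_order < 2:
            raise ValueError("spline_order must be >= 2")
        if self.legendre_degree < 1:
            raise ValueError("legendre_degree must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


def legendre_series(x: np.ndarray, order: int, degree: int) -> np.ndarray:
    """(1/4π) Σ_{n=1..degree} (2n+1)/(n(n+1))^order · P_n(x)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for n in range(1, degree + 1):
        out += (2 * n + 1) / (n * (n + 1)) ** order * eval_legendre(n, x)
    return out / (4 * np.pi)


@dataclass(frozen=True)
class CsdBasis:
    """G and H matrices over an electrode montage."""

    G: np.ndarray = field(repr=False)
    H: np.ndarray = field(repr=False)
    montage: Montage
    params: CsdParams


def csd_basis(montage: Montage, params: CsdParams = CsdParams()) -> CsdBasis:
    """Evaluate the g/h series on all electrode pairs.

    Raises if two electrodes coincide (the spline system is singular).
    """
    if len(montage) < 4:
        raise ValueError("CSD needs at least 4 channels")
    cosang = montage.pairwise_cos()
    off = ~np.eye(len(montage), dtype=bool)
    if np.any(cosang[off] > 1.0 - 1e-12):
        i, j = np.where((cosang > 1.0 - 1e-12) & off)
        pair = (montage.labels[i[0]], montage.labels[j[0]])
        raise ValueError(f"coincident electrode positions: {pair}")
    G = legendre_series(cosang, params.spline_order, params.legendre_degree)
    H = legendre_series(cosang, params.spline_order - 1, params.legendre_degree)
    return CsdBasis(G, H, montage, params)


def csd_transform_matrix(basis: CsdBasis) -> np.ndarray:
    """Linear operator L with ``csd = L @ v`` for scalp vectors v.

    Solving the augmented system once for all unit inputs gives the
    coefficient map ``C`` (rows of the augmented inverse); the CSD
    operator is then ``H C / r²``.
    """
    n = len(basis.montage)
    p = basis.params
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = basis.G + p.lam * np.eye(n)
    A[:n, n] = 1.0   # constant term c0
    A[n, :n] = 1.0   # zero-sum constraint on c
    Ainv = np.linalg.inv(A)
    C = Ainv[:n, :n]  # maps v -> spline coefficients c
    return (basis.H @ C) / p.head_radius**2


def csd_transform(epochs: EpochArray, basis: CsdBasis,
                  params: CsdParams | None = None) -> EpochArray:
    """Apply the surface Laplacian to every time sample of every trial."""
    if tuple(epochs.ch_names) != tuple(basis.montage.labels):
        extra = set(epochs.ch_names) - set(basis.montage.labels)
        missing = set(basis.montage.labels) - set(epochs.ch_names)
        if extra or missing:
            raise ValueError(
                f"channel mismatch with CSD basis; not in basis: {sorted(extra)}; "
                f"missing from epochs: {sorted(missing)}"
            )
        # same channel set, different order: reorder to basis order
        epochs = epochs.pick(list(basis.montage.labels))
    L = csd_transform_matrix(basis)
    n_ch, n_t, n_tr = epochs.data.shape
    flat = epochs.data.reshape(n_ch, n_t * n_tr)
    out = (L @ flat).reshape(n_ch, n_t, n_tr)
    return EpochArray(out, epochs.srate, epochs.times, epochs.ch_names,
                      epochs.trial_labels, epochs.subject_id)
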