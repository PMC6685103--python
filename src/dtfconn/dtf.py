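"""Directed transfer function (DTF) from a fitted MVAR model.

The lag matrices are transformed to the frequency domain,

    A(f) = sum_{i=0..p} A_i exp(-j 2 pi f i / fs),   A_0 = -I,

inverted to the transfer matrix H(f) = A(f)^-1, and row-normalised into
the squared DTF

    gamma_ij(f)^2 = |H_ij(f)|^2 / sum_m |H_im(f)|^2,

the share of total spectral inflow into channel i contributed by channel
j.  Rows of gamma^2 therefore sum to one at every frequency.  Band
summaries average gamma^2 over a named frequency band; the scalar
``dtf_mean`` (mean off-diagonal band value) is the single-number
connectivity-strength readout used for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, SingularFrequencyError
from .mvar import MVARModel

__all__ = [
    "SpectralTransfer",
    "DTFResult",
    "default_freq_grid",
    "spectral_transfer",
    "dtf_from_transfer",
    "band_summary",
    "dtf",
]


def default_freq_grid(lo: float = 1.0, hi: float = 45.0, step: float = 0.5):
    """Default analysis grid: ``lo`` to ``hi`` Hz inclusive, ``step`` Hz apart."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


@dataclass
class SpectralTransfer:
    """Frequency-domain MVAR coefficients and their inverse.

    ``A_of_f[k]`` and ``H[k]`` are the complex N x N matrices at
    ``freqs[k]``; H(f) A(f) = I holds at every grid frequency.
    """

    freqs: np.ndarray
    H: np.ndarray
    A_of_f: np.ndarray
    labels: list[str] = field(default_factory=list)
    order: int | None = None


@dataclass
class DTFResult:
    """Squared DTF over a frequency grid, with optional band summary.

    ``gamma2[k, i, j]`` is the inflow share from channel j to channel i
    at ``freqs[k]``; every row sums to 1.  ``band_mean``/``dtf_mean``
    are filled by :func:`band_summary`.
    """

    gamma2: np.ndarray
    freqs: np.ndarray
    labels: list[str] = field(default_factory=list)
    order: int | None = None
    band_name: str | None = None
    band: tuple[float, float] | None = None
    band_mean: np.ndarray | None = None
    dtf_mean: float | None = None

    @property
    def n_channels(self) -> int:
        return self.gamma2.shape[1]


def spectral_transfer(
    model: MVARModel, freqs: np.ndarray, fs: float
) -> SpectralTransfer:
    """Evaluate A(f) and the transfer matrix H(f) = A(f)^-1 on a grid.

    Raises
    ------
    ConfigurationError
        If any frequency reaches the Nyquist rate.
    SingularFrequencyError
        If A(f) is numerically singular at some grid frequency; the
        error lists the offending frequencies.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= fs / 2) or np.any(freqs < 0):
        raise ConfigurationError(
            f"analysis frequencies must lie in [0, {fs / 2}) Hz"
        )
    n = model.n_channels
    p = model.order
    dt = 1.0 / fs
    # A(f) = -I + sum_k A_k e^{-j 2 pi f k dt}; the sign convention
    # vanishes after |.|^2
    phase = np.exp(
        -2j * np.pi * freqs[:, None] * dt * np.arange(1, p + 1)[None, :]
    )  # (F, p)
    A_of_f = np.einsum("fk,kij->fij", phase, model.coeffs)
    A_of_f -= np.eye(n)[None]

    # determinant magnitude is dimension-dependent, so test conditioning
    conds = np.linalg.cond(A_of_f)
    bad = ~np.isfinite(conds) | (conds > 1e12)
    if bad.any():
        raise SingularFrequencyError(freqs[bad])
    H = np.linalg.inv(A_of_f)
    return SpectralTransfer(
        freqs=freqs, H=H, A_of_f=A_of_f, labels=list(model.labels), order=p
    )


def dtf_from_transfer(st: SpectralTransfer) -> DTFResult:
    """Row-normalise |H(f)|^2 into the squared DTF.

    Raises an internal-consistency error if a row of H is entirely zero,
    which cannot happen for an invertible transfer matrix.
    """
    power = np.abs(st.H) ** 2
    row_sums = power.sum(axis=2, keepdims=True)
    if np.any(row_sums == 0):
        raise ConfigurationError("all-zero row in |H|^2; transfer matrix invalid")
    gamma2 = power / row_sums
    return DTFResult(
        gamma2=gamma2, freqs=st.freqs, labels=list(st.labels), order=st.order
    )


def band_summary(
    res: DTFResult,
    band: tuple[float, float],
    band_name: str | None = None,
    include_diagonal: bool = False,
) -> DTFResult:
    """Average gamma^2 over a band and attach the scalar summary.

    ``band_mean`` is the mean of gamma^2 over grid frequencies inside
    [lo, hi] (inclusive); ``dtf_mean`` is the mean of its off-diagonal
    entries (set ``include_diagonal=True`` to average the full matrix,
    in which case self-inflow dominates).

    Raises
    ------
    ConfigurationError
        If no grid frequency falls inside the band.
    """
    lo, hi = band
    if not lo < hi:
        raise ConfigurationError(f"band must satisfy lo < hi, got {band}")
    sel = (res.freqs >= lo) & (res.freqs <= hi)
    if not sel.any():
        raise ConfigurationError(
            f"no grid frequency inside band [{lo}, {hi}] Hz "
            f"(grid spans [{res.freqs.min()}, {res.freqs.max()}] Hz)"
        )
    band_mean = res.gamma2[sel].mean(axis=0)
    if include_diagonal:
        dtf_mean = float(band_mean.mean())
    else:
        off = ~np.eye(res.n_channels, dtype=bool)
        dtf_mean = float(band_mean[off].mean())
    return replace(
        res,
        band_name=band_name or f"{lo}-{hi}Hz",
        band=(float(lo), float(hi)),
        band_mean=band_mean,
        dtf_mean=dtf_mean,
    )


def dtf(
    model: MVARModel,
    fs: float,
    freqs: np.ndarray | None = None,
    band: tuple[float, float] | None = None,
    band_name: str | None = None,
    include_diagonal: bool = False,
) -> DTFResult:
    """Convenience chain: spectral transfer -> DTF -> optional band summary."""
    if freqs is None:
        freqs = default_freq_grid()
    res = dtf_from_transfer(spectral_transfer(model, freqs, fs))
    if band is not None:
        res = band_summary(res, band, band_name, include_diagonal)
    return res
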