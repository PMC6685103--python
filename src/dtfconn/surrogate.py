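"""Surrogate-data significance testing for DTF links.

An estimated DTF is never exactly zero, so apparent links need a null
reference.  The null is built by shuffling: each channel's samples are
randomly permuted (independently per channel, within each epoch),
destroying all cross-channel temporal alignment while preserving each
channel's amplitude distribution.  The fixed-order MVAR fit and the DTF
band summary are recomputed on every shuffled copy, yielding an
empirical distribution of band-mean gamma^2 per directed link under the
no-connectivity hypothesis.  Links whose observed value fails to exceed
the null are pruned.

P-values use the add-one empirical estimator
p = (1 + #{null >= observed}) / (1 + n_shuffles), which can never be 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg

from .dtf import DTFResult, default_freq_grid
from .errors import ConditioningError, ConfigurationError
from .mvar import _lagged_design
from .recording import MultichannelRecording

__all__ = ["SurrogateNull", "SignificanceMask", "build_null", "prune"]

logger = logging.getLogger(__name__)


@dataclass
class SurrogateNull:
    """Empirical null distribution of band-mean gamma^2 per link.

    ``null_values[s, i, j]`` is the band-mean DTF from channel j to
    channel i in shuffle s; exactly ``n_shuffles`` draws per link.
    """

    n_shuffles: int
    null_values: np.ndarray
    alpha: float
    seed: int | None
    band: tuple[float, float]
    band_name: str
    order: int
    labels: list[str] = field(default_factory=list)
    include_diagonal: bool = False
    n_retries: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.null_values.shape[0] != self.n_shuffles:
            raise ConfigurationError("null_values must hold n_shuffles draws per link")


@dataclass
class SignificanceMask:
    """Per-link keep/drop decisions with empirical p-values.

    ``keep[i, j]`` is True iff the observed inflow j -> i exceeded the
    (1 - alpha) null quantile (equivalently, add-one p <= alpha).  The
    diagonal is always False/NaN: self-inflow is not a link.
    """

    keep: np.ndarray
    p_values: np.ndarray
    alpha: float
    labels: list[str] = field(default_factory=list)


def _fast_fit(epochs: np.ndarray, p: int) -> np.ndarray:
    """Fixed-order pooled OLS returning only the lag matrices.

    Solves the normal equations directly (Cholesky); raises
    ConditioningError if the Gram matrix is singular, letting the caller
    retry with a fresh permutation.
    """
    X, Y = _lagged_design(epochs, p)
    n_ch = epochs.shape[1]
    try:
        c, low = linalg.cho_factor(X.T @ X)
        coef = linalg.cho_solve((c, low), X.T @ Y)
    except np.linalg.LinAlgError as err:
        raise ConditioningError(str(err))
    return np.stack([coef[k * n_ch : (k + 1) * n_ch].T for k in range(p)], axis=0)


def _band_mean_dtf(
    coeffs: np.ndarray, fs: float, freqs: np.ndarray, band_sel: np.ndarray
) -> np.ndarray:
    """Band-mean gamma^2 for a coefficient stack, no container overhead."""
    p, n, _ = coeffs.shape
    phase = np.exp(
        -2j * np.pi * freqs[band_sel, None] / fs * np.arange(1, p + 1)[None, :]
    )
    A_of_f = np.einsum("fk,kij->fij", phase, coeffs) - np.eye(n)[None]
    H = np.linalg.inv(A_of_f)
    power = np.abs(H) ** 2
    gamma2 = power / power.sum(axis=2, keepdims=True)
    return gamma2.mean(axis=0)


def build_null(
    rec: MultichannelRecording,
    order: int,
    band: tuple[float, float],
    freqs: np.ndarray | None = None,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    band_name: str | None = None,
    include_diagonal: bool = False,
    max_retries: int = 50,
) -> SurrogateNull:
    """Build the shuffling null for every directed link.

    Each of the ``n_shuffles`` draws independently permutes the time
    samples of every channel (within each epoch, so surrogates keep the
    epoch structure of the observed data), refits the MVAR at the fixed
    observed-data ``order``, and records the band-mean gamma^2 matrix.
    Deterministic given ``seed``.

    A shuffle whose fit fails numerically is retried with a fresh
    permutation; retries are counted in the result and logged.
    """
    if n_shuffles < 1:
        raise ConfigurationError("n_shuffles must be >= 1")
    if n_shuffles < 100:
        warnings.warn(
            f"n_shuffles={n_shuffles} gives coarse p-value resolution "
            f"(finest nonzero p = {1 / (1 + n_shuffles):.3f})",
            stacklevel=2,
        )
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    lo, hi = band
    band_sel = (freqs >= lo) & (freqs <= hi)
    if not band_sel.any():
        raise ConfigurationError(f"no grid frequency inside band {band}")

    rng = np.random.default_rng(seed)
    epochs = rec.epoch_data if rec.epoch_length is not None else rec.data[None]
    n = rec.n_channels
    null_values = np.empty((n_shuffles, n, n))
    retries = 0
    for s in range(n_shuffles):
        for attempt in range(max_retries + 1):
            shuffled = rng.permuted(epochs, axis=2)
            try:
                coeffs = _fast_fit(shuffled, order)
                null_values[s] = _band_mean_dtf(coeffs, rec.fs, freqs, band_sel)
                break
            except ConditioningError:
                retries += 1
                if attempt == max_retries:
                    raise
    if retries:
        logger.info("surrogate fitting retried %d permutation(s)", retries)
    return SurrogateNull(
        n_shuffles=n_shuffles,
        null_values=null_values,
        alpha=alpha,
        seed=seed,
        band=(float(lo), float(hi)),
        band_name=band_name or f"{lo}-{hi}Hz",
        order=order,
        labels=list(rec.labels),
        include_diagonal=include_diagonal,
        n_retries=retries,
    )


def prune(
    observed: DTFResult,
    null: SurrogateNull,
    alpha: float | None = None,
    fdr: bool = False,
) -> tuple[SignificanceMask, DTFResult]:
    """Remove links whose observed band-mean DTF is explained by the null.

    Per off-diagonal link, p = (1 + #{null >= observed}) / (1 + S); the
    link is kept iff p <= alpha.  The returned DTF has non-significant
    entries of ``band_mean`` set to 0 and ``dtf_mean`` recomputed; the
    full gamma2 spectrum is left untouched.  With ``fdr=True`` the
    per-link p-values are Benjamini-Hochberg adjusted before
    thresholding (off by default; the plain per-link test is the
    reference procedure).

    Raises
    ------
    ConfigurationError
        If observed and null were produced under different
        configurations (band, order, or channel set).
    """
    if observed.band_mean is None or observed.band is None:
        raise ConfigurationError("observed DTFResult lacks a band summary")
    if tuple(observed.band) != tuple(null.band):
        raise ConfigurationError(
            f"band mismatch: observed {observed.band} vs null {null.band}"
        )
    if observed.order is not None and observed.order != null.order:
        raise ConfigurationError(
            f"order mismatch: observed {observed.order} vs null {null.order}"
        )
    if observed.labels and null.labels and observed.labels != null.labels:
        raise ConfigurationError("channel label mismatch between observed and null")
    alpha = null.alpha if alpha is None else alpha
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")

    n = observed.n_channels
    obs = observed.band_mean
    exceed = (null.null_values >= obs[None]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + null.n_shuffles)
    off = ~np.eye(n, dtype=bool)
    if fdr:
        from scipy.stats import false_discovery_control

        p_adj = p.copy()
        p_adj[off] = false_discovery_control(p[off], method="bh")
        decide = p_adj
    else:
        decide = p
    keep = (decide <= alpha) & off
    p_values = np.where(off, p, np.nan)

    band_mean = np.where(keep | ~off, obs, 0.0)
    pruned = replace(
        observed,
        band_mean=band_mean,
        dtf_mean=float(band_mean[off].mean()),
    )
    mask = SignificanceMask(
        keep=keep, p_values=p_values, alpha=float(alpha), labels=list(observed.labels)
    )
    return mask, pruned
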