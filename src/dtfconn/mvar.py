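"""Multivariate autoregressive (MVAR) model estimation.

The model is x(t) = sum_{n=1..p} A_n x(t-n) + e(t) with white innovation
noise e; the lag matrices A_n encode directed, lagged influence between
channels and are the raw material of the directed transfer function.

Estimation is ordinary least squares on the lagged regression.  Epoched
recordings are fitted by pooling normal-equation rows across epochs,
with lag windows never crossing an epoch boundary, so discontinuities
introduced by artifact rejection cannot masquerade as dynamics.  Order
selection minimises Schwarz's Bayesian Criterion (SBC) or the logarithm
of Akaike's Final Prediction Error (FPE); both follow the ARfit
(Schneider & Neumaier, 2001) definitions:

    sbc(p) = logdp / m - log(ne) * (ne - np) / ne
    fpe(p) = logdp / m - log(ne * (ne - np) / (ne + np))

where m is the channel count, ne the number of regression rows (held
fixed across candidate orders), np = m * p the regressors per row, and
logdp the log-determinant of the residual cross-product matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .errors import ConditioningError, ConfigurationError
from .recording import MultichannelRecording

__all__ = ["MVARModel", "OrderSelection", "fit", "fit_epochs", "select_order"]

_COND_LIMIT = 1e12


@dataclass
class MVARModel:
    """A fitted MVAR model.

    Attributes
    ----------
    order : int
        Model order p.
    coeffs : ndarray, shape (p, n, n)
        Lag matrices A_1..A_p; coeffs[k, i, j] is the influence of
        channel j at lag k+1 on channel i.
    noise_cov : ndarray, shape (n, n)
        Innovation covariance, from residuals with small-sample divisor
        (rows - n*p - 1).
    n_samples_used : int
        Number of regression rows behind the estimate.
    sbc, fpe : float or None
        Criterion values at this order, when produced by order selection.
    labels : list of str
        Channel names carried through from the recording.
    """

    order: int
    coeffs: np.ndarray
    noise_cov: np.ndarray
    n_samples_used: int
    sbc: float | None = None
    fpe: float | None = None
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (self.order, self.n_channels, self.n_channels):
            raise ConfigurationError(
                f"coeffs shape {self.coeffs.shape} inconsistent with order "
                f"{self.order}"
            )
        asym = np.abs(self.noise_cov - self.noise_cov.T).max()
        if asym > 1e-8:
            raise ConfigurationError(f"noise_cov asymmetric by {asym:.2e}")
        if np.linalg.eigvalsh(self.noise_cov).min() < -1e-10:
            raise ConfigurationError("noise_cov has a negative eigenvalue")

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "order": self.order,
                "coeffs": self.coeffs.tolist(),
                "noise_cov": self.noise_cov.tolist(),
                "n_samples_used": self.n_samples_used,
                "sbc": self.sbc,
                "fpe": self.fpe,
                "labels": self.labels,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MVARModel":
        d = json.loads(text)
        return cls(
            order=d["order"],
            coeffs=np.array(d["coeffs"]),
            noise_cov=np.array(d["noise_cov"]),
            n_samples_used=d["n_samples_used"],
            sbc=d.get("sbc"),
            fpe=d.get("fpe"),
            labels=d.get("labels", []),
        )


def _lagged_design(epochs: np.ndarray, p: int, offset: int | None = None):
    """Stack the pooled lagged regression for 3-D epoch data.

    Parameters
    ----------
    epochs : ndarray (n_epochs, n_channels, samples_per_epoch)
    p : model order
    offset : first usable sample index within each epoch (>= p); using a
        common offset across candidate orders keeps criterion values
        comparable.

    Returns
    -------
    X : (rows, n*p) regressors [x(t-1), ..., x(t-p)]
    Y : (rows, n) targets x(t)
    """
    if offset is None:
        offset = p
    n_ep, n_ch, spe = epochs.shape
    if offset < p:
        raise ConfigurationError("offset must be >= model order")
    rows_per = spe - offset
    if rows_per < 1:
        raise ConfigurationError(
            f"epochs of {spe} samples too short for order {p} (offset {offset})"
        )
    X = np.empty((n_ep * rows_per, n_ch * p))
    Y = np.empty((n_ep * rows_per, n_ch))
    for e in range(n_ep):
        seg = epochs[e]  # (n_ch, spe)
        Y[e * rows_per : (e + 1) * rows_per] = seg[:, offset:].T
        for k in range(p):
            X[
                e * rows_per : (e + 1) * rows_per, k * n_ch : (k + 1) * n_ch
            ] = seg[:, offset - 1 - k : spe - 1 - k].T
    return X, Y


def _diagnose_channels(rec: MultichannelRecording) -> str:
    """Name channels likely responsible for a rank-deficient design."""
    culprits = []
    sd = rec.data.std(axis=1)
    for i in np.flatnonzero(sd == 0):
        culprits.append(f"{rec.labels[i]} (constant)")
    if (sd > 0).sum() >= 2:
        c = np.corrcoef(rec.data[sd > 0])
        ii, jj = np.where(np.triu(np.abs(c) > 1 - 1e-12, k=1))
        live = [l for l, s in zip(rec.labels, sd) if s > 0]
        for i, j in zip(ii, jj):
            culprits.append(f"{live[i]}~{live[j]} (collinear)")
    return ", ".join(culprits) if culprits else "unidentified"


def _ols(X: np.ndarray, Y: np.ndarray):
    """QR-based least squares with conditioning check."""
    coef, _, rank, sv = linalg.lstsq(X, Y, lapack_driver="gelsd")
    cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
    if rank < X.shape[1] or cond > _COND_LIMIT:
        raise ConditioningError(
            f"lagged design is ill-conditioned (rank {rank}/{X.shape[1]}, "
            f"condition number {cond:.3e})"
        )
    resid = Y - X @ coef
    return coef, resid, cond


def fit(
    rec: MultichannelRecording, p: int, offset: int | None = None
) -> MVARModel:
    """Fit an order-p MVAR model by pooled ordinary least squares.

    For an epoched recording every epoch contributes its own lag-valid
    rows; a continuous recording is one epoch.  The innovation
    covariance uses the small-sample divisor ``rows - n*p - 1``.

    Raises
    ------
    ConditioningError
        If the design is rank-deficient; the message names zero-variance
        or collinear channels where identifiable.
    """
    if p < 1:
        raise ConfigurationError(f"model order must be >= 1, got {p}")
    epochs = rec.epoch_data if rec.epoch_length is not None else rec.data[None]
    X, Y = _lagged_design(epochs, p, offset)
    n_par = X.shape[1]
    if X.shape[0] <= n_par:
        raise ConfigurationError(
            f"{X.shape[0]} regression rows cannot identify {n_par} "
            f"parameters per channel"
        )
    try:
        coef, resid, _ = _ols(X, Y)
    except ConditioningError as err:
        raise ConditioningError(f"{err}; suspect channels: {_diagnose_channels(rec)}")
    n_ch = rec.n_channels
    # coef is (n*p, n): block k rows give A_{k+1}^T
    coeffs = np.stack(
        [coef[k * n_ch : (k + 1) * n_ch].T for k in range(p)], axis=0
    )
    dof = max(X.shape[0] - n_par - 1, 1)
    noise_cov = resid.T @ resid / dof
    noise_cov = (noise_cov + noise_cov.T) / 2
    return MVARModel(
        order=p,
        coeffs=coeffs,
        noise_cov=noise_cov,
        n_samples_used=X.shape[0],
        labels=list(rec.labels),
    )


def fit_epochs(rec: MultichannelRecording, p: int) -> list[MVARModel]:
    """Fit one MVAR model per epoch (non-pooled mode)."""
    if rec.epoch_length is None:
        return [fit(rec, p)]
    out = []
    for e in range(rec.n_epochs):
        single = MultichannelRecording(
            data=rec.epoch_data[e], fs=rec.fs, labels=list(rec.labels)
        )
        out.append(fit(single, p))
    return out


@dataclass
class OrderSelection:
    """Criterion curves over the candidate order range."""

    selected: int
    criterion: str
    orders: list[int]
    sbc: list[float]
    fpe: list[float]


def select_order(
    rec: MultichannelRecording,
    p_min: int = 1,
    p_max: int = 20,
    criterion: str = "SBC",
) -> OrderSelection:
    """Choose the MVAR order minimising SBC or FPE over [p_min, p_max].

    All candidate orders are fitted on the same regression rows (each
    epoch's first ``p_max`` samples serve only as lags) so the criterion
    values are directly comparable.  The full criterion curves are
    returned for audit.

    Raises
    ------
    ConfigurationError
        If p_min > p_max, or the identifiability guard
        ``p_max * n_channels < rows / 10`` fails.
    """
    if p_min < 1 or p_min > p_max:
        raise ConfigurationError(f"invalid order range [{p_min}, {p_max}]")
    crit = criterion.upper()
    if crit not in ("SBC", "FPE"):
        raise ConfigurationError(f"criterion must be SBC or FPE, got {criterion!r}")
    epochs = rec.epoch_data if rec.epoch_length is not None else rec.data[None]
    n_ep, n_ch, spe = epochs.shape
    ne = n_ep * (spe - p_max)
    if ne < 1:
        raise ConfigurationError("epochs shorter than p_max")
    if p_max * n_ch >= ne / 10:
        raise ConfigurationError(
            f"identifiability guard failed: p_max*N = {p_max * n_ch} "
            f">= rows/10 = {ne / 10:.0f}; lower p_max or supply more data"
        )

    orders = list(range(p_min, p_max + 1))
    sbc_vals, fpe_vals = [], []
    X_full, Y = _lagged_design(epochs, p_max, offset=p_max)
    for p in orders:
        X = X_full[:, : n_ch * p]
        try:
            _, resid, _ = _ols(X, Y)
        except ConditioningError as err:
            raise ConditioningError(
                f"order {p}: {err}; suspect channels: {_diagnose_channels(rec)}"
            )
        n_par = n_ch * p
        sign, logdp = np.linalg.slogdet(resid.T @ resid)
        if sign <= 0:
            logdp = -np.inf
        sbc_vals.append(logdp / n_ch - np.log(ne) * (ne - n_par) / ne)
        fpe_vals.append(logdp / n_ch - np.log(ne * (ne - n_par) / (ne + n_par)))

    curve = sbc_vals if crit == "SBC" else fpe_vals
    selected = orders[int(np.argmin(curve))]
    return OrderSelection(
        selected=selected,
        criterion=crit,
        orders=orders,
        sbc=[float(v) for v in sbc_vals],
        fpe=[float(v) for v in fpe_vals],
    )
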