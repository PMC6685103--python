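"""Signal conditioning for multichannel EEG.

The conditioning chain mirrors standard clinical resting-EEG practice:
zero-phase low-pass at 100 Hz, zero-phase band-stop notch around the
50 Hz mains line, and polynomial baseline (drift) removal.  Epochs whose
amplitude exceeds a configurable peak limit are rejected as a simple,
fully documented stand-in for toolbox-based ocular/muscle artifact
removal.  A per-channel signal-to-noise ratio (variance ratio against a
designated noise interval) gates channels before causality analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigurationError, EmptyDataError
from .recording import MultichannelRecording

__all__ = [
    "SNRReport",
    "RejectionLog",
    "condition",
    "reject_artifacts",
    "compute_snr",
    "gate_channels",
]

logger = logging.getLogger(__name__)


def _polynomial_detrend(data: np.ndarray, order: int) -> np.ndarray:
    """Remove a least-squares polynomial of given order from each row."""
    n = data.shape[1]
    # orthonormal polynomial basis on [-1, 1] for numerical stability
    t = np.linspace(-1.0, 1.0, n)
    basis = np.polynomial.legendre.legvander(t, order)
    q, _ = np.linalg.qr(basis)
    return data - (data @ q) @ q.T


def condition(
    rec: MultichannelRecording,
    lowpass_hz: float = 100.0,
    notch_band: tuple[float, float] = (49.0, 51.0),
    baseline_poly_order: int = 3,
) -> MultichannelRecording:
    """Low-pass, notch and baseline-correct a recording, zero-phase.

    Filters are applied forward-backward (``filtfilt``) so that no group
    delay distorts the temporal structure the autoregressive model will
    later estimate.  Low-pass: Butterworth order 4; notch: Butterworth
    order 2 band-stop.  The polynomial baseline of ``baseline_poly_order``
    is removed per channel after filtering.

    Raises
    ------
    ConfigurationError
        If the requested bands are not realisable at the recording's
        sampling rate.
    """
    nyq = rec.fs / 2.0
    if not 0 < lowpass_hz < nyq:
        raise ConfigurationError(
            f"low-pass cutoff {lowpass_hz} Hz outside (0, {nyq}) Hz at fs={rec.fs}"
        )
    lo, hi = notch_band
    if not 0 < lo < hi < nyq:
        raise ConfigurationError(
            f"notch band {notch_band} must lie inside (0, {nyq}) Hz at fs={rec.fs}"
        )
    if baseline_poly_order < 0:
        raise ConfigurationError("baseline polynomial order must be >= 0")

    data = rec.data
    b, a = signal.butter(4, lowpass_hz / nyq, btype="low")
    data = signal.filtfilt(b, a, data, axis=1)
    b, a = signal.butter(2, [lo / nyq, hi / nyq], btype="bandstop")
    data = signal.filtfilt(b, a, data, axis=1)
    data = _polynomial_detrend(data, baseline_poly_order)
    out = rec.copy()
    out.data = data
    return out


@dataclass
class RejectionLog:
    """Which epochs an amplitude-threshold rejection dropped and why."""

    amplitude_limit: float
    dropped: list[int] = field(default_factory=list)
    kept: list[int] = field(default_factory=list)
    peak_per_epoch: list[float] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def reject_artifacts(
    rec: MultichannelRecording, amplitude_limit: float = 100.0
) -> tuple[MultichannelRecording, RejectionLog]:
    """Drop epochs containing any sample beyond ``amplitude_limit`` (µV).

    The recording must be epoched.  A peak-amplitude criterion stands in
    for dedicated ocular/muscle artifact removal: high-amplitude
    transients are the signature of both.

    Raises
    ------
    EmptyDataError
        If every epoch is rejected.
    """
    if amplitude_limit <= 0:
        raise ConfigurationError("amplitude_limit must be positive")
    if rec.epoch_length is None:
        raise ConfigurationError("recording must be epoched before rejection")
    ep = rec.epoch_data  # (n_epochs, n_channels, spe)
    peaks = np.abs(ep).max(axis=(1, 2))
    keep = peaks <= amplitude_limit
    log = RejectionLog(
        amplitude_limit=float(amplitude_limit),
        dropped=[int(i) for i in np.flatnonzero(~keep)],
        kept=[int(i) for i in np.flatnonzero(keep)],
        peak_per_epoch=[float(p) for p in peaks],
    )
    if not keep.any():
        raise EmptyDataError(
            f"all {len(peaks)} epochs exceeded the {amplitude_limit} µV limit"
        )
    if log.dropped:
        logger.info("rejected %d/%d epochs: %s", log.n_dropped, len(peaks), log.dropped)
    return rec.select_epochs(log.kept), log


@dataclass
class SNRReport:
    """Per-channel signal-to-noise ratio as a variance ratio.

    SNR_i = sigma_signal(i)^2 / sigma_noise(i)^2, with the noise standard
    deviation estimated from a designated quiet ("pre") interval.
    """

    labels: list[str]
    per_channel_snr: np.ndarray
    noise_sd_estimate: np.ndarray
    noise_interval: tuple[float, float]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, map(float, self.per_channel_snr)))


def compute_snr(
    rec: MultichannelRecording, noise_interval: tuple[float, float] = (0.0, 1.0)
) -> SNRReport:
    """Estimate per-channel SNR against a designated noise interval.

    The noise variance is the per-channel variance inside
    ``noise_interval`` (seconds from recording start); the signal
    variance is taken over the whole recording.

    Raises
    ------
    ConfigurationError
        If the interval falls outside the recording.
    EmptyDataError
        If a channel's noise interval has zero variance (division guard).
    """
    start_s, end_s = noise_interval
    if not (0 <= start_s < end_s <= rec.duration):
        raise ConfigurationError(
            f"noise interval {noise_interval} s outside recording of "
            f"{rec.duration:.2f} s"
        )
    i0, i1 = int(round(start_s * rec.fs)), int(round(end_s * rec.fs))
    if i1 - i0 < 2:
        raise ConfigurationError("noise interval holds fewer than 2 samples")
    noise_sd = rec.data[:, i0:i1].std(axis=1, ddof=0)
    if np.any(noise_sd == 0):
        dead = [rec.labels[i] for i in np.flatnonzero(noise_sd == 0)]
        raise EmptyDataError(f"zero-variance noise interval on channels {dead}")
    signal_sd = rec.data.std(axis=1, ddof=0)
    snr = (signal_sd / noise_sd) ** 2
    return SNRReport(
        labels=list(rec.labels),
        per_channel_snr=snr,
        noise_sd_estimate=noise_sd,
        noise_interval=(float(start_s), float(end_s)),
    )


def gate_channels(
    rec: MultichannelRecording,
    report: SNRReport,
    min_snr: float = 1.0,
    max_snr: float | None = None,
) -> tuple[MultichannelRecording, list[str]]:
    """Keep channels whose SNR falls in [min_snr, max_snr].

    Returns the gated recording and the list of passing labels; the gate
    settings are logged.  Raises :class:`EmptyDataError` if no channel
    passes.
    """
    snr = report.as_dict()
    passed = [
        l
        for l in rec.labels
        if snr[l] >= min_snr and (max_snr is None or snr[l] <= max_snr)
    ]
    logger.info(
        "SNR gate [%s, %s]: %d/%d channels pass",
        min_snr,
        max_snr if max_snr is not None else "inf",
        len(passed),
        rec.n_channels,
    )
    if not passed:
        raise EmptyDataError("no channel passed the SNR gate")
    return rec.select_channels(passed), passed
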