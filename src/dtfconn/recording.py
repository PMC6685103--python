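"""Multichannel EEG recording container.

The recording is the unit of data flowing through the EEG half of the
pipeline: a channels x samples matrix in microvolts, with a sampling rate
and 10-20-system channel labels.  Epoching is represented by setting
``epoch_length`` (seconds); the data stay stored as a single 2-D matrix of
concatenated equal-length epochs so that filtering and plotting code can
treat it uniformly, while model-fitting code uses :attr:`epoch_data` to
avoid regressing across epoch boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = ["MultichannelRecording"]


@dataclass
class MultichannelRecording:
    """Channels x samples multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Unique per-channel names (10-20 system for scalp EEG).
    epoch_length : float or None
        Epoch duration in seconds once :meth:`epoch` has been applied;
        ``None`` for a continuous recording.
    """

    data: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)
    epoch_length: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigurationError(
                f"data must be 2-D (channels x samples), got shape {self.data.shape}"
            )
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.data.shape[0])]
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ConfigurationError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ConfigurationError("channel labels must be unique")
        if not self.fs > 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if self.epoch_length is not None:
            spe = self.samples_per_epoch
            if spe < 1 or self.n_samples % spe != 0:
                raise ConfigurationError(
                    "data length is not a whole number of epochs"
                )

    # ------------------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.n_samples / self.fs

    @property
    def samples_per_epoch(self) -> int:
        if self.epoch_length is None:
            return self.n_samples
        return int(round(self.epoch_length * self.fs))

    @property
    def n_epochs(self) -> int:
        if self.epoch_length is None:
            return 1
        return self.n_samples // self.samples_per_epoch

    @property
    def epoch_data(self) -> np.ndarray:
        """Data as a 3-D array (n_epochs, n_channels, samples_per_epoch)."""
        spe = self.samples_per_epoch
        n_ep = self.n_samples // spe
        return (
            self.data[:, : n_ep * spe]
            .reshape(self.n_channels, n_ep, spe)
            .transpose(1, 0, 2)
        )

    # ------------------------------------------------------------------
    def epoch(self, length_s: float) -> "MultichannelRecording":
        """Cut into non-overlapping epochs of ``length_s`` seconds.

        Trailing samples that do not fill a whole epoch are dropped.
        """
        spe = int(round(length_s * self.fs))
        if spe < 2:
            raise ConfigurationError(f"epoch of {length_s} s holds <2 samples")
        n_ep = self.n_samples // spe
        if n_ep < 1:
            raise ConfigurationError(
                f"recording of {self.duration:.2f} s shorter than one epoch"
            )
        return replace(
            self, data=self.data[:, : n_ep * spe].copy(), epoch_length=length_s
        )

    def select_epochs(self, indices) -> "MultichannelRecording":
        """Keep only the epochs at ``indices`` (in order)."""
        if self.epoch_length is None:
            raise ConfigurationError("recording is not epoched")
        ep = self.epoch_data[np.asarray(indices, dtype=int)]
        data = ep.transpose(1, 0, 2).reshape(self.n_channels, -1)
        return replace(self, data=data)

    def select_channels(self, labels) -> "MultichannelRecording":
        idx = [self.labels.index(l) for l in labels]
        return replace(self, data=self.data[idx].copy(), labels=list(labels))

    def copy(self) -> "MultichannelRecording":
        return replace(self, data=self.data.copy(), labels=list(self.labels))
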