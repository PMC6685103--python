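"""Global brain connectivity (GBC) maps for resting-state fMRI.

GBC assigns each voxel inside a network mask (e.g. default mode network
or executive control network) the mean Pearson correlation between its
time series and every other in-mask voxel's time series — a voxelwise
"hubness" readout of how strongly each voxel participates in its
network.  Input volumes are assumed preprocessed and mask-aligned; the
only conditioning applied here is a per-voxel linear detrend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigurationError, EmptyMaskError, MaskMismatchError

__all__ = ["GBCMap", "GBCDifference", "gbc_map", "compare_gbc"]

logger = logging.getLogger(__name__)


@dataclass
class GBCMap:
    """Per-voxel mean correlation to the rest of the in-mask voxels.

    ``values`` holds one value per in-mask voxel (flattened C order over
    the mask); NaN marks voxels excluded as zero-variance.
    """

    values: np.ndarray
    mask: np.ndarray
    mask_name: str = "custom"
    n_timepoints: int = 0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.values) != int(self.mask.sum()):
            raise ConfigurationError("one GBC value per in-mask voxel required")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ConfigurationError("GBC values must lie in [-1, 1]")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def to_volume(self, fill=np.nan) -> np.ndarray:
        """Expand to a 3-D array with ``fill`` outside the mask."""
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = self.values
        return vol


def gbc_map(
    volume: np.ndarray,
    mask: np.ndarray,
    min_timepoints: int = 10,
    mask_name: str = "custom",
    detrend: bool = True,
    fisher_z: bool = False,
) -> GBCMap:
    """Compute the GBC map of a 4-D volume inside a binary mask.

    For each in-mask voxel v, GBC(v) is the mean over all *other*
    in-mask voxels u of corr(ts_v, ts_u); the self-correlation is
    excluded.  Zero-variance voxels get NaN and are excluded from every
    other voxel's average (and logged).  With ``fisher_z=True`` the
    correlations are averaged on the arctanh scale and transformed back.

    Raises
    ------
    ConfigurationError
        On shape mismatch or too few timepoints.
    EmptyMaskError
        If fewer than 2 voxels are in the mask.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.ndim != 4:
        raise ConfigurationError(f"volume must be 4-D, got shape {volume.shape}")
    if volume.shape[:3] != mask.shape:
        raise ConfigurationError(
            f"volume spatial shape {volume.shape[:3]} != mask shape {mask.shape}"
        )
    n_t = volume.shape[3]
    if n_t < min_timepoints:
        raise ConfigurationError(
            f"{n_t} timepoints < required minimum {min_timepoints}"
        )
    n_vox = int(mask.sum())
    if n_vox < 2:
        raise EmptyMaskError(f"mask holds {n_vox} voxel(s); need >= 2")

    ts = volume[mask]  # (n_vox, n_t)
    if detrend:
        ts = signal.detrend(ts, axis=1)
    sd = ts.std(axis=1)
    valid = sd > 0
    n_dead = int((~valid).sum())
    if n_dead:
        logger.warning("excluding %d zero-variance voxel(s) from GBC", n_dead)
    if valid.sum() < 2:
        raise EmptyMaskError("fewer than 2 voxels with nonzero variance")

    r = np.corrcoef(ts[valid])
    np.fill_diagonal(r, np.nan)
    if fisher_z:
        with np.errstate(divide="ignore"):
            z = np.arctanh(np.clip(r, -1.0, 1.0))
        vals_valid = np.tanh(np.nanmean(z, axis=1))
    else:
        vals_valid = np.nanmean(r, axis=1)
    values = np.full(n_vox, np.nan)
    values[valid] = vals_valid
    return GBCMap(values=values, mask=mask, mask_name=mask_name, n_timepoints=n_t)


@dataclass
class GBCDifference:
    """Descriptive voxelwise difference between two GBC maps (a - b)."""

    diff: np.ndarray
    mask: np.ndarray
    mean_diff: float
    community_means: dict[int, float] = field(default_factory=dict)

    def to_volume(self, fill=np.nan) -> np.ndarray:
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = self.diff
        return vol


def compare_gbc(
    map_a: GBCMap,
    map_b: GBCMap,
    community_labels: np.ndarray | None = None,
) -> GBCDifference:
    """Voxelwise difference map_a - map_b with summary means.

    Purely descriptive — no inferential statistic is attached.  Optional
    ``community_labels`` (one integer per in-mask voxel) yield
    per-community mean differences.

    Raises
    ------
    MaskMismatchError
        If the two maps do not share an identical mask.
    """
    if map_a.mask.shape != map_b.mask.shape or not np.array_equal(
        map_a.mask, map_b.mask
    ):
        raise MaskMismatchError("GBC maps computed on different masks")
    diff = map_a.values - map_b.values
    comm: dict[int, float] = {}
    if community_labels is not None:
        community_labels = np.asarray(community_labels)
        if len(community_labels) != len(diff):
            raise ConfigurationError(
                "community_labels length must match in-mask voxel count"
            )
        for c in np.unique(community_labels):
            comm[int(c)] = float(np.nanmean(diff[community_labels == c]))
    return GBCDifference(
        diff=diff,
        mask=map_a.mask,
        mean_diff=float(np.nanmean(diff)),
        community_means=comm,
    )
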