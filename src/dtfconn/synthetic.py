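"""Ground-truth-known synthetic data for validating the pipeline.

Two generators:

* a stationary multivariate autoregressive (MVAR) process with a known
  sparse directed-coupling matrix, used to validate model fitting, the
  directed transfer function, and the surrogate significance test;
* a 4-D voxel time-series volume with block-correlated communities
  inside a mask, used to validate the global-brain-connectivity map.

Both are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, StabilityError
from .montage import MONTAGE_32, POSTERIOR_ELECTRODES, coords_for
from .recording import MultichannelRecording

__all__ = [
    "GroundTruthNetwork",
    "SyntheticFMRIVolume",
    "spectral_radius",
    "simulate_mvar",
    "random_stable_network",
    "control_network",
    "attenuate_electrodes",
    "simulate_fmri_blocks",
]


def spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the companion matrix of lag matrices A_1..A_p.

    The MVAR process x(t) = sum_n A_n x(t-n) + e(t) is (asymptotically)
    stationary iff this radius is strictly below 1.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    p, n, _ = coeffs.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class GroundTruthNetwork:
    """A known, stable MVAR generating process.

    Parameters
    ----------
    coupling : ndarray, shape (p, n, n)
        Lag-ordered coefficient matrices A_1..A_p; entry [k, i, j] is the
        influence of channel j at lag k+1 on channel i.
    noise_sd : ndarray, shape (n,)
        Per-channel innovation standard deviation (white, zero-mean,
        mutually uncorrelated).
    labels : list of str, optional
        Channel names.
    """

    coupling: np.ndarray
    noise_sd: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.coupling = np.atleast_3d(np.asarray(self.coupling, dtype=float))
        if self.coupling.ndim != 3 or self.coupling.shape[1] != self.coupling.shape[2]:
            raise ConfigurationError(
                f"coupling must be (p, n, n), got {self.coupling.shape}"
            )
        n = self.coupling.shape[1]
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (n,)
        ).copy()
        if np.any(self.noise_sd <= 0):
            raise ConfigurationError("noise_sd must be positive")
        radius = spectral_radius(self.coupling)
        if radius >= 1:
            raise StabilityError(radius)
        self._radius = radius

    @property
    def n_channels(self) -> int:
        return self.coupling.shape[1]

    @property
    def order(self) -> int:
        return self.coupling.shape[0]

    @property
    def radius(self) -> float:
        """Companion-matrix spectral radius (< 1 by construction)."""
        return self._radius

    @property
    def edge_set(self) -> list[tuple[int, int]]:
        """Ordered (source, target) pairs with nonzero off-diagonal coupling."""
        nz = np.any(self.coupling != 0, axis=0)
        return [
            (j, i)
            for i in range(self.n_channels)
            for j in range(self.n_channels)
            if i != j and nz[i, j]
        ]


def simulate_mvar(
    network: GroundTruthNetwork,
    n_samples: int,
    fs: float = 250.0,
    burn_in: int = 1000,
    seed: int | None = None,
) -> MultichannelRecording:
    """Simulate a stationary multichannel recording from a known network.

    x(t) = sum_{n=1..p} A_n x(t-n) + e(t), with Gaussian i.i.d. innovations.
    The first ``burn_in`` samples are discarded so that the returned
    segment has forgotten the zero initial condition.

    Returns a :class:`MultichannelRecording`; deterministic given ``seed``.
    """
    if n_samples < 1:
        raise ConfigurationError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    p, n = network.order, network.n_channels
    total = n_samples + burn_in
    noise = rng.standard_normal((total, n)) * network.noise_sd
    x = np.zeros((total + p, n))
    A = network.coupling
    for t in range(total):
        acc = noise[t]
        for k in range(p):
            acc = acc + A[k] @ x[t + p - 1 - k]
        x[t + p] = acc
    data = x[p + burn_in :].T
    labels = network.labels or [f"ch{i}" for i in range(n)]
    return MultichannelRecording(data=data, fs=fs, labels=list(labels))


def random_stable_network(
    n_channels: int,
    order: int,
    density: float = 0.2,
    strength: float = 0.9,
    seed: int | None = None,
) -> GroundTruthNetwork:
    """Random sparse MVAR network rescaled to a target spectral radius.

    Off-diagonal couplings appear independently with probability
    ``density``; diagonal (self) terms are always present.  Coefficients
    are drawn N(0, 1) then the whole stack is scaled so the
    companion-matrix spectral radius equals ``strength`` (< 1).
    """
    if not 0 < strength < 1:
        raise ConfigurationError("strength must be in (0, 1)")
    rng = np.random.default_rng(seed)
    coeffs = rng.standard_normal((order, n_channels, n_channels))
    mask = rng.random((n_channels, n_channels)) < density
    np.fill_diagonal(mask, True)
    coeffs *= mask
    radius = spectral_radius(coeffs)
    # scaling A_k by s^k scales every companion eigenvalue by s exactly
    s = strength / radius
    for k in range(order):
        coeffs[k] *= s ** (k + 1)
    return GroundTruthNetwork(coupling=coeffs, noise_sd=np.ones(n_channels))


def control_network(
    labels: list[str] | None = None,
    self_coupling: float = 0.45,
    neighbour_coupling: float = 0.35,
    n_neighbours: int = 3,
    noise_sd: float = 1.0,
    target_radius: float = 0.92,
) -> GroundTruthNetwork:
    """Deterministic healthy-control-like scalp network.

    Each electrode keeps a lag-1 self term and sends lag-1 couplings to
    its ``n_neighbours`` spatially nearest montage neighbours, so nearby
    electrodes exchange inflow the way volume-conducted cortical activity
    does at sensor level.  The coefficient stack is rescaled to the
    requested companion spectral radius.
    """
    labels = list(labels) if labels is not None else list(MONTAGE_32)
    xy = coords_for(labels)
    n = len(labels)
    A = np.zeros((1, n, n))
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    for i in range(n):
        nbrs = np.argsort(d[i])[:n_neighbours]
        A[0, i, nbrs] = neighbour_coupling / n_neighbours
    A[0] += np.eye(n) * self_coupling
    r = spectral_radius(A)
    A *= target_radius / r
    return GroundTruthNetwork(coupling=A, noise_sd=np.full(n, noise_sd), labels=labels)


def attenuate_electrodes(
    network: GroundTruthNetwork,
    electrodes: list[str] | None = None,
    factor: float = 0.2,
    direction: str = "inflow",
) -> GroundTruthNetwork:
    """Patient-like variant: scale couplings of the given electrodes.

    ``direction`` selects which off-diagonal couplings are multiplied by
    ``factor``: ``"inflow"`` scales the electrodes' rows (what they
    receive), ``"outflow"`` their columns (what they send), ``"both"``
    rows and columns.  Self terms are untouched.  Default electrode set
    is the posterior group.

    Row-only attenuation keeps the remaining electrodes' direct inflows
    exactly at their control values, so a downstream comparison has an
    unambiguous ground-truth "affected" set; ``"both"`` also degrades
    the inflow of every electrode that listens to an attenuated one.
    """
    if network.labels is None:
        raise ConfigurationError("network has no electrode labels")
    if direction not in ("inflow", "outflow", "both"):
        raise ConfigurationError(
            f"direction must be inflow, outflow or both, got {direction!r}"
        )
    electrodes = electrodes if electrodes is not None else POSTERIOR_ELECTRODES
    idx = [network.labels.index(e) for e in electrodes if e in network.labels]
    A = network.coupling.copy()
    n = network.n_channels
    off = ~np.eye(n, dtype=bool)
    scale = np.ones((n, n))
    if direction in ("inflow", "both"):
        scale[idx, :] = factor
    if direction in ("outflow", "both"):
        scale[:, idx] = factor
    for k in range(A.shape[0]):
        A[k][off] *= scale[off]
    return GroundTruthNetwork(
        coupling=A, noise_sd=network.noise_sd.copy(), labels=list(network.labels)
    )


# ----------------------------------------------------------------------
# fMRI block-community generator
# ----------------------------------------------------------------------


@dataclass
class SyntheticFMRIVolume:
    """4-D volume with block-correlated voxel communities inside a mask.

    ``community_labels`` holds one integer per in-mask voxel (flattened
    C order over the mask).  Target pairwise Pearson correlations are
    ``within_r`` inside a community and ``between_r`` across communities.
    """

    data: np.ndarray
    mask: np.ndarray
    community_labels: np.ndarray
    within_r: float
    between_r: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape[:3] != self.mask.shape:
            raise ConfigurationError("data and mask spatial shapes differ")
        if len(self.community_labels) != int(self.mask.sum()):
            raise ConfigurationError("one community label per in-mask voxel required")
        # equality (within_r == between_r) is the degenerate single-factor
        # case, permitted so that an all-independent volume can be expressed
        if not (0 <= self.between_r <= self.within_r < 1):
            raise ConfigurationError(
                f"need 0 <= between_r <= within_r < 1, got "
                f"({self.between_r}, {self.within_r})"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def in_mask_timeseries(self) -> np.ndarray:
        """(n_voxels, n_timepoints) matrix of in-mask voxel time series."""
        return self.data[self.mask]


def simulate_fmri_blocks(
    shape: tuple[int, int, int],
    n_timepoints: int,
    n_communities: int = 2,
    within_r: float = 0.6,
    between_r: float = 0.1,
    seed: int | None = None,
    mask: np.ndarray | None = None,
) -> SyntheticFMRIVolume:
    """Simulate a 4-D volume of block-correlated voxel communities.

    Each in-mask voxel v in community k follows

        x_v(t) = sqrt(b) g(t) + sqrt(w - b) c_k(t) + sqrt(1 - w) e_v(t)

    with independent standard-normal global factor g, community factor
    c_k and voxel noise e_v, so that Pearson correlations are w =
    ``within_r`` within a community and b = ``between_r`` across
    communities.  Out-of-mask voxels hold independent noise.  In-mask
    voxels are split into ``n_communities`` near-equal contiguous blocks
    in flattened order.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ConfigurationError(f"shape must be three positive extents, got {shape}")
    if not (within_r >= between_r >= 0):
        raise ConfigurationError("require within_r >= between_r >= 0")
    if within_r >= 1:
        raise ConfigurationError("within_r must be < 1")
    if n_communities < 1:
        raise ConfigurationError("n_communities must be >= 1")

    rng = np.random.default_rng(seed)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ConfigurationError("mask shape differs from requested shape")
    n_vox = int(mask.sum())
    if n_vox < n_communities:
        raise ConfigurationError("fewer in-mask voxels than communities")

    labels = (np.arange(n_vox) * n_communities) // n_vox

    g = rng.standard_normal(n_timepoints)
    c = rng.standard_normal((n_communities, n_timepoints))
    e = rng.standard_normal((n_vox, n_timepoints))
    w, b = float(within_r), float(between_r)
    ts = (
        np.sqrt(b) * g[None, :]
        + np.sqrt(w - b) * c[labels]
        + np.sqrt(1.0 - w) * e
    )

    data = rng.standard_normal(shape + (n_timepoints,))
    data[mask] = ts
    return SyntheticFMRIVolume(
        data=data,
        mask=mask,
        community_labels=labels,
        within_r=w,
        between_r=b,
    )
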