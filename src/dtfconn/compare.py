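"""Electrode-wise comparison of DTF connectivity profiles.

A pruned DTF band matrix is collapsed into one scalar per electrode
(mean significant inflow, outflow, or their average).  Profiles from two
conditions — e.g. a group of healthy controls versus a patient's
per-epoch values, or a patient before versus after treatment — are then
compared electrode by electrode with a two-sample test, and the
electrodes passing the significance level are reported with the
direction of the difference.

Test choice under ``auto`` follows common clinical-EEG practice: use
Student's t when both samples pass a Shapiro-Wilk normality check at
0.05, otherwise Wilcoxon's rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dtf import DTFResult
from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "ElectrodeDTFProfile",
    "ComparisonReport",
    "electrode_profile",
    "mean_profile",
    "compare_profiles",
]

_MODES = ("inflow", "outflow", "total")


@dataclass
class ElectrodeDTFProfile:
    """One scalar band-DTF value per electrode for one observation unit.

    The observation unit can be a subject (pooled fit) or a single epoch
    of a subject, depending on the comparison design.
    """

    values: dict[str, float]
    band: str | None = None
    subject_id: str | None = None
    condition: str | None = None
    mode: str | None = None

    def __post_init__(self):
        if any(v < 0 for v in self.values.values()):
            raise ConfigurationError("electrode DTF values must be >= 0")


def electrode_profile(
    pruned: DTFResult, mode: str = "total", subject_id: str | None = None,
    condition: str | None = None,
) -> ElectrodeDTFProfile:
    """Collapse a pruned band-DTF matrix into per-electrode scalars.

    inflow  : mean of the electrode's row (off-diagonal) — how much
              significant inflow it receives;
    outflow : mean of its column — how much it sends;
    total   : mean of inflow and outflow.

    Pruned (non-significant) links count as 0, so the profile reflects
    only connectivity that survived the surrogate test.
    """
    if mode not in _MODES:
        raise ConfigurationError(f"mode must be one of {_MODES}, got {mode!r}")
    if pruned.band_mean is None:
        raise ConfigurationError("DTFResult lacks a band summary")
    m = pruned.band_mean
    n = pruned.n_channels
    off = ~np.eye(n, dtype=bool)
    inflow = np.array([m[i][off[i]].mean() for i in range(n)])
    outflow = np.array([m[:, j][off[:, j]].mean() for j in range(n)])
    if mode == "inflow":
        vals = inflow
    elif mode == "outflow":
        vals = outflow
    else:
        vals = (inflow + outflow) / 2.0
    labels = pruned.labels or [f"ch{i}" for i in range(n)]
    return ElectrodeDTFProfile(
        values=dict(zip(labels, map(float, vals))),
        band=pruned.band_name,
        subject_id=subject_id,
        condition=condition,
        mode=mode,
    )


def mean_profile(
    profiles: list[ElectrodeDTFProfile], subject_id: str | None = None,
    condition: str | None = None,
) -> ElectrodeDTFProfile:
    """Element-wise mean of per-epoch profiles for one subject.

    When a group of subjects is compared against a single subject's
    per-epoch values, summarising each group subject by the mean of its
    *per-epoch* profiles (rather than by a pooled-fit profile) keeps the
    estimator — and hence its finite-sample bias — identical on both
    sides of the test.
    """
    if not profiles:
        raise InsufficientDataError("no profiles to average")
    labels = list(profiles[0].values)
    for p in profiles:
        if list(p.values) != labels:
            raise ConfigurationError("profiles do not share a common electrode set")
    vals = {
        e: float(np.mean([p.values[e] for p in profiles])) for e in labels
    }
    return ElectrodeDTFProfile(
        values=vals,
        band=profiles[0].band,
        subject_id=subject_id,
        condition=condition,
        mode=profiles[0].mode,
    )


@dataclass
class ComparisonReport:
    """Electrode-wise two-sample comparison result."""

    per_electrode_p: dict[str, float]
    per_electrode_stat: dict[str, float]
    selected_electrodes: list[str]
    direction: dict[str, str]
    test_used: dict[str, str]
    alpha: float
    n_a: int
    n_b: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "electrode": e,
                "statistic": self.per_electrode_stat[e],
                "p": self.per_electrode_p[e],
                "direction": self.direction[e],
                "test": self.test_used[e],
                "selected": e in self.selected_electrodes,
            }
            for e in self.per_electrode_p
        ]
        return pd.DataFrame(rows)


def _choose_test(a: np.ndarray, b: np.ndarray, test: str) -> str:
    if test in ("t", "wilcoxon"):
        return test
    if test != "auto":
        raise ConfigurationError(f"test must be auto, t or wilcoxon, got {test!r}")
    # Shapiro-Wilk requires n >= 3 and non-constant data
    for s in (a, b):
        if np.ptp(s) == 0:
            return "wilcoxon"
        if stats.shapiro(s).pvalue < 0.05:
            return "wilcoxon"
    return "t"


def compare_profiles(
    group_a: list[ElectrodeDTFProfile],
    group_b: list[ElectrodeDTFProfile],
    alpha: float = 0.05,
    test: str = "auto",
    fdr: bool = False,
) -> ComparisonReport:
    """Electrode-wise two-sample comparison of DTF profiles.

    ``group_a`` is the reference sample (e.g. healthy controls, one
    profile per subject); ``group_b`` the comparison sample (e.g. one
    profile per epoch of a single patient, or post-treatment epochs).
    Electrodes with p <= alpha are selected and labelled ``lower`` /
    ``higher`` according to group_b's mean relative to group_a's.

    With ``fdr=True`` Benjamini-Hochberg adjusted p-values are
    thresholded instead (off by default).

    Raises
    ------
    ConfigurationError
        If the profiles do not share a common electrode set.
    InsufficientDataError
        If either side has fewer than 3 observations.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if len(group_a) < 3 or len(group_b) < 3:
        raise InsufficientDataError(
            f"need >= 3 observations per side, got {len(group_a)} vs {len(group_b)}"
        )
    labels = list(group_a[0].values)
    for prof in list(group_a) + list(group_b):
        if list(prof.values) != labels:
            raise ConfigurationError("profiles do not share a common electrode set")

    p_map: dict[str, float] = {}
    stat_map: dict[str, float] = {}
    dir_map: dict[str, str] = {}
    test_map: dict[str, str] = {}
    for e in labels:
        a = np.array([prof.values[e] for prof in group_a])
        b = np.array([prof.values[e] for prof in group_b])
        chosen = _choose_test(a, b, test)
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            stat, p = 0.0, 1.0  # identical constant samples: no evidence
        elif chosen == "t":
            stat, p = stats.ttest_ind(a, b, equal_var=False)
        else:
            stat, p = stats.ranksums(a, b)
        p_map[e] = float(p)
        stat_map[e] = float(stat)
        dir_map[e] = "lower" if b.mean() < a.mean() else "higher"
        test_map[e] = chosen

    if fdr:
        adj = stats.false_discovery_control(
            [p_map[e] for e in labels], method="bh"
        )
        decide = dict(zip(labels, adj))
    else:
        decide = p_map
    selected = [e for e in labels if decide[e] <= alpha]
    return ComparisonReport(
        per_electrode_p=p_map,
        per_electrode_stat=stat_map,
        selected_electrodes=selected,
        direction=dir_map,
        test_used=test_map,
        alpha=float(alpha),
        n_a=len(group_a),
        n_b=len(group_b),
    )
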