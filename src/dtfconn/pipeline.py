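"""End-to-end pipeline orchestration.

Wires the stages together under a single serialisable configuration:
condition -> epoch -> artifact rejection -> SNR report -> order
selection -> pooled MVAR fit -> DTF band summary -> surrogate null ->
link pruning -> per-epoch electrode profiles -> group comparison, and
the fMRI GBC branch.  Every run writes its results plus a provenance
manifest (config, seeds, package/library versions, output checksums) so
any output can be reproduced bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from .compare import (
    ComparisonReport,
    compare_profiles,
    electrode_profile,
    mean_profile,
)
from .dtf import default_freq_grid, dtf
from .errors import ConfigurationError, DTFConnError, EmptyMaskError
from .gbc import compare_gbc, gbc_map
from .io import (
    read_nifti,
    write_band_matrix_csv,
    write_gbc_csv,
    write_gbc_nifti,
    write_nifti,
)
from .mvar import fit, fit_epochs, select_order
from .preprocessing import compute_snr, condition, reject_artifacts
from .recording import MultichannelRecording
from .surrogate import build_null, prune

__all__ = ["PipelineConfig", "run_eeg_pipeline", "run_gbc_pipeline", "process_recording"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable settings of the EEG/fMRI analysis, serialisable to JSON.

    Defaults mirror the reference analysis settings: 100 Hz low-pass,
    49-51 Hz notch, order-3 polynomial baseline, 2-s epochs, +-100 µV
    artifact limit, SBC order selection, 1-45 Hz grid at 0.5 Hz, gamma
    band 30-45 Hz, 1000 shuffles at alpha 0.05.
    """

    lowpass_hz: float = 100.0
    notch_band: tuple[float, float] = (49.0, 51.0)
    baseline_poly_order: int = 3
    epoch_length_s: float = 2.0
    amplitude_limit_uv: float = 100.0
    snr_noise_interval: tuple[float, float] = (0.0, 1.0)
    order_range: tuple[int, int] = (1, 20)
    order_criterion: str = "SBC"
    freq_lo: float = 1.0
    freq_hi: float = 45.0
    freq_step: float = 0.5
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"gamma": (30.0, 45.0)}
    )
    band: str = "gamma"
    include_diagonal: bool = False
    n_shuffles: int = 1000
    alpha: float = 0.05
    comparison_mode: str = "total"
    comparison_test: str = "auto"
    comparison_alpha: float = 0.05
    seed: int = 0

    # -- validation ----------------------------------------------------
    def validate(self, fs: float | None = None) -> None:
        """Fail fast on an inconsistent configuration.

        With ``fs`` given, also checks the filter bands against Nyquist.
        """
        if self.band not in self.bands:
            raise ConfigurationError(
                f"band {self.band!r} not among defined bands {list(self.bands)}"
            )
        lo, hi = self.bands[self.band]
        if not (self.freq_lo <= lo < hi <= self.freq_hi):
            raise ConfigurationError(
                f"band {self.band}=({lo}, {hi}) Hz outside frequency grid "
                f"[{self.freq_lo}, {self.freq_hi}] Hz"
            )
        if not 0 < self.alpha < 1 or not 0 < self.comparison_alpha < 1:
            raise ConfigurationError("alpha values must be in (0, 1)")
        p_min, p_max = self.order_range
        if p_min < 1 or p_min > p_max:
            raise ConfigurationError(f"invalid order range {self.order_range}")
        if self.n_shuffles < 1:
            raise ConfigurationError("n_shuffles must be >= 1")
        if fs is not None:
            nyq = fs / 2
            if not self.lowpass_hz < nyq:
                raise ConfigurationError(
                    f"low-pass {self.lowpass_hz} Hz >= Nyquist {nyq} Hz"
                )
            if not self.notch_band[1] < nyq:
                raise ConfigurationError(
                    f"notch band {self.notch_band} exceeds Nyquist {nyq} Hz"
                )
            if not self.freq_hi < nyq:
                raise ConfigurationError(
                    f"analysis grid top {self.freq_hi} Hz >= Nyquist {nyq} Hz"
                )

    # -- serialisation -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        for key in ("notch_band", "snr_noise_interval", "order_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        return cls(**d)

    def freq_grid(self) -> np.ndarray:
        return default_freq_grid(self.freq_lo, self.freq_hi, self.freq_step)

    def stage_seed(self, *names) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        h = zlib.crc32("/".join(str(n) for n in names).encode())
        return int(
            np.random.SeedSequence([self.seed, h]).generate_state(1)[0] % (2**31)
        )


def _stage(name: str, rec_name: str):
    """Context manager tagging failures with the stage and input name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, DTFConnError):
                raise DTFConnError(
                    f"stage {name!r} failed on recording {rec_name!r}: {exc}"
                ) from exc
            return False

    return _Ctx()


def process_recording(
    rec: MultichannelRecording,
    config: PipelineConfig,
    name: str = "recording",
) -> dict:
    """Run one recording through conditioning, MVAR, DTF and pruning.

    Returns a dict with the conditioned recording, SNR report, order
    selection, pooled model, observed and pruned DTF, significance mask,
    and per-epoch electrode profiles (pooled significance mask applied
    to each epoch's band matrix).
    """
    config.validate(fs=rec.fs)
    freqs = config.freq_grid()
    band = config.bands[config.band]

    with _stage("condition", name):
        cond = condition(
            rec,
            lowpass_hz=config.lowpass_hz,
            notch_band=config.notch_band,
            baseline_poly_order=config.baseline_poly_order,
        )
    with _stage("snr", name):
        snr = compute_snr(cond, noise_interval=config.snr_noise_interval)
    with _stage("epoch", name):
        epoched = cond.epoch(config.epoch_length_s)
    with _stage("reject_artifacts", name):
        clean, rejection = reject_artifacts(epoched, config.amplitude_limit_uv)
    with _stage("select_order", name):
        sel = select_order(
            clean,
            p_min=config.order_range[0],
            p_max=config.order_range[1],
            criterion=config.order_criterion,
        )
    with _stage("fit", name):
        model = fit(clean, sel.selected)
    with _stage("dtf", name):
        observed = dtf(
            model,
            fs=clean.fs,
            freqs=freqs,
            band=band,
            band_name=config.band,
            include_diagonal=config.include_diagonal,
        )
    with _stage("surrogate", name):
        null = build_null(
            clean,
            order=sel.selected,
            band=band,
            freqs=freqs,
            n_shuffles=config.n_shuffles,
            alpha=config.alpha,
            seed=config.stage_seed("surrogate", name),
            band_name=config.band,
            include_diagonal=config.include_diagonal,
        )
        mask, pruned = prune(observed, null)
    with _stage("epoch_profiles", name):
        epoch_profiles = []
        off = ~np.eye(clean.n_channels, dtype=bool)
        for e_idx, e_model in enumerate(fit_epochs(clean, sel.selected)):
            e_dtf = dtf(
                e_model,
                fs=clean.fs,
                freqs=freqs,
                band=band,
                band_name=config.band,
                include_diagonal=config.include_diagonal,
            )
            bm = np.where(mask.keep | ~off, e_dtf.band_mean, 0.0)
            e_pruned = replace(
                e_dtf, band_mean=bm, dtf_mean=float(bm[off].mean())
            )
            epoch_profiles.append(
                electrode_profile(
                    e_pruned,
                    mode=config.comparison_mode,
                    subject_id=f"{name}/epoch{e_idx}",
                )
            )
    profile = electrode_profile(pruned, mode=config.comparison_mode, subject_id=name)

    return {
        "name": name,
        "conditioned": clean,
        "snr": snr,
        "rejection": rejection,
        "order_selection": sel,
        "model": model,
        "observed": observed,
        "null": null,
        "mask": mask,
        "pruned": pruned,
        "profile": profile,
        "epoch_profiles": epoch_profiles,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path, config: PipelineConfig, inputs: list[str]) -> Path:
    import scipy

    files = sorted(
        p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": json.loads(config.to_json()),
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "seed": config.seed,
        "inputs": inputs,
        "versions": {
            "dtfconn": _pkg_version,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
        "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def _write_comparison(report: ComparisonReport, out_dir: Path, stem: str) -> None:
    report.to_frame().to_csv(out_dir / f"{stem}.csv", index=False)
    (out_dir / f"{stem}.json").write_text(
        json.dumps(
            {
                "selected_electrodes": report.selected_electrodes,
                "alpha": report.alpha,
                "n_a": report.n_a,
                "n_b": report.n_b,
                "direction": {
                    e: report.direction[e] for e in report.selected_electrodes
                },
            },
            indent=2,
        )
    )


def run_eeg_pipeline(
    config: PipelineConfig,
    controls: dict[str, MultichannelRecording],
    patient: dict[str, MultichannelRecording] | None = None,
    out_dir: str | Path = "results",
) -> dict:
    """Full EEG branch: per-recording DTF analysis plus group comparisons.

    Parameters
    ----------
    controls : mapping name -> recording
        The reference group (one pooled electrode profile per control).
    patient : mapping condition -> recording, optional
        E.g. ``{"pre": ..., "post": ...}``.  The patient contributes
        per-epoch profiles as the within-subject replicates.  With a
        ``pre`` recording, a controls-vs-pre comparison is emitted; with
        both ``pre`` and ``post``, a pre-vs-post comparison as well.

    Returns the per-recording results plus comparison reports; all
    tables and a provenance manifest are written under ``out_dir``.
    """
    montages = [tuple(r.labels) for r in controls.values()] + [
        tuple(r.labels) for r in (patient or {}).values()
    ]
    if len(set(montages)) > 1:
        raise ConfigurationError("all recordings must share the same montage labels")
    first = next(iter(controls.values()), None)
    if first is None:
        raise ConfigurationError("at least one control recording is required")
    config.validate(fs=first.fs)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, dict] = {}
    for name, rec in controls.items():
        logger.info("processing control %s", name)
        results[name] = process_recording(rec, config, name=name)
    for cond_name, rec in (patient or {}).items():
        name = f"patient_{cond_name}"
        logger.info("processing %s", name)
        results[name] = process_recording(rec, config, name=name)

    for name, res in results.items():
        write_band_matrix_csv(res["pruned"], out_dir / f"{name}_band_matrix.csv")
        import pandas as pd

        pd.DataFrame(
            {
                "electrode": list(res["profile"].values),
                "value": list(res["profile"].values.values()),
            }
        ).to_csv(out_dir / f"{name}_profile.csv", index=False)

    comparisons: dict[str, ComparisonReport] = {}
    # each control is summarised by the mean of its per-epoch profiles so
    # both sides of the group-vs-epochs test share one estimator (and bias)
    control_profiles = [
        mean_profile(results[n]["epoch_profiles"], subject_id=n) for n in controls
    ]
    if patient and "pre" in patient:
        rep = compare_profiles(
            control_profiles,
            results["patient_pre"]["epoch_profiles"],
            alpha=config.comparison_alpha,
            test=config.comparison_test,
        )
        comparisons["controls_vs_pre"] = rep
        _write_comparison(rep, out_dir, "comparison_controls_vs_pre")
    if patient and "pre" in patient and "post" in patient:
        rep = compare_profiles(
            results["patient_pre"]["epoch_profiles"],
            results["patient_post"]["epoch_profiles"],
            alpha=config.comparison_alpha,
            test=config.comparison_test,
        )
        comparisons["pre_vs_post"] = rep
        _write_comparison(rep, out_dir, "comparison_pre_vs_post")

    _write_manifest(out_dir, config, inputs=sorted(results))
    return {"recordings": results, "comparisons": comparisons, "out_dir": out_dir}


def run_gbc_pipeline(
    volumes: dict[str, str | Path],
    mask_path: str | Path,
    out_dir: str | Path = "results_gbc",
    config: PipelineConfig | None = None,
    min_timepoints: int = 10,
    mask_name: str = "custom",
    fisher_z: bool = False,
) -> dict:
    """fMRI branch: GBC map per volume plus pairwise difference maps.

    ``volumes`` maps condition names (e.g. pre/post/control) to 4-D
    NIfTI paths; ``mask_path`` is a 3-D binary NIfTI.  Differences are
    emitted for consecutive name pairs in insertion order.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mask_path = Path(mask_path)
    if not mask_path.exists():
        raise ConfigurationError(f"mask path does not exist: {mask_path}")
    mask_data, affine = read_nifti(mask_path)
    mask = mask_data > 0.5
    if not mask.any():
        raise EmptyMaskError(f"mask {mask_path} contains no voxels")

    maps = {}
    for name, vpath in volumes.items():
        vpath = Path(vpath)
        if not vpath.exists():
            raise ConfigurationError(f"volume path does not exist: {vpath}")
        vol, _ = read_nifti(vpath)
        with _stage("gbc", name):
            maps[name] = gbc_map(
                vol,
                mask,
                min_timepoints=min_timepoints,
                mask_name=mask_name,
                fisher_z=fisher_z,
            )
        write_gbc_nifti(maps[name], out_dir / f"gbc_{name}.nii.gz", affine)
        write_gbc_csv(maps[name], out_dir / f"gbc_{name}.csv")

    diffs = {}
    names = list(maps)
    for a, b in zip(names[1:], names[:-1]):  # later minus earlier
        with _stage("compare_gbc", f"{a}-{b}"):
            d = compare_gbc(maps[a], maps[b])
        diffs[f"{a}_minus_{b}"] = d
        write_nifti(d.to_volume(), out_dir / f"gbc_diff_{a}_minus_{b}.nii.gz", affine)

    _write_manifest(out_dir, config, inputs=sorted(volumes))
    return {"maps": maps, "diffs": diffs, "out_dir": out_dir}
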