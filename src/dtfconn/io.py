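"""Readers and writers for the pipeline's on-disk formats.

EEG recordings travel as EDF (read through MNE; written by a minimal
plain-EDF writer, since writing EDF needs no external dependency) or as
a self-describing CSV whose header line carries the sampling rate.
fMRI volumes and masks travel as NIfTI through nibabel.  DTF and GBC
results export to plain CSV for downstream analysis.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .dtf import DTFResult
from .errors import ConfigurationError
from .gbc import GBCMap
from .recording import MultichannelRecording

__all__ = [
    "write_csv_recording",
    "read_csv_recording",
    "write_edf",
    "read_edf",
    "write_nifti",
    "read_nifti",
    "dtf_long_frame",
    "write_dtf_csv",
    "write_band_matrix_csv",
    "write_gbc_nifti",
    "write_gbc_csv",
]


# ----------------------------------------------------------------------
# CSV recordings: rows = samples, columns = labelled channels, first
# line "# fs=<Hz>" carries the sampling rate.
# ----------------------------------------------------------------------


def write_csv_recording(rec: MultichannelRecording, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        pd.DataFrame(rec.data.T, columns=rec.labels).to_csv(fh, index=False)
    return path


def read_csv_recording(path) -> MultichannelRecording:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise ConfigurationError(
                f"{path}: missing '# fs=<Hz>' header line"
            )
        fs = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    return MultichannelRecording(
        data=df.to_numpy().T, fs=fs, labels=[str(c) for c in df.columns]
    )


# ----------------------------------------------------------------------
# EDF
# ----------------------------------------------------------------------


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: MultichannelRecording, path) -> Path:
    """Write a recording as a plain EDF file (µV, int16 samples).

    Uses 1-second data records, so the sampling rate must be a whole
    number of Hz; trailing samples that do not fill a whole second are
    dropped.  Each channel is scaled to its own physical min/max, giving
    a quantisation step of (max - min) / 65535.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ConfigurationError(
            f"EDF writer needs an integer sampling rate, got {fs}; use CSV"
        )
    spr = int(round(fs))  # samples per 1-s record per signal
    n_rec = rec.n_samples // spr
    if n_rec < 1:
        raise ConfigurationError("recording shorter than one EDF data record (1 s)")
    ns = rec.n_channels
    data = rec.data[:, : n_rec * spr]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin == 0
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    now = datetime(2000, 1, 1)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X X X X", 80),
            _edf_field(now.strftime("%d.%m.%y"), 8),
            _edf_field(now.strftime("%H.%M.%S"), 8),
            _edf_field(256 * (ns + 1), 8),
            _edf_field("", 44),
            _edf_field(n_rec, 8),
            _edf_field(1, 8),
            _edf_field(ns, 4),
        ]
    )
    sig = b"".join(_edf_field(l, 16) for l in rec.labels)
    sig += b"".join(_edf_field("", 80) for _ in range(ns))
    sig += b"".join(_edf_field("uV", 8) for _ in range(ns))
    sig += b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in pmin)
    sig += b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in pmax)
    sig += b"".join(_edf_field(dmin, 8) for _ in range(ns))
    sig += b"".join(_edf_field(dmax, 8) for _ in range(ns))
    sig += b"".join(_edf_field("", 80) for _ in range(ns))
    sig += b"".join(_edf_field(spr, 8) for _ in range(ns))
    sig += b"".join(_edf_field("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # channel-major within the record
    return path


def read_edf(path) -> MultichannelRecording:
    """Read an EDF recording via MNE, returning amplitudes in µV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads EEG in volts
    return MultichannelRecording(
        data=data, fs=float(raw.info["sfreq"]), labels=list(raw.ch_names)
    )


# ----------------------------------------------------------------------
# NIfTI
# ----------------------------------------------------------------------


def write_nifti(data: np.ndarray, path, affine: np.ndarray | None = None) -> Path:
    import nibabel as nib

    path = Path(path)
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))
    return path


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"volume path does not exist: {path}")
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


# ----------------------------------------------------------------------
# Result exports
# ----------------------------------------------------------------------


def dtf_long_frame(res: DTFResult) -> pd.DataFrame:
    """Long-format (source, target, frequency, gamma2) table."""
    labels = res.labels or [f"ch{i}" for i in range(res.n_channels)]
    f_idx, tgt, src = np.meshgrid(
        np.arange(len(res.freqs)),
        np.arange(res.n_channels),
        np.arange(res.n_channels),
        indexing="ij",
    )
    return pd.DataFrame(
        {
            "source": [labels[j] for j in src.ravel()],
            "target": [labels[i] for i in tgt.ravel()],
            "frequency": res.freqs[f_idx.ravel()],
            "gamma2": res.gamma2.ravel(),
        }
    )


def write_dtf_csv(res: DTFResult, path) -> Path:
    path = Path(path)
    dtf_long_frame(res).to_csv(path, index=False)
    return path


def write_band_matrix_csv(res: DTFResult, path) -> Path:
    if res.band_mean is None:
        raise ConfigurationError("DTFResult lacks a band summary")
    labels = res.labels or [f"ch{i}" for i in range(res.n_channels)]
    path = Path(path)
    pd.DataFrame(res.band_mean, index=labels, columns=labels).to_csv(path)
    return path


def write_gbc_nifti(gbc: GBCMap, path, affine: np.ndarray | None = None) -> Path:
    return write_nifti(gbc.to_volume(fill=np.nan), path, affine)


def write_gbc_csv(gbc: GBCMap, path) -> Path:
    path = Path(path)
    i, j, k = np.where(gbc.mask)
    pd.DataFrame(
        {"i": i, "j": j, "k": k, "gbc": gbc.values}
    ).to_csv(path, index=False)
    return path
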