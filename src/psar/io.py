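"""Reading and writing ECG records and analysis artifacts.

Supported signal formats:

* two-column CSV (time in seconds, amplitude in mV), sampling rate inferred
  and checked for uniformity;
* a minimal subset of the WFDB format — a ``.hea`` text header plus a
  ``.dat`` file holding little-endian 16-bit samples (format 16), with
  per-channel gain and baseline applied to recover millivolts.

Artifact writers cover fiducial annotation tables (CSV), trajectories and
density grids (NPZ/CSV) and density metadata (JSON).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EmbeddedTrajectory
from .density import DensityMap
from .fiducials import WAVES, FiducialPoints
from .signal import ECGSignal


class MissingLeadError(KeyError):
    """The requested lead is not present in the record."""


class NonUniformSamplingError(ValueError):
    """The CSV time column is not uniformly spaced."""


def load_signal(path: str | Path, format: str | None = None, lead: str = "I") -> ECGSignal:
    """Load a single-lead ECG in mV.

    ``format`` is ``"csv"`` or ``"wfdb"``; if omitted it is inferred from
    the file suffix (``.csv`` vs ``.hea``/bare record name).
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "wfdb"
    if format == "csv":
        return load_csv(path, lead=lead)
    if format == "wfdb":
        return load_wfdb(path, lead=lead)
    raise ValueError(f"unknown format {format!r}")


def load_csv(path: str | Path, lead: str = "I", rtol: float = 1e-3) -> ECGSignal:
    """Read a two-column (time s, amplitude mV) CSV.

    The sampling rate is recovered from the median time step; any step
    deviating from it by more than ``rtol`` (relative) raises
    :class:`NonUniformSamplingError`.
    """
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time s, amplitude mV)")
    t = df.iloc[:, 0].to_numpy(dtype=np.float64)
    y = df.iloc[:, 1].to_numpy(dtype=np.float64)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0 or np.any(np.abs(dt - step) > rtol * step):
        raise NonUniformSamplingError(f"{path}: time column is not uniformly sampled")
    return ECGSignal(y, fs=1.0 / step, lead=lead, t0=float(t[0]))


def save_csv(sig: ECGSignal, path: str | Path) -> None:
    """Write a signal as a two-column (time s, amplitude mV) CSV."""
    df = pd.DataFrame({"time_s": sig.times, "amplitude_mv": sig.samples})
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------- WFDB ----

_WFDB_FMT = 16  # little-endian int16, one sample per frame


def load_wfdb(path: str | Path, lead: str = "I") -> ECGSignal:
    """Read one channel of a WFDB record (format-16 signals only).

    ``path`` may be the ``.hea`` file or the bare record name.  Gain and
    baseline from the header are applied, yielding mV.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    sig_lines = lines[1 : 1 + n_sig]
    names, gains, baselines, fnames = [], [], [], []
    for ln in sig_lines:
        f = ln.split()
        fnames.append(f[0])
        fmt = int(f[1].split("x")[0].split(":")[0].split("+")[0])
        if fmt != _WFDB_FMT:
            raise ValueError(f"unsupported WFDB signal format {fmt} (only 16)")
        gain_field = f[2] if len(f) > 2 else "200"
        if "(" in gain_field:
            gain_s, base_s = gain_field.split("(")
            baselines.append(int(base_s.rstrip(")").split("/")[0]))
            gains.append(float(gain_s))
        else:
            gains.append(float(gain_field.split("/")[0]))
            baselines.append(0)
        names.append(f[-1])
    if lead not in names:
        raise MissingLeadError(
            f"lead {lead!r} not in record (has {names})"
        )
    ch = names.index(lead)
    dat = hea.parent / fnames[ch]
    raw = np.fromfile(dat, dtype="<i2")
    if n_samples:
        raw = raw[: n_samples * n_sig]
    frames = raw.reshape(-1, n_sig)
    mv = (frames[:, ch].astype(np.float64) - baselines[ch]) / gains[ch]
    return ECGSignal(mv, fs=fs, lead=lead)


def save_wfdb(
    sig: ECGSignal, record_path: str | Path, gain: float = 1000.0
) -> None:
    """Write a single-channel WFDB record (format 16, ``gain`` ADC units/mV)."""
    record_path = Path(record_path)
    record_path.parent.mkdir(parents=True, exist_ok=True)
    name = record_path.name
    adc = np.clip(np.round(sig.samples * gain), -32768, 32767).astype("<i2")
    (record_path.with_suffix(".dat")).write_bytes(adc.tobytes())
    fs_s = f"{sig.fs:g}"
    hea = (
        f"{name} 1 {fs_s} {len(sig)}\n"
        f"{name}.dat 16 {gain:g}(0) 16 0 {int(adc[0])} 0 0 {sig.lead}\n"
    )
    record_path.with_suffix(".hea").write_text(hea)


# ----------------------------------------------------------- artifacts ----


def save_fiducials_csv(fids: FiducialPoints, path: str | Path) -> None:
    """Annotation table: one row per (beat, wave) with sample index and time."""
    rows = []
    for i, beat in enumerate(fids.beats):
        for wave in WAVES:
            idx = beat.get(wave)
            if idx is not None:
                rows.append(
                    {"beat": i, "wave": wave, "sample": idx,
                     "time_s": idx / fids.fs}
                )
    pd.DataFrame(rows, columns=["beat", "wave", "sample", "time_s"]).to_csv(
        path, index=False
    )


def save_trajectory(traj: EmbeddedTrajectory, path: str | Path) -> None:
    """NPZ (x, y, z, cycle_id) or 4-column CSV, by file suffix."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path, points=traj.points, cycle_ids=traj.cycle_ids, mode=traj.mode
        )
    else:
        df = pd.DataFrame(traj.points, columns=["x", "y", "z"])
        df["cycle_id"] = traj.cycle_ids
        df.to_csv(path, index=False, float_format="%.9g")


def save_density_npz(dm: DensityMap, path: str | Path) -> None:
    np.savez_compressed(
        Path(path),
        grid=dm.grid,
        u_range=np.array(dm.u_range),
        v_range=np.array(dm.v_range),
        normalized=dm.normalized,
        n_points_in=dm.n_points_in,
        n_points_clipped=dm.n_points_clipped,
    )


def density_metadata(dm: DensityMap, **extra) -> dict:
    meta = {
        "rows": dm.shape[0],
        "cols": dm.shape[1],
        "u_range": list(dm.u_range),
        "v_range": list(dm.v_range),
        "normalized": dm.normalized,
        "n_points_in": dm.n_points_in,
        "n_points_clipped": dm.n_points_clipped,
        "occupied_bins": dm.occupied_bins(),
    }
    meta.update(extra)
    return meta


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
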