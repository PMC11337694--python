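"""End-to-end run configuration and orchestration.

``RunConfig`` is a validated (pydantic, unknown keys rejected) description
of one analysis run: load -> resample -> denoise/detrend -> fiducials ->
split -> embed -> project -> density -> artifacts.  ``run_pipeline``
executes it and writes a small artifact bundle (density PNG + NPZ, fiducial
CSV, metadata JSON); ``export_dataset`` turns labelled records into an
image-folder tree for any downstream image classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as psar_io
from .core import reconstruct_attractor, split_cycles
from .density import DensityMap, make_density_map, normalize_density, project_points, render_image
from .fiducials import FiducialPoints, detect_r_peaks, refine_fiducials
from .preprocess import preprocess_pipeline
from .signal import ECGSignal

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_FAILURE = 1
EXIT_DEGRADED = 2


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    input: str
    format: str | None = None  # csv | wfdb | None (infer)
    lead: str = "I"
    target_fs: float | None = 500.0
    preprocess: bool = True
    split: str = Field(default="RR", pattern="^(RR|QRS|STPQ)$")
    mode: str = Field(default="circular", pattern="^(circular|truncated)$")
    grid: int = Field(default=224, ge=1)
    u_range: tuple[float, float] | None = None
    v_range: tuple[float, float] | None = None
    normalize: str = Field(default="linear", pattern="^(linear|log)$")
    window_s: float | None = None  # windowing for export; None = whole record
    stride_s: float | None = None
    out_dir: str = "psar_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True)
        )


@dataclass
class PipelineResult:
    """Artifact bundle handle returned by :func:`run_pipeline`."""

    exit_code: int
    density: DensityMap | None
    fiducials: FiducialPoints | None
    n_beats: int
    n_segments: int
    out_dir: Path
    files: dict[str, Path]


def analyze_signal(
    sig: ECGSignal, cfg: RunConfig
) -> tuple[DensityMap | None, FiducialPoints, int]:
    """Core analysis on an in-memory signal; returns (density, fiducials, n_segments)."""
    if cfg.preprocess:
        sig = preprocess_pipeline(sig, target_fs=cfg.target_fs)
    elif cfg.target_fs is not None and not np.isclose(cfg.target_fs, sig.fs):
        from .preprocess import resample_signal

        sig = resample_signal(sig, cfg.target_fs)
    r = detect_r_peaks(sig)
    fids = refine_fiducials(sig, r)
    segments = split_cycles(fids, cfg.split)
    if not segments:
        return None, fids, 0
    traj = reconstruct_attractor(sig, fids, method=cfg.split, mode=cfg.mode)
    if len(traj) == 0:
        return None, fids, len(segments)
    pts = project_points(traj)
    dm = make_density_map(
        pts, rows=cfg.grid, cols=cfg.grid, u_range=cfg.u_range, v_range=cfg.v_range
    )
    return dm, fids, len(segments)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute a configured run and write the artifact bundle.

    Outputs under ``cfg.out_dir``: ``density.png``, ``density.npz``,
    ``fiducials.csv``, ``metadata.json``.  Deterministic for a fixed config
    and input.  Exit code 2 marks a degraded run (no usable segments).
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig = psar_io.load_signal(cfg.input, format=cfg.format, lead=cfg.lead)
    dm, fids, n_seg = analyze_signal(sig, cfg)
    files: dict[str, Path] = {}
    files["fiducials"] = out / "fiducials.csv"
    psar_io.save_fiducials_csv(fids, files["fiducials"])
    meta = {
        "config": cfg.model_dump(),
        "n_beats": len(fids),
        "n_segments": n_seg,
    }
    if dm is None:
        logger.warning("no usable segments; emitting empty bundle")
        files["metadata"] = out / "metadata.json"
        psar_io.save_json(meta, files["metadata"])
        return PipelineResult(EXIT_DEGRADED, None, fids, len(fids), n_seg, out, files)
    dmn = normalize_density(dm, cfg.normalize)
    files["density_png"] = out / "density.png"
    render_image(dmn, files["density_png"])
    files["density_npz"] = out / "density.npz"
    psar_io.save_density_npz(dmn, files["density_npz"])
    files["metadata"] = out / "metadata.json"
    psar_io.save_json(psar_io.density_metadata(dm, **meta), files["metadata"])
    return PipelineResult(EXIT_OK, dmn, fids, len(fids), n_seg, out, files)


def export_dataset(
    records: list[tuple[str, str | None, ECGSignal]],
    cfg: RunConfig,
    out_dir: str | Path,
) -> Path:
    """Write per-class directories of density PNGs plus a manifest CSV.

    ``records`` is a list of (record id, class label, signal).  Records with
    a missing label are skipped with a warning.  If ``cfg.window_s`` is set
    the record is cut into windows of that length (stride ``cfg.stride_s``,
    default equal to the window) and one image is emitted per window.
    """
    import pandas as pd

    if not records:
        raise ValueError("no records to export")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec_id, label, sig in records:
        if label is None:
            logger.warning("record %s has no class label; skipped", rec_id)
            continue
        (out / label).mkdir(exist_ok=True)
        for w_idx, win in enumerate(_windows(sig, cfg.window_s, cfg.stride_s)):
            dm, _, _ = analyze_signal(win, cfg)
            if dm is None:
                logger.warning("record %s window %d produced no density; skipped",
                               rec_id, w_idx)
                continue
            fname = f"{rec_id}_w{w_idx}.png"
            render_image(normalize_density(dm, cfg.normalize), out / label / fname)
            rows.append({
                "record": rec_id, "class": label, "split": cfg.split,
                "window": w_idx, "file": f"{label}/{fname}",
            })
    pd.DataFrame(
        rows, columns=["record", "class", "split", "window", "file"]
    ).to_csv(out / "manifest.csv", index=False)
    return out


def _windows(sig: ECGSignal, window_s: float | None, stride_s: float | None):
    if window_s is None:
        yield sig
        return
    w = int(round(window_s * sig.fs))
    s = int(round((stride_s or window_s) * sig.fs))
    for start in range(0, len(sig) - w + 1, max(1, s)):
        yield ECGSignal(
            sig.samples[start : start + w], fs=sig.fs, lead=sig.lead,
            t0=sig.t0 + start / sig.fs,
        )
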