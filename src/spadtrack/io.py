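"""File formats: TIFF stacks, bit-packed raw, calibration maps, track CSVs.

Frame stacks are stored as standard multipage TIFF with 8- or 16-bit pages
(maximally portable; binary data is stored as 0/1 bytes), with acquisition
metadata (bin count, exposure, frame interval, pixel size) as JSON in the
ImageDescription tag.  A space-efficient bit-packed raw format with a JSON
sidecar is provided for binary stacks.  Calibration is a two-page TIFF
(32-bit-float dark counts, 8-bit usable mask) carrying brightness and PSF
width in the description.  Tracks travel as tidy CSV
(``frame, particle, x_nm, y_nm``); time is always ``frame * frame_interval``
from metadata and never stored redundantly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .likelihood import Calibration, FrameStack, TrackSet
from .psf import PixelGrid, PsfModel

__all__ = [
    "write_stack",
    "read_stack",
    "write_packed_stack",
    "read_packed_stack",
    "write_calibration",
    "read_calibration",
    "tracks_to_dataframe",
    "dataframe_to_tracks",
    "write_tracks",
    "read_tracks",
    "write_ensemble",
    "load_config",
    "dump_config",
]


def _stack_metadata(stack: FrameStack) -> dict:
    return {
        "bin_count": stack.bin_count,
        "exposure_s": stack.exposure,
        "frame_interval_s": stack.frame_interval,
        "pixel_size_nm": stack.grid.pixel_size,
    }


def write_stack(path, stack: FrameStack) -> None:
    """Write a stack as multipage TIFF with JSON metadata in the description."""
    dtype = np.uint8 if stack.bin_count <= 255 else np.uint16
    tifffile.imwrite(
        str(path),
        stack.counts.astype(dtype),
        description=json.dumps(_stack_metadata(stack)),
    )


def read_stack(
    path,
    exposure: float | None = None,
    bin_count: int | None = None,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> FrameStack:
    """Read a multipage TIFF stack; explicit arguments override metadata.

    Raises a descriptive error if a page cannot be decoded or required
    metadata is missing.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        meta = {}
        desc = tif.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        try:
            counts = tif.asarray()
        except Exception as exc:  # corrupt page
            raise IOError(f"failed to decode frames from {path}: {exc}") from exc
    if counts.ndim == 2:
        counts = counts[None]
    exposure = exposure if exposure is not None else meta.get("exposure_s")
    bin_count = bin_count if bin_count is not None else meta.get("bin_count", 1)
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_nm")
    frame_interval = (
        frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    )
    if exposure is None or pixel_size is None:
        raise IOError(
            f"{path} lacks exposure/pixel-size metadata; pass them explicitly"
        )
    grid = PixelGrid(counts.shape[1], counts.shape[2], pixel_size)
    bad = np.nonzero(counts.max(axis=(1, 2)) > bin_count)[0]
    if bad.size:
        raise IOError(
            f"{path}: frame {int(bad[0])} has counts exceeding bin_count={bin_count}"
        )
    return FrameStack(
        counts=counts.astype(np.int64),
        exposure=float(exposure),
        grid=grid,
        bin_count=int(bin_count),
        frame_interval=frame_interval,
    )


def write_packed_stack(path, stack: FrameStack) -> None:
    """Bit-packed raw binary stack with a JSON sidecar (binary data only)."""
    if stack.bin_count != 1:
        raise ValueError("bit-packing requires binary data (bin_count == 1)")
    path = Path(path)
    packed = np.packbits(stack.counts.astype(np.uint8), axis=None)
    packed.tofile(path)
    sidecar = dict(_stack_metadata(stack))
    sidecar.update(
        {
            "shape": list(stack.counts.shape),
            "bit_order": "big",
            "frame_order": "C",
        }
    )
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_packed_stack(path) -> FrameStack:
    """Read a bit-packed raw stack written by :func:`write_packed_stack`."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise IOError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    shape = tuple(meta["shape"])
    n_bits = int(np.prod(shape))
    packed = np.fromfile(path, dtype=np.uint8)
    bits = np.unpackbits(packed, count=n_bits)
    counts = bits.reshape(shape).astype(np.int64)
    grid = PixelGrid(shape[1], shape[2], meta["pixel_size_nm"])
    return FrameStack(
        counts=counts,
        exposure=meta["exposure_s"],
        grid=grid,
        bin_count=1,
        frame_interval=meta.get("frame_interval_s"),
    )


def write_calibration(path, cal: Calibration) -> None:
    """Two-page TIFF: float32 dark counts and uint8 usable mask."""
    desc = json.dumps({"h": cal.h, "psf_sigma_nm": cal.psf.sigma})
    with tifffile.TiffWriter(str(path)) as writer:
        writer.write(cal.dc.astype(np.float32), description=desc)
        writer.write(cal.mask.astype(np.uint8))


def read_calibration(path, pixel_size: float | None = None) -> Calibration:
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        if len(tif.pages) < 2:
            raise IOError(f"{path} is not a two-page calibration file")
        meta = json.loads(tif.pages[0].description)
        dc = tif.pages[0].asarray().astype(float)
        mask = tif.pages[1].asarray().astype(bool)
    return Calibration(
        dc=dc, mask=mask, h=meta["h"], psf=PsfModel(meta["psf_sigma_nm"])
    )


def tracks_to_dataframe(tracks: TrackSet) -> pd.DataFrame:
    """Tidy long-format tracks: one row per (frame, particle)."""
    m, n = tracks.n_particles, tracks.n_frames
    return pd.DataFrame(
        {
            "frame": np.tile(np.arange(n), m),
            "particle": np.repeat(np.arange(m), n),
            "x_nm": tracks.positions[..., 0].reshape(-1),
            "y_nm": tracks.positions[..., 1].reshape(-1),
        }
    )


def dataframe_to_tracks(df: pd.DataFrame) -> TrackSet:
    particles = np.sort(df["particle"].unique())
    n = df["frame"].nunique()
    positions = np.empty((len(particles), n, 2))
    for k, pid in enumerate(particles):
        sub = df[df["particle"] == pid].sort_values("frame")
        if len(sub) != n:
            raise ValueError("all particles must cover the same frames")
        positions[k, :, 0] = sub["x_nm"].to_numpy()
        positions[k, :, 1] = sub["y_nm"].to_numpy()
    return TrackSet(positions)


def write_tracks(path, tracks: TrackSet) -> None:
    tracks_to_dataframe(tracks).to_csv(path, index=False)


def read_tracks(path) -> TrackSet:
    return dataframe_to_tracks(pd.read_csv(path))


def write_ensemble(out_dir, ensemble, config: dict | None = None) -> None:
    """Export a posterior ensemble: MAP tracks, intervals, run metadata.

    Writes ``map_tracks.csv``, ``intervals.csv`` (per frame/particle/axis
    bounds), and ``run.json`` (config echo, acceptance rates, log-posterior
    trace, diagnostics).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    map_sample = ensemble.map_sample
    write_tracks(out_dir / "map_tracks.csv", map_sample.tracks)
    ci = ensemble.credible_intervals(0.95)
    m, n = ci["median"].shape[:2]
    rows = {
        "frame": np.tile(np.arange(n), m),
        "particle": np.repeat(np.arange(m), n),
    }
    for key in ("median", "low", "high"):
        rows[f"x_{key}_nm"] = ci[key][..., 0].reshape(-1)
        rows[f"y_{key}_nm"] = ci[key][..., 1].reshape(-1)
    pd.DataFrame(rows).to_csv(out_dir / "intervals.csv", index=False)
    meta = {
        "config": config or {},
        "acceptance": ensemble.acceptance,
        "diagnostics": {k: float(v) for k, v in ensemble.diagnostics.items()},
        "frame_interval_s": ensemble.frame_interval,
        "map_log_posterior": map_sample.log_posterior,
        "modal_n_particles": int(ensemble.modal_m),
        "msd_samples_nm2": [float(s.msd) for s in ensemble.samples],
        "log_posterior_trace": [float(s.log_posterior) for s in ensemble.samples],
        "n_particles_trace": [int(s.n_particles) for s in ensemble.samples],
    }
    with open(out_dir / "run.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
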