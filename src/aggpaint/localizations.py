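"""Localization tables: I/O, quality filtering, fiducials, drift, rendering.

A localization table is a :class:`pandas.DataFrame` with the canonical
columns ``frame`` (int), ``x_nm``, ``y_nm``, ``precision_nm``, ``signal``
and ``background``, in field-of-view coordinates with the origin at the
upper-left pixel corner, x to the right and y down, nanometre units
throughout. Acquisition geometry travels separately in
:class:`AcquisitionMeta`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

#: Canonical column order of a localization table.
COLUMNS = ["frame", "x_nm", "y_nm", "precision_nm", "signal", "background"]

#: Columns a raw CSV must provide (``background`` is optional, filled with 0).
MANDATORY = ["frame", "x", "y", "precision", "signal"]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Camera and acquisition geometry.

    Parameters
    ----------
    pixel_size_nm : float
        Camera pixel pitch in nm (98.6 for the antibody-PAINT instrument,
        107 for the aptamer-PAINT instrument).
    exposure_ms : float
        Exposure time per frame, ms.
    n_frames : int
        Number of frames in the acquisition.
    fov_px : int
        Field-of-view width/height in pixels (square sensor assumed).
    """

    pixel_size_nm: float = 98.6
    exposure_ms: float = 50.0
    n_frames: int = 4000
    fov_px: int = 512

    def __post_init__(self) -> None:
        if not (self.pixel_size_nm > 0 and self.exposure_ms > 0):
            raise ValueError("pixel_size_nm and exposure_ms must be positive")
        if not (self.n_frames > 0 and self.fov_px >= 1):
            raise ValueError("n_frames must be positive and fov_px >= 1")

    @property
    def fov_nm(self) -> float:
        """Field-of-view side length in nm."""
        return self.fov_px * self.pixel_size_nm

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AcquisitionMeta":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**{k: cfg[k] for k in cfg if k in cls.__dataclass_fields__})


def read_localizations(
    path: str | Path,
    meta: AcquisitionMeta,
    units: str = "px",
    column_map: dict[str, str] | None = None,
    on_malformed: str = "raise",
) -> pd.DataFrame:
    """Read a localization CSV into the canonical table.

    Parameters
    ----------
    path : path
        CSV with a header naming at least ``frame, x, y, precision, signal``
        (a ``background`` column is used when present). Alternative header
        names can be supplied via ``column_map`` (canonical -> file name).
    meta : AcquisitionMeta
        Used to convert pixel coordinates to nm.
    units : {"px", "nm"}
        Units of the x/y columns in the file. ``precision`` is always nm.
    on_malformed : {"raise", "drop"}
        Non-numeric cells either abort with an error naming the offending
        line, or the affected rows are dropped with a logged report.
    """
    if units not in ("px", "nm"):
        raise ValueError(f"units must be 'px' or 'nm', got {units!r}")
    colmap = {c: c for c in MANDATORY + ["background"]}
    if column_map:
        colmap.update(column_map)

    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    if column_map is None and "x_nm" in raw.columns:
        # canonical table written by write_localizations: nm by construction
        colmap.update({"x": "x_nm", "y": "y_nm", "precision": "precision_nm"})
        units = "nm"
    missing = [c for c in MANDATORY if colmap[c] not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing} in {path}")

    used = [colmap[c] for c in MANDATORY]
    if colmap["background"] in raw.columns:
        used.append(colmap["background"])
    num = raw[used].apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1) | raw[used].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
        if on_malformed == "raise":
            raise ValueError(f"non-numeric cell(s) on line(s) {lines} of {path}")
        logger.warning("dropping %d malformed row(s) at line(s) %s", len(lines), lines)
        num = num[~bad]

    scale = meta.pixel_size_nm if units == "px" else 1.0
    out = pd.DataFrame(
        {
            "frame": num[colmap["frame"]].astype(np.int64),
            "x_nm": num[colmap["x"]].to_numpy(float) * scale,
            "y_nm": num[colmap["y"]].to_numpy(float) * scale,
            "precision_nm": num[colmap["precision"]].to_numpy(float),
            "signal": num[colmap["signal"]].to_numpy(float),
        }
    )
    if colmap["background"] in raw.columns:
        out["background"] = num[colmap["background"]].to_numpy(float)
    else:
        out["background"] = 0.0
    return out.reset_index(drop=True)


def write_localizations(locs: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical table to CSV (nm units, full float precision)."""
    locs.to_csv(path, index=False, columns=[c for c in COLUMNS if c in locs])


def filter_localizations(
    locs: pd.DataFrame,
    min_signal: float = 40.0,
    max_precision_nm: float = 25.0,
) -> pd.DataFrame:
    """Quality filter: keep ``signal >= min_signal`` and
    ``precision <= max_precision_nm`` (both boundaries inclusive).

    Row order is preserved; an empty result is not an error.
    """
    if min_signal <= 0 or max_precision_nm <= 0:
        raise ValueError("thresholds must be positive")
    keep = (locs["signal"] >= min_signal) & (locs["precision_nm"] <= max_precision_nm)
    return locs[keep].reset_index(drop=True)


def detect_fiducials(
    locs: pd.DataFrame,
    min_frames: int = 100,
    r_fid_nm: float = 100.0,
    max_gap_frames: int = 0,
) -> list[dict]:
    """Identify fiducial-marker tracks.

    A fiducial is a bright bead that localizes essentially every frame at one
    location. Candidate locations are found by spatial DBSCAN with radius
    ``r_fid_nm`` (chaining accommodates slow stage drift); a candidate is
    accepted when it is present for a run of strictly more than ``min_frames``
    consecutive frames (runs may bridge gaps of up to ``max_gap_frames``).
    Continuous presence is what separates a bead from a densely decorated
    aggregate, which also accumulates >100 distinct frames over a movie but
    only in short binding bursts.

    Returns a list of track dicts with keys ``track_id``, ``member_index``
    (positional indices into ``locs``), ``centroid_nm``, ``span_frames``
    (distinct frames) and ``longest_run`` (frames).
    """
    from sklearn.cluster import DBSCAN

    if len(locs) == 0:
        raise ValueError("empty localization table")
    xy = locs[["x_nm", "y_nm"]].to_numpy(float)
    labels = DBSCAN(eps=r_fid_nm, min_samples=min_frames).fit_predict(xy)

    tracks: list[dict] = []
    for lab in np.unique(labels[labels >= 0]):
        idx = np.flatnonzero(labels == lab)
        frames = np.unique(locs["frame"].to_numpy()[idx])
        gaps = np.diff(frames)
        run_breaks = np.flatnonzero(gaps > max_gap_frames + 1)
        run_edges = np.concatenate(([0], run_breaks + 1, [len(frames)]))
        run_frames = [
            frames[run_edges[i + 1] - 1] - frames[run_edges[i]] + 1
            for i in range(len(run_edges) - 1)
        ]
        longest = int(max(run_frames))
        if longest > min_frames:
            tracks.append(
                {
                    "track_id": len(tracks),
                    "member_index": idx,
                    "centroid_nm": (float(xy[idx, 0].mean()), float(xy[idx, 1].mean())),
                    "span_frames": int(len(frames)),
                    "longest_run": longest,
                }
            )
    return tracks


def remove_fiducials(locs: pd.DataFrame, tracks: list[dict]) -> pd.DataFrame:
    """Drop all localizations belonging to the given fiducial tracks."""
    if not tracks:
        return locs.reset_index(drop=True)
    drop = np.concatenate([t["member_index"] for t in tracks])
    keep = np.ones(len(locs), bool)
    keep[drop] = False
    return locs[keep].reset_index(drop=True)


def _moving_average(a: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; odd-reflection padding keeps linear trends
    unbiased at both edges."""
    if window <= 1:
        return a
    half = min(window // 2, len(a) - 1)
    if half < 1:
        return a
    padded = np.pad(a, half, mode="reflect", reflect_type="odd")
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    return np.convolve(padded, kernel, mode="valid")


def estimate_drift(
    locs: pd.DataFrame,
    tracks: list[dict],
    n_frames: int,
    smooth_window_frames: int = 100,
) -> pd.DataFrame:
    """Estimate per-frame stage drift from fiducial tracks.

    For every track, the per-frame displacement relative to its position at
    its first appearance is computed (averaging multiple localizations in one
    frame); displacements are averaged across tracks, linearly interpolated
    over frames with no fiducial coverage, smoothed with a centered moving
    average, and anchored to (0, 0) at frame 0.

    Returns a DataFrame with columns ``frame``, ``dx_nm``, ``dy_nm`` covering
    frames ``0 .. n_frames-1``.
    """
    if not tracks:
        raise ValueError("no fiducials: cannot estimate drift")
    frames_all = np.arange(n_frames)
    sum_d = np.zeros((n_frames, 2))
    n_obs = np.zeros(n_frames)
    frame_col = locs["frame"].to_numpy()
    xy = locs[["x_nm", "y_nm"]].to_numpy(float)
    for t in tracks:
        idx = t["member_index"]
        df = pd.DataFrame({"frame": frame_col[idx], "x": xy[idx, 0], "y": xy[idx, 1]})
        per_frame = df.groupby("frame")[["x", "y"]].mean()
        ref = per_frame.iloc[0].to_numpy()
        fr = per_frame.index.to_numpy()
        disp = per_frame.to_numpy() - ref
        valid = fr < n_frames
        sum_d[fr[valid]] += disp[valid]
        n_obs[fr[valid]] += 1

    covered = n_obs > 0
    if not covered.any():
        raise ValueError("fiducial tracks cover no frames in range")
    mean_d = np.full((n_frames, 2), np.nan)
    mean_d[covered] = sum_d[covered] / n_obs[covered, None]
    for dim in range(2):
        mean_d[:, dim] = np.interp(
            frames_all, frames_all[covered], mean_d[covered, dim]
        )
        mean_d[:, dim] = _moving_average(mean_d[:, dim], smooth_window_frames)
    mean_d -= mean_d[0]  # (0, 0) at frame 0 by convention
    return pd.DataFrame(
        {"frame": frames_all, "dx_nm": mean_d[:, 0], "dy_nm": mean_d[:, 1]}
    )


def apply_drift(locs: pd.DataFrame, drift: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-frame drift from every localization.

    All frames present in ``locs`` must be covered by the drift table.
    """
    lut = drift.set_index("frame")[["dx_nm", "dy_nm"]]
    frames = locs["frame"].to_numpy()
    missing = np.setdiff1d(np.unique(frames), lut.index.to_numpy())
    if missing.size:
        raise ValueError(f"drift table does not cover frame(s) {missing[:10].tolist()}")
    shift = lut.loc[frames].to_numpy()
    out = locs.copy()
    out["x_nm"] = out["x_nm"].to_numpy() - shift[:, 0]
    out["y_nm"] = out["y_nm"].to_numpy() - shift[:, 1]
    return out


def render_superres(
    locs: pd.DataFrame,
    meta: AcquisitionMeta,
    render_px_nm: float = 13.0,
    path: str | Path | None = None,
) -> np.ndarray:
    """Bin localizations into a super-resolved count raster.

    The grid has pitch ``render_px_nm`` and covers the full field of view;
    the raster is returned (row = y, col = x) and optionally written as a
    single-channel TIFF.
    """
    if render_px_nm <= 0:
        raise ValueError("render_px_nm must be positive")
    n_bins = int(np.ceil(meta.fov_nm / render_px_nm))
    edges = np.arange(n_bins + 1) * render_px_nm
    # clip into the FOV so every localization lands in a bin
    limit = np.nextafter(edges[-1], 0)
    raster, _, _ = np.histogram2d(
        np.clip(locs["y_nm"].to_numpy(float), 0.0, limit),
        np.clip(locs["x_nm"].to_numpy(float), 0.0, limit),
        bins=(edges, edges),
    )
    raster = raster.astype(np.uint32)
    if path is not None:
        tifffile.imwrite(str(path), raster)
    return raster
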