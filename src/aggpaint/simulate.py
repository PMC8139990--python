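"""Synthetic-data generators mirroring the statistical structure of the
experiments.

``simulate_paint`` builds a DNA-PAINT localization stream from planted
linear fibrils: docking sites along each fibril bind imaging strands as a
per-frame Bernoulli process with exponential dwell times, every bound frame
yields one localization scattered isotropically with the photon-limited
precision sigma = sigma_PSF / sqrt(N), non-specific background appears as
single-frame events, fiducial beads localize every frame, and a common
stage drift displaces everything. ``simulate_timecourse`` draws per-cell
aggregate counts from the logistic replication model with lognormal
multiplicative noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .localizations import AcquisitionMeta, COLUMNS
from .kinetics import logistic_fraction


@dataclass
class SceneSpec:
    """Parameters of a synthetic DNA-PAINT acquisition.

    Fibrils may be given explicitly as segments (``fibril_segments``,
    endpoint pairs in nm) or sampled: ``n_fibrils`` straight segments at
    uniform random position/orientation with lognormal lengths of the given
    mean (35 nm, matching sonicated seed fibrils). Docking sites sit every
    ``site_spacing_nm`` along a fibril. Binding events start with
    probability ``binding_rate_per_site`` per frame and persist for an
    exponential dwell (>= 1 frame). Photon counts are lognormal (median
    ``photon_median``, log-sd ``photon_sigma_log``); the localization
    scatter follows sigma_PSF/sqrt(N). Background events are strictly
    single-frame and uniform over the field of view. Fiducials localize in
    every frame with a bright, tight signal and follow the stage drift.
    """

    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    fibril_segments: list[tuple[tuple[float, float], tuple[float, float]]] | None = None
    n_fibrils: int = 20
    fibril_length_mean_nm: float = 35.0
    fibril_length_sigma_log: float = 0.35
    site_spacing_nm: float = 8.0
    binding_rate_per_site: float = 5e-4  # event starts per frame
    dwell_mean_ms: float = 500.0
    photon_median: float = 2000.0
    photon_sigma_log: float = 0.3
    sigma_psf_nm: float = 250.0
    background_rate: float = 0.05  # single-frame events per frame per FOV
    background_signal_median: float = 1000.0
    n_fiducials: int = 3
    fiducial_positions_nm: list[tuple[float, float]] | None = None
    fiducial_photon_median: float = 50000.0
    drift_profile: str = "linear"  # or "random_walk" or "none"
    drift_rate_nm_per_frame: tuple[float, float] = (0.03, 0.02)
    drift_step_nm: float = 0.05  # random-walk step SD

    def __post_init__(self):
        if self.site_spacing_nm <= 0 or self.sigma_psf_nm <= 0:
            raise ValueError("site_spacing_nm and sigma_psf_nm must be positive")
        for r in (self.binding_rate_per_site, self.background_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if self.drift_profile not in ("linear", "random_walk", "none"):
            raise ValueError(f"unknown drift profile {self.drift_profile!r}")


@dataclass
class GroundTruth:
    """Planted truth of a synthetic scene.

    ``fibrils`` has one row per fibril (id, endpoints, true length, site
    count); ``provenance`` aligns row-for-row with the localization table
    and labels each localization ``fibril`` / ``background`` / ``fiducial``
    with its source id; ``drift`` is the true per-frame displacement.
    """

    fibrils: pd.DataFrame
    provenance: pd.DataFrame
    drift: pd.DataFrame


def _sample_fibrils(spec: SceneSpec, rng: np.random.Generator):
    segs = []
    if spec.fibril_segments is not None:
        segs = [np.asarray(s, float) for s in spec.fibril_segments]
    else:
        fov = spec.meta.fov_nm
        m = spec.fibril_length_mean_nm
        slog = spec.fibril_length_sigma_log
        mu = np.log(m) - slog**2 / 2  # lognormal with the requested mean
        for _ in range(spec.n_fibrils):
            for _attempt in range(100):
                length = rng.lognormal(mu, slog)
                theta = rng.uniform(0, np.pi)
                x0, y0 = rng.uniform(0, fov, size=2)
                x1 = x0 + length * np.cos(theta)
                y1 = y0 + length * np.sin(theta)
                if 0 <= x1 <= fov and 0 <= y1 <= fov:
                    segs.append(np.array([[x0, y0], [x1, y1]]))
                    break
            else:
                raise RuntimeError("could not place fibril inside FOV")
    return segs


def simulate_paint(
    spec: SceneSpec, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a localization table and its ground truth.

    Deterministic under a fixed seed. Returns ``(locs, truth)`` with
    ``locs`` in the canonical nm-coordinate table layout.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    meta = spec.meta
    n_frames = meta.n_frames
    dwell_frames_mean = spec.dwell_mean_ms / meta.exposure_ms

    # stage drift
    if spec.drift_profile == "linear":
        rates = np.asarray(spec.drift_rate_nm_per_frame, float)
        drift = np.arange(n_frames)[:, None] * rates[None, :]
    elif spec.drift_profile == "random_walk":
        steps = rng.normal(0, spec.drift_step_nm, size=(n_frames, 2))
        steps[0] = 0
        drift = np.cumsum(steps, axis=0)
    else:
        drift = np.zeros((n_frames, 2))

    segs = _sample_fibrils(spec, rng)
    fib_rows = []
    site_pos = []
    site_fibril = []
    for fid, seg in enumerate(segs):
        (x0, y0), (x1, y1) = seg
        length = float(np.hypot(x1 - x0, y1 - y0))
        # sites cover the whole fibril, endpoints included, at ~site_spacing
        n_sites = max(2, int(np.round(length / spec.site_spacing_nm)) + 1)
        ts = np.linspace(0.0, 1.0, n_sites) if length > 0 else np.zeros(1)
        for t in ts:
            site_pos.append((x0 + t * (x1 - x0), y0 + t * (y1 - y0)))
            site_fibril.append(fid)
        fib_rows.append(
            {
                "fibril_id": fid,
                "x0_nm": x0, "y0_nm": y0, "x1_nm": x1, "y1_nm": y1,
                "length_nm": length,
                "n_sites": n_sites,
            }
        )
    fibrils = pd.DataFrame(
        fib_rows,
        columns=["fibril_id", "x0_nm", "y0_nm", "x1_nm", "y1_nm", "length_nm", "n_sites"],
    )

    frames, xs, ys, photons, kinds, sources = [], [], [], [], [], []

    def emit(frame, x, y, n_ph, kind, src):
        sigma = spec.sigma_psf_nm / np.sqrt(n_ph)
        dx, dy = rng.normal(0, sigma, size=2)
        frames.append(frame)
        xs.append(x + dx + drift[frame, 0])
        ys.append(y + dy + drift[frame, 1])
        photons.append(n_ph)
        kinds.append(kind)
        sources.append(src)

    # fibril docking-site binding bursts
    log_ph_mu = np.log(spec.photon_median)
    for sid, (sx, sy) in enumerate(site_pos):
        starts = np.flatnonzero(rng.random(n_frames) < spec.binding_rate_per_site)
        for f0 in starts:
            dwell = max(1, int(np.ceil(rng.exponential(dwell_frames_mean))))
            for f in range(f0, min(f0 + dwell, n_frames)):
                n_ph = rng.lognormal(log_ph_mu, spec.photon_sigma_log)
                emit(f, sx, sy, n_ph, "fibril", site_fibril[sid])

    # sparse single-frame background
    n_bg = rng.poisson(spec.background_rate * n_frames)
    bg_frames = rng.integers(0, n_frames, size=n_bg)
    bg_xy = rng.uniform(0, meta.fov_nm, size=(n_bg, 2))
    for i in range(n_bg):
        n_ph = rng.lognormal(np.log(spec.background_signal_median), spec.photon_sigma_log)
        emit(int(bg_frames[i]), bg_xy[i, 0], bg_xy[i, 1], n_ph, "background", i)

    # fiducials localize every frame
    if spec.fiducial_positions_nm is not None:
        fid_pos = [tuple(p) for p in spec.fiducial_positions_nm]
    else:
        fid_pos = [
            tuple(rng.uniform(0.1 * meta.fov_nm, 0.9 * meta.fov_nm, size=2))
            for _ in range(spec.n_fiducials)
        ]
    for fi, (fx, fy) in enumerate(fid_pos):
        for f in range(n_frames):
            n_ph = rng.lognormal(np.log(spec.fiducial_photon_median), 0.1)
            emit(f, fx, fy, n_ph, "fiducial", fi)

    photons_arr = np.asarray(photons, float)
    locs = pd.DataFrame(
        {
            "frame": np.asarray(frames, np.int64),
            "x_nm": np.asarray(xs, float),
            "y_nm": np.asarray(ys, float),
            "precision_nm": spec.sigma_psf_nm / np.sqrt(photons_arr),
            "signal": photons_arr,
            "background": np.full(len(frames), 100.0),
        },
        columns=COLUMNS,
    )
    order = np.lexsort((locs["x_nm"].to_numpy(), locs["frame"].to_numpy()))
    locs = locs.iloc[order].reset_index(drop=True)
    provenance = pd.DataFrame(
        {"kind": np.asarray(kinds, object)[order], "source_id": np.asarray(sources)[order]}
    )
    drift_df = pd.DataFrame(
        {"frame": np.arange(n_frames), "dx_nm": drift[:, 0], "dy_nm": drift[:, 1]}
    )
    return locs, GroundTruth(fibrils, provenance, drift_df)


def simulate_timecourse(
    k: float,
    p_max: float,
    f0: float,
    s: float,
    times_h=(0, 4, 24, 48, 72),
    n_cells_per_time: int = 30,
    n_replicates: int = 3,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-cell aggregate counts from the logistic model.

    Each cell's count is ``round(P_max f(t) exp(eps))`` with
    ``eps ~ Normal(0, s)``; cells are split evenly over replicates for
    replicate-pooled summaries. Columns: ``time_h, replicate, cell_id,
    count``. Deterministic under a fixed seed.
    """
    if s < 0:
        raise ValueError("noise scale s must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for t in times_h:
        mean = p_max * logistic_fraction(t, k, f0)
        for cell in range(n_cells_per_time):
            eps = rng.normal(0.0, s) if s > 0 else 0.0
            rows.append(
                {
                    "time_h": float(t),
                    "replicate": cell % n_replicates,
                    "cell_id": cell,
                    "count": int(round(mean * np.exp(eps))),
                }
            )
    return pd.DataFrame(rows, columns=["time_h", "replicate", "cell_id", "count"])
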