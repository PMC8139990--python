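"""Three-stage spatio-temporal clustering of localizations into aggregates.

Stage 1 clusters localizations spatially (DBSCAN, eps 30 nm, min 3) into
docking-strand binding sites; stage 2 clusters each site's localizations
temporally (eps 2500 ms, min 1) into binding bursts and removes single-frame
events, which are characteristic of non-specific binding; stage 3 clusters
burst positions spatially (eps 60 nm, min 2) into aggregate clusters. A
cluster of two or more bursts is read as one super-resolved protein
aggregate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .localizations import AcquisitionMeta

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionParams:
    """The five thresholds of the three clustering stages."""

    eps_site_nm: float = 30.0
    min_locs_per_site: int = 3
    eps_burst_ms: float = 2500.0
    min_frames_per_burst: int = 2  # bursts spanning 1 distinct frame are dropped
    eps_cluster_nm: float = 60.0
    min_bursts_per_cluster: int = 2
    burst_position: str = "mean"  # or "precision" for 1/sigma^2 weighting

    def to_dict(self) -> dict:
        return asdict(self)


def dbscan(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """DBSCAN labels for an (n, d) coordinate array; noise is -1.

    The neighborhood boundary is inclusive (distance <= eps) and a core
    point needs ``min_samples`` neighbors counting itself. Labels are stable
    under permutation of the input up to relabeling.
    """
    from sklearn.cluster import DBSCAN

    if eps <= 0 or min_samples < 1:
        raise ValueError("eps must be positive and min_samples >= 1")
    points = np.asarray(points, float)
    if points.size == 0:
        return np.empty(0, dtype=int)
    if points.ndim == 1:
        points = points[:, None]
    return DBSCAN(eps=eps, min_samples=min_samples).fit_predict(points)


def group_sites(
    locs: pd.DataFrame,
    eps_xy_nm: float = 30.0,
    min_pts: int = 3,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Stage 1: spatial DBSCAN into binding sites.

    Returns ``(sites, labels)`` where ``labels`` assigns every input row a
    site id or -1 (noise, discarded downstream) and ``sites`` summarizes one
    site per row (site_id, n_locs, centroid_x_nm, centroid_y_nm).
    """
    labels = dbscan(locs[["x_nm", "y_nm"]].to_numpy(float), eps_xy_nm, min_pts)
    rows = []
    for lab in np.unique(labels[labels >= 0]):
        m = labels == lab
        rows.append(
            {
                "site_id": int(lab),
                "n_locs": int(m.sum()),
                "centroid_x_nm": float(locs["x_nm"].to_numpy()[m].mean()),
                "centroid_y_nm": float(locs["y_nm"].to_numpy()[m].mean()),
            }
        )
    sites = pd.DataFrame(rows, columns=["site_id", "n_locs", "centroid_x_nm", "centroid_y_nm"])
    return sites, labels


def extract_bursts(
    site_locs: pd.DataFrame,
    meta: AcquisitionMeta,
    eps_t_ms: float = 2500.0,
    site_id: int = 0,
    position: str = "mean",
) -> list[dict]:
    """Stage 2: temporal DBSCAN of one site's localizations into bursts.

    Frame-start times (frame x exposure) are clustered in 1-D with
    ``min_samples = 1``, so every localization joins a burst; bursts whose
    members span exactly one distinct frame are then deleted as non-specific
    single-frame events. Each surviving burst carries a representative
    position (unweighted mean of member x-y, or inverse-variance weighted
    when ``position='precision'``).
    """
    frames = site_locs["frame"].to_numpy()
    t_ms = frames.astype(float) * meta.exposure_ms
    labels = dbscan(t_ms[:, None], eps_t_ms, 1)
    bursts = []
    row_index = site_locs.index.to_numpy()
    for lab in np.unique(labels):
        m = labels == lab
        distinct = np.unique(frames[m])
        if len(distinct) < 2:
            continue
        xy = site_locs[["x_nm", "y_nm"]].to_numpy(float)[m]
        if position == "precision":
            w = 1.0 / site_locs["precision_nm"].to_numpy(float)[m] ** 2
            rep = (xy * w[:, None]).sum(0) / w.sum()
        else:
            rep = xy.mean(0)
        bursts.append(
            {
                "site_id": site_id,
                "x_nm": float(rep[0]),
                "y_nm": float(rep[1]),
                "start_frame": int(distinct.min()),
                "end_frame": int(distinct.max()),
                "n_frames": int(len(distinct)),
                "n_locs": int(m.sum()),
                "loc_index": row_index[m],
            }
        )
    return bursts


def cluster_bursts(
    bursts: pd.DataFrame,
    eps_xy_nm: float = 60.0,
    min_bursts: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Stage 3: spatial DBSCAN of burst positions into aggregate clusters.

    Singleton bursts (DBSCAN noise) are not aggregates. Cluster ids are made
    deterministic by sorting on (earliest member frame, centroid x, y).
    Returns ``(clusters, labels)`` with ``labels`` mapping each burst row to
    a cluster id or -1.
    """
    if len(bursts) == 0:
        empty = pd.DataFrame(
            columns=["cluster_id", "n_bursts", "n_locs", "centroid_x_nm", "centroid_y_nm", "start_frame"]
        )
        return empty, np.empty(0, dtype=int)
    raw = dbscan(bursts[["x_nm", "y_nm"]].to_numpy(float), eps_xy_nm, min_bursts)
    rows = []
    for lab in np.unique(raw[raw >= 0]):
        m = raw == lab
        rows.append(
            {
                "raw_label": int(lab),
                "n_bursts": int(m.sum()),
                "n_locs": int(bursts["n_locs"].to_numpy()[m].sum()),
                "centroid_x_nm": float(bursts["x_nm"].to_numpy()[m].mean()),
                "centroid_y_nm": float(bursts["y_nm"].to_numpy()[m].mean()),
                "start_frame": int(bursts["start_frame"].to_numpy()[m].min()),
            }
        )
    clusters = pd.DataFrame(rows)
    if len(clusters):
        clusters = clusters.sort_values(
            ["start_frame", "centroid_x_nm", "centroid_y_nm"]
        ).reset_index(drop=True)
        remap = {int(r): i for i, r in enumerate(clusters["raw_label"])}
        labels = np.array([remap.get(int(l), -1) for l in raw])
        clusters["cluster_id"] = np.arange(len(clusters))
        clusters = clusters[
            ["cluster_id", "n_bursts", "n_locs", "centroid_x_nm", "centroid_y_nm", "start_frame"]
        ]
    else:
        labels = np.full(len(bursts), -1)
    return clusters, labels


@dataclass
class DetectionResult:
    """Outcome of the three-stage pipeline.

    Attributes
    ----------
    sites, bursts, clusters : DataFrame
        Stage outputs; ``bursts`` carries a ``cluster_id`` column (-1 for
        bursts not belonging to any aggregate).
    params : DetectionParams
    meta : AcquisitionMeta
    """

    sites: pd.DataFrame
    bursts: pd.DataFrame
    clusters: pd.DataFrame
    params: DetectionParams = field(default_factory=DetectionParams)
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    locs: pd.DataFrame | None = None

    @property
    def n_aggregates(self) -> int:
        return len(self.clusters)

    def cluster_burst_positions(self, cluster_id: int) -> np.ndarray:
        """(n, 2) array of burst representative positions of one cluster."""
        m = self.bursts["cluster_id"] == cluster_id
        if not m.any():
            raise KeyError(f"no cluster {cluster_id}")
        return self.bursts.loc[m, ["x_nm", "y_nm"]].to_numpy(float)

    def cluster_localization_positions(self, cluster_id: int) -> np.ndarray:
        """(n, 2) array of member localization positions of one cluster."""
        if self.locs is None or "loc_index" not in self.bursts:
            raise ValueError("localization membership not available")
        m = self.bursts["cluster_id"] == cluster_id
        if not m.any():
            raise KeyError(f"no cluster {cluster_id}")
        idx = np.concatenate(self.bursts.loc[m, "loc_index"].to_list())
        return self.locs.loc[idx, ["x_nm", "y_nm"]].to_numpy(float)


def detect_aggregates(
    locs: pd.DataFrame,
    meta: AcquisitionMeta,
    params: DetectionParams | None = None,
) -> DetectionResult:
    """Run the full three-stage pipeline on a quality-filtered,
    fiducial-free, drift-corrected localization table."""
    params = params or DetectionParams()
    sites, site_labels = group_sites(locs, params.eps_site_nm, params.min_locs_per_site)
    all_bursts: list[dict] = []
    for sid in sites["site_id"]:
        site_locs = locs[site_labels == sid]
        all_bursts.extend(
            extract_bursts(
                site_locs,
                meta,
                params.eps_burst_ms,
                site_id=int(sid),
                position=params.burst_position,
            )
        )
    bursts = pd.DataFrame(
        all_bursts,
        columns=["site_id", "x_nm", "y_nm", "start_frame", "end_frame", "n_frames", "n_locs", "loc_index"],
    )
    clusters, labels = cluster_bursts(
        bursts, params.eps_cluster_nm, params.min_bursts_per_cluster
    )
    bursts = bursts.copy()
    bursts["cluster_id"] = labels if len(bursts) else np.empty(0, dtype=int)
    logger.info(
        "detection: %d localizations -> %d sites -> %d bursts -> %d clusters",
        len(locs), len(sites), len(bursts), len(clusters),
    )
    return DetectionResult(sites, bursts, clusters, params, meta, locs)
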