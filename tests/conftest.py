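import numpy as np
import pytest

from aggpaint import (
    SceneSpec,
    simulate_paint,
    filter_localizations,
    detect_fiducials,
    estimate_drift,
    apply_drift,
    detect_aggregates,
)
from aggpaint.localizations import remove_fiducials


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic acquisition (20 fibrils, fiducials, drift)."""
    spec = SceneSpec()
    locs, truth = simulate_paint(spec, seed=11)
    return spec, locs, truth


@pytest.fixture(scope="session")
def pipeline_result(default_scene):
    """Full pipeline run on the default scene: filter, drift-correct,
    detect. Returns (spec, truth, corrected locs, DetectionResult)."""
    spec, locs, truth = default_scene
    filtered = filter_localizations(locs)
    tracks = detect_fiducials(filtered)
    drift = estimate_drift(filtered, tracks, spec.meta.n_frames)
    clean = apply_drift(remove_fiducials(filtered, tracks), drift)
    result = detect_aggregates(clean, spec.meta)
    return spec, truth, clean, result


def dbscan_reference(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Exhaustive O(n^2) DBSCAN used as an oracle in tests.

    Core points (>= min_samples neighbors within eps, inclusive, counting
    self) are connected when within eps; border points join the first
    reachable cluster; everything else is noise (-1).
    """
    points = np.asarray(points, float)
    n = len(points)
    if n == 0:
        return np.empty(0, dtype=int)
    if points.ndim == 1:
        points = points[:, None]
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    adj = d2 <= eps**2
    core = adj.sum(1) >= min_samples
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for nb in np.flatnonzero(adj[j]):
                if labels[nb] == -1:
                    labels[nb] = cid
                    if core[nb]:
                        stack.append(nb)
        cid += 1
    return labels


def assert_same_clustering(labels_a, labels_b, points, eps):
    """Equality of two DBSCAN labelings up to relabeling.

    Border points may legitimately be claimed by either adjacent cluster
    (assignment-order ambiguity), so the check is: identical noise sets,
    identical partition restricted to points whose cluster membership is
    unambiguous, and every ambiguous point assigned to a cluster that has a
    member within eps of it in both labelings.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    assert (labels_a == -1).tolist() == (labels_b == -1).tolist()
    points = np.asarray(points, float)
    if points.ndim == 1:
        points = points[:, None]
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    adj = d2 <= eps**2
    for lab, other in ((labels_a, labels_b), (labels_b, labels_a)):
        for i in np.flatnonzero(lab != -1):
            same = np.flatnonzero((other == other[i]) & (np.arange(len(lab)) != i))
            assert len(same) == 0 or adj[i, same].any() or (lab == lab[i]).sum() == 1
    # partition agreement on clustered points via pairwise co-membership of
    # points that are mutual core neighbors (unambiguous)
    clustered = (labels_a != -1) & (labels_b != -1)
    ca = labels_a[clustered]
    cb = labels_b[clustered]
    sub_adj = adj[np.ix_(clustered, clustered)]
    same_a = ca[:, None] == ca[None, :]
    same_b = cb[:, None] == cb[None, :]
    # directly-connected pairs must agree on co-membership
    assert (same_a == same_b)[sub_adj].all()
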