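"""Logistic self-replication kinetics of intracellular aggregates.

The aggregate number per cell is modeled as ``P_max * f(t)`` where ``f``
obeys the logistic replication equation

    df/dt = k f (1 - f),    f(t) = f0 exp(kt) / (1 - f0 + f0 exp(kt)),

with replication rate ``k`` (h^-1), initial fraction ``f0`` and carrying
capacity ``P_max``. Fitting is Bayesian with lognormally distributed
multiplicative noise, flat priors on ``k`` and ``P_max``, a ``1/f0`` prior
on the initial fraction and a log-flat prior on the nuisance noise scale
``s``; the posterior is evaluated on a deterministic dense grid, which makes
every fit bit-reproducible.

The effective replication rate decomposes into elongation (growth) and
fragmentation rates through the mean aggregate size mu in monomer
equivalents: ``k = sqrt(k_g * k_f)`` and ``mu = sqrt(k_g / k_f)``, so
``k_g = k * mu`` and ``k_f = k / mu``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


def logistic_fraction(t, k, f0):
    """Logistic fraction f(t) = f0 e^{kt} / (1 - f0 + f0 e^{kt}).

    Overflow-safe for large ``k*t`` (computed through the logistic sigmoid);
    ``t`` in hours, ``k`` in h^-1, ``0 < f0 < 1``, ``k >= 0``. Broadcasts
    over array arguments.
    """
    f0 = np.asarray(f0, float)
    if np.any(f0 <= 0) or np.any(f0 >= 1):
        raise ValueError("f0 must lie strictly between 0 and 1")
    k = np.asarray(k, float)
    if np.any(k < 0):
        raise ValueError("k must be non-negative")
    out = expit(k * np.asarray(t, float) + logit(f0))
    return float(out) if out.ndim == 0 else out


def solve_k_single_timepoint(count, t_h, f0, p_max):
    """Replication rate from one time point with ``f0`` and ``P_max`` fixed.

    Inverts the logistic solution: with ``f = count / P_max``,
    ``k = (1/t) ln[f (1 - f0) / (f0 (1 - f))]``. Used for inhibitor
    experiments with a single measurement, where ``f0`` and ``P_max`` are
    taken from the untreated fit. A count at or below the initial level is
    clamped to ``k = 0`` with a warning; a saturated count (>= P_max) is
    unresolvable and raises.
    """
    if not (0 < f0 < 1) or p_max <= 0 or t_h <= 0:
        raise ValueError("need 0 < f0 < 1, p_max > 0, t_h > 0")
    f = count / p_max
    if f >= 1:
        raise ValueError("count >= P_max: saturation, k unresolvable")
    if f <= f0:
        logger.warning("count/P_max <= f0: no apparent growth, clamping k to 0")
        return 0.0
    return float(np.log(f * (1 - f0) / (f0 * (1 - f))) / t_h)


def decompose_rates(k: float, mu: float) -> tuple[float, float]:
    """Split the replication rate into growth and fragmentation rates.

    ``k_g = k * mu`` and ``k_f = k / mu`` so that ``k = sqrt(k_g k_f)`` and
    ``mu = sqrt(k_g / k_f)`` hold identically. ``k`` in s^-1 (or any unit,
    which both outputs inherit), ``mu`` the mean aggregate size in monomer
    equivalents (>= 1).
    """
    if k <= 0 or mu < 1:
        raise ValueError("need k > 0 and mu >= 1")
    return k * mu, k / mu


def doubling_time(k: float) -> float:
    """Exponential-phase doubling time ln(2)/k, hours for k in h^-1."""
    if k <= 0:
        return float("inf")
    return LN2 / k


@dataclass(frozen=True)
class GridConfig:
    """Posterior grid for the four-parameter fit.

    ``k`` and ``P_max`` grids are linear (flat prior); the ``f0`` grid is
    logarithmic with the 1/f0 prior weight absorbed; the noise-scale grid is
    logarithmic with the log-flat prior absorbed. ``pmax_bounds=None``
    defaults to [max(data), 10 x max(data)].
    """

    k_bounds: tuple[float, float] = (1e-3, 2.0)
    n_k: int = 400
    pmax_bounds: tuple[float, float] | None = None
    n_pmax: int = 100
    f0_bounds: tuple[float, float] = (1e-4, 0.5)
    n_f0: int = 100
    s_bounds: tuple[float, float] = (0.02, 1.5)
    n_s: int = 40

    def coarse(self, factor: int = 2) -> "GridConfig":
        """Same bounds at 1/factor resolution per axis."""
        return GridConfig(
            self.k_bounds, max(self.n_k // factor, 8),
            self.pmax_bounds, max(self.n_pmax // factor, 8),
            self.f0_bounds, max(self.n_f0 // factor, 8),
            self.s_bounds, max(self.n_s // factor, 8),
        )


def _marginal_quantiles(grid, weights, qs):
    w = weights / weights.sum()
    c = np.cumsum(w)
    c = np.concatenate(([0.0], c))
    # cell-edge interpolation on the cumulative mass
    edges = np.concatenate(([grid[0]], 0.5 * (grid[1:] + grid[:-1]), [grid[-1]]))
    return np.interp(qs, c, edges)


@dataclass
class ReplicationResults:
    """Posterior summary of a logistic replication fit.

    Carries the MAP estimate, marginal posteriors, the 95% equal-tail
    credible interval for ``k``, the MAP doubling time, and boundary /
    data-handling flags. Produced by :meth:`ReplicationModel.fit`.
    """

    model: "ReplicationModel"
    config: GridConfig
    k_map: float
    pmax_map: float
    f0_map: float
    s_map: float
    k_ci: tuple[float, float]
    k_median: float
    pmax_median: float
    f0_median: float
    s_median: float
    k_grid: np.ndarray
    k_marginal: np.ndarray
    boundary_flags: list[str] = field(default_factory=list)
    zero_counts_replaced: int = 0

    @property
    def params_map(self) -> dict:
        return {"k": self.k_map, "p_max": self.pmax_map, "f0": self.f0_map, "s": self.s_map}

    @property
    def doubling_time_map(self) -> float:
        return doubling_time(self.k_map)

    @property
    def doubling_time_ci(self) -> tuple[float, float]:
        lo, hi = self.k_ci
        return doubling_time(hi), doubling_time(lo)

    def predict(self, t_h) -> np.ndarray:
        """MAP model curve P_max f(t)."""
        return self.pmax_map * logistic_fraction(t_h, self.k_map, self.f0_map)

    def summary(self) -> str:
        lines = [
            "Logistic replication fit (grid Bayesian, lognormal noise)",
            "=" * 58,
            f"data points          : {len(self.model.t_h)}",
            f"k (replication rate) : {self.k_map:.3g} h^-1  "
            f"[95% CI {self.k_ci[0]:.3g}, {self.k_ci[1]:.3g}]",
            f"doubling time ln2/k  : {self.doubling_time_map:.3g} h  "
            f"[{self.doubling_time_ci[0]:.3g}, {self.doubling_time_ci[1]:.3g}]",
            f"P_max                : {self.pmax_map:.4g}",
            f"f0                   : {self.f0_map:.3g}",
            f"noise scale s        : {self.s_map:.3g}",
        ]
        if self.zero_counts_replaced:
            lines.append(
                f"note: {self.zero_counts_replaced} zero count(s) replaced by 0.5"
            )
        for flagged in self.boundary_flags:
            lines.append(f"warning: {flagged}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "k_map_per_h": self.k_map,
            "k_ci95_per_h": list(self.k_ci),
            "k_median_per_h": self.k_median,
            "p_max_map": self.pmax_map,
            "f0_map": self.f0_map,
            "s_map": self.s_map,
            "doubling_time_h": self.doubling_time_map,
            "doubling_time_ci_h": list(self.doubling_time_ci),
            "boundary_flags": self.boundary_flags,
            "zero_counts_replaced": self.zero_counts_replaced,
        }

    def plot_fit(self, ax=None):
        """Data and MAP curve on one axis (created when ``ax`` is None)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.t_h, self.model.counts, "o", label="median counts")
        tt = np.linspace(0, max(self.model.t_h) * 1.05, 200)
        ax.plot(tt, self.predict(tt), "-", label=f"MAP k={self.k_map:.2g} h$^{{-1}}$")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("aggregates per cell")
        ax.legend()
        return ax


class ReplicationModel:
    """Logistic replication model for aggregate-count time courses.

    Parameters
    ----------
    t_h : array-like
        Time points in hours.
    counts : array-like
        Aggregate counts per cell at each time point — normally the
        per-time-point medians of the per-cell counts. Zero counts are
        replaced by a 0.5 pseudo-count (the lognormal likelihood is
        undefined at zero) and flagged in the results.

    Examples
    --------
    >>> t = [0, 4, 24, 48, 72]
    >>> counts = [2, 4, 40, 70, 75]
    >>> res = ReplicationModel(t, counts).fit()
    >>> print(res.summary())          # doctest: +SKIP
    """

    def __init__(self, t_h, counts):
        t_h = np.asarray(t_h, float)
        counts = np.asarray(counts, float)
        if t_h.shape != counts.shape or t_h.ndim != 1:
            raise ValueError("t_h and counts must be 1-D and the same length")
        if len(t_h) < 3:
            raise ValueError("need at least 3 time points")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if np.all(counts == 0):
            raise ValueError("all counts are zero: nothing to fit")
        self.zero_counts_replaced = int((counts == 0).sum())
        if self.zero_counts_replaced:
            logger.info(
                "replacing %d zero count(s) by 0.5 pseudo-count",
                self.zero_counts_replaced,
            )
            counts = np.where(counts == 0, 0.5, counts)
        order = np.argsort(t_h)
        self.t_h = t_h[order]
        self.counts = counts[order]

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, time_col: str = "time_h", count_col: str = "count"
    ) -> "ReplicationModel":
        """Build from a medians table (one row per time point)."""
        return cls(df[time_col].to_numpy(), df[count_col].to_numpy())

    @classmethod
    def from_cell_counts(
        cls, df: pd.DataFrame, time_col: str = "time_h", count_col: str = "count"
    ) -> "ReplicationModel":
        """Build from per-cell counts, pooling to per-time-point medians."""
        med = df.groupby(time_col)[count_col].median()
        return cls(med.index.to_numpy(), med.to_numpy())

    def fit(self, config: GridConfig | None = None) -> ReplicationResults:
        """Evaluate the posterior on the configured grid.

        The log-likelihood of the medians ``m_i`` is
        ``sum_i N(log m_i | log(P_max f(t_i)), s)``. The noise scale ``s``
        is marginalized numerically. Returns a :class:`ReplicationResults`
        with MAP, marginal medians and the 95% equal-tail interval for
        ``k``; grid-boundary hits of the MAP or the CI are flagged.
        """
        cfg = config or GridConfig()
        pmax_bounds = cfg.pmax_bounds or (self.counts.max(), 10.0 * self.counts.max())
        k = np.linspace(*cfg.k_bounds, cfg.n_k)
        pmax = np.linspace(*pmax_bounds, cfg.n_pmax)
        f0 = np.geomspace(*cfg.f0_bounds, cfg.n_f0)
        s = np.geomspace(*cfg.s_bounds, cfg.n_s)

        logm = np.log(self.counts)
        n = len(logm)
        # sum of squared log-residuals over the (k, f0, pmax) grid
        sse = np.zeros((cfg.n_k, cfg.n_f0, cfg.n_pmax))
        log_pmax = np.log(pmax)
        lf0 = logit(f0)
        for t_i, lm in zip(self.t_h, logm):
            logf = np.log(expit(k[:, None] * t_i + lf0[None, :]))  # (n_k, n_f0)
            resid = lm - (logf[:, :, None] + log_pmax[None, None, :])
            sse += resid**2

        sse_min = sse.min()
        log_peak = (-n * np.log(s) - sse_min / (2 * s**2)).max()
        marg_k = np.zeros(cfg.n_k)
        marg_f0 = np.zeros(cfg.n_f0)
        marg_pmax = np.zeros(cfg.n_pmax)
        marg_s = np.zeros(cfg.n_s)
        for j, s_j in enumerate(s):
            w = np.exp(-n * np.log(s_j) - sse / (2 * s_j**2) - log_peak)
            marg_k += w.sum(axis=(1, 2))
            marg_f0 += w.sum(axis=(0, 2))
            marg_pmax += w.sum(axis=(0, 1))
            marg_s[j] = w.sum()

        ik, if0, ip = np.unravel_index(np.argmin(sse), sse.shape)
        i_s = int(np.argmax(-n * np.log(s) - sse_min / (2 * s**2)))
        k_lo, k_med, k_hi = _marginal_quantiles(k, marg_k, [0.025, 0.5, 0.975])

        flags = []
        total = marg_k.sum()
        if marg_k[0] / total > 0.025 or marg_k[-1] / total > 0.025:
            flags.append("k posterior mass concentrates at a grid boundary")
        if ik in (0, cfg.n_k - 1):
            flags.append("k MAP at grid boundary")
        # the P_max grid starts at max(data) by design, so sitting on the
        # lower edge is expected for saturated time courses; only the upper
        # edge signals an ill-chosen grid
        if ip == cfg.n_pmax - 1:
            flags.append("P_max MAP at upper grid boundary")
        if if0 in (0, cfg.n_f0 - 1):
            flags.append("f0 MAP at grid boundary")
        for flagged in flags:
            logger.warning(flagged)

        return ReplicationResults(
            model=self,
            config=cfg,
            k_map=float(k[ik]),
            pmax_map=float(pmax[ip]),
            f0_map=float(f0[if0]),
            s_map=float(s[i_s]),
            k_ci=(float(k_lo), float(k_hi)),
            k_median=float(k_med),
            pmax_median=float(_marginal_quantiles(pmax, marg_pmax, [0.5])[0]),
            f0_median=float(_marginal_quantiles(f0, marg_f0, [0.5])[0]),
            s_median=float(_marginal_quantiles(s, marg_s, [0.5])[0]),
            k_grid=k,
            k_marginal=marg_k / total,
            boundary_flags=flags,
            zero_counts_replaced=self.zero_counts_replaced,
        )
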