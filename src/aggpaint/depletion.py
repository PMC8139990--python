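"""Immunodepletion mixture deconvolution and density-to-concentration
calibration.

The aggregate population detected in culture medium by the aptamer probe is
a mixture of alpha-synuclein aggregates (A), amyloid-beta aggregates (B) and
a baseline signal (b). Depleting with an anti-amyloid-beta antibody (6E10)
removes B; depleting with an anti-alpha-synuclein antibody (Syn211) removes
A; an isotype IgG control should leave the density unchanged. The mean
densities of the four conditions give three simultaneous equations

    N_medium = A + B + b,   N_6E10 = A + b,   N_syn211 = B + b,

solved exactly for the three components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DepletionObservations:
    """Mean aggregate densities (per µm²) of the four depletion conditions."""

    medium: float
    igg: float
    m6e10: float
    syn211: float

    def __post_init__(self):
        for name in ("medium", "igg", "m6e10", "syn211"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} density must be non-negative")


@dataclass
class MixtureSolution:
    """Solved mixture components and their shares.

    ``alpha_syn + abeta + baseline`` equals the medium-only density exactly
    before clamping; components driven negative by noisy means are clamped
    to zero and flagged. Percentages are over the depletable signal
    (alpha_syn + abeta).
    """

    alpha_syn: float
    abeta: float
    baseline: float
    alpha_syn_percent: float | None
    abeta_percent: float | None
    flags: list[str] = field(default_factory=list)
    raw: tuple[float, float, float] = (0.0, 0.0, 0.0)


def solve_mixture(obs: DepletionObservations, igg_tolerance: float = 0.2) -> MixtureSolution:
    """Solve the three-component depletion equations.

    ``A = N_medium - N_syn211`` (what the anti-alpha-synuclein antibody
    removed), ``B = N_medium - N_6E10``, ``b = N_6E10 + N_syn211 -
    N_medium``. The IgG control acts as a validation gate: a relative
    deviation from the medium-only density beyond ``igg_tolerance`` is
    flagged (it does not enter the equations). Negative components clamp to
    zero with a flag; if nothing is depletable the percentages are None.
    """
    flags: list[str] = []
    if obs.medium > 0 and abs(obs.igg - obs.medium) / obs.medium > igg_tolerance:
        flags.append(
            f"IgG control deviates from medium-only by "
            f"{abs(obs.igg - obs.medium) / obs.medium:.0%} (> {igg_tolerance:.0%})"
        )
        logger.warning(flags[-1])
    A = obs.medium - obs.syn211
    B = obs.medium - obs.m6e10
    b = obs.m6e10 + obs.syn211 - obs.medium
    raw = (A, B, b)
    clamped = {}
    for name, v in zip(("alpha_syn", "abeta", "baseline"), raw):
        if v < 0:
            flags.append(f"{name} component negative ({v:.4g}), clamped to 0")
            v = 0.0
        clamped[name] = v
    depletable = clamped["alpha_syn"] + clamped["abeta"]
    if depletable > 0:
        pa = 100.0 * clamped["alpha_syn"] / depletable
        pb = 100.0 * clamped["abeta"] / depletable
    else:
        flags.append("no depletable signal: percentages undefined")
        pa = pb = None
    return MixtureSolution(
        alpha_syn=clamped["alpha_syn"],
        abeta=clamped["abeta"],
        baseline=clamped["baseline"],
        alpha_syn_percent=pa,
        abeta_percent=pb,
        flags=flags,
        raw=raw,
    )


def removed_counts(obs: DepletionObservations) -> dict:
    """Aggregate numbers removed by each antibody.

    ``removed_by_6E10 = N_medium - N_6E10`` (the amyloid-beta component) and
    ``removed_by_syn211 = N_medium - N_syn211`` (the alpha-synuclein
    component).
    """
    return {
        "removed_by_6e10": obs.medium - obs.m6e10,
        "removed_by_syn211": obs.medium - obs.syn211,
    }


def fold_changes(obs_a: DepletionObservations, obs_b: DepletionObservations) -> dict:
    """Ratios of removed counts between two conditions (b over a)."""
    ra, rb = removed_counts(obs_a), removed_counts(obs_b)
    out = {}
    for key in ra:
        out[key.replace("removed_by", "fold_change")] = (
            rb[key] / ra[key] if ra[key] != 0 else float("inf")
        )
    return out


def calibrate_concentration(
    densities,
    standards: list[tuple[float, float]],
) -> list[dict]:
    """Convert aggregate surface densities to monomer-equivalent nM.

    ``standards`` is a list of ``(known_nM, density)`` pairs from a
    preformed-fibril dilution series; a least-squares line (fitted
    intercept, since the baseline signal is nonzero) maps density to
    concentration. Each query returns the estimate, a standard error from
    the calibration residuals, and range flags — a density below the
    smallest standard is "below the detection range".
    """
    if len(standards) < 2:
        raise ValueError("need at least 2 calibration standards")
    conc = np.asarray([s[0] for s in standards], float)
    dens = np.asarray([s[1] for s in standards], float)
    if np.ptp(dens) == 0:
        raise ValueError("degenerate standards: all densities equal")
    # regress concentration on density (inverse prediction done directly)
    X = np.column_stack([np.ones_like(dens), dens])
    coef, res_ss, *_ = np.linalg.lstsq(X, conc, rcond=None)
    n = len(standards)
    dof = n - 2
    sigma2 = float(res_ss[0] / dof) if dof > 0 and len(res_ss) else 0.0
    XtX_inv = np.linalg.inv(X.T @ X)

    out = []
    lo, hi = dens.min(), dens.max()
    for d in np.atleast_1d(np.asarray(densities, float)):
        x = np.array([1.0, d])
        est = float(x @ coef)
        se = float(np.sqrt(sigma2 * (1.0 + x @ XtX_inv @ x))) if sigma2 else 0.0
        flags = []
        if d < lo:
            flags.append("below the detection range")
        elif d > hi:
            flags.append("above the calibrated range")
        out.append(
            {"density": float(d), "conc_nM": est, "se_nM": se, "flags": flags}
        )
    return out
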