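# aggpaint

Quantitative analysis of seeded protein-aggregate replication from DNA-PAINT
single-molecule localization microscopy data.

When cells take up small α-synuclein fibril seeds, the seeds template the
aggregation of endogenous protein: aggregates grow, fragment, and so
self-replicate in a prion-like fashion. DNA-PAINT imaging resolves the
resulting intracellular (and secreted) aggregates one by one, so their
number and morphology per cell can be followed over time. This package
implements the full quantitative chain from raw localization tables to
replication kinetics, for microscopists and biophysicists who want the
analysis reproducible and testable on synthetic ground truth:

- **Localization handling** — CSV ingest (pixel or nm units), quality
  filtering (signal ≥ 40, precision ≤ 25 nm), fiducial-bead detection,
  drift estimation/correction, 13 nm super-resolved rendering.
- **Aggregate detection** — the three-stage DBSCAN cascade: spatial
  (ε = 30 nm, min 3) into binding sites, temporal (ε = 2500 ms, min 1) into
  bursts with single-frame non-specific events removed, spatial again
  (ε = 60 nm, min 2 bursts) into super-resolved aggregates.
- **Morphometry** — skeleton-based fibril length (rasterize at 1/8 camera
  pixel, 3×3 morphological closing, skeletonize to one pixel, traverse with
  8-connectivity step costs), second-moment eccentricity, per-cell ROI
  counts, and replicate-pooled cohort statistics (median per biological
  replicate; mean ± SD over the medians).
- **Replication kinetics** — Bayesian fit of the logistic self-replication
  model
  `df/dt = k f (1 − f)`, `f(t) = f₀ e^{kt} / (1 − f₀ + f₀ e^{kt})`,
  to per-time-point median counts `P_max·f(t)`, with lognormal noise, flat
  priors on `k` and `P_max`, a `1/f₀` prior, and a marginalized noise
  scale, on a deterministic dense grid (`ReplicationModel.fit()` returns a
  `ReplicationResults` with MAP, marginal 95% credible interval for `k`,
  doubling time, and `summary()`). Rate decomposition into growth and
  fragmentation via `k = √(k_g k_f)`, `µ = √(k_g/k_f)`, and the
  single-time-point inverse solve for inhibitor experiments.
- **Transport budget** — Stokes–Einstein diffusivity `D = k_B T/(6πηR_H)`,
  Smoluchowski encounter flux `J = 4πaDc_∞` onto a spherical cell,
  seed-concentration bookkeeping in monomer equivalents, per-encounter
  seeding probability, and the secreted-aggregate budget.
- **Immunodepletion deconvolution** — exact three-component solve
  (α-synuclein / amyloid-β / baseline) from medium-only and
  antibody-depleted mean densities, plus density→concentration calibration
  against a fibril dilution series.
- **Synthetic data** — generators for DNA-PAINT localization streams from
  planted fibrils (binding-site bursts, photon-limited scatter
  σ = σ_PSF/√N, fiducials, drift, single-frame background) and logistic
  count time courses with lognormal noise, with full ground truth, so every
  stage is testable end to end.

## Worked example

Fit the replication model to a synthetic count time course generated at the
reference kinetics (k = 0.22 h⁻¹, 5 time points, 30 cells × 3 replicates,
lognormal noise s = 0.3):

```python
from aggpaint import ReplicationModel, simulate_timecourse

counts = simulate_timecourse(k=0.22, p_max=80.0, f0=0.025, s=0.3, seed=0)
res = ReplicationModel.from_cell_counts(counts).fit()
print(res.summary())
```

```
Logistic replication fit (grid Bayesian, lognormal noise)
==========================================================
data points          : 5
k (replication rate) : 0.216 h^-1  [95% CI 0.193, 0.279]
doubling time ln2/k  : 3.2 h  [2.48, 3.58]
P_max                : 86.5
f0                   : 0.0246
noise scale s        : 0.0348
```

The MAP replication rate (0.216 h⁻¹) recovers the generating rate within
2%, and the 95% credible interval covers it; the doubling time is
ln 2 / k. The diffusion-encounter chain for extracellular seeds:

```python
from aggpaint import TransportParams, seeding_chain

chain = seeding_chain(TransportParams(), fraction_seeded=0.125)
```

returns `D = 4.8e-12 m²/s` for a 50 nm seed in culture medium at 37 °C, an
encounter flux of ~2.2e3 seeds/s onto a 10 µm cell at 6 nM, ~3.2e7
encounters over a 4 h exposure, and a per-encounter seeding probability of
~4e-9 given that 12.5% of cells end up seeded — i.e. seeding is an
extremely rare outcome of a seed–cell encounter.

A command-line interface wraps the pipeline
(`aggpaint simulate | drift-correct | detect | morphology |
fit-replication | fit-inhibitor | seeding-prob | immunodeplete | calibrate |
render`); every subcommand writes a JSON manifest with parameter echoes and
input digests alongside its outputs.

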