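# erkpulse

Analysis of pulsatile ERK activity in single cells from FRET-biosensor time
series, and of the spatial organization of pulsing cells in tissue.

Epidermal stem cells show transient pulses of ERK (MAPK) activity whose
frequency, rather than mean level, tracks proliferative state: pulses are
stochastic events with exponentially distributed interpulse intervals
(mean ≈ 1.5 h, pulse duration ≈ 0.25 h), they shut down as cells commit to
differentiation (Involucrin-reporter onset), and low-pulsing cells form
~50 μm spatial clusters in the basal layer. `erkpulse` implements the
quantitative machinery for those observations as a tested, reusable
pipeline:

- **Trace ingestion** — tracked single-cell tables (`cell_id, frame,
  time_h, x_um, y_um, cfp, fret[, reporter]`), ERK activity as the
  FRET/CFP ratio, >90-min trace filter.
- **Pulse detection** — pulses as prominent local peaks; amplitude =
  prominence, duration = width at half prominence, frequency = count/span;
  exponential interval fit (rate = 1/mean) with a KS goodness-of-fit check;
  pulse-class gate at 1.5 pulses/h and basal gate at 1.2 FRET/CFP.
- **Variance metrics** — instantaneous (cross-population) variance and
  per-cell moving variance in overlapping 50-min windows, `s²` with
  denominator n−1; the time-averaged moving variance is the per-cell
  pulse-level score.
- **Phase diagrams** — per-cell trajectories in the (reporter moving mean,
  ERK moving variance) plane, binned into a vector field of mean
  displacements; arrows rescaled by the global axis maxima
  (x′ = x/max Inv, y′ = y/max Var) and converted to signed transition
  probabilities r_x = x′/(|x′|+|y′|), r_y = y′/(|x′|+|y′|), normalized so
  |r_x| + |r_y| = 1.
- **Spatial clustering** — radial distribution function
  g(r) = N(r, Δr)/N_ref(r, Δr) inside a field of interest built from the
  observed cells, with a 50-realization Monte-Carlo CSR envelope;
  clustered/dispersed for one population, grouped/segregated for the
  cross-RDF between high- and low-pulsing cells.
- **Synthetic data** — generators for pulse trains (exponential gaps,
  raised-cosine pulses, coupled reporter onset) and marked point patterns
  (CSR / Thomas clusters), so every stage is testable without external
  data.

See `docs/methods.md` for the models, defaults, and numerical choices.

## Worked example

```python
import numpy as np
from erkpulse import (SimConfig, simulate_cohort, detect_pulses,
                      fit_exponential, moving_variance, pulse_level_score)

# 60 cells, 24 h at 5-min sampling, mean interpulse interval 1.52 h
cohort = simulate_cohort([SimConfig(seed=20240101, label="pulsing")], 60)

pulses = [detect_pulses(tr) for tr in cohort]
freqs = [ps.frequency_per_h for ps in pulses]
gaps = np.concatenate([ps.intervals_h for ps in pulses])
fit = fit_exponential(gaps)
levels = [pulse_level_score(moving_variance(tr)) for tr in cohort]

print(f"mean frequency {np.mean(freqs):.2f} pulses/h")
print(f"mean detected interval {fit.mean_interval_h:.2f} h (n={fit.n})")
print(f"median pulse level {np.median(levels):.5f} ratio^2")
```

prints

```
mean frequency 0.56 pulses/h
mean detected interval 1.62 h (n=748)
median pulse level 0.00371 ratio^2
```

The detected frequency sits below the generator rate (0.66/h) and the mean
detected interval above the generated 1.52 h because pulses closer than the
~10-min resolution limit merge into one peak — the censoring analyzed in
`docs/methods.md`. The pulse level for a pulse-free control cohort is an
order of magnitude smaller (0.00040; `analysis/03_variance_metrics.py`).

The numbered scripts under `analysis/` run the full narrative — simulate
cohorts, pulse statistics, variance metrics, phase diagram, spatial
clustering — writing small summary tables to `results/` and bulky
simulated track tables to `scratch/`:

```bash
cd analysis
python 01_simulate_cohorts.py && python 02_pulse_statistics.py
python 03_variance_metrics.py && python 04_phase_diagram.py
python 05_spatial_clustering.py
```

A `erkpulse` command-line interface wraps the same functions
(`erkpulse simulate traces`, `ingest`, `detect`, `variance`, `phase`,
`rdf`, `run`); `erkpulse run --config cfg.json --outdir out/` executes an
end-to-end pipeline and writes a checksummed manifest.

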