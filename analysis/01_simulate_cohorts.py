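"""Simulate the synthetic study cohorts used throughout the analysis.

Generates three cohorts of single-cell ERK traces (5-min sampling, 24 h):
 * pulsing     — stochastic pulses at the observed mean interpulse interval
                 of 1.52 h (0.25 h raised-cosine pulses on a 1.1 basal ratio)
 * control     — pulse-free traces with measurement noise only, emulating a
                 non-responsive biosensor control
 * differentiating — pulses shut down at a per-cell random time while the
                 differentiation reporter rises

Writes track tables under scratch/sim/ and prints cohort-level summaries.
"""

import numpy as np

from erkpulse.simulate import SimConfig, simulate_cohort
from erkpulse.traces import traces_to_table, write_tracks
from _common import RESULTS, SCRATCH, SEED

N_PER_COHORT = 60


def main() -> None:
    rng = np.random.default_rng(SEED)
    pulsing = simulate_cohort([SimConfig(seed=SEED, label="pulsing")], N_PER_COHORT)
    control = simulate_cohort(
        [SimConfig(seed=SEED + 1, pulse_rate_per_h=0.0, label="control")], N_PER_COHORT
    )
    diff_cfgs = [
        SimConfig(
            seed=int(rng.integers(2**31)),
            reporter_onset_model="coupled_to_pulse_shutdown",
            shutdown_time_h=float(rng.uniform(4.0, 20.0)),
            label=f"differentiating_{i}",
        )
        for i in range(N_PER_COHORT)
    ]
    differentiating = simulate_cohort(diff_cfgs, 1)

    for name, cohort in [
        ("pulsing", pulsing),
        ("control", control),
        ("differentiating", differentiating),
    ]:
        path = SCRATCH / f"traces_{name}.csv"
        write_tracks(traces_to_table(cohort), path)
        ratios = np.concatenate([t.ratio for t in cohort])
        print(
            f"{name}: {len(cohort)} traces x {len(cohort[0])} samples -> {path.name}; "
            f"ratio mean {ratios.mean():.3f}, sd {ratios.std():.3f}"
        )


if __name__ == "__main__":
    main()
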