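"""Functional tomogram of a multi-source phantom recording.

Plants 10 brain and 10 non-brain dipoles with unique frequencies, builds
the summed MEG recording, decomposes it, localizes every elementary
oscillation, and scores the recovered positions against the ground truth.
"""

import numpy as np

import megtomo as mt
from megtomo.simulate import DipolePlan

spec = mt.PhantomSpec(n_sensors=128)
sensors, annotated, native = mt.make_phantom(spec)
grid = spec.grid(edge=0.01)
trials = mt.build_trial_patterns(
    grid, sensors, l_max=12, center=spec.head_center,
    max_source_radius=spec.head_radius,
)
brain, nonbrain = mt.remove_overlap([
    mt.resample_mask(native["brain"], grid),
    mt.resample_mask(native["nonbrain"], grid),
])

T, fs = 60.0, 600.0
plan_b = mt.plan_dipoles(10, brain, duration=T, seed=1, trials=trials)
plan_nb = mt.plan_dipoles(10, nonbrain, duration=T, seed=2, trials=trials,
                          exclude_freq_indices=plan_b.freq_indices)
plan = DipolePlan(
    positions=np.concatenate([plan_b.positions, plan_nb.positions]),
    directions=np.concatenate([plan_b.directions, plan_nb.directions]),
    amplitudes=np.concatenate([plan_b.amplitudes, plan_nb.amplitudes]),
    frequencies=np.concatenate([plan_b.frequencies, plan_nb.frequencies]),
    phases=np.concatenate([plan_b.phases, plan_nb.phases]),
    duration=T,
    freq_indices=np.concatenate([plan_b.freq_indices, plan_nb.freq_indices]),
    cells=np.concatenate([plan_b.cells, plan_nb.cells]),
    direction_indices=np.concatenate([plan_b.direction_indices,
                                      plan_nb.direction_indices]),
)
rec = mt.simulate_meg(plan, sensors, fs, center=spec.head_center)
print(f"recording: {rec.n_channels} channels x {rec.n_samples} samples "
      f"({rec.duration:.0f} s at {rec.sampling_rate:.0f} Hz)")

decomp = mt.compute_spectrum(rec, nu_max=18.0)
oscillations = mt.extract_all_oscillations(decomp, power_floor=1e-12)
tomo, matches = mt.build_tomogram(oscillations, trials)
print(f"{len(oscillations)} oscillations localized; "
      f"{np.count_nonzero(tomo.volume)} occupied cells; "
      f"total energy {tomo.total_energy:.3e} T^2")

score = mt.score_recovery(matches, plan, trials)
print(f"cell accuracy {score['cell_accuracy']:.0%}, "
      f"cell+direction accuracy {score['exact_accuracy']:.0%}, "
      f"mean displacement {score['mean_cell_displacement']:.2f} cells")
# Noiseless on-grid sources recover exactly: 100% / 100% / 0.00.
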