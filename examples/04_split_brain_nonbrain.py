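"""Brain / non-brain splitting of a phantom MEG and its power statistics.

Runs the full pipeline on a 10+10-dipole phantom with 5% sensor noise and
a prescribed 10:1 brain/non-brain sensor-power ratio, then reports the
classification, the recovered BNbR, and the additivity of the partial
reconstructions.
"""

from dataclasses import replace

import numpy as np

import megtomo as mt
from megtomo.simulate import DipolePlan

spec = mt.PhantomSpec(n_sensors=64)
sensors, annotated, native = mt.make_phantom(spec)
grid = spec.grid(edge=0.025)
trials = mt.build_trial_patterns(
    grid, sensors, l_max=8, center=spec.head_center,
    max_source_radius=spec.head_radius,
)
brain, nonbrain = mt.remove_overlap([
    mt.resample_mask(native["brain"], grid),
    mt.resample_mask(native["nonbrain"], grid),
])

T = 20.0
plan_b = mt.plan_dipoles(10, brain, duration=T, seed=1, trials=trials)
plan_nb = mt.plan_dipoles(10, nonbrain, duration=T, seed=2, trials=trials,
                          exclude_freq_indices=plan_b.freq_indices)


def pattern_energy(plan):
    return sum(
        np.sum(mt.sensor_reading(
            mt.CurrentDipole(plan.positions[i],
                             plan.amplitudes[i] * plan.directions[i]),
            sensors, center=spec.head_center) ** 2)
        for i in range(plan.n_sources)
    )


target_ratio = 10.0
scale = np.sqrt(target_ratio * pattern_energy(plan_nb) / pattern_energy(plan_b))
plan_b = replace(plan_b, amplitudes=plan_b.amplitudes * scale)
plan = DipolePlan(
    positions=np.concatenate([plan_b.positions, plan_nb.positions]),
    directions=np.concatenate([plan_b.directions, plan_nb.directions]),
    amplitudes=np.concatenate([plan_b.amplitudes, plan_nb.amplitudes]),
    frequencies=np.concatenate([plan_b.frequencies, plan_nb.frequencies]),
    phases=np.concatenate([plan_b.phases, plan_nb.phases]),
    duration=T,
    freq_indices=np.concatenate([plan_b.freq_indices, plan_nb.freq_indices]),
)

rec = mt.simulate_meg(plan, sensors, 200.0, noise_level=0.05, seed=3,
                      center=spec.head_center)
decomp = mt.compute_spectrum(rec, nu_max=20.0)
oscillations = mt.extract_all_oscillations(decomp)
_, matches = mt.build_tomogram(oscillations, trials)
classification, signals = mt.split_stage(
    decomp, matches, brain, nonbrain, grid, times=rec.times
)
print("frequencies classified:",
      {"brain": int(classification.brain.sum()),
       "nonbrain": int(classification.nonbrain.sum()),
       "unclassified": int(classification.unclassified.sum())})

band = (0.3, 20.0)
bnbr = mt.brain_nonbrain_ratio(
    mt.summary_power_per_channel(decomp, classification.brain, band),
    mt.summary_power_per_channel(decomp, classification.nonbrain, band),
)
print(f"prescribed brain/non-brain power ratio: {target_ratio:.1f}")
print(f"recovered  BNbR over {band[0]}-{band[1]} Hz:  {bnbr:.2f}")

total = signals["brain"] + signals["nonbrain"] + signals["unclassified"]
band_limited = mt.reconstruct_partial_signal(
    decomp, np.ones(decomp.n_frequencies), rec.times
)
err = np.abs(total - band_limited).max() / np.abs(band_limited).max()
print(f"partial signals sum to the band-limited record "
      f"(max relative deviation {err:.1e})")
# The planted frequencies dominate the spectrum, so BNbR lands close to the
# prescribed ratio; the remaining noise frequencies split across all three
# classes but carry little power.
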