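# megtomo

Frequency-pattern functional tomography for multichannel
magnetoencephalography (MEG): decompose a long recording into elementary
coherent oscillations, localize every oscillation by exhaustive dipole-grid
scanning, classify each frequency as «brain» or «non-brain» from annotated
anatomical masks, and reconstruct the two partial signals together with
their power statistics.

## The problem

An MEG helmet records everything electrically active inside and near the
head: cortical rhythms, but also scalp and neck muscles, the nasopharynx,
eye movement, heartbeat-modulated sources.  These physiological noise
sources share frequency bands with brain rhythms, so no bandpass filter can
separate them.  `megtomo` separates them *by source location* instead: each
frequency of the record is assigned to the single spatial source that best
explains its sensor pattern, and the record is split into partial signals
according to where those sources live.

## Method

For a record of duration `T` sampled in `K` channels, the whole-record
Fourier transform on the grid `ν_n = n/T` gives coefficients `a_nk`, `b_nk`
(so the resolution is `1/T`; 0.0033 Hz for 300 s).  Each frequency restores
as `B_nk(t) = ρ_nk sin(2πν_n t + φ_nk)` with `ρ_nk = √(a² + b²)` and
`φ_nk = atan2(a_nk, b_nk)`.  Phase alignment across channels is scored by
the coherence

    C1f = 1 − min_t Σ_k B²_nk(t) / max_t Σ_k B²_nk(t)  ∈ [0, 1],

computed in closed form.  Coherent frequencies become single elementary
oscillations `D_n ρ̂_nk sin(2πν_n t + φ_n)` with a unit-norm signed spatial
pattern `ρ̂_nk`; incoherent frequencies are split into at most two
quadrature components first.

Each pattern is localized by exhaustive comparison against trial patterns
of unit current dipoles in a spherical conductor (`B = −μ₀∇U`, the
single-shell model; radial dipoles are silent) placed at the centers of a
cubic grid with `L_max` tangential directions per cell, minimizing

    χ(i,j,s,l) = Σ_k (ρ̂tr_ijslk − ρ̂_nk)².

The oscillation energy `D²` accumulates at the winning cell, forming the
functional tomogram.  Frequencies whose winning cell falls in the «brain»
(resp. «non-brain») voxel mask form the brain (non-brain) partial spectrum;
the partial signals are the inverse transforms restricted to each class and
sum back to the band-limited record exactly.  The headline statistic is the
brain-to-non-brain power ratio

    BNbR = Σ_k P(b)(k) / Σ_k P(nb)(k),   P(k) = ∫₀ᵀ Σ_n f(n) B²_nk dt,

reported per frequency band (defaults 0.3–100, 0.3–4, 4–100 Hz).

A built-in dipole-phantom simulator (spherical head, helmet of virtual
magnetometers, random tangential dipoles with unique grid frequencies and
10–100 nAm moments) generates ground-truth data for every stage.

## Worked example

`examples/` holds one short script per capability.  Localizing a single
known dipole (`examples/02_forward_and_localize.py`):

```text
scan grid (25, 25, 25), 12 directions per cell -> 187,500 trial slots
peak sensor reading: 5.231e-13 T
planted  cell (15, 11, 17), direction 4
matched  cell (15, 11, 17), direction 4, chi_min = 0.00e+00
```

The planted 50 nAm dipole produces a ~0.5 pT peak reading; the exhaustive
scan recovers its exact cell and moment direction with zero misfit.
Splitting a noisy 20-source phantom built with a prescribed 10:1
brain/non-brain power ratio (`examples/04_split_brain_nonbrain.py`):

```text
frequencies classified: {'brain': 140, 'nonbrain': 151, 'unclassified': 109}
prescribed brain/non-brain power ratio: 10.0
recovered  BNbR over 0.3-20.0 Hz:  9.98
partial signals sum to the band-limited record (max relative deviation 1.5e-15)
```

All 20 planted frequencies classify correctly (the remaining counted
frequencies are low-power sensor noise), the recovered BNbR matches the
prescribed ratio to 0.2%, and the three partial reconstructions add up to
the band-limited input to machine precision.

## Command line

The same pipeline is available as `megtomo simulate | decompose | tomogram
| split | report`, communicating through documented formats (HDF5
recordings, CSV sensor/match/classification tables, NIfTI volumes, JSON
reports).  `megtomo simulate --out-dir sim` writes a complete phantom
dataset to start from.

## Layout

- `src/megtomo/spectral.py` — whole-record transform, coherence, oscillation extraction
- `src/megtomo/forward.py` — single-shell dipole model, trial-pattern grid
- `src/megtomo/localize.py` — exhaustive χ matching, functional tomogram
- `src/megtomo/masks.py` — annotated volumes → disjoint grid masks
- `src/megtomo/partial.py` — frequency classification, partial signals, powers, BNbR
- `src/megtomo/simulate.py` — dipole-phantom generator
- `src/megtomo/io.py`, `config.py`, `pipeline.py`, `cli.py` — formats, configuration, stage glue, CLI
- `docs/methods.md` — modeling assumptions, conventions, and limitations
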