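# Methods

This note records the modeling assumptions, conventions and numerical
choices behind `megtomo`, and what the phantom-based validation does and
does not demonstrate.

## Spectral decomposition

The record is transformed once, over its full duration `T`, onto the grid
`ν_n = n/T`, `n = 1..N`, `N = ⌊ν_max T⌋`.  Coefficients follow the `2/T`
integral convention, so a grid-frequency sinusoid of amplitude `A` yields
`ρ = A`; they are computed by FFT (exact for band-limited input at this
grid).  The DC row is dropped — SQUID sensors carry no meaningful constant
offset — and no window or detrending is applied beyond that: the method
relies on whole-record periodicity of the grid frequencies, and windowing
would destroy the exact closed-form power identities used downstream.  The
bin at the Nyquist frequency is excluded when it would be the last row,
because its amplitude is not representable under this convention.

**Phase convention.** `φ = atan2(a, b)` with the *cosine* coefficient
first, so the restored row is `ρ sin(2πνt + φ)`.  Most other toolboxes use
`atan2(b, a)`; phases exported from this package differ from those by a
90° rotation.

## Coherence

`C1f = 1 − min/max` of the instantaneous channel-summed power over one
period.  With `P = Σ_k ρ²_k` and `A = |Σ_k ρ²_k e^{2iφ_k}|` the exact
closed form is `C1f = 2A/(P + A)`; the dense-time-sampling definition is
kept in the tests as an independent oracle.  Equal phases give 1; the
statistic also gives 1 when phases differ only by π (anti-phase lobes of
one dipolar source), which is the desired behavior for signed field
patterns.  It is undefined (raised as an error) on an all-zero row.

## Signed patterns

Field patterns of a dipolar source have signed lobes, but per-channel
amplitudes `ρ_nk` are nonnegative; the sign lives in the phase.  The
package folds phase offsets of π into the pattern: the reference phase is
half the amplitude-weighted circular mean of the doubled phases
(`φ_ref = ½ arg Σ ρ² e^{2iφ}`, taken in (−π/2, π/2]), each channel gets
sign +1 when its phase is within π/2 of the reference and −1 otherwise,
and the common phase of the oscillation is `φ_ref`.  When all phases are
equal this reduces to the plain normalized amplitude pattern (possibly
times −1 with the phase shifted by π — the same physical signal).  The
overall sign of a pattern is not physical; matching and scoring treat
`(pattern, φ)` and `(−pattern, φ + π)` as identical.

## Splitting incoherent frequencies

A single-frequency multichannel signal spans at most two temporal
quadratures, `sin(2πνt)` and `cos(2πνt)`.  Sampled over full periods, any
mixture of same-frequency sinusoids whitens to a distribution that is
*rotation-invariant* in that 2-D subspace, so fixed-point ICA contrasts
(kurtosis, negentropy) carry no information and cannot identify the
mixing: separation of same-frequency sources from temporal statistics
alone is fundamentally ambiguous up to a quadrature rotation.  The package
therefore resolves the degeneracy with the one distinguished decomposition
that exists: the SVD of the `K×2` quadrature-coefficient matrix, giving at
most two components that are orthogonal in sensor space, exactly in phase
quadrature, and additive in energy (`ΣD²_m = ρ²_n` by construction).  When
two genuine sources are phase-shifted by exactly π/2 and their patterns
have small overlap, this recovers them; for other phase shifts the
components are the principal axes of the mixture, not the physical
sources, and this limitation is intrinsic to any statistics-based
separation at a single frequency.  A scikit-learn FastICA path
(`ICASettings(method="fastica")`) is retained for experimentation and
falls back to the single-oscillation treatment on non-convergence.

Components below 1% of the row energy (configurable) are discarded; a row
whose components all fall below the floor is kept whole.  The coherence
threshold above which a row counts as a single source defaults to 0.95
("close to 1"); it is a free parameter with no canonical value.

## Forward model and trial patterns

Sources are current dipoles in a homogeneous conducting sphere
(single-shell model): `B(r) = −μ₀∇U`, `U = −(Q×r₀)·r / (4πF)`,
`F = a(ar + r² − r₀·r)`, `a = |r − r₀|`, positions relative to the sphere
center.  The gradient is analytic and validated against central
differences of `U`.  Radial dipoles and dipoles at the center are silent,
so trial moments scan only the `L_max` tangential directions, spaced
`360/L_max°`, with the first direction the projection of global +x onto
the tangential plane (+y when degenerate) — a deterministic, reproducible
indexing.  Channels are idealized point magnetometers (a reading is the
field component along the sensor orientation); physical gradiometer coil
geometry is not modeled.

The sphere center defaults to a least-squares fit of the sensor positions;
the simulator passes the known phantom center.  Grid cells are 0-based
with centers at `origin + (index + 0.5)·edge`, all coordinates in meters
in the head frame.  Trial patterns are generated lazily in chunks (default
8192 slots) and never materialized whole; the production grid (25 cm cube,
2 mm edge, 24 directions) enumerates 46,875,000 slots.  Slots with a field
norm below `10⁻¹³ T per A·m` (e.g. the sphere-center cell) are invalid.

**Scan-volume restriction.** The scan may cover the whole cube with no
further condition, but the single-shell formula is only physically
meaningful for sources *inside* the conductor; normalized patterns of
exterior cells are near-degenerate artifacts that can capture slightly
off-grid sources.  `TrialPatternSet(max_source_radius=...)` invalidates
cells outside a chosen radius; the phantom validation restricts the scan
to the head sphere, and without this restriction the half-edge
perturbation robustness below does not hold.  The default is
unrestricted.

## Matching

For unit vectors `χ = 2(1 − cosine similarity)`; the scan maximizes
`|similarity|` over all valid slots (equivalently minimizes χ over the
pattern and its negative).  Ties are broken by preferring a direct over a
sign-flipped match (implemented as a 10⁻¹² relative bias — χ differences
below that are numerically meaningless) and then by the lowest slot linear
index (I, then J, then S, then L).  A sign-flipped winner at direction `l`
is the same physical source as a direct winner at the antipodal direction
`(l + L/2) mod L`; `canonical_direction` maps both to one representative
and all recovery scoring is performed modulo this equivalence.  Matching
streams one chunked pass over the trial set for all patterns at once, one
matrix product per chunk.

## Masks and classification

Annotated volumes are binarized over a configurable label set, then
downsampled to the scan grid by the *presence* rule — a grid cell is
inside the region as soon as one native true-voxel center falls in it —
with an optional `min_fraction` majority threshold (several downsampling
rules are defensible; presence is the conservative choice that never
loses thin structures).  After
downsampling, voxels shared between regions are removed from all of them,
in that order.  A frequency follows the mask containing the matched cell
of its largest-energy oscillation; frequencies matched outside both masks
(possible since the scan is unconstrained) form an explicit third,
«unclassified» class, excluded from BNbR and reported separately.  The
three indicator functions partition the grid, so the three partial
reconstructions sum to the band-limited record exactly.

## Powers

Instantaneous power is the per-frequency sum of squares (no cross terms
between frequencies, as defined).  Summary power per channel uses the
exact closed form `(T/2) Σ_{n∈band} f(n) ρ²_nk` — each grid frequency
completes an integer number of cycles on `[0, T]`, so the quadrature
integral is exact; the trapezoid oracle lives in the tests.  BNbR defaults
to bands 0.3–100, 0.3–4 and 4–100 Hz; zero non-brain power yields an
infinite ratio with a warning, not an error.

## Phantom simulator

The phantom is a 9 cm spherical head centered in a 25 cm annotated cube
(5 mm voxels): «brain» is the upper half of an inner 7 cm sphere, «non-
brain» the lower half of the head sphere (face/neck side), separated by a
1 cm gap so the regions stay disjoint at any downsampling.  Sensors are a
quasi-uniform Fibonacci cap of radial inward magnetometers at 11 cm
(default 128 channels; 275 gives a CTF-like count), reaching 35% of the
radius below the equator like a recording helmet.  Dipoles get uniform
positions over region voxel centers (skipping a 2 cm core around the
center where tangential patterns degenerate), tangential directions
(snapped to trial directions for on-grid validation), uniform amplitudes
of 10–100 nAm, unique frequencies drawn from the record grid in a
1–17.667 Hz band, and uniform phases.  Separate named seed streams drive
positions, amplitudes, frequencies, phases and noise.  Sensor noise is
additive white Gaussian with standard deviation a stated fraction of the
noiseless signal's overall standard deviation.

The production protocol — 1,200 Hz sampling, 300 s records, thousands of
sources, 2 mm/24-direction scan — is available through presets; at
T = 300 s the 1–17.667 Hz band holds just over 5,000 grid frequencies
(a 0.033 Hz step would hold only ~500, so large source counts require the
record's own 1/300 Hz grid).  The validation suite runs a desk-scale
version of the same protocol: 600 Hz, 60 s, 50 sources, 1 cm grid with 12
directions and 128 channels, which completes in seconds per run and
exercises the identical code path.  Smaller module-level fixtures use 64
channels and a 2.5 cm grid.

What the phantom does *not* emulate: 1/f background activity, heartbeat
and respiration harmonics, head movement, correlated sensor noise,
gradiometer coil geometry, and realistic (non-spherical) conductor
anatomy.  Passing phantom validation therefore demonstrates correctness
of the algorithms under the model's own assumptions — exact recovery of
on-grid single-shell sources, exact additivity and power bookkeeping,
ratio recovery under white noise — not localization accuracy on real
heads.

## Validation summary (computed by the test suite)

- Noiseless on-grid sources recover their exact cell and direction (no
  shift), at both fixture scales.
- Off-grid sources perturbed by up to half a cell edge localize within
  the 26-neighborhood of their cell in ≥95% of cases, with the scan
  restricted to the head sphere.
- Brain + non-brain + unclassified reconstructions equal the band-limited
  record to 10⁻⁶ relative.
- A prescribed brain/non-brain sensor-power ratio is recovered by the full
  pipeline to 0.1% without noise and within 10% with 5% sensor noise,
  with ≥95% of planted frequencies classified correctly.
- Parseval, energy-conservation, permutation-equivariance and closed-form
  vs. quadrature identities hold to stated tolerances.

## Known limitations

- Normalized-pattern matching discards amplitude information, so depth is
  the least-constrained coordinate; off-grid and noisy sources drift
  mainly radially.
- Same-frequency source separation is identifiable only up to a
  quadrature rotation (see above); at most two components per frequency.
- The frequency-level classification assigns a whole frequency to one
  region even when phase-split components straddle regions; the match
  table retains the component-level information for finer analysis.
- One static source per frequency is assumed for the whole record; moving
  or switching sources violate the model.
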