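"""Shared fixtures: small phantoms and recordings built at test time."""

from __future__ import annotations

import numpy as np
import pytest

import megtomo as mt
from megtomo.simulate import DipolePlan


def merge_plans(plans: list[DipolePlan], duration: float) -> DipolePlan:
    return DipolePlan(
        positions=np.concatenate([p.positions for p in plans]),
        directions=np.concatenate([p.directions for p in plans]),
        amplitudes=np.concatenate([p.amplitudes for p in plans]),
        frequencies=np.concatenate([p.frequencies for p in plans]),
        phases=np.concatenate([p.phases for p in plans]),
        duration=duration,
        freq_indices=np.concatenate([p.freq_indices for p in plans]),
        cells=np.concatenate([p.cells for p in plans])
        if all(p.cells is not None for p in plans) else None,
        direction_indices=np.concatenate([p.direction_indices for p in plans])
        if all(p.direction_indices is not None for p in plans) else None,
    )


@pytest.fixture(scope="session")
def mini_phantom():
    """Coarse, fast phantom: 64 sensors, 2.5 cm scan grid, 8 directions."""
    spec = mt.PhantomSpec(n_sensors=64)
    sensors, annotated, native = mt.make_phantom(spec)
    grid = spec.grid(0.025)
    trials = mt.build_trial_patterns(
        grid, sensors, l_max=8, center=spec.head_center,
        max_source_radius=spec.head_radius,
    )
    brain, nonbrain = mt.remove_overlap([
        mt.resample_mask(native["brain"], grid),
        mt.resample_mask(native["nonbrain"], grid),
    ])
    return {
        "spec": spec,
        "sensors": sensors,
        "annotated": annotated,
        "native": native,
        "grid": grid,
        "trials": trials,
        "brain": brain,
        "nonbrain": nonbrain,
    }


@pytest.fixture(scope="session")
def mini_run(mini_phantom):
    """Noiseless 10+10-dipole recording on the mini phantom, decomposed."""
    ph = mini_phantom
    T, fs = 20.0, 200.0
    plan_b = mt.plan_dipoles(
        10, ph["brain"], duration=T, freq_band=(1.0, 17.667), seed=11,
        trials=ph["trials"],
    )
    plan_nb = mt.plan_dipoles(
        10, ph["nonbrain"], duration=T, freq_band=(1.0, 17.667), seed=12,
        trials=ph["trials"], exclude_freq_indices=plan_b.freq_indices,
    )
    plan = merge_plans([plan_b, plan_nb], T)
    recording = mt.simulate_meg(
        plan, ph["sensors"], fs, center=ph["spec"].head_center
    )
    decomp = mt.compute_spectrum(recording, 20.0)
    return {
        "plan": plan,
        "plan_brain": plan_b,
        "plan_nonbrain": plan_nb,
        "recording": recording,
        "decomp": decomp,
        **ph,
    }


@pytest.fixture(scope="session")
def desk_phantom():
    """Desk-scale phantom: 128 sensors, 1 cm scan grid, 12 directions."""
    spec = mt.PhantomSpec(n_sensors=128)
    sensors, annotated, native = mt.make_phantom(spec)
    grid = spec.grid(0.01)
    trials = mt.build_trial_patterns(
        grid, sensors, l_max=12, center=spec.head_center,
        max_source_radius=spec.head_radius,
    )
    brain, nonbrain = mt.remove_overlap([
        mt.resample_mask(native["brain"], grid),
        mt.resample_mask(native["nonbrain"], grid),
    ])
    return {
        "spec": spec,
        "sensors": sensors,
        "annotated": annotated,
        "native": native,
        "grid": grid,
        "trials": trials,
        "brain": brain,
        "nonbrain": nonbrain,
    }


@pytest.fixture(scope="session")
def desk_run50(desk_phantom):
    """50 noiseless on-grid dipoles at 600 Hz / 60 s, fully localized."""
    ph = desk_phantom
    T, fs = 60.0, 600.0
    plan_b = mt.plan_dipoles(
        25, ph["brain"], duration=T, freq_band=(1.0, 17.667), seed=21,
        trials=ph["trials"],
    )
    plan_nb = mt.plan_dipoles(
        25, ph["nonbrain"], duration=T, freq_band=(1.0, 17.667), seed=22,
        trials=ph["trials"], exclude_freq_indices=plan_b.freq_indices,
    )
    plan = merge_plans([plan_b, plan_nb], T)
    recording = mt.simulate_meg(plan, ph["sensors"], fs, center=ph["spec"].head_center)
    decomp = mt.compute_spectrum(recording, 18.0)
    oscillations = mt.extract_all_oscillations(decomp, power_floor=1e-12)
    tomo, matches = mt.build_tomogram(oscillations, ph["trials"])
    return {
        "plan": plan,
        "plan_brain": plan_b,
        "plan_nonbrain": plan_nb,
        "recording": recording,
        "decomp": decomp,
        "oscillations": oscillations,
        "tomogram": tomo,
        "matches": matches,
        **ph,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def tone_recording(
    amplitudes, frequencies, phases, fs=200.0, duration=10.0
) -> mt.MultichannelRecording:
    """Multichannel sum of grid-frequency tones; rows of ``amplitudes`` are
    channels, columns match ``frequencies``."""
    amp = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    t = np.arange(int(round(fs * duration))) / fs
    args = 2.0 * np.pi * np.outer(np.asarray(frequencies, float), t)
    args += np.asarray(phases, float)[:, None]
    return mt.MultichannelRecording(amp @ np.sin(args), fs)
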