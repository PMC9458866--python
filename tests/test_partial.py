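"""Frequency classification, partial reconstruction, powers, and BNbR."""

import numpy as np
import pytest
from scipy.integrate import trapezoid

import megtomo as mt

from .conftest import tone_recording


def grid_mask(volume, name):
    grid = mt.GridSpec(origin=np.zeros(3), shape=volume.shape, edge=0.01)
    return mt.BinaryMask(volume=volume, name=name, affine=grid.affine("m"), grid=grid)


def fake_match(n, cell, energy=1.0):
    return mt.SourceMatch(
        oscillation=None, grid_index=cell, direction=0,
        chi_min=0.0, sign=1, energy=energy, n=n,
    )


@pytest.fixture()
def two_masks():
    brain = np.zeros((4, 4, 4), bool)
    nonbrain = np.zeros((4, 4, 4), bool)
    brain[:2] = True
    nonbrain[2:] = True
    return grid_mask(brain, "brain"), grid_mask(nonbrain, "non-brain")


class TestClassify:
    def test_all_brain_matches(self, two_masks):
        brain, nonbrain = two_masks
        matches = [fake_match(n, (0, 1, 1)) for n in range(1, 6)]
        cls = mt.classify_frequencies(matches, brain, nonbrain, 5)
        assert cls.brain.all()
        assert not cls.nonbrain.any()

    def test_match_outside_both_masks_is_unclassified(self, two_masks):
        brain, nonbrain = two_masks
        cls = mt.classify_frequencies([fake_match(1, (9, 9, 9))], brain, nonbrain, 2)
        assert cls.unclassified[0] == 1
        assert cls.brain[0] == 0 and cls.nonbrain[0] == 0

    def test_unmatched_frequency_is_unclassified(self, two_masks):
        brain, nonbrain = two_masks
        cls = mt.classify_frequencies([fake_match(2, (0, 0, 0))], brain, nonbrain, 3)
        assert list(cls.unclassified) == [1, 0, 1]

    def test_largest_energy_oscillation_decides(self, two_masks):
        brain, nonbrain = two_masks
        matches = [
            fake_match(1, (0, 0, 0), energy=1.0),    # brain, weak
            fake_match(1, (3, 0, 0), energy=5.0),    # non-brain, strong
        ]
        cls = mt.classify_frequencies(matches, brain, nonbrain, 1)
        assert cls.nonbrain[0] == 1

    def test_overlapping_masks_rejected(self):
        a = grid_mask(np.ones((2, 2, 2), bool), "a")
        b = grid_mask(np.ones((2, 2, 2), bool), "b")
        with pytest.raises(ValueError):
            mt.classify_frequencies([], a, b, 1)

    def test_phantom_split_counts(self, mini_run):
        """10 brain + 10 non-brain planted dipoles classify 10/10."""
        decomp = mini_run["decomp"]
        oscs = mt.extract_all_oscillations(decomp, power_floor=1e-12)
        _, matches = mt.build_tomogram(oscs, mini_run["trials"])
        cls = mt.classify_frequencies(
            matches, mini_run["brain"], mini_run["nonbrain"], decomp.n_frequencies
        )
        assert int(cls.brain.sum()) == 10
        assert int(cls.nonbrain.sum()) == 10


class TestPartialReconstruction:
    def test_full_indicator_restores_band_limited_signal(self, mini_run):
        decomp = mini_run["decomp"]
        rec = mini_run["recording"]
        full = mt.reconstruct_partial_signal(
            decomp, np.ones(decomp.n_frequencies), rec.times
        )
        # the recording is noiseless and band-limited by construction
        assert np.abs(full - rec.samples).max() < 1e-6 * np.abs(rec.samples).max()

    def test_zero_indicator_gives_zero_signal(self, mini_run):
        decomp = mini_run["decomp"]
        out = mt.reconstruct_partial_signal(
            decomp, np.zeros(decomp.n_frequencies), np.linspace(0, 1, 7)
        )
        assert not out.any()

    def test_partition_additivity(self, mini_run, rng):
        decomp = mini_run["decomp"]
        t = np.linspace(0.0, 2.0, 101)
        labels = rng.integers(0, 3, size=decomp.n_frequencies)
        parts = sum(
            mt.reconstruct_partial_signal(decomp, (labels == i).astype(int), t)
            for i in range(3)
        )
        full = mt.reconstruct_partial_signal(decomp, np.ones_like(labels), t)
        assert np.abs(parts - full).max() < 1e-6 * np.abs(full).max()


class TestPowers:
    def test_single_tone_instantaneous_power(self):
        rec = tone_recording([[2.0]], [10.0], [0.0])
        d = mt.compute_spectrum(rec, 50.0)
        ind = np.zeros(d.n_frequencies)
        ind[d.freq_index(10.0) - 1] = 1
        t = np.linspace(0.0, 0.1, 201)
        p = mt.instantaneous_power(d, ind, t)
        ref = 4.0 * np.sin(2 * np.pi * 10.0 * t) ** 2
        assert np.abs(p - ref).max() < 1e-9
        assert p.max() == pytest.approx(4.0, rel=1e-9)

    def test_time_average_matches_closed_form(self, mini_run):
        decomp = mini_run["decomp"]
        ind = np.ones(decomp.n_frequencies)
        t = mini_run["recording"].times
        p = mt.instantaneous_power(decomp, ind, t)
        rho2 = mt.summary_power_spectrum(decomp)
        assert p.mean() == pytest.approx(float(rho2.sum()) / 2.0, rel=1e-6)

    def test_zero_indicator_zero_power(self, mini_run):
        decomp = mini_run["decomp"]
        t = np.linspace(0, 1, 11)
        assert not mt.instantaneous_power(
            decomp, np.zeros(decomp.n_frequencies), t
        ).any()

    def test_single_tone_summary_power(self):
        rec = tone_recording([[2.0]], [10.0], [0.4], duration=10.0)
        d = mt.compute_spectrum(rec, 50.0)
        ind = np.ones(d.n_frequencies)
        p = mt.summary_power_per_channel(d, ind)
        assert p[0] == pytest.approx(20.0, rel=1e-9)  # rho^2 T / 2

    def test_summary_power_matches_quadrature_oracle(self, mini_run):
        """Closed form vs trapezoid integration of B^2 at 1,200 Hz."""
        decomp = mini_run["decomp"]
        ind = np.zeros(decomp.n_frequencies)
        ind[mini_run["plan"].freq_indices[:5] - 1] = 1
        closed = mt.summary_power_per_channel(decomp, ind)
        fs = 1200.0
        t = np.arange(int(decomp.duration * fs) + 1) / fs
        sig = mt.reconstruct_partial_signal(decomp, ind, t)
        quad = trapezoid(sig**2, t, axis=1)
        assert np.abs(closed - quad).max() < 1e-6 * closed.max()

    def test_band_restriction_and_power_decomposition(self, mini_run):
        decomp = mini_run["decomp"]
        n = decomp.n_frequencies
        labels = np.zeros(n, dtype=int)
        labels[::3] = 1
        labels[1::3] = 2
        band = (2.0, 15.0)
        parts = [
            mt.summary_power_per_channel(decomp, (labels == i).astype(int), band)
            for i in range(3)
        ]
        total = mt.summary_power_per_channel(decomp, np.ones(n), band)
        assert np.allclose(sum(parts), total, rtol=1e-12)

    def test_band_without_grid_frequencies_gives_zeros(self, mini_run):
        decomp = mini_run["decomp"]
        # grid step is 0.05 Hz; (18.01, 18.04) contains no grid frequency
        out = mt.summary_power_per_channel(
            decomp, np.ones(decomp.n_frequencies), (18.01, 18.04)
        )
        assert not out.any()


class TestBNbR:
    def test_identical_partial_powers_give_unity(self):
        p = np.array([1.0, 2.0, 3.0])
        assert mt.brain_nonbrain_ratio(p, p.copy()) == 1.0

    def test_zero_nonbrain_power_is_infinite_not_fatal(self):
        assert np.isinf(mt.brain_nonbrain_ratio(np.ones(3), np.zeros(3)))

    def test_prescribed_energy_ratio_recovered_exactly(self, mini_run):
        """Scale brain amplitudes for a 10x sensor-pattern energy ratio;
        the noiseless pipeline BNbR must hit 10 within 0.1%."""
        from .conftest import merge_plans
        from dataclasses import replace

        ratio = 10.0
        ph = mini_run
        plan_b, plan_nb = ph["plan_brain"], ph["plan_nonbrain"]
        sensors, c = ph["sensors"], ph["spec"].head_center

        def pattern_energy(plan):
            return sum(
                np.sum(mt.sensor_reading(
                    mt.CurrentDipole(plan.positions[i],
                                     plan.amplitudes[i] * plan.directions[i]),
                    sensors, center=c) ** 2)
                for i in range(plan.n_sources)
            )

        e_b, e_nb = pattern_energy(plan_b), pattern_energy(plan_nb)
        scale = np.sqrt(ratio * e_nb / e_b)
        plan_b2 = replace(plan_b, amplitudes=plan_b.amplitudes * scale)
        plan = merge_plans([plan_b2, plan_nb], plan_b.duration)
        rec = mt.simulate_meg(plan, sensors, 200.0, center=c)
        decomp = mt.compute_spectrum(rec, 20.0)
        oscs = mt.extract_all_oscillations(decomp, power_floor=1e-12)
        _, matches = mt.build_tomogram(oscs, ph["trials"])
        cls = mt.classify_frequencies(
            matches, ph["brain"], ph["nonbrain"], decomp.n_frequencies
        )
        band = (0.3, 20.0)
        pb = mt.summary_power_per_channel(decomp, cls.brain, band)
        pnb = mt.summary_power_per_channel(decomp, cls.nonbrain, band)
        assert mt.brain_nonbrain_ratio(pb, pnb) == pytest.approx(ratio, rel=1e-3)

    def test_power_report_bands(self, mini_run):
        decomp = mini_run["decomp"]
        oscs = mt.extract_all_oscillations(decomp, power_floor=1e-12)
        _, matches = mt.build_tomogram(oscs, mini_run["trials"])
        cls = mt.classify_frequencies(
            matches, mini_run["brain"], mini_run["nonbrain"], decomp.n_frequencies
        )
        report = mt.make_power_report(
            decomp, cls, bands=((0.3, 20.0), (0.3, 4.0), (4.0, 20.0))
        )
        assert set(report.bnbr) == {(0.3, 20.0), (0.3, 4.0), (4.0, 20.0)}
        assert report.bnbr[(0.3, 20.0)] > 0
        total = report.brain_power + report.nonbrain_power + report.unclassified_power
        ref = mt.summary_power_per_channel(
            decomp, np.ones(decomp.n_frequencies), (0.3, 20.0)
        )
        assert np.allclose(total, ref, rtol=1e-9)
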