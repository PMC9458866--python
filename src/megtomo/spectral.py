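"""Whole-record Fourier decomposition and extraction of coherent oscillations.

A long multichannel MEG record is decomposed on the frequency grid
``nu_n = n / T`` (``T`` = full record duration), so the frequency resolution
is ``1/T`` — 0.0033 Hz for a 300 s record.  For each grid frequency the
multichannel signal is restored as

    B_nk(t) = rho_nk * sin(2*pi*nu_n*t + phi_nk)

with ``rho_nk = sqrt(a_nk**2 + b_nk**2)`` and ``phi_nk = atan2(a_nk, b_nk)``.

.. note::
   The phase convention is ``phi = atan2(a, b)`` — *cosine* coefficient
   first — so that the restored signal is a pure sine when ``a = 0``.  This
   differs from the more common ``atan2(b, a)``; keep it in mind when
   comparing phases with other toolboxes.

Frequencies whose channels share one common phase form elementary coherent
oscillations, each characterized by an amplitude, a phase, and a unit-norm
spatial pattern that is later matched against forward-modeled dipole
patterns.  Phase coherence across channels is scored by the statistic
``C1f`` in [0, 1] (1 = a single common phase up to sign).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import NonFiniteDataError, NyquistError, ZeroAmplitudeError

logger = logging.getLogger(__name__)

__all__ = [
    "MultichannelRecording",
    "SpectralDecomposition",
    "CoherentOscillation",
    "ICASettings",
    "compute_spectrum",
    "restore_frequency_signal",
    "coherence",
    "coherence_all",
    "extract_oscillations",
    "summary_power_spectrum",
]


@dataclass(frozen=True)
class MultichannelRecording:
    """A multichannel magnetic-induction time series.

    Parameters
    ----------
    samples
        ``(K, Nt)`` array of magnetic induction in tesla.
    sampling_rate
        Sampling rate in Hz.
    channel_ids
        ``K`` channel labels.  Defaults to ``CH000 ...``.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2 or samples.shape[0] < 1:
            raise ValueError("samples must be a (K, Nt) array with K >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_ids:
            ids = tuple(f"CH{i:03d}" for i in range(samples.shape[0]))
            object.__setattr__(self, "channel_ids", ids)
        elif len(self.channel_ids) != samples.shape[0]:
            raise ValueError("channel_ids length must equal K")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length ``T`` in seconds (``Nt / sampling_rate``)."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class SpectralDecomposition:
    """Fourier coefficients of a record on the grid ``nu_n = n/T``.

    Rows are frequencies ``n = 1..N`` (the DC term is dropped: a constant
    field offset carries no information in SQUID measurements), columns are
    channels.  Coefficients follow the ``2/T`` integral convention, so a pure
    sinusoid of amplitude ``A`` at a grid frequency has ``rho = A``.
    """

    frequencies: np.ndarray          # (N,) Hz
    cos_coeffs: np.ndarray           # a_nk, (N, K) tesla
    sin_coeffs: np.ndarray           # b_nk, (N, K) tesla
    duration: float                  # T, seconds
    channel_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.cos_coeffs.shape != self.sin_coeffs.shape:
            raise ValueError("cos/sin coefficient shapes differ")
        if self.frequencies.shape[0] != self.cos_coeffs.shape[0]:
            raise ValueError("frequency grid does not match coefficient rows")

    @property
    def n_frequencies(self) -> int:
        return self.frequencies.shape[0]

    @property
    def n_channels(self) -> int:
        return self.cos_coeffs.shape[1]

    @property
    def delta_nu(self) -> float:
        """Frequency resolution ``1/T`` in Hz."""
        return 1.0 / self.duration

    @property
    def amplitudes(self) -> np.ndarray:
        """``rho_nk = sqrt(a**2 + b**2)``, (N, K), tesla."""
        return np.hypot(self.cos_coeffs, self.sin_coeffs)

    @property
    def phases(self) -> np.ndarray:
        """``phi_nk = atan2(a_nk, b_nk)`` (cosine coefficient first)."""
        return np.arctan2(self.cos_coeffs, self.sin_coeffs)

    def row(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(a_nk, b_nk)`` for 1-based frequency index ``n``."""
        if not 1 <= n <= self.n_frequencies:
            raise IndexError(
                f"frequency index {n} outside 1..{self.n_frequencies}"
            )
        return self.cos_coeffs[n - 1], self.sin_coeffs[n - 1]

    def freq_index(self, freq_hz: float) -> int:
        """1-based index of the grid frequency nearest ``freq_hz``."""
        n = int(round(freq_hz * self.duration))
        if not 1 <= n <= self.n_frequencies:
            raise IndexError(f"{freq_hz} Hz outside the decomposed band")
        return n

    def band_indices(self, low_hz: float, high_hz: float) -> np.ndarray:
        """0-based row indices with ``low <= nu_n <= high``."""
        return np.nonzero(
            (self.frequencies >= low_hz) & (self.frequencies <= high_hz)
        )[0]


@dataclass(frozen=True)
class CoherentOscillation:
    """One elementary coherent oscillation.

    ``D * pattern_k * sin(2*pi*freq*t + phase)`` per channel, with a signed
    unit-norm ``pattern``.  A sign flip of the pattern together with a phase
    shift of pi leaves the signal unchanged; the stored representative has
    ``phase`` in ``(-pi/2, pi/2]``.
    """

    frequency: float                 # Hz
    amplitude: float                 # D, tesla
    phase: float                     # radians
    pattern: np.ndarray              # (K,), signed, unit 2-norm
    coherence: float                 # C1f of the parent frequency row
    freq_index: int                  # 1-based n on the decomposition grid
    component_index: int = 0         # m, 0-based within the frequency

    @property
    def energy(self) -> float:
        """``D**2`` in tesla^2."""
        return self.amplitude ** 2

    def signal(self, times: np.ndarray) -> np.ndarray:
        """Evaluate the oscillation on a time grid -> ``(K, len(times))``."""
        t = np.asarray(times, dtype=float)
        return (
            self.amplitude
            * self.pattern[:, None]
            * np.sin(2.0 * np.pi * self.frequency * t + self.phase)[None, :]
        )


@dataclass(frozen=True)
class ICASettings:
    """Settings for splitting an incoherent frequency row into components.

    method
        ``"quadrature_svd"`` (default): principal-axes decomposition of the
        two-quadrature coefficient matrix.  A single-frequency multichannel
        signal spans at most two temporal quadratures, and its sampled joint
        distribution is rotation-invariant after whitening, so fixed-point
        ICA contrasts carry no information there; the SVD gives the unique
        decomposition into spatially orthogonal, temporally uncorrelated
        components and is fully deterministic.
        ``"fastica"``: scikit-learn FastICA on one densely sampled period,
        kept for experimentation; falls back to the single-oscillation
        treatment if it fails to converge.
    max_components
        Upper bound on extracted components per frequency (the single-
        frequency rank bound of 2 applies on top of this).
    energy_floor
        Minimum fraction of the row energy ``rho_n**2`` a component must
        carry to be kept.
    seed
        Random seed for the FastICA path.
    """

    method: str = "quadrature_svd"
    max_components: int = 8
    energy_floor: float = 0.01
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-6


def compute_spectrum(
    recording: MultichannelRecording, nu_max: float
) -> SpectralDecomposition:
    """Whole-record Fourier decomposition up to ``nu_max``.

    Coefficients are computed by FFT and scaled to the ``2/T`` integral
    convention.  ``N = floor(nu_max * T)`` rows are kept (the Nyquist bin is
    excluded when it would coincide with row ``N``, since its amplitude is
    not representable under this convention).

    Raises
    ------
    NyquistError
        If ``nu_max`` exceeds half the sampling rate.
    NonFiniteDataError
        If any sample is NaN or infinite.
    """
    fs = recording.sampling_rate
    if nu_max > fs / 2.0 + 1e-12:
        raise NyquistError(
            f"nu_max={nu_max} Hz exceeds Nyquist {fs / 2.0} Hz"
        )
    if not np.all(np.isfinite(recording.samples)):
        raise NonFiniteDataError("recording contains non-finite samples")
    T = recording.duration
    if nu_max * T < 1.0:
        raise ValueError("nu_max * T < 1: no grid frequency below nu_max")
    nt = recording.n_samples
    n_rows = min(int(np.floor(nu_max * T + 1e-9)), (nt - 1) // 2)
    spectrum = np.fft.rfft(recording.samples, axis=1)
    sel = spectrum[:, 1 : n_rows + 1]
    a = (2.0 / nt) * sel.real.T.copy()
    b = (-2.0 / nt) * sel.imag.T.copy()
    freqs = np.arange(1, n_rows + 1) / T
    return SpectralDecomposition(
        frequencies=freqs,
        cos_coeffs=a,
        sin_coeffs=b,
        duration=T,
        channel_ids=recording.channel_ids,
    )


def restore_frequency_signal(
    decomp: SpectralDecomposition, n: int, times: np.ndarray
) -> np.ndarray:
    """Restore the multichannel signal at grid frequency ``n`` (1-based).

    Returns ``rho_nk * sin(2*pi*nu_n*t + phi_nk)`` as ``(K, len(times))``.
    """
    a, b = decomp.row(n)
    t = np.asarray(times, dtype=float)
    omega_t = 2.0 * np.pi * decomp.frequencies[n - 1] * t
    # rho*sin(wt + phi) expanded: b*sin(wt) + a*cos(wt)
    return b[:, None] * np.sin(omega_t)[None, :] + a[:, None] * np.cos(omega_t)[None, :]


def _row_phase_stats(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Return ``(P, A)`` with ``P = sum(rho**2)`` and ``A = |sum(rho**2 e^{2i phi})|``."""
    z = b + 1j * a  # rho * e^{i phi}
    p = float(np.sum(z.real**2 + z.imag**2))
    amp = float(abs(np.sum(z * z)))
    return p, amp


def coherence(decomp: SpectralDecomposition, n: int) -> float:
    """Phase-coherence statistic ``C1f`` at grid frequency ``n`` (1-based).

    ``C1f = 1 - min/max`` of the instantaneous total power
    ``sum_k B_nk(t)**2`` over one period.  With ``P = sum_k rho_nk**2`` and
    ``A = |sum_k rho_nk**2 exp(2i phi_nk)|`` this equals ``2A / (P + A)``
    in closed form.  Equal phases in all channels give 1; a two-channel
    equal-amplitude quadrature pair gives 0.

    Raises
    ------
    ZeroAmplitudeError
        If every channel amplitude at ``n`` is zero.
    """
    a, b = decomp.row(n)
    p, amp = _row_phase_stats(a, b)
    if p == 0.0:
        raise ZeroAmplitudeError(
            f"coherence undefined at frequency index {n}: all amplitudes zero"
        )
    return 2.0 * amp / (p + amp)


def coherence_all(decomp: SpectralDecomposition) -> np.ndarray:
    """Vectorized ``C1f`` for every frequency row (NaN where all-zero)."""
    z = decomp.sin_coeffs + 1j * decomp.cos_coeffs
    p = np.sum(z.real**2 + z.imag**2, axis=1)
    amp = np.abs(np.sum(z * z, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 2.0 * amp / (p + amp)
    out[p == 0.0] = np.nan
    return out


def _signed_pattern(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Fold per-channel phases into a signed unit pattern.

    Returns ``(pattern, common_phase, D)``.  The reference phase is half the
    amplitude-weighted circular mean of the doubled phases (so a channel
    pi out of phase pulls the reference the same way as an in-phase one);
    channels within pi/2 of the reference get sign +1, the rest -1.  When
    every channel shares one phase this reduces to the plain normalized
    amplitude pattern, possibly times -1 with the phase shifted by pi.
    """
    z = b + 1j * a
    d = float(np.sqrt(np.sum(z.real**2 + z.imag**2)))
    if d == 0.0:
        raise ZeroAmplitudeError("cannot form a pattern from an all-zero row")
    phi_ref = 0.5 * float(np.angle(np.sum(z * z)))  # in (-pi/2, pi/2]
    phi = np.arctan2(a, b)
    signs = np.where(np.cos(phi - phi_ref) >= 0.0, 1.0, -1.0)
    pattern = signs * np.hypot(a, b) / d
    return pattern, phi_ref, d


def _oscillation_from_row(
    a: np.ndarray,
    b: np.ndarray,
    frequency: float,
    c1f: float,
    n: int,
    m: int,
) -> CoherentOscillation:
    pattern, phase, d = _signed_pattern(a, b)
    return CoherentOscillation(
        frequency=frequency,
        amplitude=d,
        phase=phase,
        pattern=pattern,
        coherence=c1f,
        freq_index=n,
        component_index=m,
    )


def _split_quadrature_svd(
    a: np.ndarray, b: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Principal-axes split of one frequency row into rank-1 components.

    The row's signal is ``Q @ [sin(wt), cos(wt)]`` with ``Q = [b | a]``;
    the SVD of ``Q`` yields at most two components that are orthogonal in
    space and in exact temporal quadrature.  Returns per-component
    ``(a_k, b_k)`` coefficient vectors; component energies are additive.
    """
    q = np.column_stack([b, a])
    u, s, vt = np.linalg.svd(q, full_matrices=False)
    out = []
    for m in range(len(s)):
        if s[m] == 0.0:
            continue
        spatial = u[:, m] * s[m]
        out.append((spatial * vt[m, 1], spatial * vt[m, 0]))
    return out


def _split_fastica(
    a: np.ndarray,
    b: np.ndarray,
    settings: ICASettings,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """FastICA split of one frequency row (experimental path).

    Samples one period densely, runs FastICA, and projects each source back
    onto the two quadratures.  Raises on non-convergence so the caller can
    fall back.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    k = a.shape[0]
    n_comp = min(k, 2, settings.max_components)
    theta = np.linspace(0.0, 2.0 * np.pi, 1024, endpoint=False)
    basis = np.vstack([np.sin(theta), np.cos(theta)])  # (2, Nt)
    x = (np.column_stack([b, a]) @ basis).T  # (Nt, K)
    ica = FastICA(
        n_components=n_comp,
        random_state=settings.seed,
        max_iter=settings.max_iter,
        tol=settings.tol,
        whiten="unit-variance",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        sources = ica.fit_transform(x)  # (Nt, M)
    mixing = ica.mixing_  # (K, M)
    # mean removed by FastICA is zero for full periods; project sources
    coef, *_ = np.linalg.lstsq(basis.T, sources, rcond=None)  # (2, M)
    out = []
    for m in range(mixing.shape[1]):
        spatial = mixing[:, m]
        out.append((spatial * coef[1, m], spatial * coef[0, m]))
    return out


def extract_oscillations(
    decomp: SpectralDecomposition,
    n: int,
    coherence_threshold: float = 0.95,
    ica: ICASettings | None = None,
) -> list[CoherentOscillation]:
    """Extract elementary coherent oscillations at grid frequency ``n``.

    If the row's coherence reaches ``coherence_threshold`` the row is a
    single oscillation with amplitude ``rho_n = sqrt(sum_k rho_nk**2)``.
    Otherwise the row is split into phase-shifted components (see
    :class:`ICASettings`), keeping components above the energy floor.  The
    returned total energy never exceeds ``rho_n**2`` beyond roundoff.

    An all-zero row returns an empty list.
    """
    ica = ica or ICASettings()
    a, b = decomp.row(n)
    p = float(np.sum(a * a + b * b))
    if p == 0.0:
        return []
    freq = float(decomp.frequencies[n - 1])
    _, amp = _row_phase_stats(a, b)
    c1f = 2.0 * amp / (p + amp)
    if c1f >= coherence_threshold or decomp.n_channels == 1:
        return [_oscillation_from_row(a, b, freq, c1f, n, 0)]

    if ica.method == "fastica":
        try:
            parts = _split_fastica(a, b, ica)
        except Exception as exc:  # non-convergence or degenerate input
            logger.warning(
                "FastICA failed at %.4f Hz (%s); keeping single oscillation",
                freq,
                exc,
            )
            return [_oscillation_from_row(a, b, freq, c1f, n, 0)]
    elif ica.method == "quadrature_svd":
        parts = _split_quadrature_svd(a, b)
    else:
        raise ValueError(f"unknown split method {ica.method!r}")

    parts = parts[: min(ica.max_components, 2)]
    floor = ica.energy_floor * p
    out = []
    for am, bm in parts:
        energy = float(np.sum(am * am + bm * bm))
        if energy < floor or energy == 0.0:
            continue
        out.append(
            _oscillation_from_row(am, bm, freq, c1f, n, len(out))
        )
    if not out:  # every component under the floor: keep the row whole
        return [_oscillation_from_row(a, b, freq, c1f, n, 0)]
    return out


def extract_all_oscillations(
    decomp: SpectralDecomposition,
    coherence_threshold: float = 0.95,
    ica: ICASettings | None = None,
    power_floor: float = 0.0,
) -> list[CoherentOscillation]:
    """Run :func:`extract_oscillations` over every frequency row.

    ``power_floor`` skips rows whose power ``rho_n**2`` is below the given
    fraction of the strongest row (0 keeps everything non-zero).
    """
    powers = summary_power_spectrum(decomp)
    cutoff = power_floor * float(powers.max(initial=0.0))
    out: list[CoherentOscillation] = []
    for n in range(1, decomp.n_frequencies + 1):
        if powers[n - 1] <= cutoff:
            continue
        out.extend(extract_oscillations(decomp, n, coherence_threshold, ica))
    return out


def summary_power_spectrum(decomp: SpectralDecomposition) -> np.ndarray:
    """Per-frequency power summed over channels: ``P(nu_n) = sum_k rho_nk**2``."""
    return np.sum(
        decomp.cos_coeffs**2 + decomp.sin_coeffs**2, axis=1
    )


def band_power(
    decomp: SpectralDecomposition, low_hz: float, high_hz: float
) -> float:
    """Total ``sum_k rho**2`` within ``[low, high]`` Hz (inclusive)."""
    idx = decomp.band_indices(low_hz, high_hz)
    return float(summary_power_spectrum(decomp)[idx].sum())
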