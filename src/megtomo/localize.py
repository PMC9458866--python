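"""Exhaustive pattern matching on the trial grid and tomogram accumulation.

Every experimental pattern (a signed unit K-vector) is compared against the
full trial-pattern set with the quadratic misfit

    chi(i, j, s, l) = sum_k (trial_k - pattern_k)**2
                    = 2 * (1 - <trial, pattern>)      (both unit norm),

evaluated for both the pattern and its negative — a pattern's sign is
absorbed by a pi phase offset of its oscillation, so only |cosine
similarity| is physically meaningful.  The winning slot indices (I, J, S, L)
give the source cell and moment direction; the oscillation energy ``D**2``
is accumulated into that cell of the functional tomogram.

Determinism: ties are broken by preferring the direct (un-negated) match
and then the lowest slot linear index (I, then J, then S, then L).  Because
trial directions come in antipodal pairs when ``L_max`` is even, a sign-
flipped match at direction ``l`` is the same physical source as a direct
match at ``(l + L_max/2) % L_max``; :func:`canonical_direction` maps both
to one representative for scoring recovered against planted sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GridCoverageError
from .forward import GridSpec, TrialPatternSet
from .spectral import CoherentOscillation

__all__ = [
    "SourceMatch",
    "FunctionalTomogram",
    "match_pattern",
    "match_patterns",
    "build_tomogram",
    "canonical_direction",
]

# relative bias that prefers a direct over a sign-flipped match when the
# two misfits are numerically indistinguishable
_SIGN_TIE_EPS = 1e-12


@dataclass(frozen=True)
class SourceMatch:
    """Best trial-grid match of one experimental pattern."""

    oscillation: CoherentOscillation | None
    grid_index: tuple[int, int, int]   # (I, J, S)
    direction: int                     # L
    chi_min: float
    sign: int                          # +1 direct match, -1 matched -pattern
    energy: float                      # D**2, tesla^2
    n: int = -1                        # 1-based frequency index (fallback)

    @property
    def freq_index(self) -> int:
        if self.oscillation is not None:
            return self.oscillation.freq_index
        if self.n < 1:
            raise ValueError("match has neither an oscillation nor a frequency index")
        return self.n


@dataclass(frozen=True)
class FunctionalTomogram:
    """3-D source-energy volume on the scan grid (tesla^2 per cell)."""

    volume: np.ndarray
    grid: GridSpec
    provenance: dict = field(default_factory=dict)

    @property
    def total_energy(self) -> float:
        return float(self.volume.sum())


def match_patterns(
    patterns: np.ndarray, trials: TrialPatternSet
) -> list[tuple[tuple[int, int, int], int, float, int]]:
    """Match each row of ``patterns`` (M, K) against all trial slots.

    One streamed pass over the (chunk-generated) trial set serves all M
    patterns at once.  Returns per pattern ``((I, J, S), L, chi_min, sign)``.

    Raises
    ------
    GridCoverageError
        If no trial slot is valid.
    """
    p = np.atleast_2d(np.asarray(patterns, dtype=float))
    m = p.shape[0]
    best_score = np.full(m, -np.inf)
    best_slot = np.full(m, -1, dtype=np.int64)
    best_sign = np.ones(m, dtype=np.int64)
    any_valid = False
    for start, chunk, valid in trials.iter_chunks():
        if not np.any(valid):
            continue
        any_valid = True
        sims = p @ chunk[valid].T                       # (M, C_valid)
        # score favors |sim|, with a direct (+) match winning exact ties
        score = np.maximum(sims, -sims * (1.0 - _SIGN_TIE_EPS))
        local = np.argmax(score, axis=1)                # first max = lowest slot
        local_score = score[np.arange(m), local]
        improved = local_score > best_score
        if np.any(improved):
            slot_ids = start + np.flatnonzero(valid)
            rows = np.flatnonzero(improved)
            best_score[rows] = local_score[rows]
            best_slot[rows] = slot_ids[local[rows]]
            best_sign[rows] = np.where(
                sims[rows, local[rows]] >= 0.0, 1, -1
            )
    if not any_valid:
        raise GridCoverageError("no valid trial slots to match against")
    out = []
    ijs, l = trials.decode_slot(best_slot)
    for row in range(m):
        sim = best_score[row] if best_sign[row] > 0 else best_score[row] / (1.0 - _SIGN_TIE_EPS)
        chi = max(0.0, 2.0 * (1.0 - min(1.0, sim)))
        out.append(
            (tuple(int(v) for v in ijs[row]), int(l[row]), float(chi), int(best_sign[row]))
        )
    return out


def match_pattern(
    pattern: np.ndarray,
    trials: TrialPatternSet,
    oscillation: CoherentOscillation | None = None,
) -> SourceMatch:
    """Locate the trial slot minimizing chi for one unit-norm pattern."""
    vec = np.asarray(pattern, dtype=float).reshape(-1)
    nrm = np.linalg.norm(vec)
    if not np.isclose(nrm, 1.0, atol=1e-6):
        raise ValueError("pattern must be unit-norm")
    (ijs, l, chi, sign), = match_patterns(vec[None, :] / nrm, trials)
    energy = oscillation.energy if oscillation is not None else float("nan")
    return SourceMatch(
        oscillation=oscillation,
        grid_index=ijs,
        direction=l,
        chi_min=chi,
        sign=sign,
        energy=energy,
    )


def build_tomogram(
    oscillations: list[CoherentOscillation],
    trials: TrialPatternSet,
    provenance: dict | None = None,
) -> tuple[FunctionalTomogram, list[SourceMatch]]:
    """Match every oscillation and accumulate ``D**2`` per winning cell.

    The sum of the returned volume equals the total matched energy
    ``sum_m D_m**2`` exactly (no normalization is applied).
    """
    if not oscillations:
        raise ValueError("no oscillations to localize")
    patterns = np.stack([osc.pattern for osc in oscillations])
    results = match_patterns(patterns, trials)
    volume = np.zeros(trials.grid.shape, dtype=float)
    matches = []
    for osc, (ijs, l, chi, sign) in zip(oscillations, results):
        volume[ijs] += osc.energy
        matches.append(
            SourceMatch(
                oscillation=osc,
                grid_index=ijs,
                direction=l,
                chi_min=chi,
                sign=sign,
                energy=osc.energy,
                n=osc.freq_index,
            )
        )
    tomo = FunctionalTomogram(
        volume=volume, grid=trials.grid, provenance=dict(provenance or {})
    )
    return tomo, matches


def canonical_direction(l: int, l_max: int) -> int:
    """Representative of the antipodal direction pair ``{l, l + L/2}``.

    A dipole with direction ``l`` and phase ``phi`` is the same source as
    one with the opposite direction and phase ``phi + pi``; for even
    ``l_max`` both map to ``l % (l_max // 2)``.
    """
    if l_max % 2 == 0:
        return int(l) % (l_max // 2)
    return int(l)
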