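"""Stage glue: decompose -> tomogram -> split -> report.

Each stage is a plain function over in-memory objects; the CLI wraps them
with file I/O.  The stages mirror the data flow of the method: spectral
decomposition of the whole record, exhaustive localization of every
elementary oscillation, mask-based frequency classification, and partial
signal/power reporting.
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .forward import GridSpec, SensorArray, build_trial_patterns, fit_sphere_center
from .localize import FunctionalTomogram, SourceMatch, build_tomogram
from .masks import BinaryMask, remove_overlap, resample_mask
from .partial import (
    FrequencyClassification,
    PowerReport,
    classify_frequencies,
    make_power_report,
    reconstruct_partial_signal,
)
from .spectral import (
    CoherentOscillation,
    ICASettings,
    MultichannelRecording,
    SpectralDecomposition,
    compute_spectrum,
    extract_all_oscillations,
)

__all__ = [
    "decompose_stage",
    "tomogram_stage",
    "split_stage",
    "report_stage",
]


def decompose_stage(
    recording: MultichannelRecording, config: PipelineConfig
) -> tuple[SpectralDecomposition, list[CoherentOscillation]]:
    """Whole-record decomposition and oscillation extraction."""
    sp = config.spectral
    decomp = compute_spectrum(recording, sp.nu_max)
    ica = ICASettings(
        method=sp.ica_method,
        energy_floor=sp.ica_energy_floor,
        seed=sp.ica_seed,
    )
    oscillations = extract_all_oscillations(
        decomp,
        coherence_threshold=sp.coherence_threshold,
        ica=ica,
        power_floor=sp.power_floor,
    )
    return decomp, oscillations


def tomogram_stage(
    oscillations: list[CoherentOscillation],
    sensors: SensorArray,
    config: PipelineConfig,
):
    """Exhaustive localization of all oscillations on the scan grid."""
    center = config.grid_center()
    if center is None:
        center = fit_sphere_center(sensors.positions)
    grid = GridSpec.cube(center, config.grid.extent, config.grid.edge_mm / 1000.0)
    trials = build_trial_patterns(
        grid,
        sensors,
        l_max=config.grid.l_max,
        center=center,
        chunk_size=config.grid.chunk_size,
        max_source_radius=config.grid.max_source_radius,
    )
    tomo, matches = build_tomogram(
        oscillations, trials, provenance={"config": config.hash()}
    )
    return tomo, matches, trials


def split_stage(
    decomp: SpectralDecomposition,
    matches: list[SourceMatch],
    brain_mask: BinaryMask,
    nonbrain_mask: BinaryMask,
    grid: GridSpec,
    times: np.ndarray | None = None,
    min_fraction: float | None = None,
):
    """Resample masks to the scan grid, classify, and reconstruct signals.

    Returns ``(classification, signals)`` where ``signals`` maps class name
    to a (K, Nt) partial reconstruction (empty when ``times`` is None).
    """
    on_grid = []
    for mask in (brain_mask, nonbrain_mask):
        if mask.grid is not None and tuple(mask.grid.shape) == tuple(grid.shape):
            on_grid.append(mask)
        else:
            on_grid.append(resample_mask(mask, grid, min_fraction=min_fraction))
    brain_g, nonbrain_g = remove_overlap(on_grid)
    classification = classify_frequencies(
        matches, brain_g, nonbrain_g, decomp.n_frequencies
    )
    signals = {}
    if times is not None:
        for name in ("brain", "nonbrain", "unclassified"):
            signals[name] = reconstruct_partial_signal(
                decomp, classification.indicator(name), times
            )
    return classification, signals


def report_stage(
    decomp: SpectralDecomposition,
    classification: FrequencyClassification,
    config: PipelineConfig,
    truth_regions: dict[int, str] | None = None,
) -> tuple[PowerReport, dict]:
    """Power report plus optional classification accuracy vs. ground truth.

    ``truth_regions`` maps 1-based frequency indices to the true region
    name ("brain" / "nonbrain") of the planted source at that frequency.
    """
    bands = tuple(tuple(b) for b in config.bands)
    report = make_power_report(decomp, classification, bands=bands)
    extra: dict = {"config": config.hash()}
    if truth_regions:
        labels = {"brain": classification.brain, "nonbrain": classification.nonbrain}
        hits = sum(
            int(labels[region][n - 1] == 1)
            for n, region in truth_regions.items()
            if region in labels
        )
        extra["classification_accuracy"] = hits / len(truth_regions)
    return report, extra
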