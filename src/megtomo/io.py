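"""File formats: HDF5 recordings, delimited sensors/tables, NIfTI volumes.

Recording container (HDF5): ``/data`` — (K, Nt) float64 tesla; ``/channels``
— channel id strings; root attrs ``sampling_rate_hz`` and ``duration_s``.
A plain-text alternative for small fixtures holds one sample row per line
(columns = channels) with ``# sampling_rate_hz=...`` and optionally
``# channels=...`` header comments.

Volumes are written as uncompressed NIfTI with affines in millimeters (the
convention NIfTI viewers expect); in memory everything is meters.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .forward import GridSpec, SensorArray
from .localize import FunctionalTomogram, SourceMatch
from .masks import AnnotatedVolume, BinaryMask
from .partial import FrequencyClassification, PowerReport
from .spectral import CoherentOscillation, MultichannelRecording, SpectralDecomposition

__all__ = [
    "save_recording",
    "load_recording",
    "save_sensors",
    "load_sensors",
    "save_spectrum",
    "save_oscillations",
    "load_oscillations",
    "save_annotated_volume",
    "load_annotated_volume",
    "save_mask",
    "load_mask",
    "save_mask_indices",
    "save_tomogram",
    "load_tomogram",
    "save_matches",
    "load_matches",
    "save_classification",
    "save_report",
]


# ---------------------------------------------------------------- recordings

def save_recording(path, recording: MultichannelRecording) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.samples)
        f.create_dataset(
            "channels",
            data=np.array(recording.channel_ids, dtype=h5py.string_dtype()),
        )
        f.attrs["sampling_rate_hz"] = recording.sampling_rate
        f.attrs["duration_s"] = recording.duration


def _load_recording_text(path: Path) -> MultichannelRecording:
    rate = None
    channels: tuple[str, ...] = ()
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition("=")
            key = key.strip()
            if key == "sampling_rate_hz":
                rate = float(value)
            elif key == "channels":
                channels = tuple(v.strip() for v in value.split(","))
    if rate is None:
        raise ValueError(f"{path}: missing '# sampling_rate_hz=' header")
    data = np.loadtxt(path, comments="#", delimiter=None, ndmin=2)
    return MultichannelRecording(
        samples=data.T, sampling_rate=rate, channel_ids=channels
    )


def load_recording(path) -> MultichannelRecording:
    """Load a recording from the HDF5 container or the text fixture format."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            return MultichannelRecording(
                samples=f["data"][()],
                sampling_rate=float(f.attrs["sampling_rate_hz"]),
                channel_ids=tuple(c.decode() if isinstance(c, bytes) else str(c)
                                  for c in f["channels"][()]),
            )
    return _load_recording_text(path)


# ------------------------------------------------------------------- sensors

def save_sensors(path, sensors: SensorArray) -> None:
    df = pd.DataFrame(
        {
            "channel_id": sensors.channel_ids,
            "x": sensors.positions[:, 0],
            "y": sensors.positions[:, 1],
            "z": sensors.positions[:, 2],
            "ox": sensors.orientations[:, 0],
            "oy": sensors.orientations[:, 1],
            "oz": sensors.orientations[:, 2],
        }
    )
    df.to_csv(path, index=False)


def load_sensors(path) -> SensorArray:
    df = pd.read_csv(path)
    return SensorArray(
        positions=df[["x", "y", "z"]].to_numpy(float),
        orientations=df[["ox", "oy", "oz"]].to_numpy(float),
        channel_ids=tuple(df["channel_id"].astype(str)),
    )


# ------------------------------------------------------------------- spectra

def save_spectrum(path, decomp: SpectralDecomposition) -> None:
    """Long-format CSV: frequency_hz, channel_id, a, b, rho, phi."""
    n, k = decomp.cos_coeffs.shape
    rho = decomp.amplitudes
    phi = decomp.phases
    df = pd.DataFrame(
        {
            "frequency_hz": np.repeat(decomp.frequencies, k),
            "channel_id": np.tile(np.asarray(decomp.channel_ids), n),
            "a": decomp.cos_coeffs.ravel(),
            "b": decomp.sin_coeffs.ravel(),
            "rho": rho.ravel(),
            "phi": phi.ravel(),
        }
    )
    df.to_csv(path, index=False)


def save_oscillations(path, oscillations: list[CoherentOscillation],
                      channel_ids: tuple[str, ...]) -> None:
    """Wide CSV: one row per oscillation, pattern entries as pat_<channel>."""
    rows = []
    for osc in oscillations:
        row = {
            "n": osc.freq_index,
            "m": osc.component_index,
            "frequency_hz": osc.frequency,
            "amplitude": osc.amplitude,
            "phase": osc.phase,
            "coherence": osc.coherence,
        }
        row.update({f"pat_{cid}": v for cid, v in zip(channel_ids, osc.pattern)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_oscillations(path) -> list[CoherentOscillation]:
    df = pd.read_csv(path)
    pat_cols = [c for c in df.columns if c.startswith("pat_")]
    out = []
    for _, row in df.iterrows():
        out.append(
            CoherentOscillation(
                frequency=float(row["frequency_hz"]),
                amplitude=float(row["amplitude"]),
                phase=float(row["phase"]),
                pattern=row[pat_cols].to_numpy(float),
                coherence=float(row["coherence"]),
                freq_index=int(row["n"]),
                component_index=int(row["m"]),
            )
        )
    return out


# ------------------------------------------------------------------- volumes

def _nifti_affine_mm(affine_m: np.ndarray) -> np.ndarray:
    aff = affine_m.copy()
    aff[:3] *= 1000.0
    return aff


def _affine_m(img) -> np.ndarray:
    aff = np.asarray(img.affine, dtype=float).copy()
    aff[:3] /= 1000.0
    return aff


def save_annotated_volume(path, volume: AnnotatedVolume) -> None:
    img = nib.Nifti1Image(
        volume.labels.astype(np.int16), _nifti_affine_mm(volume.affine)
    )
    nib.save(img, str(path))


def load_annotated_volume(path) -> AnnotatedVolume:
    img = nib.load(str(path))
    return AnnotatedVolume(
        labels=np.asarray(img.dataobj, dtype=np.int64), affine=_affine_m(img)
    )


def save_mask(path, mask: BinaryMask) -> None:
    img = nib.Nifti1Image(
        mask.volume.astype(np.uint8), _nifti_affine_mm(mask.affine)
    )
    img.header["descrip"] = mask.name.encode()[:79]
    nib.save(img, str(path))


def load_mask(path, name: str | None = None, grid: GridSpec | None = None) -> BinaryMask:
    img = nib.load(str(path))
    label = name or img.header["descrip"].tobytes().split(b"\x00")[0].decode() or "region"
    return BinaryMask(
        volume=np.asarray(img.dataobj) > 0,
        name=label,
        affine=_affine_m(img),
        grid=grid,
    )


def save_mask_indices(path, mask: BinaryMask) -> None:
    """Index form of a mask: CSV with ordinal, I, J, S."""
    idx = mask.index_set
    ijs = np.stack(np.unravel_index(idx, mask.volume.shape), axis=-1)
    pd.DataFrame(
        {"ordinal": idx, "I": ijs[:, 0], "J": ijs[:, 1], "S": ijs[:, 2]}
    ).to_csv(path, index=False)


def save_tomogram(path, tomogram: FunctionalTomogram) -> None:
    img = nib.Nifti1Image(
        tomogram.volume.astype(np.float32),
        _nifti_affine_mm(tomogram.grid.affine("m")),
    )
    nib.save(img, str(path))


def load_tomogram(path, grid: GridSpec) -> FunctionalTomogram:
    img = nib.load(str(path))
    return FunctionalTomogram(
        volume=np.asarray(img.dataobj, dtype=float), grid=grid
    )


# ----------------------------------------------------------- tables and json

def save_matches(path, matches: list[SourceMatch]) -> None:
    rows = []
    for match in matches:
        osc = match.oscillation
        rows.append(
            {
                "frequency_hz": osc.frequency if osc else np.nan,
                "n": osc.freq_index if osc else match.n,
                "m": osc.component_index if osc else -1,
                "I": match.grid_index[0],
                "J": match.grid_index[1],
                "S": match.grid_index[2],
                "L": match.direction,
                "chi_min": match.chi_min,
                "sign": match.sign,
                "energy": match.energy,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_matches(path, oscillations: list[CoherentOscillation] | None = None
                 ) -> list[SourceMatch]:
    """Load a match table; re-attaches oscillations by (n, m) when given."""
    df = pd.read_csv(path)
    lookup = {}
    if oscillations:
        lookup = {(o.freq_index, o.component_index): o for o in oscillations}
    out = []
    for _, row in df.iterrows():
        out.append(
            SourceMatch(
                oscillation=lookup.get((int(row["n"]), int(row["m"]))),
                grid_index=(int(row["I"]), int(row["J"]), int(row["S"])),
                direction=int(row["L"]),
                chi_min=float(row["chi_min"]),
                sign=int(row["sign"]),
                energy=float(row["energy"]),
                n=int(row["n"]),
            )
        )
    return out


def save_classification(path, classification: FrequencyClassification,
                        decomp: SpectralDecomposition,
                        matches: list[SourceMatch] | None = None) -> None:
    """CSV: frequency_hz, class, I, J, S, L, energy (match columns NaN when
    a frequency had no localized oscillation)."""
    best: dict[int, SourceMatch] = {}
    for match in matches or []:
        n = match.freq_index
        if n not in best or match.energy > best[n].energy:
            best[n] = match
    labels = np.where(
        classification.brain == 1,
        "brain",
        np.where(classification.nonbrain == 1, "nonbrain", "unclassified"),
    )
    rows = []
    for n in range(1, decomp.n_frequencies + 1):
        match = best.get(n)
        rows.append(
            {
                "frequency_hz": decomp.frequencies[n - 1],
                "class": labels[n - 1],
                "I": match.grid_index[0] if match else np.nan,
                "J": match.grid_index[1] if match else np.nan,
                "S": match.grid_index[2] if match else np.nan,
                "L": match.direction if match else np.nan,
                "energy": match.energy if match else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def save_report(path, report: PowerReport, extra: dict | None = None) -> None:
    payload = report.as_dict()
    payload.update(extra or {})

    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(type(obj).__name__)

    with open(path, "w") as f:
        json.dump(payload, f, indent=2, default=_default)
        f.write("\n")


def save_grid(path, grid: GridSpec, l_max: int, center: np.ndarray,
              meta: dict | None = None) -> None:
    payload = {
        "origin_m": grid.origin.tolist(),
        "shape": list(grid.shape),
        "edge_m": grid.edge,
        "l_max": l_max,
        "center_m": np.asarray(center, float).tolist(),
    }
    payload.update(meta or {})
    with open(path, "w") as f:
        json.dump(payload, f, indent=2)
        f.write("\n")


def load_grid(path) -> tuple[GridSpec, int, np.ndarray, dict]:
    with open(path) as f:
        payload = json.load(f)
    grid = GridSpec(
        origin=np.asarray(payload["origin_m"]),
        shape=tuple(payload["shape"]),
        edge=float(payload["edge_m"]),
    )
    meta = {k: v for k, v in payload.items()
            if k not in {"origin_m", "shape", "edge_m", "l_max", "center_m"}}
    return grid, int(payload["l_max"]), np.asarray(payload["center_m"]), meta
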