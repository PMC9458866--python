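"""Current-dipole forward model in a spherical conductor, and trial patterns.

The magnetic field of a current dipole ``Q`` at ``r0`` inside a homogeneous
conducting sphere is evaluated with the closed-form single-shell solution

    B(r) = -mu0 * grad U(r),
    U(r) = -(1/4pi) * (Q x r0) . r / F,
    F    = a * (a*r + r**2 - r0 . r),   a = |r - r0|,

where positions are taken relative to the sphere center.  Radial dipoles
(``Q`` parallel to ``r0``) and dipoles at the center are magnetically
silent: they produce no field outside the sphere.  Only the two tangential
moment components are therefore scanned when building trial patterns.

Trial patterns are the sensor-space fingerprints of unit dipoles placed at
the centers of a regular cubic grid, with ``L_max`` moment directions per
cell spaced ``360/L_max`` degrees apart in the plane orthogonal to the cell
radius.  Pattern sets are generated in chunks and never materialized whole:
the production-scale grid (25 cm cube, 2 mm edge, 24 directions) enumerates
46,875,000 slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .exceptions import FieldPointError, GridCoverageError

MU0 = 4.0e-7 * np.pi  # vacuum permeability, T*m/A

__all__ = [
    "SensorArray",
    "CurrentDipole",
    "GridSpec",
    "TrialPatternSet",
    "dipole_field",
    "sensor_reading",
    "build_trial_patterns",
    "fit_sphere_center",
    "tangential_directions",
]


@dataclass(frozen=True)
class SensorArray:
    """Point-magnetometer array: positions and unit orientations, head frame.

    Physical gradiometer coil geometry is not modeled; each channel reads
    the field component along its orientation at its position.
    """

    positions: np.ndarray        # (K, 3) meters
    orientations: np.ndarray     # (K, 3) unit vectors
    channel_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        ori = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if pos.shape != ori.shape or pos.shape[1] != 3:
            raise ValueError("positions and orientations must both be (K, 3)")
        norms = np.linalg.norm(ori, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("orientations must be unit vectors")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        if not self.channel_ids:
            ids = tuple(f"MEG{i:03d}" for i in range(pos.shape[0]))
            object.__setattr__(self, "channel_ids", ids)
        elif len(self.channel_ids) != pos.shape[0]:
            raise ValueError("channel_ids length must equal K")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class CurrentDipole:
    """A current dipole: position (head frame, meters) and moment (A*m)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )
        object.__setattr__(
            self, "moment", np.asarray(self.moment, dtype=float).reshape(3)
        )
        if not (np.all(np.isfinite(self.position)) and np.all(np.isfinite(self.moment))):
            raise ValueError("dipole position and moment must be finite")


def fit_sphere_center(positions: np.ndarray) -> np.ndarray:
    """Least-squares sphere fit to points -> center (3,).

    Solves the algebraic fit ``|x|**2 = 2 c . x + (R**2 - |c|**2)``.
    """
    x = np.asarray(positions, dtype=float)
    a = np.column_stack([2.0 * x, np.ones(len(x))])
    rhs = np.sum(x * x, axis=1)
    sol, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    return sol[:3]


def _field_batch(
    r0: np.ndarray,      # (C, 3) dipole positions relative to sphere center
    q: np.ndarray,       # (C, 3) moments, A*m
    points: np.ndarray,  # (K, 3) field points relative to sphere center
) -> np.ndarray:
    """Vectorized single-shell field -> (C, K, 3) tesla.

    Degenerate geometry (F == 0) yields zero field for that pair rather
    than raising; scalar entry points validate and raise instead.
    """
    r = points[None, :, :]                        # (1, K, 3)
    a_vec = r - r0[:, None, :]                    # (C, K, 3)
    a = np.linalg.norm(a_vec, axis=2)             # (C, K)
    rn = np.linalg.norm(points, axis=1)[None, :]  # (1, K)
    r0_dot_r = r0 @ points.T                      # (C, K)
    a_dot_r = np.einsum("ckj,kj->ck", a_vec, points)
    f = a * (a * rn + rn**2 - r0_dot_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_a = np.where(a > 0, 1.0 / a, 0.0)
        c1 = a**2 / np.where(rn > 0, rn, np.inf) + a_dot_r * inv_a + 2.0 * a + 2.0 * rn
        c2 = a + 2.0 * rn + a_dot_r * inv_a
    grad_f = c1[:, :, None] * r - c2[:, :, None] * r0[:, None, :]
    qxr0 = np.cross(q, r0)                        # (C, 3)
    qxr0_dot_r = np.einsum("cj,kj->ck", qxr0, points)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_f2 = np.where(np.abs(f) > 0, 1.0 / f**2, 0.0)
    b = (MU0 / (4.0 * np.pi)) * inv_f2[:, :, None] * (
        f[:, :, None] * qxr0[:, None, :] - qxr0_dot_r[:, :, None] * grad_f
    )
    return np.where(np.isfinite(b), b, 0.0)


def dipole_field(
    dipole: CurrentDipole,
    point: np.ndarray,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Magnetic field (tesla) of a dipole at one exterior point.

    ``center`` is the conductor sphere center in the head frame (default:
    origin).  Raises :class:`FieldPointError` when the geometry is
    degenerate (``F -> 0``: field point on the dipole or approaching the
    axis degeneracy of the potential).
    """
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    r0 = (dipole.position - c)[None, :]
    r = (np.asarray(point, dtype=float).reshape(3) - c)[None, :]
    a_vec = r - r0
    a = float(np.linalg.norm(a_vec))
    rn = float(np.linalg.norm(r))
    f = a * (a * rn + rn**2 - float(np.dot(r0[0], r[0])))
    scale = max(rn, float(np.linalg.norm(r0)), 1e-30) ** 3
    if abs(f) < 1e-12 * scale:
        raise FieldPointError("degenerate field point: F -> 0")
    return _field_batch(r0, dipole.moment[None, :], r)[0, 0]


def sensor_reading(
    dipole: CurrentDipole,
    sensors: SensorArray,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Project the dipole field onto each sensor orientation -> (K,) tesla."""
    c = fit_sphere_center(sensors.positions) if center is None else np.asarray(center, float)
    b = _field_batch(
        (dipole.position - c)[None, :],
        dipole.moment[None, :],
        sensors.positions - c,
    )[0]
    return np.einsum("kj,kj->k", b, sensors.orientations)


@dataclass(frozen=True)
class GridSpec:
    """Regular cubic source grid.

    Cell ``(i, j, s)`` has its center at ``origin + (index + 0.5) * edge``;
    indices are 0-based, coordinates are meters in the head frame.
    """

    origin: np.ndarray          # (3,) meters, low corner
    shape: tuple[int, int, int]
    edge: float                 # meters

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "origin", np.asarray(self.origin, dtype=float).reshape(3)
        )
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if any(v < 1 for v in self.shape) or self.edge <= 0:
            raise ValueError("grid shape must be positive and edge > 0")

    @classmethod
    def cube(cls, center: np.ndarray, extent: float, edge: float) -> "GridSpec":
        """Cube of side ``extent`` centered on ``center``."""
        n = int(round(extent / edge))
        c = np.asarray(center, dtype=float).reshape(3)
        return cls(origin=c - extent / 2.0, shape=(n, n, n), edge=edge)

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.shape, dtype=float) * self.edge

    def cell_centers(self, flat_index: np.ndarray) -> np.ndarray:
        """Centers of cells given flat C-order cell indices -> (n, 3)."""
        idx = np.asarray(flat_index, dtype=np.int64)
        ijs = np.stack(np.unravel_index(idx, self.shape), axis=-1)
        return self.origin + (ijs + 0.5) * self.edge

    def index_of(self, points: np.ndarray) -> np.ndarray:
        """Cell (i, j, s) indices containing each point -> (n, 3) int."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((p - self.origin) / self.edge).astype(np.int64)

    def affine(self, units: str = "m") -> np.ndarray:
        """Voxel-index -> world affine (4x4); ``units`` 'm' or 'mm'."""
        scale = 1000.0 if units == "mm" else 1.0
        aff = np.eye(4)
        aff[:3, :3] = np.eye(3) * self.edge * scale
        aff[:3, 3] = (self.origin + 0.5 * self.edge) * scale
        return aff


def tangential_directions(r_vec: np.ndarray, l_max: int) -> np.ndarray | None:
    """``l_max`` unit directions in the plane orthogonal to ``r_vec``.

    The first direction is the normalized projection of global +x onto the
    tangential plane (+y when +x is degenerate); direction ``l`` is rotated
    ``360 * l / l_max`` degrees about ``r_vec``.  Returns None when
    ``|r_vec|`` is too small to define the plane.
    """
    r = np.asarray(r_vec, dtype=float).reshape(3)
    rn = np.linalg.norm(r)
    if rn < 1e-12:
        return None
    rhat = r / rn
    e1 = np.array([1.0, 0.0, 0.0]) - rhat[0] * rhat
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.array([0.0, 1.0, 0.0]) - rhat[1] * rhat
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(rhat, e1)
    angles = 2.0 * np.pi * np.arange(l_max) / l_max
    return np.cos(angles)[:, None] * e1 + np.sin(angles)[:, None] * e2


@dataclass(frozen=True)
class TrialPatternSet:
    """Lazily generated set of normalized trial patterns.

    One slot per (cell, direction); slot linear index is
    ``cell_flat * l_max + l`` so the scan order is I, then J, then S, then
    L.  Patterns are unit-norm signed K-vectors of the sensor readings of a
    unit tangential dipole at the cell center.  Slots whose raw field norm
    falls below ``norm_tol`` (per A*m) — e.g. at the conductor center —
    are invalid.
    """

    grid: GridSpec
    sensors: SensorArray
    l_max: int
    center: np.ndarray               # conductor sphere center, head frame
    chunk_size: int = 8192           # slots per generated chunk
    norm_tol: float = 1e-13          # tesla per A*m
    max_source_radius: float | None = None  # restrict slots to the conductor

    def __post_init__(self) -> None:
        if self.l_max < 2:
            raise ValueError("l_max must be >= 2")
        object.__setattr__(
            self, "center", np.asarray(self.center, dtype=float).reshape(3)
        )

    @property
    def n_slots(self) -> int:
        """Total slot count, computed without materializing any pattern."""
        return self.grid.n_cells * self.l_max

    def slot_index(self, i: int, j: int, s: int, l: int) -> int:
        cell = int(np.ravel_multi_index((i, j, s), self.grid.shape))
        return cell * self.l_max + l

    def decode_slot(self, linear: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linear slot indices -> ((n, 3) cell indices, (n,) direction l)."""
        lin = np.asarray(linear, dtype=np.int64)
        cell, l = np.divmod(lin, self.l_max)
        ijs = np.stack(np.unravel_index(cell, self.grid.shape), axis=-1)
        return ijs, l

    def _chunk(self, start: int, stop: int) -> tuple[np.ndarray, np.ndarray]:
        """Patterns and validity for slots [start, stop)."""
        lin = np.arange(start, stop, dtype=np.int64)
        cell, l = np.divmod(lin, self.l_max)
        centers = self.grid.cell_centers(cell) - self.center
        rn = np.linalg.norm(centers, axis=1)
        ok = rn >= 1e-12
        if self.max_source_radius is not None:
            # the single-shell model describes sources inside the conductor;
            # cells beyond it yield nonphysical patterns and can be excluded
            ok &= rn <= self.max_source_radius
        dirs = np.zeros_like(centers)
        if np.any(ok):
            rhat = centers[ok] / rn[ok, None]
            e1 = np.zeros_like(rhat)
            e1[:, 0] = 1.0
            e1 -= rhat[:, 0:1] * rhat
            degen = np.linalg.norm(e1, axis=1) < 1e-6
            if np.any(degen):
                e1[degen] = 0.0
                e1[degen, 1] = 1.0
                e1[degen] -= rhat[degen, 1:2] * rhat[degen]
            e1 /= np.linalg.norm(e1, axis=1)[:, None]
            e2 = np.cross(rhat, e1)
            ang = 2.0 * np.pi * l[ok] / self.l_max
            dirs[ok] = np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2
        b = _field_batch(centers, dirs, self.sensors.positions - self.center)
        readings = np.einsum("ckj,kj->ck", b, self.sensors.orientations)
        norms = np.linalg.norm(readings, axis=1)
        valid = ok & (norms >= self.norm_tol)
        patterns = np.zeros_like(readings)
        patterns[valid] = readings[valid] / norms[valid, None]
        return patterns, valid

    def iter_chunks(self) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
        """Yield ``(start_slot, patterns (C, K), valid (C,))`` chunks."""
        total = self.n_slots
        if total == 0:
            raise GridCoverageError("empty trial grid")
        for start in range(0, total, self.chunk_size):
            stop = min(start + self.chunk_size, total)
            patterns, valid = self._chunk(start, stop)
            yield start, patterns, valid

    def pattern_at(self, i: int, j: int, s: int, l: int) -> np.ndarray:
        """Single trial pattern (zeros if the slot is invalid)."""
        lin = self.slot_index(i, j, s, l)
        patterns, _ = self._chunk(lin, lin + 1)
        return patterns[0]

    def direction_vector(self, i: int, j: int, s: int, l: int) -> np.ndarray:
        """Unit moment direction of slot (i, j, s, l)."""
        cell = np.ravel_multi_index((i, j, s), self.grid.shape)
        center = self.grid.cell_centers(np.array([cell]))[0] - self.center
        dirs = tangential_directions(center, self.l_max)
        if dirs is None:
            raise GridCoverageError("direction undefined at the sphere center")
        return dirs[l]


def build_trial_patterns(
    grid: GridSpec,
    sensors: SensorArray,
    l_max: int = 24,
    center: np.ndarray | None = None,
    chunk_size: int = 8192,
    norm_tol: float = 1e-13,
    max_source_radius: float | None = None,
) -> TrialPatternSet:
    """Construct the (lazy) trial-pattern set for a grid and sensor array.

    ``center`` defaults to a least-squares sphere fit of the sensor
    positions.  ``max_source_radius`` optionally invalidates cells outside
    the conductor sphere (by default the whole grid is scanned with no
    condition, which admits nonphysical exterior cells).  Raises :class:`GridCoverageError` when
    the grid lies entirely outside sensor coverage.
    """
    c = fit_sphere_center(sensors.positions) if center is None else np.asarray(center, float)
    trials = TrialPatternSet(
        grid=grid,
        sensors=sensors,
        l_max=l_max,
        center=c,
        chunk_size=chunk_size,
        norm_tol=norm_tol,
        max_source_radius=max_source_radius,
    )
    # cheap coverage sanity check: grid center vs. sensor cloud extent
    sensor_span = np.linalg.norm(sensors.positions - c, axis=1).max()
    grid_center = grid.origin + grid.extent / 2.0
    if np.linalg.norm(grid_center - c) > 10.0 * sensor_span:
        raise GridCoverageError("source grid lies far outside sensor coverage")
    return trials
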