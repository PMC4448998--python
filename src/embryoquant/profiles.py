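"""Spatial summarization of calibrated recordings into expression profiles.

A time-normalized calibrated series is reduced to one of several tensors
on the canonical 101-point normalized time grid:

* **T** -- total in-shell signal per time point;
* **APT** -- signal in 20 equal-width slices along the anterior-posterior
  axis (the shell ellipsoid's major axis) per time point;
* **DVT** / **LRT** -- the same binning along the dorsal-ventral or
  left-right axis of the founder-cell coordinate frame;
* **XYZ** -- signal accumulated into a regular grid of cubes aligned
  with the founder-cell frame.

All reductions integrate only over the shell and conserve total signal:
summing the spatial axes of any profile reproduces T at every time
point.  Binning is by voxel center; bins are half-open ``[a, b)`` with
the final bin closed, and voxels projecting outside the binned extent
are assigned to the nearest end bin so no signal is lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ShellAnnotation, VoxelGrid, make_shell_mask
from .reconstruction import CalibratedSeries
from .timenorm import TIME_GRID

__all__ = [
    "ProfileConfig",
    "CoordinateFrame",
    "ExpressionProfile",
    "extract_T",
    "extract_APT",
    "build_xyz_frame",
    "extract_XYZ",
    "extract_axis_profile",
]


@dataclass(frozen=True)
class ProfileConfig:
    """Parameters of the spatial reductions.

    ``apt_slices`` slices along a body axis; ``cube_voxels`` is the cube
    edge in recording voxels (XY pitch) for the XYZ grid;
    ``frame_enlargement`` enlarges the founder-frame extent so the cube
    grid covers the whole embryo.
    """

    apt_slices: int = 20
    cube_voxels: int = 20
    frame_enlargement: float = 0.35
    time_grid: np.ndarray = field(default_factory=lambda: TIME_GRID.copy())

    def __post_init__(self) -> None:
        if self.apt_slices < 1 or self.cube_voxels < 1:
            raise ValueError("apt_slices and cube_voxels must be >= 1")
        if not (0 <= self.frame_enlargement <= 1):
            raise ValueError("frame_enlargement must be in [0, 1]")


@dataclass(frozen=True)
class CoordinateFrame:
    """Embryo coordinate frame fixed by the four founder blastomeres.

    Origin at the founder centroid; AP from ABa toward P2; DV from EMS
    toward ABp (orthogonalized against AP); LR completes a right-handed
    triple.  ``extent_um`` is the cube-grid extent per axis.
    """

    origin: np.ndarray
    ap_axis: np.ndarray
    dv_axis: np.ndarray
    lr_axis: np.ndarray
    extent_um: float

    def __post_init__(self) -> None:
        axes = np.stack([self.ap_axis, self.dv_axis, self.lr_axis])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(axes) < 0:
            raise ValueError("frame axes must be right-handed")

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """World (x, y, z) um -> frame coordinates (ap, dv, lr) um."""
        p = np.asarray(points, dtype=float) - self.origin
        return p @ np.stack([self.ap_axis, self.dv_axis, self.lr_axis]).T


@dataclass
class ExpressionProfile:
    """An expression summary tensor on the normalized time grid.

    ``values`` axes by kind: T ``[time]``; APT/DVT/LRT ``[time, bins]``;
    XYZ ``[time, nap, ndv, nlr]``; SC ``[cell, time]`` (with ``cells``
    labels).  ``valid`` marks grid points covered by the recording;
    uncovered points are zero-padded.
    """

    kind: str
    time_grid: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    recording_id: str = "recording"
    gene_label: str = ""
    cells: list[str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("T", "APT", "XYZ", "DVT", "LRT", "SC"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if (np.asarray(self.values) < -1e-12).any():
            raise ValueError("profile values must be non-negative")

    def total_over_space(self) -> np.ndarray:
        """Collapse spatial/cell axes to a T-like series over the time grid."""
        v = np.asarray(self.values)
        if self.kind == "T":
            return v.copy()
        if self.kind == "SC":
            return v.sum(axis=0)
        return v.reshape(v.shape[0], -1).sum(axis=1)


def _resample_to_grid(
    times: np.ndarray, values: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly resample per-stack values (time on axis 0) onto the grid.

    Grid points outside the recording span are zero and flagged invalid.
    """
    times = np.asarray(times, dtype=float)
    flat = values.reshape(values.shape[0], -1)
    out = np.empty((grid.size, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(grid, times, flat[:, j])
    valid = (grid >= times[0] - 1e-9) & (grid <= times[-1] + 1e-9)
    out[~valid] = 0.0
    return out.reshape((grid.size,) + values.shape[1:]), valid


def _require_normalized(series: CalibratedSeries) -> None:
    if not series.normalized:
        raise ValueError("series must be time-normalized before profile extraction")


def extract_T(
    series: CalibratedSeries,
    mask: np.ndarray | None = None,
    config: ProfileConfig = ProfileConfig(),
    recording_id: str = "recording",
    gene_label: str = "",
) -> ExpressionProfile:
    """Total in-shell signal over time."""
    _require_normalized(series)
    if mask is None:
        mask = series.mask
    totals = np.array([v[mask].sum() for v in series.volumes])
    vals, valid = _resample_to_grid(series.times, totals[:, None], config.time_grid)
    return ExpressionProfile(
        kind="T",
        time_grid=config.time_grid.copy(),
        values=vals[:, 0],
        valid=valid,
        recording_id=recording_id,
        gene_label=gene_label,
    )


def _bin_indices(coords: np.ndarray, lo: float, hi: float, n_bins: int) -> np.ndarray:
    """Half-open equal-width bins over [lo, hi); last bin closed; clamped to ends."""
    width = (hi - lo) / n_bins
    idx = np.floor((coords - lo) / width).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _binned_profile(
    series: CalibratedSeries,
    mask: np.ndarray,
    coords: np.ndarray,
    lo: float,
    hi: float,
    kind: str,
    config: ProfileConfig,
    recording_id: str,
    gene_label: str,
) -> ExpressionProfile:
    n_bins = config.apt_slices
    idx = _bin_indices(coords, lo, hi, n_bins)
    per_stack = np.empty((len(series), n_bins))
    for t, vol in enumerate(series.volumes):
        per_stack[t] = np.bincount(idx, weights=vol[mask], minlength=n_bins)
    vals, valid = _resample_to_grid(series.times, per_stack, config.time_grid)
    return ExpressionProfile(
        kind=kind,
        time_grid=config.time_grid.copy(),
        values=vals,
        valid=valid,
        recording_id=recording_id,
        gene_label=gene_label,
    )


def extract_APT(
    series: CalibratedSeries,
    mask: np.ndarray | None = None,
    shell: ShellAnnotation | None = None,
    config: ProfileConfig = ProfileConfig(),
    anterior_hint: np.ndarray | None = None,
    recording_id: str = "recording",
    gene_label: str = "",
) -> ExpressionProfile:
    """Signal in equal-width slices along the AP (major ellipsoid) axis over time.

    ``anterior_hint`` (e.g. the ABa founder position) orients the axis so
    that bin 0 is anterior; without it the annotated axis orientation is
    used as-is.
    """
    _require_normalized(series)
    shell = shell if shell is not None else series.shell
    if mask is None:
        mask = make_shell_mask(shell, series.grid)
    axis, semi_len = shell.major_axis()
    if anterior_hint is not None:
        # anterior end should project lower than the center
        if np.dot(np.asarray(anterior_hint) - np.asarray(shell.center), axis) > 0:
            axis = -axis
    centers = series.grid.voxel_centers()[mask]
    proj = (centers - np.asarray(shell.center)) @ axis
    return _binned_profile(
        series, mask, proj, -semi_len, semi_len, "APT", config, recording_id, gene_label
    )


def build_xyz_frame(
    founders: dict[str, np.ndarray],
    config: ProfileConfig = ProfileConfig(),
) -> CoordinateFrame:
    """Coordinate frame from the four founder positions.

    The frame extent is the larger of |EMS-ABp| and |ABa-P2|, enlarged by
    ``frame_enlargement`` to cover the embryo.
    """
    required = ("ABa", "ABp", "EMS", "P2")
    missing = [n for n in required if n not in founders]
    if missing:
        raise KeyError(f"missing founder positions: {missing}")
    pts = {n: np.asarray(founders[n], dtype=float) for n in required}
    origin = np.mean(list(pts.values()), axis=0)
    ap = pts["P2"] - pts["ABa"]
    ap_norm = np.linalg.norm(ap)
    if ap_norm == 0:
        raise ValueError("ABa and P2 coincide")
    ap = ap / ap_norm
    dv_raw = pts["ABp"] - pts["EMS"]
    dv = dv_raw - np.dot(dv_raw, ap) * ap
    dv_norm = np.linalg.norm(dv)
    if dv_norm < 1e-9:
        raise ValueError("founders are collinear; DV axis is degenerate")
    dv = dv / dv_norm
    lr = np.cross(ap, dv)
    extent = max(np.linalg.norm(dv_raw), np.linalg.norm(pts["P2"] - pts["ABa"]))
    extent *= 1 + config.frame_enlargement
    return CoordinateFrame(origin=origin, ap_axis=ap, dv_axis=dv, lr_axis=lr, extent_um=extent)


def extract_XYZ(
    series: CalibratedSeries,
    mask: np.ndarray | None = None,
    frame: CoordinateFrame | None = None,
    config: ProfileConfig = ProfileConfig(),
    recording_id: str = "recording",
    gene_label: str = "",
) -> ExpressionProfile:
    """Signal accumulated into founder-frame-aligned cubes over time.

    Cube edge is ``cube_voxels`` recording voxels at the XY pitch; the
    cube grid spans the frame extent centered on the frame origin.
    """
    _require_normalized(series)
    if frame is None:
        raise ValueError("extract_XYZ requires a founder coordinate frame")
    if mask is None:
        mask = series.mask
    cube_edge = config.cube_voxels * series.grid.voxel_size_um[0]
    n_cubes = max(1, int(np.ceil(frame.extent_um / cube_edge)))
    half = frame.extent_um / 2.0
    centers = series.grid.voxel_centers()[mask]
    fc = frame.to_frame(centers)  # (n, 3): ap, dv, lr
    idx3 = np.stack(
        [_bin_indices(fc[:, i], -half, half, n_cubes) for i in range(3)], axis=1
    )
    flat_idx = (idx3[:, 0] * n_cubes + idx3[:, 1]) * n_cubes + idx3[:, 2]
    per_stack = np.empty((len(series), n_cubes, n_cubes, n_cubes))
    for t, vol in enumerate(series.volumes):
        per_stack[t] = np.bincount(
            flat_idx, weights=vol[mask], minlength=n_cubes**3
        ).reshape(n_cubes, n_cubes, n_cubes)
    vals, valid = _resample_to_grid(series.times, per_stack, config.time_grid)
    return ExpressionProfile(
        kind="XYZ",
        time_grid=config.time_grid.copy(),
        values=vals,
        valid=valid,
        recording_id=recording_id,
        gene_label=gene_label,
    )


def extract_axis_profile(
    series: CalibratedSeries,
    axis: str,
    mask: np.ndarray | None = None,
    frame: CoordinateFrame | None = None,
    config: ProfileConfig = ProfileConfig(),
    recording_id: str = "recording",
    gene_label: str = "",
) -> ExpressionProfile:
    """DVT or LRT: slices along the frame's DV or LR axis over time."""
    _require_normalized(series)
    if frame is None:
        raise ValueError("axis profiles require a founder coordinate frame")
    if axis not in ("DV", "LR"):
        raise ValueError("axis must be 'DV' or 'LR'")
    if mask is None:
        mask = series.mask
    direction = frame.dv_axis if axis == "DV" else frame.lr_axis
    half = frame.extent_um / 2.0
    centers = series.grid.voxel_centers()[mask]
    proj = (centers - frame.origin) @ direction
    return _binned_profile(
        series, mask, proj, -half, half, axis + "T", config, recording_id, gene_label
    )
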