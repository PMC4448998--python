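"""Voxel-grid geometry and the ellipsoidal embryo shell.

Conventions used throughout the package:

* Image volumes are numpy arrays indexed ``[z, y, x]`` with 0-based voxel
  indices.
* The physical position of voxel ``(iz, iy, ix)`` is its *center*,
  ``((ix + 0.5) * dx, (iy + 0.5) * dy, (iz + 0.5) * dz)`` in micrometres,
  where ``(dx, dy, dz)`` is the voxel pitch.  Z is typically sampled much
  more coarsely than X/Y.
* Physical 3D points are ``(x, y, z)`` float arrays in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "ShellAnnotation", "make_shell_mask"]


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of an image volume: array shape plus physical voxel pitch.

    Parameters
    ----------
    shape
        Array shape ``(nz, ny, nx)``.
    voxel_size_um
        Physical pitch ``(dx, dy, dz)`` in micrometres.  The default
        0.2 x 0.2 x 1.0 um mirrors a high-NA camera pixel with coarse
        optical sectioning in Z.
    """

    shape: tuple[int, int, int]
    voxel_size_um: tuple[float, float, float] = (0.2, 0.2, 1.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")

    @property
    def n_voxels(self) -> int:
        nz, ny, nx = self.shape
        return nz * ny * nx

    def voxel_centers(self) -> np.ndarray:
        """Physical centers of every voxel, shape ``(nz, ny, nx, 3)`` as (x, y, z) um."""
        nz, ny, nx = self.shape
        dx, dy, dz = self.voxel_size_um
        x = (np.arange(nx) + 0.5) * dx
        y = (np.arange(ny) + 0.5) * dy
        z = (np.arange(nz) + 0.5) * dz
        zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)

    @property
    def extent_um(self) -> tuple[float, float, float]:
        nz, ny, nx = self.shape
        dx, dy, dz = self.voxel_size_um
        return (nx * dx, ny * dy, nz * dz)


def _as_rotation(rotation) -> np.ndarray:
    r = np.asarray(rotation, dtype=float)
    if r.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation matrix must be orthonormal")
    return r


@dataclass(frozen=True)
class ShellAnnotation:
    """Ellipsoidal outline of the embryo.

    All signal integration is restricted to the interior of this ellipsoid.

    Parameters
    ----------
    center
        Ellipsoid center (x, y, z) in um.
    semi_axes
        Semi-axis lengths (a, b, c) in um along the ellipsoid's own axes;
        all strictly positive.
    rotation
        3x3 orthonormal matrix whose *rows* are the ellipsoid axis
        directions in world coordinates.  Identity means the ellipsoid is
        axis-aligned with a along x, b along y, c along z.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")
        object.__setattr__(self, "rotation", _as_rotation(self.rotation))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for points of shape (..., 3) in (x, y, z) um."""
        p = np.asarray(points, dtype=float) - np.asarray(self.center)
        local = p @ self.rotation.T  # into ellipsoid axes
        scaled = local / np.asarray(self.semi_axes)
        return np.einsum("...i,...i->...", scaled, scaled) <= 1.0

    def major_axis(self) -> tuple[np.ndarray, float]:
        """Direction (unit vector, world coords) and semi-length of the major axis.

        Raises
        ------
        ValueError
            If the two longest semi-axes are equal (ambiguous AP axis).
        """
        axes = np.asarray(self.semi_axes)
        order = np.argsort(axes)[::-1]
        if np.isclose(axes[order[0]], axes[order[1]]):
            raise ValueError(
                "ambiguous major axis: the two longest semi-axes are equal"
            )
        i = int(order[0])
        return self.rotation[i].copy(), float(axes[i])

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "semi_axes": list(self.semi_axes),
            "rotation": np.asarray(self.rotation).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShellAnnotation":
        return cls(
            center=tuple(d["center"]),
            semi_axes=tuple(d["semi_axes"]),
            rotation=np.asarray(d.get("rotation", np.eye(3))),
        )


def make_shell_mask(shell: ShellAnnotation, grid: VoxelGrid) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside the shell ellipsoid.

    Raises
    ------
    ValueError
        If no voxel center falls inside the shell (shell and grid do not
        overlap usefully).
    """
    mask = shell.contains(grid.voxel_centers())
    if not mask.any():
        raise ValueError("shell does not contain any voxel center of the grid")
    return mask
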