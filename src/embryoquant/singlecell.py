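"""Approximate single-cell expression by reference-model superposition.

Without a manually annotated lineage, per-cell expression can still be
estimated by superimposing a reference 4D cell model onto the recording.
The superposition is a similarity transform (rotation + uniform scale +
translation) fitted once from the four founder blastomeres -- embryos
recorded uncompressed do not rotate appreciably during development, so a
static transform suffices.  At each time point the model nuclei alive at
that normalized time are mapped into recording space, every in-shell
voxel is assigned to its nearest nucleus in physical micrometres
(Voronoi partition, honoring Z anisotropy), and the calibrated signal is
summed per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import VoxelGrid
from .profiles import ExpressionProfile, ProfileConfig
from .reconstruction import CalibratedSeries
from .reference_model import FOUNDER_NAMES, ReferenceModel

__all__ = [
    "SimilarityTransform",
    "fit_similarity_transform",
    "infer_missing_founders",
    "assign_voxels",
    "extract_SC",
]


@dataclass(frozen=True)
class SimilarityTransform:
    """x -> scale * R @ x + translation."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return self.scale * p @ np.asarray(self.rotation).T + np.asarray(self.translation)

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(scale=1.0, rotation=np.eye(3), translation=np.zeros(3))


def fit_similarity_transform(
    source: dict[str, np.ndarray],
    target: dict[str, np.ndarray],
) -> SimilarityTransform:
    """Least-squares similarity transform from labeled source to target points.

    Closed-form (SVD-based, Umeyama) estimate of rotation, uniform scale
    and translation minimizing the sum of squared residuals over the
    matching labels.  At least four non-collinear correspondences are
    required.
    """
    labels = sorted(set(source) & set(target))
    if len(labels) < 4:
        raise ValueError(f"need >= 4 labeled correspondences, got {len(labels)}")
    src = np.array([source[k] for k in labels], dtype=float)
    dst = np.array([target[k] for k in labels], dtype=float)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / len(labels)
    U, S, Vt = np.linalg.svd(cov)
    if S[1] < 1e-12 * max(S[0], 1.0):
        raise ValueError("degenerate configuration: points are collinear")
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    var_s = (xs**2).sum() / len(labels)
    if var_s == 0:
        raise ValueError("degenerate configuration: source points coincide")
    scale = np.trace(np.diag(S) @ D) / var_s
    if scale <= 0:
        raise ValueError("fitted scale is non-positive; configuration degenerate")
    t = mu_d - scale * R @ mu_s
    residuals = dst - (scale * src @ R.T + t)
    rms = float(np.sqrt((residuals**2).sum(axis=1).mean()))
    return SimilarityTransform(scale=float(scale), rotation=R, translation=t, residual_rms=rms)


def infer_missing_founders(
    annotated: dict[str, np.ndarray],
    model: ReferenceModel | None = None,
) -> dict[str, np.ndarray]:
    """Recover founder positions from an early (<= 8 cell) annotated stage.

    A recording that starts after the 4-cell stage lacks direct founder
    coordinates; each missing founder is placed at the arithmetic mean of
    its two annotated daughters.  Daughters follow the naming scheme
    ``<founder>a`` / ``<founder>p``.
    """
    if len(annotated) > 8:
        raise ValueError(f"annotated stage has {len(annotated)} cells; supported up to 8")
    founders: dict[str, np.ndarray] = {}
    for name in FOUNDER_NAMES:
        if name in annotated:
            founders[name] = np.asarray(annotated[name], dtype=float)
            continue
        daughters = [k for k in annotated if k in (name + "a", name + "p")]
        if len(daughters) != 2:
            raise KeyError(
                f"founder {name!r} not annotated and its two daughters "
                f"({name}a, {name}p) are not both present"
            )
        founders[name] = np.mean([np.asarray(annotated[d], float) for d in daughters], axis=0)
    stray = set(annotated) - set(FOUNDER_NAMES) - {f + s for f in FOUNDER_NAMES for s in "ap"}
    if stray:
        raise ValueError(f"annotated cells are not founders or founder daughters: {sorted(stray)}")
    return founders


def assign_voxels(
    nuclei: dict[str, np.ndarray],
    mask: np.ndarray,
    grid: VoxelGrid,
) -> np.ndarray:
    """Voronoi partition of in-mask voxels by nearest nucleus.

    Returns an int volume: for in-mask voxels the index of the nearest
    nucleus in lexicographic name order (ties go to the lexicographically
    smallest name); -1 outside the mask.  Distances are physical
    micrometres, so coarse Z sampling is honored.
    """
    if not nuclei:
        raise ValueError("no nuclei to assign voxels to")
    names = sorted(nuclei)
    pts = np.array([nuclei[n] for n in names], dtype=float)
    if len(names) > 1:
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        if (d2 < 1e-18).any():
            raise ValueError("nuclei positions must be distinct")
    centers = grid.voxel_centers()[mask]  # (n, 3)
    labels = np.full(mask.shape, -1, dtype=np.int32)
    # chunked exact nearest neighbor; argmin takes the first (lexicographic) min
    out = np.empty(len(centers), dtype=np.int32)
    chunk = 1 << 16
    for s in range(0, len(centers), chunk):
        c = centers[s : s + chunk]
        d2 = ((c[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        out[s : s + chunk] = np.argmin(d2, axis=1)
    labels[mask] = out
    return labels


def extract_SC(
    series: CalibratedSeries,
    model: ReferenceModel,
    transform: SimilarityTransform,
    mask: np.ndarray | None = None,
    config: ProfileConfig = ProfileConfig(),
    recording_id: str = "recording",
    gene_label: str = "",
) -> ExpressionProfile:
    """Per-cell expression by Voronoi assignment against the superimposed model.

    For every fluorescent stack, the model cells alive at its normalized
    time are transformed into recording space and each in-shell voxel's
    calibrated signal is attributed to its nearest nucleus.  Stacks whose
    normalized time falls outside the model span are skipped with a
    warning.  At each covered time, the per-cell values sum to the
    in-shell total.
    """
    if not series.normalized:
        raise ValueError("series must be time-normalized before SC extraction")
    if mask is None:
        mask = series.mask
    cell_names = sorted(model.cells)
    name_to_row = {n: i for i, n in enumerate(cell_names)}
    model_start = min(c.birth for c in model.cells.values())
    model_end = model.end_time

    per_stack = np.zeros((len(series), len(cell_names)))
    covered = np.zeros(len(series), dtype=bool)
    for t_idx, (t, vol) in enumerate(zip(series.times, series.volumes)):
        if t < model_start - 1e-9 or t > model_end + 1e-9:
            warnings.warn(f"stack at normalized time {t:.2f} outside model span; skipped")
            continue
        positions = model.positions_at(float(np.clip(t, model_start, model_end)))
        if not positions:
            raise ValueError(f"reference model has no cells at normalized time {t:.2f}")
        nuclei = {n: transform.apply(p) for n, p in positions.items()}
        labels = assign_voxels(nuclei, mask, series.grid)
        names = sorted(nuclei)
        sums = np.bincount(labels[mask], weights=vol[mask], minlength=len(names))
        for i, n in enumerate(names):
            per_stack[t_idx, name_to_row[n]] = sums[i]
        covered[t_idx] = True

    if not covered.any():
        raise ValueError("no stack falls within the reference model's time span")
    times = series.times[covered]
    vals = per_stack[covered]
    grid = config.time_grid
    out = np.zeros((len(cell_names), grid.size))
    for j in range(len(cell_names)):
        out[j] = np.interp(grid, times, vals[:, j])
    valid = (grid >= times[0] - 1e-9) & (grid <= times[-1] + 1e-9)
    out[:, ~valid] = 0.0
    return ExpressionProfile(
        kind="SC",
        time_grid=grid.copy(),
        values=out,
        valid=valid,
        recording_id=recording_id,
        gene_label=gene_label,
        cells=cell_names,
    )
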