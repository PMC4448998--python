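"""Ground-truthed synthetic 4D recordings.

The generator emulates the statistical structure an adaptive-exposure
embryo recording is assumed to have, so that every downstream stage --
reconstruction, time normalization, profiling, single-cell mapping and
clustering -- can be exercised end-to-end with known latent values:

* an ellipsoidal embryo shell containing a dividing toy lineage
  (:mod:`embryoquant.reference_model`);
* per-cell expression programs (photons/ms per cell over normalized
  time) rendered through an isotropic Gaussian point spread and sampled
  at voxel centers;
* a linear camera (gain, fixed bit depth, optional Poisson shot noise
  and Gaussian read noise, hard saturation) driven by the feedback
  auto-exposure controller;
* a slowly drifting background plus optional bright transient blobs
  outside the shell (the "hatched worm crawling past" scenario);
* four anchor events at known wall-clock times.

A DIC channel is included only as a placeholder morphology texture at a
40 s cadence, with one fluorescent stack per three DIC stacks; it is
never quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import ChannelConfig, kth_largest, propose_exposure
from .camera import CameraConfig, expose
from .geometry import ShellAnnotation, VoxelGrid, make_shell_mask
from .recording import Channel, Recording, Stack
from .reference_model import ReferenceModel
from .timenorm import AnchorAnnotations, map_time

__all__ = [
    "ExpressionProgram",
    "GroundTruthSpec",
    "GroundTruth",
    "grid_for_shell",
    "render_scene",
    "generate_recording",
]


@dataclass(frozen=True)
class ExpressionProgram:
    """Piecewise-linear expression rate over normalized time for one cell.

    ``rate(t)`` interpolates linearly between knots and is zero outside
    the knot span.  Rates are photons/ms emitted by the whole cell.
    """

    t_knots: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.t_knots) != len(self.rates) or len(self.t_knots) < 1:
            raise ValueError("t_knots and rates must have equal positive length")
        if any(r < 0 for r in self.rates):
            raise ValueError("rates must be non-negative")
        if any(b <= a for a, b in zip(self.t_knots, self.t_knots[1:])):
            raise ValueError("t_knots must strictly increase")

    def rate(self, t_norm: float) -> float:
        return float(np.interp(t_norm, self.t_knots, self.rates, left=0.0, right=0.0))

    @classmethod
    def constant(cls, rate: float, t0: float = 0.0, t1: float = 100.0) -> "ExpressionProgram":
        return cls(t_knots=(t0, t1), rates=(rate, rate))


@dataclass(frozen=True)
class GroundTruthSpec:
    """Latent-scene parameters of a synthetic recording.

    Defaults give a 100-stack fluorescent series at a 120 s cadence
    (one fluorescent stack per three 40 s DIC stacks) spanning the full
    normalized 0-100 axis at 120 s per normalized time unit, with anchors
    at 0 s, 1200 s, 5160 s and 6480 s.
    """

    programs: dict[str, ExpressionProgram] = field(default_factory=dict)
    background_base: float = 100.0
    background_drift: float = 0.0  # counts per hour, linear
    background_sine_amp: float = 0.0
    background_sine_period_s: float = 3600.0
    psf_sigma_um: float = 1.5
    anchor_times_s: tuple[float, float, float, float] = (0.0, 1200.0, 5160.0, 6480.0)
    n_fluor_stacks: int = 100
    outlier_blobs: bool = False
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 2.0)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.anchor_times_s, self.anchor_times_s[1:])):
            raise ValueError("anchor times must strictly increase")
        if self.background_base < 0:
            raise ValueError("background must be non-negative")
        if self.n_fluor_stacks < 1:
            raise ValueError("need at least one fluorescent stack")

    def background_at(self, t_s: float) -> float:
        b = self.background_base + self.background_drift * t_s / 3600.0
        if self.background_sine_amp:
            b += self.background_sine_amp * np.sin(
                2 * np.pi * t_s / self.background_sine_period_s
            )
        return max(b, 0.0)


@dataclass
class GroundTruth:
    """Latent values of a generated recording, for parameter-recovery tests."""

    spec: GroundTruthSpec
    shell: ShellAnnotation
    anchors: AnchorAnnotations
    stack_times_s: np.ndarray
    normalized_times: np.ndarray
    exposures_ms: np.ndarray
    backgrounds: np.ndarray
    cell_rates: "dict[str, np.ndarray]"  # per fluorescent stack, photons/ms
    total_rates: np.ndarray

    def to_dict(self) -> dict:
        return {
            "shell": self.shell.to_dict(),
            "anchors": self.anchors.to_dict(),
            "stack_times_s": self.stack_times_s.tolist(),
            "normalized_times": self.normalized_times.tolist(),
            "exposures_ms": self.exposures_ms.tolist(),
            "backgrounds": self.backgrounds.tolist(),
            "cell_rates": {k: v.tolist() for k, v in self.cell_rates.items()},
            "total_rates": self.total_rates.tolist(),
        }


def grid_for_shell(
    shell: ShellAnnotation,
    voxel_size_um: tuple[float, float, float],
    margin_um: float = 5.0,
) -> VoxelGrid:
    """A voxel grid that covers the shell with a margin (for background voxels)."""
    center = np.asarray(shell.center)
    reach = float(max(shell.semi_axes)) + margin_um
    dx, dy, dz = voxel_size_um
    nx = int(np.ceil((center[0] + reach) / dx))
    ny = int(np.ceil((center[1] + reach) / dy))
    nz = int(np.ceil((center[2] + reach) / dz))
    return VoxelGrid(shape=(nz, ny, nx), voxel_size_um=voxel_size_um)


def render_scene(
    positions: dict[str, np.ndarray],
    rates: dict[str, float],
    grid: VoxelGrid,
    psf_sigma_um: float,
) -> np.ndarray:
    """Expected emission-rate volume (photons/ms per voxel) for point nuclei.

    Each nucleus contributes its whole-cell rate spread over voxels with
    normalized Gaussian weights (total rate is conserved on the grid),
    evaluated in a +-4 sigma window around the nucleus.
    """
    nz, ny, nx = grid.shape
    dx, dy, dz = grid.voxel_size_um
    vol = np.zeros(grid.shape)
    for name, pos in positions.items():
        r = rates.get(name, 0.0)
        if r <= 0:
            continue
        x0, y0, z0 = np.asarray(pos, dtype=float)
        wx = int(np.ceil(4 * psf_sigma_um / dx))
        wy = int(np.ceil(4 * psf_sigma_um / dy))
        wz = int(np.ceil(4 * psf_sigma_um / dz))
        cx = int(np.floor(x0 / dx - 0.5))
        cy = int(np.floor(y0 / dy - 0.5))
        cz = int(np.floor(z0 / dz - 0.5))
        xs = np.arange(max(0, cx - wx), min(nx, cx + wx + 1))
        ys = np.arange(max(0, cy - wy), min(ny, cy + wy + 1))
        zs = np.arange(max(0, cz - wz), min(nz, cz + wz + 1))
        if xs.size == 0 or ys.size == 0 or zs.size == 0:
            continue
        gx = np.exp(-(((xs + 0.5) * dx - x0) ** 2) / (2 * psf_sigma_um**2))
        gy = np.exp(-(((ys + 0.5) * dy - y0) ** 2) / (2 * psf_sigma_um**2))
        gz = np.exp(-(((zs + 0.5) * dz - z0) ** 2) / (2 * psf_sigma_um**2))
        w = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        total = w.sum()
        if total <= 0:
            continue
        vol[np.ix_(zs, ys, xs)] += r * w / total
    return vol


def _dic_texture(grid: VoxelGrid, t_s: float, max_count: int) -> np.ndarray:
    """Deterministic placeholder DIC texture; morphology only, never quantified."""
    nz, ny, nx = grid.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    plane = 0.5 + 0.1 * np.sin(xx / 7.0 + t_s / 500.0) * np.cos(yy / 5.0)
    vol = np.repeat(plane[None, :, :], nz, axis=0)
    return np.clip(np.rint(vol * 0.5 * max_count), 0, max_count).astype(np.uint16)


def generate_recording(
    model: ReferenceModel,
    truth_spec: GroundTruthSpec,
    camera: CameraConfig | None = None,
    channel_config: ChannelConfig | None = None,
    seed: int = 0,
    recording_id: str = "synthetic",
    include_dic: bool = False,
) -> tuple[Recording, GroundTruth]:
    """Simulate an adaptive-exposure recording of the model embryo.

    The fluorescent channel is acquired through the feedback auto-exposure
    loop; all latent values (true rates, backgrounds, normalized times)
    are returned as :class:`GroundTruth`.  Deterministic per seed.
    """
    if not model.cells:
        raise ValueError("reference model has no cells")
    camera = camera or CameraConfig()
    channel_config = channel_config or ChannelConfig(
        lower_threshold=0.25 * camera.max_count,
        upper_threshold=0.75 * camera.max_count,
    )
    rng = np.random.default_rng(seed)
    shell = model.shell
    grid = grid_for_shell(shell, truth_spec.voxel_size_um)
    mask = make_shell_mask(shell, grid)
    anchors = AnchorAnnotations(*truth_spec.anchor_times_s)

    blob_center = None
    if truth_spec.outlier_blobs:
        # bright transient object outside the shell, near the grid corner
        blob_center = np.array([2.0, 2.0, grid.extent_um[2] / 2.0])

    dic_interval = channel_config.stack_interval_s / 3.0

    exposure = float(channel_config.initial_exposure_ms)
    fluor_stacks: list[Stack] = []
    times, t_norms, exposures, bgs, totals = [], [], [], [], []
    cell_rates: dict[str, list[float]] = {name: [] for name in model.cells}
    saturation_warning = False

    for i in range(truth_spec.n_fluor_stacks):
        t = i * channel_config.stack_interval_s
        t_norm = float(map_time(anchors, t, cap=False))
        positions = model.positions_at(float(np.clip(t_norm, 0.0, model.end_time)))
        rates = {
            name: truth_spec.programs[name].rate(t_norm) if name in truth_spec.programs else 0.0
            for name in positions
        }
        rate_vol = render_scene(positions, rates, grid, truth_spec.psf_sigma_um)
        bg = truth_spec.background_at(t)
        bg_field: float | np.ndarray = bg
        if blob_center is not None and 0.3 < (i / truth_spec.n_fluor_stacks) < 0.6:
            centers = grid.voxel_centers()
            d2 = ((centers - blob_center) ** 2).sum(-1)
            blob = 0.5 * camera.max_count * np.exp(-d2 / (2 * 4.0**2))
            blob[mask] = 0.0  # the object crawls by outside the embryo
            bg_field = bg + blob

        counts = expose(rate_vol, exposure, camera, rng, background=bg_field)

        # pathology flag: even the minimum exposure saturates most of the embryo
        if exposure <= channel_config.exposure_min_ms:
            if (counts[mask] >= camera.max_count).mean() > 0.5:
                saturation_warning = True

        fluor_stacks.append(Stack(data=counts, time_s=t, exposure_ms=exposure))
        times.append(t)
        t_norms.append(t_norm)
        exposures.append(exposure)
        bgs.append(bg)
        totals.append(sum(rates.values()))
        for name in model.cells:
            cell_rates[name].append(rates.get(name, 0.0))

        stat = kth_largest(counts, channel_config.k_index)
        exposure = propose_exposure(stat, exposure, channel_config)

    channels = {channel_config.name: Channel(name=channel_config.name, stacks=fluor_stacks)}
    if include_dic:
        n_dic = truth_spec.n_fluor_stacks * 3
        dic_stacks = [
            Stack(
                data=_dic_texture(grid, j * dic_interval, camera.max_count),
                time_s=j * dic_interval,
                exposure_ms=10.0,
            )
            for j in range(n_dic)
        ]
        channels["DIC"] = Channel(name="DIC", stacks=dic_stacks)

    recording = Recording(
        channels=channels,
        grid=grid,
        bit_depth=camera.bit_depth,
        binning=channel_config.binning,
        shell=shell,
        founders={k: np.asarray(v) for k, v in model.founder_positions().items()},
        anchors=anchors,
        saturation_warning=saturation_warning,
        recording_id=recording_id,
    )
    truth = GroundTruth(
        spec=truth_spec,
        shell=shell,
        anchors=anchors,
        stack_times_s=np.array(times),
        normalized_times=np.array(t_norms),
        exposures_ms=np.array(exposures),
        backgrounds=np.array(bgs),
        cell_rates={k: np.array(v) for k, v in cell_rates.items()},
        total_rates=np.array(totals),
    )
    return recording, truth
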