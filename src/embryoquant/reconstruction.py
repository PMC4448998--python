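"""Dynamic-range reconstruction of variable-exposure recordings.

Raw counts from an adaptive-exposure recording are not directly
comparable across time: the exposure changes, the camera adds a
background offset, and the change points introduce small discontinuities
because intensity is not perfectly linear in exposure.  Reconstruction
proceeds per fluorescent stack:

1. estimate the background as the minimum of the *filtered average*
   (mean of the 40-60 percentile band) computed separately inside and
   outside the embryo shell -- robust both to bright outliers outside
   the embryo (e.g. hatched worms crawling past) and to rare cases where
   the outside estimate would drive the signal negative;
2. subtract it, clamp at zero, and divide by the exposure time, giving
   counts/ms;
3. walking forward in time, whenever the exposure differs from the
   previous stack, rescale the current and all later stacks so the
   in-shell mean is continuous across the change (saturated voxels are
   excluded from that mean, as they are not linear in exposure).

No whole-series model fit is involved: fitting the series with linear
least squares biases the reconstructed signal toward zero (regression to
the mean), so continuity is enforced only locally at change points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import ShellAnnotation, VoxelGrid, make_shell_mask
from .recording import Recording

__all__ = [
    "BackgroundConfig",
    "CalibratedSeries",
    "filtered_average",
    "estimate_background",
    "reconstruct_series",
]


@dataclass(frozen=True)
class BackgroundConfig:
    """Percentile band of the filtered-average background estimator.

    The i-th order statistic of n values has rank fraction i/n; the band
    is half-open, (band_low, band_high], so the default 0.40-0.60 band on
    100 values averages ranks 41..60.
    """

    band_low: float = 0.40
    band_high: float = 0.60

    def __post_init__(self) -> None:
        if not (0 <= self.band_low < self.band_high <= 1):
            raise ValueError("require 0 <= band_low < band_high <= 1")


def filtered_average(values, config: BackgroundConfig = BackgroundConfig()) -> float:
    """Mean of the values whose rank fraction lies in (band_low, band_high].

    Unlike the median it varies continuously with the distribution, and
    unlike the plain mean it ignores extreme outliers.  Falls back to the
    median if the band is empty under strict ranks.
    """
    flat = np.sort(np.asarray(values, dtype=float).ravel())
    n = flat.size
    if n == 0:
        raise ValueError("filtered_average of an empty sequence")
    ranks = np.arange(1, n + 1) / n
    sel = (ranks > config.band_low) & (ranks <= config.band_high)
    if not sel.any():
        return float(np.median(flat))
    return float(flat[sel].mean())


def estimate_background(
    volume: np.ndarray,
    shell: ShellAnnotation,
    grid: VoxelGrid,
    config: BackgroundConfig = BackgroundConfig(),
    mask: np.ndarray | None = None,
) -> float:
    """Conservative per-stack background: min of inside/outside filtered averages.

    The region outside the embryo normally represents the background, but
    it can be contaminated by bright transient objects; taking the
    minimum against the inside estimate discards the contaminated side
    and also avoids rare negative-signal cases.
    """
    volume = np.asarray(volume)
    if mask is None:
        mask = make_shell_mask(shell, grid)
    inside = volume[mask]
    outside = volume[~mask]
    if inside.size == 0:
        raise ValueError("shell contains no voxels of this volume")
    if outside.size == 0:
        warnings.warn("shell covers the entire volume; using inside-only background")
        return filtered_average(inside, config)
    return min(filtered_average(inside, config), filtered_average(outside, config))


@dataclass
class CalibratedSeries:
    """Background-subtracted, exposure-normalized fluorescent series.

    ``volumes`` are float arrays in counts/ms with the per-segment
    continuity scale factor already applied; ``scale_factors`` records
    the cumulative factor per stack (1 for the first segment, changing
    only at exposure-change time points).
    """

    volumes: list[np.ndarray]
    times: np.ndarray
    exposures_ms: np.ndarray
    backgrounds: np.ndarray
    scale_factors: np.ndarray
    clamped_fractions: np.ndarray
    grid: VoxelGrid
    shell: ShellAnnotation
    normalized: bool = False

    def __post_init__(self) -> None:
        n = len(self.volumes)
        for name in ("times", "exposures_ms", "backgrounds", "scale_factors", "clamped_fractions"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per stack")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def mask(self) -> np.ndarray:
        return make_shell_mask(self.shell, self.grid)

    def in_shell_means(self) -> np.ndarray:
        m = self.mask
        return np.array([v[m].mean() for v in self.volumes])

    def in_shell_totals(self) -> np.ndarray:
        m = self.mask
        return np.array([v[m].sum() for v in self.volumes])


def reconstruct_series(
    recording: Recording,
    shell: ShellAnnotation | None = None,
    config: BackgroundConfig = BackgroundConfig(),
    channel: str | None = None,
) -> CalibratedSeries:
    """Reconstruct a calibrated counts/ms series from a raw recording."""
    shell = shell if shell is not None else recording.shell
    if shell is None:
        raise ValueError("recording carries no shell annotation and none was given")
    ch = recording.channel(channel) if channel else recording.fluorescent_channel()
    if not ch.stacks:
        raise ValueError(f"channel {ch.name!r} has no stacks")
    mask = make_shell_mask(shell, recording.grid)
    max_count = recording.max_count

    volumes: list[np.ndarray] = []
    backgrounds, clamped = [], []
    cont_means = []  # in-shell mean of v', saturated voxels excluded
    for stack in ch.stacks:
        raw = stack.data.astype(float)
        bg = estimate_background(raw, shell, recording.grid, config, mask=mask)
        v = raw - bg
        n_neg = int((v[mask] < 0).sum())
        v = np.maximum(v, 0.0) / stack.exposure_ms
        unsat = mask & (stack.data < max_count)
        cont_means.append(v[unsat].mean() if unsat.any() else 0.0)
        volumes.append(v)
        backgrounds.append(bg)
        clamped.append(n_neg / mask.sum())

    # Continuity correction: chain scale factors at exposure changes.
    exposures = ch.exposures_ms
    factors = np.ones(len(volumes))
    factor = 1.0
    for i in range(1, len(volumes)):
        if exposures[i] != exposures[i - 1]:
            prev_mean = factor * cont_means[i - 1]
            cur_mean = cont_means[i]
            if cur_mean > 0:
                factor = prev_mean / cur_mean
            else:
                warnings.warn(
                    f"zero in-shell mean at exposure change (stack {i}); "
                    "carrying previous scale factor"
                )
        factors[i] = factor
    volumes = [v * f for v, f in zip(volumes, factors)]

    return CalibratedSeries(
        volumes=volumes,
        times=ch.times_s,
        exposures_ms=exposures,
        backgrounds=np.array(backgrounds),
        scale_factors=factors,
        clamped_fractions=np.array(clamped),
        grid=recording.grid,
        shell=shell,
    )
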