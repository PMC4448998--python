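"""Linear scientific-camera model: emission rate x exposure -> integer counts.

The sensor counts on a quantized integer scale with a fixed bit depth.
Expected counts are ``gain * exposure_ms * rate + background``; optional
Poisson shot noise acts on the expected photon number and Gaussian read
noise on the counts; the result is rounded and clipped to
``[0, 2**bit_depth - 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CameraConfig", "expose"]


@dataclass(frozen=True)
class CameraConfig:
    """Camera parameters.

    ``gain`` is in counts per (photon/ms x ms) = counts per photon;
    ``rate`` volumes passed to :func:`expose` are photons/ms per voxel.
    """

    bit_depth: int = 12
    gain: float = 1.0
    read_noise_sd: float = 0.0
    shot_noise: bool = False

    def __post_init__(self) -> None:
        if self.bit_depth < 8:
            raise ValueError("bit_depth must be >= 8")
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1


def expose(
    rate: np.ndarray,
    exposure_ms: float,
    camera: CameraConfig,
    rng: np.random.Generator | None = None,
    background: float = 0.0,
) -> np.ndarray:
    """Acquire one frame/stack: integer counts from an emission-rate volume.

    Parameters
    ----------
    rate
        Expected photons/ms per voxel, any shape, all >= 0.
    exposure_ms
        Exposure time in ms.
    background
        Additive background in counts (camera offset plus stray light).
    """
    if exposure_ms <= 0:
        raise ValueError("exposure must be positive")
    rate = np.asarray(rate, dtype=float)
    if (rate < 0).any():
        raise ValueError("emission rates must be non-negative")
    photons = rate * exposure_ms
    if camera.shot_noise:
        if rng is None:
            raise ValueError("shot noise requires an rng")
        photons = rng.poisson(photons).astype(float)
    counts = camera.gain * photons + background
    if camera.read_noise_sd > 0:
        if rng is None:
            raise ValueError("read noise requires an rng")
        counts = counts + rng.normal(scale=camera.read_noise_sd, size=counts.shape)
    counts = np.clip(np.rint(counts), 0, camera.max_count)
    return counts.astype(np.uint16 if camera.bit_depth <= 16 else np.uint32)
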