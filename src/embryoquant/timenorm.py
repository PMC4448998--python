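"""Normalization of recording time onto a 0-100 developmental axis.

Embryos develop at slightly different tempos, so wall-clock time is not
comparable across recordings.  Four morphological anchor events are
annotated per recording -- appearance of the first blastomeres (ABa or
EMS), gastrulation, ventral enclosure, and the 2-fold tail stage -- and
pinned to normalized times 0, 10, 43 and 54.  Between anchors the map is
linear; beyond the last anchor it extrapolates with the final segment's
slope; the axis is capped at 100.  When an annotated lineage is
available, time can instead be mapped per cell from the annotated to the
model life span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:
    from .reconstruction import CalibratedSeries
    from .reference_model import ReferenceModel

__all__ = [
    "AnchorAnnotations",
    "TimeAnchorDefaults",
    "DEFAULT_ANCHORS",
    "map_time",
    "normalize_recording",
    "map_time_per_cell",
]


@dataclass(frozen=True)
class AnchorAnnotations:
    """Wall-clock seconds of the four anchor events, strictly increasing."""

    t_start: float
    t_gast: float
    t_venc: float
    t_2ftail: float

    def __post_init__(self) -> None:
        ts = self.as_array()
        if not np.all(np.diff(ts) > 0):
            raise ValueError(f"anchor times must strictly increase, got {ts.tolist()}")

    def as_array(self) -> np.ndarray:
        return np.array([self.t_start, self.t_gast, self.t_venc, self.t_2ftail])

    def to_dict(self) -> dict:
        return {
            "anchor_start": self.t_start,
            "anchor_gast": self.t_gast,
            "anchor_venc": self.t_venc,
            "anchor_2ftail": self.t_2ftail,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnchorAnnotations":
        return cls(
            t_start=d["anchor_start"],
            t_gast=d["anchor_gast"],
            t_venc=d["anchor_venc"],
            t_2ftail=d["anchor_2ftail"],
        )


@dataclass(frozen=True)
class TimeAnchorDefaults:
    """Normalized values of the anchors plus the terminal cap."""

    values: tuple[float, ...] = (0.0, 10.0, 43.0, 54.0)
    terminal: float = 100.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.all(np.diff(v) > 0) or self.terminal <= v[-1]:
            raise ValueError("normalized anchor values must strictly increase below terminal")


DEFAULT_ANCHORS = TimeAnchorDefaults()

#: The canonical 101-point normalized time grid on which profiles live.
TIME_GRID = np.arange(101.0)


def map_time(
    anchors: AnchorAnnotations,
    t,
    defaults: TimeAnchorDefaults = DEFAULT_ANCHORS,
    cap: bool = True,
) -> np.ndarray | float:
    """Map wall-clock seconds to normalized developmental time.

    Exact at the anchors, linear between them, extrapolating with the
    first/last segment slope outside, and capped at ``defaults.terminal``
    (100).  Times before the first anchor may map to negative values;
    they are flagged with a warning rather than clamped.
    """
    xs = anchors.as_array()
    ys = np.asarray(defaults.values, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)

    out = np.interp(t_arr, xs, ys)
    lo = t_arr < xs[0]
    hi = t_arr > xs[-1]
    if lo.any():
        slope0 = (ys[1] - ys[0]) / (xs[1] - xs[0])
        out[lo] = ys[0] + slope0 * (t_arr[lo] - xs[0])
        if (out[lo] < 0).any():
            warnings.warn(
                "times before the first anchor extrapolate to negative normalized time",
                stacklevel=2,
            )
    if hi.any():
        slope1 = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        out[hi] = ys[-1] + slope1 * (t_arr[hi] - xs[-1])
    if cap:
        out = np.minimum(out, defaults.terminal)
    return float(out[0]) if scalar else out


def normalize_recording(
    series: "CalibratedSeries",
    anchors: AnchorAnnotations,
    defaults: TimeAnchorDefaults = DEFAULT_ANCHORS,
) -> "CalibratedSeries":
    """Return a copy of the series on the normalized time axis.

    Stacks whose normalized time would exceed the terminal value (100)
    are truncated: the mapping ends when normalized time reaches 100 or
    the recording ends.
    """
    from .reconstruction import CalibratedSeries  # deferred: circular import

    t_raw = np.asarray(map_time(anchors, series.times, defaults, cap=False))
    inside_span = (series.times >= anchors.t_start) & (series.times <= anchors.t_2ftail)
    if inside_span.sum() == 0:
        warnings.warn("no stack falls between the first and last anchor; pure extrapolation")
    keep = t_raw <= defaults.terminal + 1e-12
    t_norm = np.minimum(t_raw, defaults.terminal)
    idx = np.flatnonzero(keep)
    return CalibratedSeries(
        volumes=[series.volumes[i] for i in idx],
        times=t_norm[idx],
        exposures_ms=series.exposures_ms[idx],
        backgrounds=series.backgrounds[idx],
        scale_factors=series.scale_factors[idx],
        clamped_fractions=series.clamped_fractions[idx],
        grid=series.grid,
        shell=series.shell,
        normalized=True,
    )


def map_time_per_cell(
    lineage_annotation: dict[str, tuple[float, float]],
    model: "ReferenceModel",
) -> dict[str, tuple[float, float]]:
    """Per-cell linear time maps from an annotated lineage onto the model.

    Parameters
    ----------
    lineage_annotation
        Mapping cell name -> (birth, death) wall-clock seconds.
    model
        Reference model supplying each cell's normalized (birth, death).

    Returns
    -------
    dict
        Cell name -> (slope, intercept) of the line taking annotated
        wall-clock time to the model cell's normalized time.
    """
    unknown = sorted(set(lineage_annotation) - set(model.cells))
    if unknown:
        raise KeyError(f"cells absent from the reference model: {unknown}")
    out: dict[str, tuple[float, float]] = {}
    for name, (b_wall, d_wall) in lineage_annotation.items():
        if d_wall <= b_wall:
            raise ValueError(f"cell {name!r}: death must follow birth")
        cell = model.cells[name]
        slope = (cell.death - cell.birth) / (d_wall - b_wall)
        intercept = cell.birth - slope * b_wall
        out[name] = (slope, intercept)
    return out
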