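"""On-disk recording layout and tabular writers.

A recording is a directory with one subdirectory per channel, one
multi-page TIFF per time point (pages = Z slices), and a single
``metadata.json`` holding per-stack wall-clock times and exposures,
voxel sizes, bit depth, and the shell/founder/anchor annotations.
Integer counts round-trip losslessly (12-bit data in 16-bit pages,
bit depth honored from the metadata).

Profiles are written as TSV: T as (time, value); APT/DVT/LRT as a wide
time x bins table; XYZ as a long (time, ix, iy, iz, value) table; SC as
(cell, time, value).  Calibration tables are TSV of
(time, exposure_ms, background, scale_factor, clamped_fraction).
A minimal SOFT reader is included for real staged-microarray files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import ShellAnnotation, VoxelGrid
from .profiles import ExpressionProfile
from .reconstruction import CalibratedSeries
from .recording import Channel, Recording, Stack
from .timenorm import AnchorAnnotations

__all__ = [
    "write_recording",
    "read_recording",
    "write_calibration_table",
    "write_profile_tsv",
    "read_soft_table",
]


def _stack_filename(index: int) -> str:
    return f"t{index:05d}.tif"


def write_recording(recording: Recording, path) -> Path:
    """Write a recording in the standard directory layout."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    meta: dict = {
        "recording_id": recording.recording_id,
        "bit_depth": recording.bit_depth,
        "binning": recording.binning,
        "voxel_size_um": list(recording.grid.voxel_size_um),
        "shape": list(recording.grid.shape),
        "saturation_warning": recording.saturation_warning,
        "channels": {},
    }
    if recording.shell is not None:
        meta["shell"] = recording.shell.to_dict()
    if recording.founders is not None:
        meta["founders"] = {k: np.asarray(v).tolist() for k, v in recording.founders.items()}
    if recording.anchors is not None:
        meta.update(recording.anchors.to_dict())
    for name, channel in recording.channels.items():
        chan_dir = root / name
        chan_dir.mkdir(exist_ok=True)
        stacks_meta = []
        for i, stack in enumerate(channel.stacks):
            fname = _stack_filename(i)
            tifffile.imwrite(chan_dir / fname, stack.data.astype(np.uint16))
            stacks_meta.append(
                {"file": fname, "time_s": stack.time_s, "exposure_ms": stack.exposure_ms}
            )
        meta["channels"][name] = {"stacks": stacks_meta}
    (root / "metadata.json").write_text(json.dumps(meta, indent=1))
    return root


def read_recording(path) -> Recording:
    """Load a recording from the standard layout (lossless round trip)."""
    root = Path(path)
    meta_path = root / "metadata.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.json under {root}")
    meta = json.loads(meta_path.read_text())
    channels: dict[str, Channel] = {}
    for name, chan_meta in meta["channels"].items():
        stacks = []
        for sm in chan_meta["stacks"]:
            f = root / name / sm["file"]
            if not f.exists():
                raise FileNotFoundError(f"metadata references missing stack file {f}")
            data = tifffile.imread(f)
            if data.ndim == 2:
                data = data[None]
            stacks.append(Stack(data=data, time_s=sm["time_s"], exposure_ms=sm["exposure_ms"]))
        channels[name] = Channel(name=name, stacks=stacks)
    grid = VoxelGrid(
        shape=tuple(meta["shape"]), voxel_size_um=tuple(meta["voxel_size_um"])
    )
    shell = ShellAnnotation.from_dict(meta["shell"]) if "shell" in meta else None
    founders = (
        {k: np.asarray(v, dtype=float) for k, v in meta["founders"].items()}
        if "founders" in meta
        else None
    )
    anchors = AnchorAnnotations.from_dict(meta) if "anchor_start" in meta else None
    return Recording(
        channels=channels,
        grid=grid,
        bit_depth=meta["bit_depth"],
        binning=meta.get("binning", 1),
        shell=shell,
        founders=founders,
        anchors=anchors,
        saturation_warning=meta.get("saturation_warning", False),
        recording_id=meta.get("recording_id", root.name),
    )


def write_calibration_table(series: CalibratedSeries, path) -> None:
    df = pd.DataFrame(
        {
            "time": series.times,
            "exposure_ms": series.exposures_ms,
            "background": series.backgrounds,
            "scale_factor": series.scale_factors,
            "clamped_fraction": series.clamped_fractions,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_profile_tsv(profile: ExpressionProfile, path) -> None:
    """Write a profile as TSV; the layout depends on the kind (see module docs)."""
    path = Path(path)
    header = (
        f"# kind={profile.kind} recording={profile.recording_id} "
        f"gene={profile.gene_label}\n"
    )
    vals = np.asarray(profile.values)
    if profile.kind == "T":
        df = pd.DataFrame({"time": profile.time_grid, "value": vals})
    elif profile.kind in ("APT", "DVT", "LRT"):
        df = pd.DataFrame(vals, columns=[f"bin{i}" for i in range(vals.shape[1])])
        df.insert(0, "time", profile.time_grid)
    elif profile.kind == "XYZ":
        t, nx, ny, nz = vals.shape
        ti, xi, yi, zi = np.meshgrid(
            np.arange(t), np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        df = pd.DataFrame(
            {
                "time": profile.time_grid[ti.ravel()],
                "ix": xi.ravel(),
                "iy": yi.ravel(),
                "iz": zi.ravel(),
                "value": vals.ravel(),
            }
        )
        df = df[df["value"] > 0]  # long format: keep only occupied cubes
    elif profile.kind == "SC":
        rows = []
        for ci, cell in enumerate(profile.cells or []):
            for ti, t in enumerate(profile.time_grid):
                rows.append((cell, t, vals[ci, ti]))
        df = pd.DataFrame(rows, columns=["cell", "time", "value"])
    else:  # pragma: no cover - kinds are validated upstream
        raise ValueError(profile.kind)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def read_soft_table(path, value_prefix: str = "ID_REF") -> pd.DataFrame:
    """Minimal reader for GEO SOFT sample tables.

    Parses the ``!sample_table_begin`` .. ``!sample_table_end`` blocks of
    a SOFT family file into one DataFrame per sample, concatenated with a
    ``sample`` column.  Provided for use with real staged-embryo
    microarray files; no test requires it.
    """
    rows = []
    sample = None
    in_table = False
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("^SAMPLE"):
                sample = line.split("=", 1)[1].strip()
            elif line.startswith("!sample_table_begin"):
                in_table, header = True, None
            elif line.startswith("!sample_table_end"):
                in_table = False
            elif in_table:
                parts = line.split("\t")
                if header is None:
                    header = parts
                else:
                    rows.append([sample] + parts)
    if not rows or header is None:
        raise ValueError(f"no sample tables found in {path}")
    return pd.DataFrame(rows, columns=["sample"] + header)
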