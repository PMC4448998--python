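"""A toy reference 4D cell model: lineage tree plus per-cell 3D trajectories.

The model plays the role a curated wild-type 4D embryo model plays in real
analyses: it supplies, for any normalized developmental time in [0, 100],
the set of cells alive at that time and their nuclear positions, so that
image signal can be attributed to cells by nearest-nucleus (Voronoi)
assignment.  The lineage starts from the four founder blastomeres ABa,
ABp, EMS and P2 and divides synchronously in rounds; positions are
piecewise-linear in time and confined to the model's shell ellipsoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ShellAnnotation

__all__ = ["Cell", "ReferenceModel", "FOUNDER_NAMES", "generate_reference_model"]

FOUNDER_NAMES = ("ABa", "ABp", "EMS", "P2")


@dataclass
class Cell:
    """One cell of the reference model.

    ``trajectory`` is an ``(n, 4)`` array of rows ``(t, x, y, z)`` with
    strictly increasing normalized times spanning ``[birth, death]``;
    positions between knots are linearly interpolated.
    """

    name: str
    parent: str | None
    birth: float
    death: float
    trajectory: np.ndarray

    def __post_init__(self) -> None:
        traj = np.asarray(self.trajectory, dtype=float)
        if traj.ndim != 2 or traj.shape[1] != 4 or traj.shape[0] < 2:
            raise ValueError("trajectory must be an (n>=2, 4) array of (t, x, y, z)")
        if not np.all(np.diff(traj[:, 0]) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        if not (np.isclose(traj[0, 0], self.birth) and np.isclose(traj[-1, 0], self.death)):
            raise ValueError("trajectory must span [birth, death]")
        self.trajectory = traj

    def alive_at(self, t: float) -> bool:
        # birth inclusive, death exclusive except for terminal cells, which
        # callers treat via ReferenceModel.cells_alive_at
        return self.birth <= t < self.death

    def position_at(self, t: float) -> np.ndarray:
        traj = self.trajectory
        return np.array(
            [np.interp(t, traj[:, 0], traj[:, 1 + i]) for i in range(3)]
        )


@dataclass
class ReferenceModel:
    """Leaf-labeled lineage tree with per-cell 3D trajectories over [0, 100]."""

    cells: dict[str, Cell]
    shell: ShellAnnotation
    end_time: float = 100.0

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        names = set(self.cells)
        for cell in self.cells.values():
            if cell.parent is not None and cell.parent not in names:
                raise ValueError(f"cell {cell.name!r} has unknown parent {cell.parent!r}")
            if cell.parent is not None:
                parent = self.cells[cell.parent]
                if not np.isclose(cell.birth, parent.death):
                    raise ValueError(
                        f"cell {cell.name!r} birth {cell.birth} != parent death {parent.death}"
                    )

    @property
    def founders(self) -> list[Cell]:
        return [c for c in self.cells.values() if c.parent is None]

    def children(self, name: str) -> list[Cell]:
        return [c for c in self.cells.values() if c.parent == name]

    def leaves(self) -> list[Cell]:
        parents = {c.parent for c in self.cells.values() if c.parent}
        return [c for c in self.cells.values() if c.name not in parents]

    def cells_alive_at(self, t: float) -> list[Cell]:
        """Cells alive at normalized time t; terminal cells stay alive at t == death."""
        out = []
        for c in self.cells.values():
            terminal = not self.children(c.name)
            if c.birth <= t < c.death or (terminal and np.isclose(t, c.death)):
                out.append(c)
        return sorted(out, key=lambda c: c.name)

    def positions_at(self, t: float) -> dict[str, np.ndarray]:
        return {c.name: c.position_at(t) for c in self.cells_alive_at(t)}

    def founder_positions(self, t: float | None = None) -> dict[str, np.ndarray]:
        """Founder positions at time t (default: at founder birth)."""
        out = {}
        for c in self.founders:
            tt = c.birth if t is None else t
            out[c.name] = c.position_at(np.clip(tt, c.birth, c.death))
        return out

    def first_time_with_cell_count(self, count: int) -> float:
        """Earliest normalized time at which at least `count` cells are alive."""
        division_times = sorted({c.birth for c in self.cells.values()})
        for t in division_times:
            if len(self.cells_alive_at(t)) >= count:
                return float(t)
        return float(self.end_time)


def _founder_layout(shell: ShellAnnotation) -> dict[str, np.ndarray]:
    """Stylized 4-cell arrangement: ABa anterior, P2 posterior, EMS ventral,
    ABp dorsal, in the shell's own axis frame (a = AP, b = DV)."""
    cx, cy, cz = shell.center
    a, b, c = shell.semi_axes
    local = {
        "ABa": np.array([-0.55 * a, 0.0, 0.0]),
        "ABp": np.array([-0.15 * a, 0.45 * b, 0.1 * c]),
        "EMS": np.array([0.15 * a, -0.45 * b, -0.1 * c]),
        "P2": np.array([0.55 * a, 0.0, 0.0]),
    }
    return {k: np.asarray(shell.center) + v @ shell.rotation for k, v in local.items()}


def generate_reference_model(
    n_rounds: int,
    seed: int,
    shell: ShellAnnotation | None = None,
) -> ReferenceModel:
    """Build a toy reference model with `n_rounds` synchronous division rounds.

    Starting from the four founders born at normalized time 0, every cell
    of round ``r`` divides at a division time spread so that each of the
    four anchor epochs (0-10, 10-43, 43-54, 54-100) contains at least one
    round boundary when enough rounds are requested.  Daughter positions
    are jittered around the mother and pulled inside the shell; the run is
    fully determined by ``seed``.

    Parameters
    ----------
    n_rounds
        Number of division rounds, 0 <= n_rounds <= 8.  0 yields only the
        founders.
    seed
        Seed for daughter placement.
    shell
        Model shell ellipsoid; defaults to a 25 x 15 x 15 um half-axis
        ellipsoid centered at (30, 20, 20) um.
    """
    if not (0 <= n_rounds <= 8):
        raise ValueError(f"n_rounds must be in [0, 8], got {n_rounds}")
    rng = np.random.default_rng(seed)
    if shell is None:
        shell = ShellAnnotation(center=(30.0, 20.0, 20.0), semi_axes=(25.0, 15.0, 15.0))
    end_time = 100.0

    # Division times: founders live [0, t1), round-1 cells [t1, t2), ...
    # Spread so the four anchor epochs each contain cells of several rounds.
    all_times = [8.0, 20.0, 32.0, 46.0, 58.0, 70.0, 82.0, 92.0]
    div_times = all_times[:n_rounds]
    boundaries = [0.0] + div_times + [end_time]

    def clamp_inside(p: np.ndarray) -> np.ndarray:
        center = np.asarray(shell.center)
        local = (p - center) @ shell.rotation.T / np.asarray(shell.semi_axes)
        r = np.linalg.norm(local)
        if r > 0.9:
            local *= 0.9 / r
        return center + (local * np.asarray(shell.semi_axes)) @ shell.rotation

    cells: dict[str, Cell] = {}
    founder_pos = _founder_layout(shell)
    current: list[tuple[str, np.ndarray]] = []
    for name in FOUNDER_NAMES:
        birth, death = boundaries[0], boundaries[1]
        pos = founder_pos[name]
        drift = clamp_inside(pos + rng.normal(scale=0.5, size=3))
        traj = np.array([[birth, *pos], [death, *drift]])
        cells[name] = Cell(name=name, parent=None, birth=birth, death=death, trajectory=traj)
        current.append((name, drift))

    for r in range(n_rounds):
        birth, death = boundaries[r + 1], boundaries[r + 2]
        nxt: list[tuple[str, np.ndarray]] = []
        for parent_name, parent_pos in current:
            # daughters separate along a random axis, scale shrinking per round
            sep = rng.normal(size=3)
            sep = sep / np.linalg.norm(sep) * max(1.5, 6.0 / (r + 1))
            for suffix, sign in (("a", 1.0), ("p", -1.0)):
                name = f"{parent_name}.{suffix}" if "." in parent_name else f"{parent_name}{suffix}"
                p0 = clamp_inside(parent_pos + sign * sep)
                p1 = clamp_inside(p0 + rng.normal(scale=0.5, size=3))
                traj = np.array([[birth, *p0], [death, *p1]])
                cells[name] = Cell(
                    name=name, parent=parent_name, birth=birth, death=death, trajectory=traj
                )
                nxt.append((name, p1))
        current = nxt

    return ReferenceModel(cells=cells, shell=shell, end_time=end_time)
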