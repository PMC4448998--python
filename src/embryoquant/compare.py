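"""Pairwise comparison of expression profiles and clustering-tree quality.

Profiles on the shared normalized time grid are flattened to vectors and
compared with Pearson correlation, Manders overlap coefficients, or
Euclidean (l2) distance.  Distance matrices are exported in square
PHYLIP format so trees can be built with external programs (e.g. the
PHYLIP Kitsch algorithm, which yields balanced, well-discriminating
trees); a small built-in UPGMA exists for testing only.

Tree quality is scored from reporters recorded multiple times: with the
leaf-pair edge distance mu (number of edges on the path between two
leaves), r is the largest mu over all pairs, d the mean over duplicated
genes of the minimum same-gene mu (2 means duplicates are siblings --
the best possible), D the same statistic under a random placement of the
labels on the fixed topology (estimated by bootstrap or exhaustively for
tiny trees), and q = (d - 2)/(D / 2); small q means same-gene recordings
cluster far better than chance.

T profiles can also be correlated against staged bulk-expression tables
(e.g. microarrays of staged embryos), with significance from a bootstrap
over random gene pairings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .profiles import ExpressionProfile
from .timenorm import TIME_GRID

__all__ = [
    "SimilarityMatrix",
    "TreeQualityReport",
    "StageExpressionTable",
    "profile_vector",
    "similarity",
    "manders_coefficients",
    "distance_matrix",
    "write_phylip",
    "read_phylip",
    "upgma_newick",
    "tree_distances",
    "tree_quality",
    "stage_correlation",
]

METRICS = ("pearson", "manders", "l2")


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise matrix over labeled profiles."""

    labels: list[str]
    metric: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        self.values = v


@dataclass(frozen=True)
class TreeQualityReport:
    r: float
    d: float
    D: float
    q: float
    n_boot: int
    seed: int
    exhaustive: bool = False


@dataclass
class StageExpressionTable:
    """Bulk expression per gene at ordered developmental stages.

    ``stages`` are (label, cell_count) in developmental order;
    ``values`` maps gene -> per-stage array.
    """

    stages: list[tuple[str, int]]
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError("need >= 2 stages")
        counts = [c for _, c in self.stages]
        if any(b <= a for a, b in zip(counts, counts[1:])):
            raise ValueError("stage cell counts must increase with developmental order")
        n = len(self.stages)
        self.values = {g: np.asarray(v, dtype=float) for g, v in self.values.items()}
        for g, v in self.values.items():
            if v.shape != (n,):
                raise ValueError(f"gene {g!r}: expected {n} stage values")


def profile_vector(profile: ExpressionProfile, grid: np.ndarray = TIME_GRID) -> np.ndarray:
    """Flatten a profile to a time-major vector on the shared grid.

    Grid points not covered by the recording (e.g. a recording that ends
    early) are zero-padded; the profile's ``valid`` mask records them.
    """
    vals = np.asarray(profile.values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty profile")
    grid = np.asarray(grid, dtype=float)
    time_axis = 1 if profile.kind == "SC" else 0
    if vals.shape[time_axis] != profile.time_grid.size:
        raise ValueError("profile values inconsistent with its time grid")
    if not np.array_equal(profile.time_grid, grid):
        moved = np.moveaxis(vals, time_axis, 0)
        flat = moved.reshape(moved.shape[0], -1)
        res = np.empty((grid.size, flat.shape[1]))
        for j in range(flat.shape[1]):
            res[:, j] = np.interp(grid, profile.time_grid, flat[:, j])
        vals = np.moveaxis(res.reshape((grid.size,) + moved.shape[1:]), 0, time_axis)
    if profile.kind == "SC":
        vals = np.moveaxis(vals, 1, 0)  # time-major
    return vals.reshape(-1)


def manders_coefficients(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Manders overlap fractions (M1, M2) for non-negative vectors.

    M1 is the fraction of a's mass where b is positive, M2 vice versa.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sa, sb = a.sum(), b.sum()
    if sa <= 0 or sb <= 0:
        raise ValueError("Manders coefficients need vectors with positive mass")
    m1 = a[b > 0].sum() / sa
    m2 = b[a > 0].sum() / sb
    return float(m1), float(m2)


def similarity(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    """Pairwise similarity/distance of two equal-length vectors.

    pearson -> sample correlation; manders -> mean of the two overlap
    fractions; l2 -> Euclidean distance.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if metric == "pearson":
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValueError("Pearson correlation undefined for a constant vector")
        return float(np.corrcoef(a, b)[0, 1])
    if metric == "manders":
        m1, m2 = manders_coefficients(a, b)
        return (m1 + m2) / 2.0
    if metric == "l2":
        return float(np.linalg.norm(a - b))
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def distance_matrix(
    profiles: list[ExpressionProfile],
    metric: str = "pearson",
    labels: list[str] | None = None,
) -> SimilarityMatrix:
    """Symmetric distance matrix over profiles (pearson mapped to 1 - rho)."""
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    kinds = {p.kind for p in profiles}
    if len(kinds) > 1:
        raise ValueError(f"cannot mix profile kinds: {sorted(kinds)}")
    if labels is None:
        labels = [p.recording_id for p in profiles]
    vecs = [profile_vector(p) for p in profiles]
    n = len(vecs)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = similarity(vecs[i], vecs[j], metric)
            if metric == "pearson":
                dist = 1.0 - s
            elif metric == "manders":
                dist = 1.0 - s
            else:
                dist = s
            out[i, j] = out[j, i] = dist
    return SimilarityMatrix(labels=list(labels), metric=metric, values=out)


# ---------------------------------------------------------------------------
# PHYLIP distance-matrix export


def _phylip_label(label: str) -> str:
    clean = "".join(ch if ch not in "():;,[]" else "_" for ch in label)
    return f"{clean[:10]:<10}"


def write_phylip(matrix: SimilarityMatrix, path_or_buf) -> None:
    """Write a square PHYLIP distance matrix (10-char padded labels)."""
    buf = open(path_or_buf, "w") if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__") else path_or_buf
    close = buf is not path_or_buf
    try:
        n = len(matrix.labels)
        buf.write(f"{n:5d}\n")
        for i, label in enumerate(matrix.labels):
            row = " ".join(f"{v:.6f}" for v in matrix.values[i])
            buf.write(f"{_phylip_label(label)} {row}\n")
    finally:
        if close:
            buf.close()


def read_phylip(path_or_buf) -> SimilarityMatrix:
    """Read a square PHYLIP distance matrix written by :func:`write_phylip`."""
    buf = open(path_or_buf) if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__") else path_or_buf
    close = buf is not path_or_buf
    try:
        lines = [ln.rstrip("\n") for ln in buf if ln.strip()]
    finally:
        if close:
            buf.close()
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for ln in lines[1 : n + 1]:
        labels.append(ln[:10].strip())
        rows.append([float(x) for x in ln[10:].split()])
    return SimilarityMatrix(labels=labels, metric="unknown", values=np.array(rows))


# ---------------------------------------------------------------------------
# Trees


def upgma_newick(matrix: SimilarityMatrix) -> str:
    """UPGMA tree (Newick) from a distance matrix.  For testing only --
    production trees come from external programs via the PHYLIP export."""
    from scipy.cluster.hierarchy import linkage, to_tree
    from scipy.spatial.distance import squareform

    cond = squareform(matrix.values, checks=False)
    root = to_tree(linkage(cond, method="average"))

    def render(node) -> str:
        if node.is_leaf():
            return matrix.labels[node.id]
        return f"({render(node.left)},{render(node.right)})"

    return render(root) + ";"


def tree_distances(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """All leaf-pair edge counts mu for a leaf-labeled tree.

    Returns the leaf labels and a symmetric integer matrix where entry
    (i, j) is the number of edges on the path between leaves i and j.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label if lf.taxon else str(lf) for lf in leaves]
    if len(labels) < 2:
        raise ValueError("tree must have >= 2 leaves")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels")
    # depth of each leaf and of each pair's most recent common ancestor
    depth: dict[int, int] = {}
    for node in tree.preorder_node_iter():
        depth[id(node)] = 0 if node.parent_node is None else depth[id(node.parent_node)] + 1
    n = len(leaves)
    mu = np.zeros((n, n), dtype=int)
    pdm_nodes = leaves
    for i in range(n):
        for j in range(i + 1, n):
            a, b = pdm_nodes[i], pdm_nodes[j]
            # walk up to common ancestor by depth
            x, y, e = a, b, 0
            while depth[id(x)] > depth[id(y)]:
                x = x.parent_node
                e += 1
            while depth[id(y)] > depth[id(x)]:
                y = y.parent_node
                e += 1
            while x is not y:
                x, y = x.parent_node, y.parent_node
                e += 2
            mu[i, j] = mu[j, i] = e
    return labels, mu


def _min_same_gene_distances(mu: np.ndarray, genes: list[str]) -> dict[str, int]:
    by_gene: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        by_gene.setdefault(g, []).append(i)
    out = {}
    for g, idx in by_gene.items():
        if len(idx) < 2:
            continue
        out[g] = min(mu[i, j] for i, j in itertools.combinations(idx, 2))
    return out


def tree_quality(
    tree: dendropy.Tree,
    gene_by_leaf: dict[str, str],
    n_boot: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> TreeQualityReport:
    """Clustering-tree quality statistics r, d, D and q.

    ``gene_by_leaf`` maps every leaf label to its gene/reporter; genes
    with >= 2 recordings drive the statistic.  D is the expectation of d
    under random placement of the leaf labels on the fixed topology,
    estimated from ``n_boot`` seeded permutations, or exactly over all
    label permutations when ``exhaustive`` (feasible for tiny trees).
    """
    labels, mu = tree_distances(tree)
    missing = [l for l in labels if l not in gene_by_leaf]
    if missing:
        raise KeyError(f"leaves without a gene label: {missing}")
    genes = [gene_by_leaf[l] for l in labels]
    observed = _min_same_gene_distances(mu, genes)
    if not observed:
        raise ValueError("no gene has >= 2 recordings; d is undefined")
    d = float(np.mean(list(observed.values())))
    iu = np.triu_indices(len(labels), k=1)
    r = int(mu[iu].max())

    def d_of(perm_genes: list[str]) -> float:
        return float(np.mean(list(_min_same_gene_distances(mu, perm_genes).values())))

    if exhaustive:
        vals = [d_of(list(p)) for p in itertools.permutations(genes)]
        D = float(np.mean(vals))
        n_used = len(vals)
    else:
        rng = np.random.default_rng(seed)
        vals = []
        g = np.array(genes)
        for _ in range(n_boot):
            vals.append(d_of(list(rng.permutation(g))))
        D = float(np.mean(vals))
        n_used = n_boot
    q = (d - 2.0) / (D / 2.0) if D > 0 else float("nan")
    return TreeQualityReport(r=float(r), d=d, D=D, q=q, n_boot=n_used, seed=seed, exhaustive=exhaustive)


# ---------------------------------------------------------------------------
# Staged bulk-expression comparison


def stage_correlation(
    t_profiles: dict[str, np.ndarray],
    stage_table: StageExpressionTable,
    stage_times: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    grid: np.ndarray = TIME_GRID,
) -> tuple[float, float]:
    """Mean per-gene correlation of T profiles vs staged bulk expression.

    For every gene shared between the imaging profiles and the stage
    table, the T profile is sampled at the normalized times of the
    stages and Pearson-correlated with the stage values.  Significance
    is the percentile of the observed mean within a null of ``n_boot``
    random gene pairings (table genes permuted against profiles).

    Returns ``(mean_correlation, significance_percent)``.
    """
    stage_times = np.asarray(stage_times, dtype=float)
    if stage_times.size != len(stage_table.stages):
        raise ValueError("stage_times must match the number of stages")
    if stage_times.size < 3:
        raise ValueError("correlation needs >= 3 stages")
    shared = sorted(set(t_profiles) & set(stage_table.values))
    if len(shared) < 2:
        raise ValueError(f"need >= 2 shared genes, got {len(shared)}")

    sampled = {}
    for g in shared:
        prof = np.asarray(t_profiles[g], dtype=float)
        if prof.shape != grid.shape:
            raise ValueError(f"T profile for {g!r} must live on the shared grid")
        sampled[g] = np.interp(stage_times, grid, prof)

    def corr(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    def mean_corr(pairing: list[str]) -> float:
        return float(
            np.mean([corr(sampled[g], stage_table.values[h]) for g, h in zip(shared, pairing)])
        )

    observed = mean_corr(shared)
    rng = np.random.default_rng(seed)
    arr = np.array(shared)
    boots = [mean_corr(list(rng.permutation(arr))) for _ in range(n_boot)]
    significance = 100.0 * float(np.mean([b < observed for b in boots]))
    return observed, significance
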