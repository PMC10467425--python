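"""Synthetic inputs for the tACS modelling pipeline.

Everything downstream modules consume is generated here: gyrified cortical
sheet meshes with per-triangle parcel labels, uniform electric-field maps,
log-normal-weight structural connectomes with fiber lengths, distance-decaying
target functional-connectivity matrices, and the three prototypical amplitude
distributions (bimodal symmetric, bimodal asymmetric, Gaussian) used for
single-node stimulation experiments.

All generators are pure functions of their seed: the same seed yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "SurfaceMesh",
    "FieldMap",
    "Connectome",
    "TargetFC",
    "make_gyrified_mesh",
    "make_uniform_field",
    "make_connectome",
    "make_theoretical_distribution",
    "make_target_fc",
    "save_mesh",
    "load_mesh",
    "save_connectome",
    "load_connectome",
]

#: fiber-length window (mm) — tracks outside it are discarded by deterministic
#: tractography pipelines, so synthetic lengths must respect it too
LENGTH_MIN_MM = 15.0
LENGTH_MAX_MM = 180.0


@dataclass
class SurfaceMesh:
    """Triangulated white/gray-matter boundary sheet.

    ``normals`` are unit vectors per triangle, oriented toward the
    white-matter side, i.e. along the dendrite-to-axon (orthodromic) axis of
    the pyramidal cells subtended by each triangle.  ``region_labels`` assigns
    every triangle to a parcel.
    """

    vertices: np.ndarray  # (n_vertices, 3), mm
    triangles: np.ndarray  # (n_triangles, 3), int indices
    normals: np.ndarray  # (n_triangles, 3), unit
    region_labels: np.ndarray  # (n_triangles,), int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.normals = np.asarray(self.normals, dtype=float)
        self.region_labels = np.asarray(self.region_labels, dtype=int)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle indices reference missing vertices")
        if len(self.normals) != len(self.triangles):
            raise ValueError("one normal per triangle required")
        if len(self.region_labels) != len(self.triangles):
            raise ValueError("one region label per triangle required")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("normals must have unit length")

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)


@dataclass
class FieldMap:
    """One electric-field vector (V/m) per mesh triangle, sampled at centroids."""

    vectors: np.ndarray  # (n_triangles, 3), V/m

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("field vectors must be finite")


@dataclass
class Connectome:
    """Structural connectome: symmetric streamline-count-like weights and
    mean fiber lengths (mm) between region pairs."""

    region_ids: list
    weights: np.ndarray  # (n, n) symmetric, zero diagonal, >= 0
    lengths: np.ndarray  # (n, n) mm, symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        validate_connectome(self.weights, self.lengths)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


def validate_connectome(weights: np.ndarray, lengths: np.ndarray) -> None:
    for name, m in (("weights", weights), ("lengths", lengths)):
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"{name} must be square")
        if not np.allclose(m, m.T):
            raise ValueError(f"{name} must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError(f"{name} must have zero diagonal")
        if np.any(m < 0):
            raise ValueError(f"{name} must be non-negative")
    nz = lengths[lengths > 0]
    if nz.size and (nz.min() < LENGTH_MIN_MM or nz.max() > LENGTH_MAX_MM):
        raise ValueError(
            f"nonzero fiber lengths must lie in [{LENGTH_MIN_MM}, {LENGTH_MAX_MM}] mm"
        )


@dataclass
class TargetFC:
    """Target functional connectivity: phase-locking values in [0, 1]."""

    region_ids: list
    plv: np.ndarray  # (n, n), symmetric, unit diagonal

    def __post_init__(self) -> None:
        self.plv = np.asarray(self.plv, dtype=float)
        if np.any(self.plv < 0) or np.any(self.plv > 1):
            raise ValueError("PLV entries must lie in [0, 1]")
        if not np.allclose(self.plv, self.plv.T):
            raise ValueError("PLV matrix must be symmetric")
        if not np.all(np.diag(self.plv) == 1.0):
            raise ValueError("PLV diagonal must be exactly 1")


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------

def triangle_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Per-triangle unit normals of a cortical sheet, oriented toward the
    white-matter (-z) side.

    Raw facet cross-product normals sample the surface slope off the triangle
    centroid, an O(h) bias on a height field; and averaging *unit* normals is
    itself biased on steep walls because the slope-to-normal map is
    nonlinear.  The estimate here therefore averages in slope space: facet
    slopes are pooled into projected-area-weighted vertex slopes, re-averaged
    at each triangle, and only then converted to a unit normal — a centered,
    second-order estimate of the smooth surface normal at the centroid.
    Near-vertical facets (no height-field interpretation) fall back to the
    facet normal.
    """
    p = vertices[triangles]
    facet = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    nz = facet[:, 2]
    steep = np.abs(nz) < 1e-12 * np.linalg.norm(facet, axis=1)
    nz_safe = np.where(steep, 1.0, nz)
    sx = -facet[:, 0] / nz_safe
    sy = -facet[:, 1] / nz_safe
    w = np.abs(nz)  # projected area
    vs = np.zeros((len(vertices), 2))
    vw = np.zeros(len(vertices))
    for c in range(3):
        np.add.at(vs[:, 0], triangles[:, c], sx * w)
        np.add.at(vs[:, 1], triangles[:, c], sy * w)
        np.add.at(vw, triangles[:, c], w)
    vw[vw == 0] = 1.0
    vs /= vw[:, None]
    ts = vs[triangles].mean(axis=1)
    tri = np.column_stack([ts[:, 0], ts[:, 1], -np.ones(len(ts))])
    tri /= np.linalg.norm(tri, axis=1, keepdims=True)
    if np.any(steep):
        fb = facet / np.linalg.norm(facet, axis=1, keepdims=True)
        fb[fb[:, 2] > 0] *= -1
        tri[steep] = fb[steep]
    return tri


def make_gyrified_mesh(
    n_gyri: int,
    fold_depth: float,
    sheet_size: float = 60.0,
    resolution: int = 64,
    region_splits: int = 1,
    seed: int = 0,
) -> SurfaceMesh:
    """Build a sinusoidally folded cortical sheet.

    The sheet is a height field ``z = fold_depth * sin(2*pi*n_gyri*x/sheet_size)``
    over ``[0, sheet_size]^2`` (mm), triangulated on a ``resolution x resolution``
    vertex grid.  The white-matter side is declared to be below the sheet
    (-z), so all normals have a non-positive z component on a flat sheet.
    Triangles are partitioned into ``region_splits`` contiguous strips along
    the folding axis (x), so different parcels cover gyral crowns vs. walls
    and naturally differ in the shape of their normal-component distribution.

    Parameters
    ----------
    n_gyri:
        Number of full sinusoidal folds across the sheet; 0 gives a flat sheet.
    fold_depth:
        Fold amplitude in mm; larger values mean steeper gyral walls.
    sheet_size:
        Side length of the square sheet, mm.
    resolution:
        Vertices per side (>= 4).
    region_splits:
        Number of contiguous parcels along x.
    seed:
        Unused for geometry (kept for interface uniformity of the generators).
    """
    if sheet_size <= 0 or resolution <= 0:
        raise ValueError("sheet_size and resolution must be positive")
    if resolution < 4:
        raise ValueError("resolution must be >= 4")
    if n_gyri < 0:
        raise ValueError("n_gyri must be >= 0")
    if region_splits < 1:
        raise ValueError("region_splits must be >= 1")

    x = np.linspace(0.0, sheet_size, resolution)
    y = np.linspace(0.0, sheet_size, resolution)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    if n_gyri == 0:
        zz = np.zeros_like(xx)
    else:
        zz = fold_depth * np.sin(2.0 * np.pi * n_gyri * xx / sheet_size)
    vertices = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    # two triangles per grid cell with consistent winding
    tris = []
    for i in range(resolution - 1):
        for j in range(resolution - 1):
            v00 = i * resolution + j
            v01 = v00 + 1
            v10 = v00 + resolution
            v11 = v10 + 1
            tris.append((v00, v10, v01))
            tris.append((v01, v10, v11))
    triangles = np.array(tris, dtype=int)

    normals = triangle_normals(vertices, triangles)
    centroids = vertices[triangles].mean(axis=1)
    strip = np.floor(centroids[:, 0] / sheet_size * region_splits).astype(int)
    region_labels = np.clip(strip, 0, region_splits - 1)

    return SurfaceMesh(vertices, triangles, normals, region_labels)


def analytic_sheet_normal(x: np.ndarray, n_gyri: int, fold_depth: float, sheet_size: float) -> np.ndarray:
    """Exact unit normal of the generating sinusoid at coordinate x, oriented
    toward the white side (-z); the oracle for mesh-normal accuracy."""
    x = np.asarray(x, dtype=float)
    if n_gyri == 0:
        n = np.zeros((x.size, 3))
        n[:, 2] = -1.0
        return n
    k = 2.0 * np.pi * n_gyri / sheet_size
    dzdx = fold_depth * k * np.cos(k * x)
    n = np.column_stack([dzdx, np.zeros_like(x), -np.ones_like(x)])
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def make_uniform_field(mesh: SurfaceMesh, direction, magnitude: float) -> FieldMap:
    """Uniform field of given magnitude (V/m) along ``direction`` on every
    triangle — the idealization of the roughly antero-posterior current flow
    of an Oz-Cz montage."""
    direction = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise ValueError("direction must be a nonzero vector")
    vec = magnitude * direction / nrm
    return FieldMap(np.tile(vec, (mesh.n_triangles, 1)))


# ---------------------------------------------------------------------------
# connectome / FC generation
# ---------------------------------------------------------------------------

def make_connectome(
    n_regions: int,
    density: float = 1.0,
    weight_scale: float = 100.0,
    length_range: tuple = (LENGTH_MIN_MM, LENGTH_MAX_MM),
    seed: int = 0,
) -> Connectome:
    """Synthetic structural connectome.

    Weights are log-normal (heavy right tail, so log2 node strength is
    approximately linearizing, as with streamline counts from deterministic
    tractography); lengths uniform in ``length_range`` mm.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    lo, hi = length_range
    if lo < LENGTH_MIN_MM or hi > LENGTH_MAX_MM or lo >= hi:
        raise ValueError(
            f"length_range must be an increasing pair within [{LENGTH_MIN_MM}, {LENGTH_MAX_MM}]"
        )
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_regions, k=1)
    n_pairs = len(iu)
    n_edges = int(round(density * n_pairs))
    n_edges = max(n_edges, 1)
    chosen = rng.choice(n_pairs, size=n_edges, replace=False)

    weights = np.zeros((n_regions, n_regions))
    lengths = np.zeros((n_regions, n_regions))
    w = weight_scale * rng.lognormal(mean=0.0, sigma=1.0, size=n_edges)
    ell = rng.uniform(lo, hi, size=n_edges)
    weights[iu[chosen], ju[chosen]] = w
    lengths[iu[chosen], ju[chosen]] = ell
    weights += weights.T
    lengths += lengths.T
    return Connectome(list(range(n_regions)), weights, lengths)


def make_target_fc(
    connectome: Connectome,
    decay_length: float = 80.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> TargetFC:
    """Distance-decaying target PLV matrix: ``plv = exp(-length/decay_length)``
    plus Gaussian noise, clipped to [0.05, 0.95], symmetrized, unit diagonal."""
    if decay_length <= 0:
        raise ValueError("decay_length must be positive")
    rng = np.random.default_rng(seed)
    n = connectome.n_regions
    base = np.exp(-connectome.lengths / decay_length)
    base[connectome.lengths == 0] = 0.05  # unconnected pairs sit at the floor
    noise = rng.normal(0.0, noise_sd, size=(n, n))
    plv = np.clip(base + (noise + noise.T) / 2.0, 0.05, 0.95)
    plv = (plv + plv.T) / 2.0
    np.fill_diagonal(plv, 1.0)
    return TargetFC(list(connectome.region_ids), plv)


# ---------------------------------------------------------------------------
# prototypical amplitude distributions
# ---------------------------------------------------------------------------

#: component half-separations and mixture weights for the bimodal prototypes;
#: the printed facts are only the means (0 and 0.05), so the component
#: geometry is a declared package default: peaks at mean +/- 0.1 with sd 0.03
#: (symmetric), and an unequal-weight mixture with the same mean and the same
#: total peak separation (asymmetric).
BIMODAL_SD = 0.03
BIMODAL_SEPARATION = 0.2
ASYM_WEIGHTS = (0.65, 0.35)
GAUSSIAN_SD = 0.05

DISTRIBUTION_KINDS = ("bimodal_symmetric", "bimodal_asymmetric", "gaussian")


def make_theoretical_distribution(
    kind: str,
    target_mean: float,
    n_samples: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw samples from one of the three prototypical amplitude distributions.

    ``bimodal_symmetric``: equal-weight Gaussians at ``target_mean +/- 0.1``,
    sd 0.03.  ``bimodal_asymmetric``: weights (0.65, 0.35) with component
    means offset by (+0.07, -0.13) so the mixture mean still equals
    ``target_mean``.  ``gaussian``: single Gaussian, sd 0.05.

    The samples are dimensionless amplitude factors; experiments rescale them
    onto the 0-200 pA intensity axis of the single-node sweeps.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    half = BIMODAL_SEPARATION / 2.0
    if kind == "bimodal_symmetric":
        comp = rng.integers(0, 2, size=n_samples)
        means = np.where(comp == 0, target_mean - half, target_mean + half)
        return rng.normal(means, BIMODAL_SD)
    if kind == "bimodal_asymmetric":
        w_hi, w_lo = ASYM_WEIGHTS
        # offsets d_hi, d_lo with w_hi*d_hi = w_lo*d_lo and d_hi + d_lo = separation
        d_hi = BIMODAL_SEPARATION * w_lo / (w_hi + w_lo)
        d_lo = BIMODAL_SEPARATION * w_hi / (w_hi + w_lo)
        comp = rng.random(n_samples) < w_hi
        means = np.where(comp, target_mean + d_hi, target_mean - d_lo)
        return rng.normal(means, BIMODAL_SD)
    if kind == "gaussian":
        return rng.normal(target_mean, GAUSSIAN_SD, size=n_samples)
    raise ValueError(f"unknown distribution kind: {kind!r}")


# ---------------------------------------------------------------------------
# text I/O (ASCII OFF for meshes, CSV for matrices)
# ---------------------------------------------------------------------------

def save_mesh(mesh: SurfaceMesh, path: str) -> None:
    """Write the mesh as ASCII OFF plus a sidecar CSV of region labels."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    tm.export(path, file_type="off")
    pd.DataFrame({"region": mesh.region_labels}).to_csv(
        str(path) + ".regions.csv", index=False
    )


def load_mesh(path: str) -> SurfaceMesh:
    tm = trimesh.load(path, file_type="off", process=False)
    labels = pd.read_csv(str(path) + ".regions.csv")["region"].to_numpy()
    verts = np.asarray(tm.vertices)
    faces = np.asarray(tm.faces)
    return SurfaceMesh(verts, faces, triangle_normals(verts, faces), labels)


def save_connectome(conn: Connectome, weights_path: str, lengths_path: str) -> None:
    ids = [str(r) for r in conn.region_ids]
    pd.DataFrame(conn.weights, index=ids, columns=ids).to_csv(weights_path)
    pd.DataFrame(conn.lengths, index=ids, columns=ids).to_csv(lengths_path)


def load_connectome(weights_path: str, lengths_path: str) -> Connectome:
    w = pd.read_csv(weights_path, index_col=0)
    l = pd.read_csv(lengths_path, index_col=0)
    return Connectome(list(w.columns), w.to_numpy(), l.to_numpy())
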