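"""Head-model construction for rat cortical-EEG source imaging.

The volume conductor is a single-compartment, homogeneous, isotropic model
of the rat brain (conductivity 0.33 S/m).  It can be built either from a
labeled NIfTI atlas volume or, for self-contained work, from a synthetic
labeled ellipsoid that emulates the gross anatomy (a deep diencephalic
blob, a caudal cerebellar lobe, a ventricle exclusion).

Coordinates are stereotactic millimetres with the bregma as origin:
+x lateral-right, +y anterior, +z dorsal.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "LabeledVolume",
    "TetMesh",
    "ElectrodeMontage",
    "SourceGrid",
    "HeadModel",
    "RAT_REGIONS",
    "DEFAULT_INCLUDE",
    "generate_synthetic_brain",
    "tetrahedralize",
    "mesh_ball",
    "register_electrodes",
    "build_source_grid",
    "build_head_model",
    "default_montage",
]

#: Region labels used by the synthetic rat brain.  "Included" regions are
#: treated as electrically active (they may carry current dipoles);
#: "excluded" regions conduct but carry no sources (e.g. ventricles).
RAT_REGIONS = {
    1: "isocortex",
    2: "diencephalon",
    3: "cerebellum",
    4: "ventricle",
}

#: Default electrically-active label set for the synthetic brain.
DEFAULT_INCLUDE = frozenset({1, 2, 3})

#: Brain-tissue conductivity, S/m (homogeneous isotropic single compartment).
DEFAULT_SIGMA = 0.33


# ---------------------------------------------------------------------------
# Labeled volume
# ---------------------------------------------------------------------------

@dataclass
class LabeledVolume:
    """Voxel array of integer region labels (0 = outside the head).

    ``affine`` maps voxel indices (i, j, k) to stereotactic mm; voxel
    centres sit at ``affine @ (i, j, k, 1)``.
    """

    labels: np.ndarray          # (nx, ny, nz) integer labels
    voxel: float                # voxel edge length, mm
    affine: np.ndarray          # 4x4 voxel-index -> mm

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-300:
            raise ValueError("affine must be invertible")

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.labels))

    def volume_mm3(self) -> float:
        """Total labeled volume (voxel count x voxel volume)."""
        return self.n_voxels * self.voxel ** 3

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points (mm)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]

    def label_at(self, xyz: np.ndarray) -> np.ndarray:
        """Region label of the voxel owning each world point.

        Voxel ownership is half-open: a point belongs to the voxel whose
        centre is nearest below it, i.e. ``floor(voxel_coord + 0.5)``.
        Points outside the array get label 0.
        """
        vc = self.world_to_voxel(xyz)
        idx = np.floor(vc + 0.5).astype(int)
        out = np.zeros(len(idx), dtype=self.labels.dtype)
        ok = np.all((idx >= 0) & (idx < np.array(self.labels.shape)), axis=1)
        out[ok] = self.labels[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
        return out


def _ellipsoid_mask(centres: np.ndarray, centre: np.ndarray,
                    semi_axes: np.ndarray) -> np.ndarray:
    d = (centres - centre) / semi_axes
    return np.einsum("...i,...i->...", d, d) <= 1.0


def generate_synthetic_brain(
    semi_axes: tuple[float, float, float] = (7.5, 10.5, 6.0),
    voxel: float = 0.5,
    regions: list[dict] | None = None,
    centre: tuple[float, float, float] = (0.0, -2.0, -3.0),
) -> LabeledVolume:
    """Build a labeled ellipsoidal stand-in for a rat brain volume.

    The default geometry encloses ~2 cm^3 (the approximate rat brain
    volume) with its dorsal pole just below bregma level, so that
    electrode coordinates quoted as anterior/lateral offsets from bregma
    project onto the dorsal surface.

    Parameters
    ----------
    semi_axes
        Ellipsoid semi-axes (x lateral, y anterior-posterior, z dorsal), mm.
    voxel
        Voxel edge length, mm.  Must be smaller than the smallest semi-axis.
    regions
        Nested sub-region specs ``{"label", "centre", "semi_axes"}``; each
        relabels the voxels of an inner ellipsoid (clipped to the brain
        mask).  ``None`` selects the default diencephalon / cerebellum /
        ventricle layout.
    """
    semi_axes = np.asarray(semi_axes, dtype=float)
    centre = np.asarray(centre, dtype=float)
    if np.any(semi_axes <= 0) or voxel <= 0:
        raise ValueError("semi_axes and voxel must be positive")
    if voxel >= semi_axes.min():
        raise ValueError(
            f"voxel edge {voxel} mm >= smallest semi-axis {semi_axes.min()} mm: "
            "degenerate volume"
        )
    if regions is None:
        # Rough anatomical layout, scaled to the brain ellipsoid: a deep
        # central diencephalon, a caudal cerebellar lobe, and a small
        # ventricle exclusion above the diencephalon.
        s = semi_axes / np.array([7.5, 10.5, 6.0])
        regions = [
            {"label": 2, "centre": centre + s * [0.0, -2.0, -0.5],
             "semi_axes": s * [3.0, 3.0, 2.5]},
            {"label": 3, "centre": centre + s * [0.0, -8.0, 0.0],
             "semi_axes": s * [4.0, 2.8, 2.8]},
            {"label": 4, "centre": centre + s * [0.0, 1.5, 1.0],
             "semi_axes": s * [1.2, 2.0, 0.9]},
        ]

    # Anchor the voxel lattice at a multiple of the voxel pitch so that
    # voxel centres land on the stereotactic mm lattice (keeps source-grid
    # points strictly inside voxels rather than on voxel faces).
    lo = voxel * np.floor((centre - semi_axes - voxel) / voxel)
    hi = centre + semi_axes + voxel
    shape = np.ceil((hi - lo) / voxel).astype(int) + 1
    origin = lo
    affine = np.eye(4)
    affine[:3, :3] *= voxel
    affine[:3, 3] = origin

    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    cent = np.stack([ii, jj, kk], axis=-1) * voxel + origin

    labels = np.zeros(tuple(shape), dtype=np.int16)
    brain = _ellipsoid_mask(cent, centre, semi_axes)
    labels[brain] = 1
    for reg in regions:
        sub = _ellipsoid_mask(cent, np.asarray(reg["centre"], float),
                              np.asarray(reg["semi_axes"], float))
        labels[brain & sub] = int(reg["label"])
    return LabeledVolume(labels=labels, voxel=voxel, affine=affine)


# ---------------------------------------------------------------------------
# Tetrahedral meshing
# ---------------------------------------------------------------------------

@dataclass
class TetMesh:
    """Single-compartment tetrahedral volume conductor.

    ``sigma`` holds per-element conductivity in S/m (default homogeneous
    0.33 S/m).  Element node orderings are positively oriented.
    """

    nodes: np.ndarray           # (M, 3) mm
    elems: np.ndarray           # (E, 4) node indices
    sigma: np.ndarray           # (E,) S/m
    _boundary_nodes: np.ndarray | None = field(default=None, repr=False)
    _kdtree: cKDTree | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elems = np.asarray(self.elems, dtype=np.int64)
        self.sigma = np.broadcast_to(
            np.asarray(self.sigma, dtype=float), (len(self.elems),)
        ).copy()
        if np.any(self.sigma <= 0):
            raise ValueError("conductivity must be positive everywhere")
        self._orient_positive()

    def _orient_positive(self) -> None:
        vol6 = self._signed_volumes6()
        flip = vol6 < 0
        if np.any(flip):
            e = self.elems[flip]
            e[:, [2, 3]] = e[:, [3, 2]]
            self.elems[flip] = e
            vol6 = np.abs(vol6)
        bad = np.nonzero(vol6 <= 0)[0]
        if bad.size:
            raise ValueError(f"degenerate (zero-volume) element(s): {bad[:5].tolist()}")

    def _signed_volumes6(self) -> np.ndarray:
        p = self.nodes[self.elems]
        a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elems(self) -> int:
        return len(self.elems)

    def volumes(self) -> np.ndarray:
        return self._signed_volumes6() / 6.0

    def total_volume(self) -> float:
        return float(self.volumes().sum())

    def boundary_faces(self) -> np.ndarray:
        """Triangular faces that belong to exactly one tetrahedron."""
        f = self.elems[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]]
        f = np.sort(f.reshape(-1, 3), axis=1)
        uniq, counts = np.unique(f, axis=0, return_counts=True)
        return uniq[counts == 1]

    def boundary_nodes(self) -> np.ndarray:
        if self._boundary_nodes is None:
            self._boundary_nodes = np.unique(self.boundary_faces())
        return self._boundary_nodes

    # -- point location -----------------------------------------------------

    def _incidence(self) -> list[np.ndarray]:
        if not hasattr(self, "_node_elems"):
            node_elems: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for ei, el in enumerate(self.elems):
                for n in el:
                    node_elems[n].append(ei)
            self._node_elems = [np.asarray(v) for v in node_elems]
        return self._node_elems

    def find_element(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Element index containing each point, or -1 if outside.

        Candidate elements are those incident to the few nearest mesh
        nodes; a point strictly inside the mesh is always found because
        its containing element touches its nearest node's 2-ring.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self._kdtree is None:
            self._kdtree = cKDTree(self.nodes)
        incid = self._incidence()
        _, nn = self._kdtree.query(points, k=min(8, self.n_nodes))
        nn = np.atleast_2d(nn)
        out = np.full(len(points), -1, dtype=np.int64)
        for i, pt in enumerate(points):
            cand = np.unique(np.concatenate([incid[n] for n in nn[i]]))
            bary = self.barycentric(pt, cand)
            inside = np.all(bary >= -tol, axis=1)
            hits = np.nonzero(inside)[0]
            if hits.size:
                out[i] = cand[hits[0]]
        return out

    def barycentric(self, point: np.ndarray, elems: np.ndarray) -> np.ndarray:
        p = self.nodes[self.elems[elems]]        # (E, 4, 3)
        T = np.transpose(p[:, 1:] - p[:, :1], (0, 2, 1))   # (E, 3, 3)
        rhs = (point - p[:, 0])[..., None]
        lam = np.linalg.solve(T, rhs)[..., 0]
        return np.column_stack([1 - lam.sum(axis=1), lam])

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.find_element(points) >= 0


# Kuhn 6-tetrahedron decomposition of a unit cube.  Corner index = i + 2j
# + 4k; every tet contains the main diagonal (corner 0 -> corner 7), which
# makes the subdivision conforming across neighbouring cubes.
_KUHN_TETS = np.array([
    [0, 1, 3, 7],
    [0, 1, 5, 7],
    [0, 2, 3, 7],
    [0, 2, 6, 7],
    [0, 4, 5, 7],
    [0, 4, 6, 7],
])
_CUBE_CORNERS = np.array(
    [[i, j, k] for k in (0, 1) for j in (0, 1) for i in (0, 1)]
)[np.argsort([i + 2 * j + 4 * k for k in (0, 1) for j in (0, 1) for i in (0, 1)])]


def tetrahedralize(vol: LabeledVolume, target_edge: float | None = None,
                   sigma: float = DEFAULT_SIGMA) -> TetMesh:
    """Tetrahedralize a labeled voxel volume into a volume conductor.

    Each labeled voxel cube is split into six conforming tetrahedra
    (Kuhn subdivision), so the mesh volume equals the voxel-count volume
    exactly and no sliver elements can occur.  ``target_edge`` resamples
    the volume to a different cube size first (nearest-neighbour label
    lookup at the new voxel centres).
    """
    if vol.n_voxels == 0:
        raise ValueError("empty mask: nothing to mesh")
    if target_edge is not None and not np.isclose(target_edge, vol.voxel):
        vol = _resample(vol, target_edge)
        if vol.n_voxels == 0:
            raise ValueError("empty mask after resampling to target edge")
    vox_idx = np.argwhere(vol.mask)              # (V, 3)
    corners = vox_idx[:, None, :] + _CUBE_CORNERS[None, :, :]     # (V, 8, 3)
    shape = np.asarray(vol.labels.shape) + 1
    flat = np.ravel_multi_index(corners.reshape(-1, 3).T, shape)
    uniq, inv = np.unique(flat, return_inverse=True)
    node_ijk = np.column_stack(np.unravel_index(uniq, shape)).astype(float)
    # The affine maps voxel indices to voxel centres; cube corners sit
    # half a voxel below/above the centre.
    nodes = vol.voxel_to_world(node_ijk - 0.5)
    corner_ids = inv.reshape(-1, 8)              # (V, 8)
    elems = corner_ids[:, _KUHN_TETS].reshape(-1, 4)
    return TetMesh(nodes=nodes, elems=elems, sigma=sigma)


def _resample(vol: LabeledVolume, edge: float) -> LabeledVolume:
    lo = vol.affine[:3, 3] - vol.voxel
    extent = np.asarray(vol.labels.shape) * vol.voxel + vol.voxel
    shape = np.ceil(extent / edge).astype(int) + 1
    affine = np.eye(4)
    affine[:3, :3] *= edge
    affine[:3, 3] = lo
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    cent = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * edge + lo
    lab = vol.label_at(cent).reshape(tuple(shape))
    return LabeledVolume(labels=lab, voxel=edge, affine=affine)


def mesh_ball(radius: float, edge: float, sigma: float = DEFAULT_SIGMA,
              centre: tuple[float, float, float] = (0.0, 0.0, 0.0),
              lloyd_iters: int = 20, seed: int = 0) -> TetMesh:
    """Mesh a homogeneous ball with surface nodes exactly on the sphere.

    Nodes are laid out on concentric Fibonacci shells (each given an
    independent random orientation so no global direction is favoured by
    the discretization), relaxed by Lloyd iterations of the Delaunay
    mesh, and tetrahedralized by a final Delaunay pass.  Used by the
    analytic-sphere validation of the FEM forward solver.
    """
    if edge >= radius:
        raise ValueError("edge must be smaller than radius")
    centre = np.asarray(centre, dtype=float)
    rng = np.random.default_rng(seed)

    def fib_shell(r: float, n: int) -> np.ndarray:
        i = np.arange(n)
        phi = np.pi * (3.0 - np.sqrt(5.0)) * i
        z = 1 - 2 * (i + 0.5) / n
        rho = np.sqrt(np.clip(1 - z * z, 0, None))
        return r * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])

    n_shells = max(2, int(round(radius / edge)))
    radii = np.linspace(0, radius, n_shells + 1)[1:]
    pts = [np.zeros((1, 3))]
    for r in radii[:-1]:
        n = max(8, int(np.ceil(4 * np.pi * r ** 2 / (0.7 * edge ** 2))))
        rot = Rotation.random(random_state=rng.integers(2 ** 31)).as_matrix()
        pts.append(fib_shell(r, n) @ rot.T)
    rot = Rotation.random(random_state=rng.integers(2 ** 31)).as_matrix()
    n_surf = int(np.ceil(4 * np.pi * radius ** 2 / (0.7 * edge ** 2)))
    surf = fib_shell(radius, n_surf) @ rot.T
    interior = np.vstack(pts)
    n_int = len(interior)

    for _ in range(lloyd_iters):
        allp = np.vstack([interior, surf])
        el = Delaunay(allp).simplices
        p = allp[el]
        v6 = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                       np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]))
        vol = np.abs(v6) / 6.0
        cent = p.mean(axis=1)
        num = np.zeros((len(allp), 3))
        den = np.zeros(len(allp))
        w = vol[:, None] * cent
        for c in range(4):
            np.add.at(num, el[:, c], w)
            np.add.at(den, el[:, c], vol)
        newp = num / den[:, None]
        r2 = np.linalg.norm(newp[:n_int], axis=1)
        fac = np.minimum(1.0, (radius - 0.3 * edge) / np.maximum(r2, 1e-12))
        interior = newp[:n_int] * fac[:, None]

    allp = np.vstack([interior, surf])
    el = Delaunay(allp).simplices
    p = allp[el]
    v6 = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                   np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]))
    keep = np.abs(v6) > 1e-9 * np.median(np.abs(v6))
    el = el[keep]
    used = np.unique(el)
    remap = -np.ones(len(allp), dtype=np.int64)
    remap[used] = np.arange(used.size)
    return TetMesh(nodes=allp[used] + centre, elems=remap[el], sigma=sigma)


# ---------------------------------------------------------------------------
# Electrode registration
# ---------------------------------------------------------------------------

@dataclass
class ElectrodeMontage:
    """Electrode montage registered onto the mesh surface.

    Each channel is snapped to the nearest boundary node of the volume
    conductor; ``snap_distance`` records the nominal-to-node distance per
    channel and ``far_flags`` marks channels beyond ``max_snap``.
    Exactly one channel is the recording reference.
    """

    labels: list[str]
    nominal: np.ndarray         # (n, 3) mm
    node_index: np.ndarray      # (n,) mesh node per channel
    snap_distance: np.ndarray   # (n,) mm
    reference: str
    far_flags: np.ndarray       # (n,) bool

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def active(self) -> np.ndarray:
        """Indices of non-reference channels, montage order preserved."""
        return np.array([i for i, l in enumerate(self.labels)
                         if l != self.reference])

    @property
    def reference_index(self) -> int:
        return self.labels.index(self.reference)

    def positions(self, mesh: TetMesh) -> np.ndarray:
        return mesh.nodes[self.node_index]


def register_electrodes(mesh: TetMesh, coords: pd.DataFrame,
                        reference: str | None = None,
                        max_snap: float = 5.0) -> ElectrodeMontage:
    """Snap nominal electrode coordinates to the nearest mesh surface node.

    ``coords`` needs columns ``label, x_mm, y_mm, z_mm``.  The reference
    channel defaults to a row labelled ``Ref`` if present, else the first
    row.  Re-registering already-registered coordinates is idempotent
    (snap distance 0).
    """
    labels = [str(l) for l in coords["label"]]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate electrode labels")
    xyz = coords[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    if reference is None:
        reference = "Ref" if "Ref" in labels else labels[0]
    if reference not in labels:
        raise ValueError(f"reference channel {reference!r} not in montage")
    bnodes = mesh.boundary_nodes()
    tree = cKDTree(mesh.nodes[bnodes])
    k = min(len(labels) + 1, len(bnodes))
    dists, idxs = tree.query(xyz, k=k)
    dists = np.atleast_2d(dists)
    idxs = np.atleast_2d(idxs)
    # Greedy distinct-node assignment: on coarse meshes two electrodes can
    # share a nearest node, which would short them together.
    node_index = np.empty(len(labels), dtype=np.int64)
    dist = np.empty(len(labels))
    used: set[int] = set()
    for i in np.argsort(dists[:, 0]):
        for j in range(k):
            cand = int(bnodes[idxs[i, j]])
            if cand not in used:
                node_index[i] = cand
                dist[i] = dists[i, j]
                used.add(cand)
                break
        else:
            raise ValueError("not enough distinct boundary nodes for montage")
    return ElectrodeMontage(
        labels=labels,
        nominal=xyz,
        node_index=node_index,
        snap_distance=dist,
        reference=reference,
        far_flags=dist > max_snap,
    )


def default_montage() -> pd.DataFrame:
    """The 12-channel rat cortical montage plus its reference electrode.

    Anterior/lateral offsets are stereotactic mm from bregma; the dorsal
    coordinate is nominal (above the brain) and is resolved by surface
    snapping during registration.  Odd labels are left-hemisphere.
    """
    path = importlib.resources.files("ratesi.data") / "montage12.tsv"
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


# ---------------------------------------------------------------------------
# Source grid
# ---------------------------------------------------------------------------

#: Offsets of the 26-neighbourhood on a cubic lattice.
_OFFSETS26 = np.array([(i, j, k)
                       for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                       if (i, j, k) != (0, 0, 0)])


@dataclass
class SourceGrid:
    """Regular volumetric dipole grid restricted to active regions.

    ``lattice`` holds integer lattice indices (positions = lattice *
    spacing + origin); ``neighbors`` is the 26-neighbourhood adjacency
    restricted to grid members.
    """

    positions: np.ndarray       # (P, 3) mm
    spacing: float              # mm
    labels: np.ndarray          # (P,) region label per dipole
    lattice: np.ndarray         # (P, 3) integer lattice indices
    origin: np.ndarray          # (3,) mm, lattice origin
    neighbors: list[np.ndarray] # adjacency lists

    @property
    def n_dipoles(self) -> int:
        return len(self.positions)

    def raster_shape(self) -> tuple[np.ndarray, tuple[int, int, int]]:
        """Offset and shape of the minimal lattice box enclosing the grid."""
        lo = self.lattice.min(axis=0)
        hi = self.lattice.max(axis=0)
        return lo, tuple(hi - lo + 1)

    def rasterize(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter per-dipole values into a dense 3-D lattice box."""
        lo, shape = self.raster_shape()
        out = np.full(shape, fill, dtype=float)
        idx = self.lattice - lo
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = values
        return out

    def raster_index(self) -> np.ndarray:
        """Flat raster position of each dipole (inverse of :meth:`rasterize`)."""
        lo, shape = self.raster_shape()
        idx = self.lattice - lo
        return np.ravel_multi_index(idx.T, shape)


def build_source_grid(vol: LabeledVolume, spacing: float = 1.0,
                      include: frozenset[int] | set[int] = DEFAULT_INCLUDE,
                      ) -> SourceGrid:
    """Place dipoles on a regular lattice inside the active regions.

    A lattice point belongs to the grid iff the voxel owning it (half-open
    ownership) carries a label in ``include``.  The lattice is anchored at
    the stereotactic origin so dipole coordinates are integer multiples of
    ``spacing``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    include = frozenset(int(x) for x in include)
    if not include:
        raise ValueError("empty include set")
    present = set(np.unique(vol.labels).tolist()) - {0}
    if not include <= present:
        raise ValueError(f"include labels {sorted(include - present)} not present")

    corner0 = vol.voxel_to_world([0, 0, 0])[0]
    corner1 = vol.voxel_to_world(np.asarray(vol.labels.shape, float) - 1)[0]
    lo = np.ceil(np.minimum(corner0, corner1) / spacing).astype(int)
    hi = np.floor(np.maximum(corner0, corner1) / spacing).astype(int)
    axes = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    lattice = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    pos = lattice * spacing
    lab = vol.label_at(pos)
    keep = np.isin(lab, list(include))
    lattice, pos, lab = lattice[keep], pos[keep], lab[keep]
    if len(pos) == 0:
        raise ValueError("no lattice points fall inside the included regions")

    index = {tuple(l): i for i, l in enumerate(lattice)}
    neighbors = []
    for l in lattice:
        nb = [index[t] for off in _OFFSETS26
              if (t := tuple(l + off)) in index]
        neighbors.append(np.asarray(nb, dtype=np.int64))
    return SourceGrid(positions=pos.astype(float), spacing=float(spacing),
                      labels=lab, lattice=lattice,
                      origin=np.zeros(3), neighbors=neighbors)


# ---------------------------------------------------------------------------
# Convenience builder
# ---------------------------------------------------------------------------

@dataclass
class HeadModel:
    """A consistent volume / mesh / montage / source-grid bundle."""

    volume: LabeledVolume
    mesh: TetMesh
    montage: ElectrodeMontage
    grid: SourceGrid


def build_head_model(
    semi_axes: tuple[float, float, float] = (7.5, 10.5, 6.0),
    voxel: float = 0.5,
    grid_spacing: float = 1.0,
    include: frozenset[int] | set[int] = DEFAULT_INCLUDE,
    montage: pd.DataFrame | None = None,
    sigma: float = DEFAULT_SIGMA,
) -> HeadModel:
    """Build the synthetic rat head model end to end.

    The mesh and source grid are derived from the same labeled volume at
    the same resolution, which guarantees every dipole lies inside the
    conductor.  ``voxel`` controls both the segmentation and the mesh edge
    length; ``grid_spacing`` defaults to the 1 mm dipole lattice.
    """
    vol = generate_synthetic_brain(semi_axes=semi_axes, voxel=voxel)
    mesh = tetrahedralize(vol, sigma=sigma)
    mont = register_electrodes(mesh, montage if montage is not None
                               else default_montage())
    grid = build_source_grid(vol, spacing=grid_spacing, include=include)
    return HeadModel(volume=vol, mesh=mesh, montage=mont, grid=grid)
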