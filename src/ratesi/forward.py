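"""EEG forward problem: FEM lead fields for the single-compartment model.

The electrode potentials X generated by dipole moments Y follow the linear
model ``X = K Y + e``; this module computes the gain (lead-field) matrix K
by solving the quasi-static Poisson equation with linear (P1) Lagrange
finite elements on a tetrahedral mesh, St. Venant dipole loads, and a
transfer-matrix scheme (one FEM solve per electrode instead of one per
dipole).

Unit convention (pinned by a round-trip test against the analytic sphere
solution): mesh coordinates in mm, conductivity in S/m, dipole moments in
A·m, potentials in V.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import scipy.sparse as sp
from scipy.linalg import null_space
from scipy.sparse.linalg import splu

from .headmodel import ElectrodeMontage, SourceGrid, TetMesh

__all__ = [
    "DipoleSpec",
    "LeadField",
    "assemble_fem_system",
    "st_venant_load",
    "st_venant_unit_loads",
    "compute_lead_field",
    "analytic_sphere_potential",
]

# mm-based assembly -> SI: stiffness scales by 1e-3 (mm -> m) and the
# moment-matching right-hand side by 1e+3, so K_SI = 1e6 * K_mm.
_MM_TO_SI = 1.0e6


@dataclass
class DipoleSpec:
    """A current dipole: position (mm) and moment vector (A·m)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.moment = np.asarray(self.moment, dtype=float).reshape(3)
        if not np.linalg.norm(self.moment) > 0:
            raise ValueError("dipole moment must be non-zero")


@dataclass
class LeadField:
    """Gain matrix linking dipole moments to electrode potentials.

    ``K`` has shape (N, P, 3): volts at electrode n per unit dipole moment
    (A·m) along axis a at grid position p.  ``referencing`` records whether
    potentials are against the reference electrode or average-referenced.
    """

    K: np.ndarray               # (N, P, 3)
    montage: ElectrodeMontage
    grid: SourceGrid
    referencing: str            # "reference" | "average"
    units: str = "V per (A*m)"

    @property
    def n_channels(self) -> int:
        return self.K.shape[0]

    @property
    def n_dipoles(self) -> int:
        return self.K.shape[1]

    def block(self, p: int) -> np.ndarray:
        """N x 3 lead-field block of dipole p."""
        return self.K[:, p, :]

    def matrix(self) -> np.ndarray:
        """Flat N x 3P gain matrix (dipole-major column blocks)."""
        n = self.n_channels
        return self.K.reshape(n, -1)

    def average_referenced(self) -> "LeadField":
        if self.referencing == "average":
            return self
        return LeadField(K=self.K - self.K.mean(axis=0, keepdims=True),
                         montage=self.montage, grid=self.grid,
                         referencing="average", units=self.units)

    # -- persistence --------------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("K", data=self.matrix())
            f.create_dataset("positions", data=self.grid.positions)
            f.create_dataset(
                "labels",
                data=np.array([self.montage.labels[i] for i in self.montage.active],
                              dtype=h5py.string_dtype()),
            )
            f.attrs["units"] = self.units
            f.attrs["referencing"] = self.referencing
            f.attrs["grid_spacing_mm"] = self.grid.spacing


def assemble_fem_system(mesh: TetMesh) -> sp.csc_matrix:
    """Assemble the P1 FEM stiffness operator for the Poisson equation.

    With the insulating (natural Neumann) boundary the operator is
    symmetric positive semi-definite with row sums zero; its null space is
    the constant potential.  Units: S·mm (mm coordinates, S/m
    conductivity).
    """
    p = mesh.nodes[mesh.elems]                  # (E, 4, 3)
    T = p[:, 1:] - p[:, :1]                     # (E, 3, 3) edge matrix rows
    detT = np.linalg.det(T)
    bad = np.nonzero(np.abs(detT) < 1e-300)[0]
    if bad.size:
        raise ValueError(f"degenerate element(s) in FEM assembly: {bad[:5].tolist()}")
    vol = np.abs(detT) / 6.0
    Tinv = np.linalg.inv(T)                     # columns are grad(lambda_1..3)
    grads = np.empty((len(mesh.elems), 4, 3))
    grads[:, 1:, :] = np.transpose(Tinv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    local = np.einsum("e,eid,ejd->eij", mesh.sigma * vol, grads, grads)
    rows = np.repeat(mesh.elems, 4, axis=1).reshape(-1)
    cols = np.tile(mesh.elems, (1, 4)).reshape(-1)
    A = sp.coo_matrix((local.reshape(-1), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes))
    return A.tocsc()


def _node_adjacency(mesh: TetMesh) -> list[np.ndarray]:
    """Edge-connected node neighbour lists (cached on the mesh object)."""
    if not hasattr(mesh, "_node_adj"):
        pairs = mesh.elems[:, [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]]
        pairs = pairs.reshape(-1, 2)
        pairs = np.unique(np.sort(pairs, axis=1), axis=0)
        adj: list[list[int]] = [[] for _ in range(mesh.n_nodes)]
        for a, b in pairs:
            adj[a].append(b)
            adj[b].append(a)
        mesh._node_adj = [np.asarray(v, dtype=np.int64) for v in adj]
    return mesh._node_adj


def st_venant_unit_loads(mesh: TetMesh, position: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """St. Venant monopole loads for unit dipole moments along x, y, z.

    The dipole is approximated by monopole loads on the mesh node nearest
    to ``position`` and its edge-connected neighbours, chosen as the
    minimum-norm solution matching the zeroth moment (total load 0) and the
    first moment (the dipole moment) exactly.

    Returns ``(node_indices, Q)`` with ``Q`` of shape (k, 3): column a
    holds the loads reproducing a unit moment along axis a (A·m, with
    positions in mm, so the matching is done in mm and rescaled).
    """
    position = np.asarray(position, dtype=float).reshape(3)
    if not mesh.contains(position)[0]:
        raise ValueError(f"dipole position {position} is outside the mesh")
    if mesh._kdtree is None:
        from scipy.spatial import cKDTree
        mesh._kdtree = cKDTree(mesh.nodes)
    _, nearest = mesh._kdtree.query(position)
    adj = _node_adjacency(mesh)
    idx = np.concatenate([[nearest], adj[nearest]])
    if len(idx) < 14:                           # widen to the 2-ring when the
        idx = np.unique(np.concatenate(         # 1-ring is too small to also
            [idx] + [adj[n] for n in idx]))     # control the quadrupole
    d = mesh.nodes[idx] - position              # (k, 3) mm
    X = np.vstack([np.ones(len(idx)), d.T])     # (4, k) constraint matrix
    B = np.vstack([np.zeros(3), np.eye(3)])     # unit moments, zero monopole
    Q, *_ = np.linalg.lstsq(X, B, rcond=None)   # minimum-norm exact match
    # Suppress the leading (quadrupole) artifact within the null space of
    # the exact constraints; this keeps monopole and dipole moments exact
    # to machine precision while cancelling the next-order source error.
    pairs = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    Xq = np.array([d[:, a] * d[:, b] for a, b in pairs])
    Z = null_space(X)
    if Z.shape[1]:
        U, *_ = np.linalg.lstsq(Xq @ Z, -Xq @ Q, rcond=None)
        Q = Q + Z @ U
    return idx, Q


def st_venant_load(mesh: TetMesh, dipole: DipoleSpec) -> np.ndarray:
    """Dense node load vector for a dipole (moment in A·m, matching in mm)."""
    idx, Q = st_venant_unit_loads(mesh, dipole.position)
    b = np.zeros(mesh.n_nodes)
    b[idx] = Q @ dipole.moment
    return b


def compute_lead_field(mesh: TetMesh, montage: ElectrodeMontage,
                       grid: SourceGrid, average_reference: bool = True,
                       method: str = "transfer") -> LeadField:
    """Compute the lead field K for all grid dipoles and montage channels.

    ``method="transfer"`` (default) performs one FEM solve per electrode:
    the singular Neumann system is deflated by grounding the reference
    electrode's node, the sparse factorization is reused across
    right-hand sides, and K entries are inner products of transfer rows
    with St. Venant load vectors.  ``method="direct"`` solves one FEM
    system per dipole instead (the small-mesh consistency oracle).
    """
    if method not in ("transfer", "direct"):
        raise ValueError(f"unknown method {method!r}")
    A = assemble_fem_system(mesh)
    ref_node = montage.node_index[montage.reference_index]
    keep = np.ones(mesh.n_nodes, dtype=bool)
    keep[ref_node] = False
    A_red = A[keep][:, keep].tocsc()
    red_of = np.cumsum(keep) - 1                # full -> reduced index
    try:
        lu = splu(A_red)
    except RuntimeError as exc:                 # pragma: no cover
        raise ValueError(f"singular FEM system (disconnected mesh?): {exc}")

    act = montage.active
    elec_nodes = montage.node_index[act]
    P = grid.n_dipoles
    K = np.empty((len(act), P, 3))

    if method == "transfer":
        rhs = np.zeros((A_red.shape[0], len(act)))
        for j, node in enumerate(elec_nodes):
            if node == ref_node:
                raise ValueError("active electrode coincides with reference node")
            rhs[red_of[node], j] = 1.0
        T = lu.solve(rhs).T                     # (N, M-1) transfer rows
        for p in range(P):
            idx, Q = st_venant_unit_loads(mesh, grid.positions[p])
            m = idx != ref_node
            K[:, p, :] = T[:, red_of[idx[m]]] @ Q[m]
    else:
        for p in range(P):
            idx, Q = st_venant_unit_loads(mesh, grid.positions[p])
            b = np.zeros((A_red.shape[0], 3))
            m = idx != ref_node
            b[red_of[idx[m]]] = Q[m]
            phi = lu.solve(b)                   # (M-1, 3)
            K[:, p, :] = phi[red_of[elec_nodes]]

    K *= _MM_TO_SI                              # V per (A*m)
    lf = LeadField(K=K, montage=montage, grid=grid, referencing="reference")
    return lf.average_referenced() if average_reference else lf


# ---------------------------------------------------------------------------
# Analytic oracle: dipole in a homogeneous conducting sphere
# ---------------------------------------------------------------------------

def _legendre_pair(n_max_x: np.ndarray):
    """Generator of (n, P_n(x), P_n'(x)) via stable three-term recurrences."""
    x = n_max_x
    p_prev = np.ones_like(x)
    p = x.copy()
    dp_prev = np.zeros_like(x)
    dp = np.ones_like(x)
    n = 1
    while True:
        yield n, p, dp
        p_next = ((2 * n + 1) * x * p - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p
        p_prev, p = p, p_next
        dp_prev, dp = dp, dp_next
        n += 1


def analytic_sphere_potential(radius: float, sigma: float, dipole: DipoleSpec,
                              surface_points: np.ndarray,
                              tol: float = 1e-10, n_max: int = 2000
                              ) -> np.ndarray:
    """Surface potential of a dipole inside a homogeneous conducting sphere.

    Truncated spherical-harmonic series for the insulated (Neumann) sphere,
    centred at the origin.  For an eccentric dipole at radius b with moment
    m the surface potential at direction e is

        V = (4*pi*sigma)^-1 * sum_n (2n+1)/n * b^(n-1)/R^(n+1)
            * [ n*m_r*P_n(c) + P_n'(c)*(m.e - c*m_r) ],   c = r0_hat . e,

    which reduces to the classic 3*(m.e)/(4*pi*sigma*R^2) for a central
    dipole.  Inputs in mm / S/m / A·m, output in volts.  The series is
    truncated once a term falls below ``tol`` of the running sum.
    """
    R = radius * 1e-3                           # -> metres
    r0 = dipole.position * 1e-3
    m = dipole.moment
    pts = np.atleast_2d(np.asarray(surface_points, dtype=float)) * 1e-3
    b = np.linalg.norm(r0)
    if b >= R * (1 - 1e-9):
        raise ValueError("dipole must lie strictly inside the sphere")
    if not np.allclose(np.linalg.norm(pts, axis=1), R, rtol=1e-6):
        raise ValueError("surface points must lie on the sphere")

    e = pts / R
    pref = 1.0 / (4 * np.pi * sigma)
    if b < 1e-12 * R:
        return pref * 3.0 * (e @ m) / R ** 2

    r0_hat = r0 / b
    c = e @ r0_hat
    m_r = float(m @ r0_hat)
    m_dot_e = e @ m
    V = np.zeros(len(e))
    for n, p, dp in _legendre_pair(c):
        radial = (2 * n + 1) / n * b ** (n - 1) / R ** (n + 1)
        term = pref * radial * (n * m_r * p + dp * (m_dot_e - c * m_r))
        V += term
        scale = np.max(np.abs(V))
        if n > 10 and np.max(np.abs(term)) < tol * max(scale, 1e-300):
            break
        if n >= n_max:
            break
    return V
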