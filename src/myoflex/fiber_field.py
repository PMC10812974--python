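"""Muscle fiber directions from a harmonic potential.

A Laplace problem is solved on the muscle region with the two tendon
attachment surfaces as Dirichlet boundaries (potential 0 at the source, 1 at
the sink); the per-element gradient of the linear interpolant, normalised,
gives the reference fiber direction of each muscle element.  Directions are
element-wise constant because linear tetrahedra have constant gradients; no
smoothing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .fem_core import Mesh

__all__ = ["ScalarField", "FiberField", "solve_laplace", "fiber_directions"]


@dataclass(frozen=True)
class ScalarField:
    """Nodal scalar field; NaN on nodes outside the muscle region."""

    values: np.ndarray


@dataclass(frozen=True)
class FiberField:
    """Unit fiber direction per muscle element.

    ``elements`` are the muscle element indices into the parent mesh;
    ``directions`` the matching unit vectors.
    """

    elements: np.ndarray
    directions: np.ndarray

    def expand(self, mesh: Mesh) -> np.ndarray:
        """Full-size (n_elements, 3) array; unit x for non-muscle rows."""
        out = np.zeros((mesh.n_elements, 3))
        out[:, 0] = 1.0
        out[self.elements] = self.directions
        return out


def _muscle_submesh(mesh: Mesh):
    elems = np.nonzero(mesh.region == "muscle")[0]
    if len(elems) == 0:
        raise ValueError("mesh has no muscle region")
    cells = mesh.cells[elems]
    nodes = np.unique(cells)
    return elems, cells, nodes


def solve_laplace(mesh: Mesh, source_set: str, sink_set: str) -> ScalarField:
    """Linear-tetrahedron Galerkin solution of ``div grad phi = 0``.

    ``phi = 0`` on the source node set and ``phi = 1`` on the sink set, both
    restricted to the muscle region.  The reduced linear system is solved to a
    relative residual of 1e-10 or better; the discrete maximum principle keeps
    ``phi`` within [0, 1] on well-shaped meshes.
    """
    elems, cells, nodes = _muscle_submesh(mesh)
    src = np.intersect1d(mesh.set_nodes(source_set), nodes)
    snk = np.intersect1d(mesh.set_nodes(sink_set), nodes)
    if len(src) == 0 or len(snk) == 0:
        raise ValueError("source/sink sets must be non-empty on the muscle region")
    if len(np.intersect1d(src, snk)):
        raise ValueError("source and sink sets overlap")

    # connectivity check on the muscle region
    loc = np.full(mesh.n_nodes, -1, dtype=np.int64)
    loc[nodes] = np.arange(len(nodes))
    lc = loc[cells]
    pairs_i = lc[:, [0, 0, 0, 1, 1, 2]].ravel()
    pairs_j = lc[:, [1, 2, 3, 2, 3, 3]].ravel()
    adj = sp.coo_matrix(
        (np.ones(len(pairs_i)), (pairs_i, pairs_j)), shape=(len(nodes),) * 2
    )
    n_comp, _ = csgraph.connected_components(adj, directed=False)
    if n_comp != 1:
        raise ValueError("muscle region is disconnected")

    sub = Mesh(mesh.points[nodes], lc, mesh.region[elems])
    G = sub.shape_gradients()
    V = sub.volumes()
    ke = np.einsum("e,eai,ebi->eab", V, G, G)
    rows = np.repeat(lc, 4, axis=1).ravel()
    cols = np.tile(lc, (1, 4)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(len(nodes),) * 2).tocsr()

    phi = np.zeros(len(nodes))
    phi[loc[snk]] = 1.0
    fixed = np.zeros(len(nodes), dtype=bool)
    fixed[loc[src]] = True
    fixed[loc[snk]] = True
    free = np.nonzero(~fixed)[0]
    fixed_ids = np.nonzero(fixed)[0]
    rhs = -K[free][:, fixed_ids].dot(phi[fixed_ids])
    Kff = K[free][:, free].tocsc()
    phi[free] = spla.spsolve(Kff, rhs)

    res = np.linalg.norm(Kff.dot(phi[free]) - rhs)
    scale = max(np.linalg.norm(rhs), 1e-30)
    if res / scale > 1e-10:
        raise RuntimeError(f"Laplace solve residual too large: {res / scale:.3e}")

    values = np.full(mesh.n_nodes, np.nan)
    values[nodes] = phi
    return ScalarField(values=values)


def fiber_directions(mesh: Mesh, phi: ScalarField, source_set: str = None,
                     sink_set: str = None) -> FiberField:
    """Normalised per-element gradients of the potential on the muscle region.

    The orientation sign is fixed for reproducibility: each direction is
    flipped, if needed, to have a positive component along the source-to-sink
    centroid axis (when the sets are given) or along the mean gradient.
    Raises on zero-gradient (degenerate) elements, naming them.
    """
    elems, cells, nodes = _muscle_submesh(mesh)
    G = mesh.shape_gradients()[elems]
    vals = phi.values[cells]
    grad = np.einsum("ea,eai->ei", vals, G)
    nrm = np.linalg.norm(grad, axis=1)
    bad = np.nonzero(nrm <= 1e-12)[0]
    if len(bad):
        raise ValueError(
            f"zero potential gradient in muscle element(s) {elems[bad].tolist()}"
        )
    d = grad / nrm[:, None]

    if source_set is not None and sink_set is not None:
        axis = mesh.points[mesh.set_nodes(sink_set)].mean(axis=0) - mesh.points[
            mesh.set_nodes(source_set)
        ].mean(axis=0)
    else:
        axis = d.mean(axis=0)
    axis_n = np.linalg.norm(axis)
    if axis_n > 0.0:
        flip = d @ (axis / axis_n) < 0.0
        d[flip] *= -1.0
    return FiberField(elements=elems, directions=d)
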