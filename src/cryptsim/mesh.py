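"""Triangulated semi-flexible polymer network representing the basal membrane.

The basal membrane (BM) separating the epithelium from the sub-epithelial
fibroblasts is discretized as a triangle mesh whose edges are harmonic
springs and whose interior (hinge) edges carry a dihedral bending energy:

    E = sum_edges 1/2 * k_stretch * (l - l_rest)^2
      + sum_inner_edges k_bend * (1 - cos(theta - theta_0))

with ``theta`` the signed dihedral angle between the two adjacent triangle
normals and ``theta_0`` a (per-edge) spontaneous angle, zero by default.
The membrane permanently re-organizes: edges stretched beyond ``l_max``
are split (strain-preserving, so re-organization does not relax elastic
stress into permanent growth) and edges compressed below ``l_min`` are
collapsed; growth of the stress-free area is imposed only externally via
:meth:`BMNetwork.apply_radial_growth`.
Keeping the mesh size within ``[l_min, l_max]`` keeps the network
impenetrable for cells of comparable radius while bounding the number of
polymer elements.

Orientation convention: triangle normals point away from the epithelial
(luminal) side.  The signed mean curvature at a knot is positive where
the surface is concave toward the lumen -- i.e. a crypt-like invagination
(a pocket bulging away from the lumen) is positive, a villus-like bulge
into the lumen negative.  The unperturbed cylinder of radius R has
curvature +1/(2R).

Geometry units are micrometres throughout.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["BMNetwork", "build_cylinder_mesh"]


def _scatter3(out: np.ndarray, idx: np.ndarray, vec: np.ndarray) -> None:
    """out[idx] += vec with repeated indices (bincount; faster than ufunc.at)."""
    n = len(out)
    for c in range(3):
        out[:, c] += np.bincount(idx, weights=vec[:, c], minlength=n)


class MeshError(RuntimeError):
    """Raised for invalid or pathological mesh configurations."""


class BMNetwork:
    """Triangulated basal-membrane network.

    Parameters
    ----------
    knots : (N, 3) array
        Knot (vertex) positions in micrometres.
    triangles : (F, 3) int array
        Oriented knot triples; normals point away from the epithelial side.
    k_stretch : float
        Edge spring constant (force / um).
    k_bend : float
        Dihedral bending modulus (energy units).
    l_min, l_max : float
        Allowed edge-length interval enforced by :meth:`remesh`.
    rest_lengths : dict, optional
        Mapping ``(i, j) -> rest length``; defaults to the as-built lengths.
    """

    def __init__(
        self,
        knots: np.ndarray,
        triangles: np.ndarray,
        k_stretch: float = 5.0,
        k_bend: float = 20.0,
        l_min: float = 2.4,
        l_max: float = 5.6,
        rest_lengths: dict | None = None,
    ):
        self.knots = np.asarray(knots, dtype=float).copy()
        self.triangles = np.asarray(triangles, dtype=np.int64).copy()
        self.k_stretch = float(k_stretch)
        self.k_bend = float(k_bend)
        self.l_min = float(l_min)
        self.l_max = float(l_max)
        self._rest: dict[tuple[int, int], float] = {}
        self._dirty = True
        self._build_topology()
        if rest_lengths is not None:
            self._rest.update({self._key(*k): float(v) for k, v in rest_lengths.items()})
            self._sync_rest_array()
        # composes knot index maps across remesh passes (old index -> new)
        self.last_remesh_knot_map: np.ndarray | None = None

    # ------------------------------------------------------------------
    # topology bookkeeping

    @staticmethod
    def _key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    def _build_topology(self) -> None:
        """(Re)derive edges, boundary info and hinge data from triangles."""
        tri = self.triangles
        if tri.size == 0:
            raise MeshError("mesh has no triangles")
        # directed edges per triangle: (v0,v1), (v1,v2), (v2,v0)
        directed = np.concatenate(
            [tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]], axis=0
        )
        opposite = np.concatenate([tri[:, 2], tri[:, 0], tri[:, 1]], axis=0)
        und = np.sort(directed, axis=1)
        edges, inverse, counts = np.unique(
            und, axis=0, return_inverse=True, return_counts=True
        )
        if np.any(counts > 2):
            raise MeshError("non-manifold edge (more than 2 incident triangles)")
        self.edges = edges
        self._edge_counts = counts
        self.boundary_edge_mask = counts == 1
        nk = len(self.knots)
        self.boundary_knot_mask = np.zeros(nk, dtype=bool)
        self.boundary_knot_mask[edges[self.boundary_edge_mask].ravel()] = True

        # hinge (interior) edges: endpoints + the two opposite vertices,
        # ordered so tri1 contains the directed edge (a, b)
        inner_idx = np.nonzero(counts == 2)[0]
        hinge = np.full((len(inner_idx), 4), -1, dtype=np.int64)
        edge_to_hinge = np.full(len(edges), -1, dtype=np.int64)
        edge_to_hinge[inner_idx] = np.arange(len(inner_idx))
        flip = und[:, 0] != directed[:, 0]  # directed edge reversed vs sorted
        hpos = edge_to_hinge[inverse]
        interior_row = hpos >= 0
        fwd = interior_row & ~flip   # triangle containing the edge as (a, b)
        rev = interior_row & flip    # triangle containing it as (b, a)
        hinge[hpos[fwd], 2] = opposite[fwd]
        hinge[hpos[rev], 3] = opposite[rev]
        if np.any(hinge[:, 2:] < 0):
            raise MeshError("inconsistent triangle orientation across an edge")
        hinge[:, 0] = edges[inner_idx, 0]
        hinge[:, 1] = edges[inner_idx, 1]
        self.hinges = hinge
        self.inner_edge_index = inner_idx

        # rest lengths: keep existing entries, default new edges stress-free
        lengths = self.edge_lengths()
        rest = dict(self._rest)
        self._rest = {}
        for k, (i, j) in enumerate(map(tuple, edges)):
            key = (int(i), int(j))
            self._rest[key] = rest.get(key, float(lengths[k]))
        self._sync_rest_array()
        self._dirty = False

    def _sync_rest_array(self) -> None:
        self.edge_rest = np.array(
            [self._rest[(int(i), int(j))] for i, j in self.edges], dtype=float
        )

    # ------------------------------------------------------------------
    # basic geometry

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    def edge_vectors(self) -> np.ndarray:
        return self.knots[self.edges[:, 1]] - self.knots[self.edges[:, 0]]

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.edge_vectors(), axis=1)

    def triangle_normals(self, normalize: bool = True) -> np.ndarray:
        t = self.triangles
        a = self.knots[t[:, 1]] - self.knots[t[:, 0]]
        b = self.knots[t[:, 2]] - self.knots[t[:, 0]]
        n = np.cross(a, b)
        if normalize:
            n /= np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-30)
        return n

    def triangle_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.triangle_normals(normalize=False), axis=1)

    def surface_area(self) -> float:
        return float(self.triangle_areas().sum())

    def knot_normals(self) -> np.ndarray:
        """Area-weighted knot normals (away from the epithelial side)."""
        n = self.triangle_normals(normalize=False)  # area-weighted
        out = np.zeros_like(self.knots)
        for c in range(3):
            _scatter3(out, self.triangles[:, c], n)
        out /= np.maximum(np.linalg.norm(out, axis=1, keepdims=True), 1e-30)
        return out

    def euler_characteristic(self) -> int:
        return self.n_knots - len(self.edges) + len(self.triangles)

    # ------------------------------------------------------------------
    # audits

    def audit_manifold(self) -> None:
        """Raise MeshError unless the mesh is an oriented 2-manifold with
        boundary whose boundary edges form simple cycles."""
        self._build_topology() if self._dirty else None
        counts = self._edge_counts
        if not np.all((counts == 1) | (counts == 2)):
            raise MeshError("edge incident to more than two triangles")
        # orientation consistency is checked in _build_topology (hinges)
        for ring in self.boundary_rings():
            if len(ring) < 3:
                raise MeshError("degenerate boundary ring")

    def boundary_rings(self) -> list[list[int]]:
        """Ordered knot cycles of the mesh boundary."""
        bedges = self.edges[self.boundary_edge_mask]
        nbr: dict[int, list[int]] = {}
        for i, j in bedges:
            nbr.setdefault(int(i), []).append(int(j))
            nbr.setdefault(int(j), []).append(int(i))
        for k, v in nbr.items():
            if len(v) != 2:
                raise MeshError(f"boundary knot {k} has {len(v)} boundary edges")
        rings = []
        seen: set[int] = set()
        for start in sorted(nbr):
            if start in seen:
                continue
            ring = [start]
            seen.add(start)
            prev, cur = None, start
            while True:
                nxt = [v for v in nbr[cur] if v != prev]
                if not nxt:
                    raise MeshError("open boundary chain")
                prev, cur = cur, nxt[0]
                if cur == start:
                    break
                if cur in seen:
                    raise MeshError("boundary cycles intersect")
                ring.append(cur)
                seen.add(cur)
            rings.append(ring)
        return rings

    # ------------------------------------------------------------------
    # elastic forces

    def elastic_energy(self, theta0: np.ndarray | None = None) -> float:
        l = self.edge_lengths()
        e_stretch = 0.5 * self.k_stretch * np.sum((l - self.edge_rest) ** 2)
        theta = self.dihedral_angles()
        t0 = np.zeros_like(theta) if theta0 is None else np.asarray(theta0, float)
        e_bend = self.k_bend * np.sum(1.0 - np.cos(theta - t0))
        return float(e_stretch + e_bend)

    def dihedral_angles(self) -> np.ndarray:
        """Signed dihedral angle per hinge edge.

        Positive where the two triangles fold toward the epithelial side,
        i.e. form a crypt-like (invaginating) crease.
        """
        x0 = self.knots[self.hinges[:, 0]]
        x1 = self.knots[self.hinges[:, 1]]
        x2 = self.knots[self.hinges[:, 2]]
        x3 = self.knots[self.hinges[:, 3]]
        n1 = np.cross(x1 - x0, x2 - x0)
        n2 = np.cross(x3 - x0, x1 - x0)
        e = x1 - x0
        elen = np.linalg.norm(e, axis=1)
        ehat = e / np.maximum(elen[:, None], 1e-30)
        sin = np.einsum("ij,ij->i", np.cross(n1, n2), ehat)
        n1n = np.linalg.norm(n1, axis=1)
        n2n = np.linalg.norm(n2, axis=1)
        cos = np.einsum("ij,ij->i", n1, n2)
        return np.arctan2(sin / np.maximum(n1n * n2n, 1e-30),
                          cos / np.maximum(n1n * n2n, 1e-30))

    def elastic_forces(self, theta0: np.ndarray | None = None) -> np.ndarray:
        """Per-knot force = -gradient of the elastic energy.

        ``theta0`` optionally supplies a spontaneous dihedral angle per
        hinge edge (same order as :attr:`hinges`), e.g. to let membrane
        regions in contact with Paneth cells prefer an invaginated shape.
        """
        F = np.zeros_like(self.knots)
        # stretching
        vec = self.edge_vectors()
        l = np.linalg.norm(vec, axis=1)
        u = vec / np.maximum(l[:, None], 1e-30)
        f = self.k_stretch * (l - self.edge_rest)
        contrib = f[:, None] * u
        _scatter3(F, self.edges[:, 0], contrib)
        _scatter3(F, self.edges[:, 1], -contrib)

        # bending: E = k_b (1 - cos(theta - theta0))
        h = self.hinges
        x0, x1 = self.knots[h[:, 0]], self.knots[h[:, 1]]
        x2, x3 = self.knots[h[:, 2]], self.knots[h[:, 3]]
        n1 = np.cross(x1 - x0, x2 - x0)
        n2 = np.cross(x3 - x0, x1 - x0)
        e = x1 - x0
        elen = np.maximum(np.linalg.norm(e, axis=1), 1e-30)
        ehat = e / elen[:, None]
        n1sq = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-30)
        n2sq = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-30)
        sin = np.einsum("ij,ij->i", np.cross(n1, n2), ehat) / np.sqrt(n1sq * n2sq)
        cos = np.einsum("ij,ij->i", n1, n2) / np.sqrt(n1sq * n2sq)
        theta = np.arctan2(sin, cos)
        t0 = np.zeros_like(theta) if theta0 is None else np.asarray(theta0, float)
        dE = self.k_bend * np.sin(theta - t0)  # dE/dtheta

        g1 = n1 / n1sq[:, None]
        g2 = n2 / n2sq[:, None]
        grad2 = elen[:, None] * g1
        grad3 = elen[:, None] * g2
        c20 = np.einsum("ij,ij->i", x2 - x1, ehat)
        c30 = np.einsum("ij,ij->i", x3 - x1, ehat)
        c21 = np.einsum("ij,ij->i", x2 - x0, ehat)
        c31 = np.einsum("ij,ij->i", x3 - x0, ehat)
        # theta gradients (signs fixed against finite differences)
        grad0 = -(c20[:, None] * g1 + c30[:, None] * g2)
        grad1 = c21[:, None] * g1 + c31[:, None] * g2
        grad2 = -grad2
        grad3 = -grad3
        _scatter3(F, h[:, 0], -dE[:, None] * grad0)
        _scatter3(F, h[:, 1], -dE[:, None] * grad1)
        _scatter3(F, h[:, 2], -dE[:, None] * grad2)
        _scatter3(F, h[:, 3], -dE[:, None] * grad3)
        return F

    def theta0_from_knot_mask(self, mask: np.ndarray, theta_pc: float) -> np.ndarray:
        """Spontaneous hinge angles from a per-knot flag (e.g. PC contact).

        A hinge edge gets spontaneous angle ``theta_pc`` when both of its
        endpoint knots are flagged, zero otherwise.
        """
        both = mask[self.hinges[:, 0]] & mask[self.hinges[:, 1]]
        return np.where(both, float(theta_pc), 0.0)

    # ------------------------------------------------------------------
    # curvature

    def knot_curvature(self) -> np.ndarray:
        """Signed discrete mean curvature per knot (1/um).

        Cotangent-Laplacian estimate; positive for crypt-like invagination
        (surface concave toward the lumen).  Boundary knots are NaN.
        """
        tri = self.triangles
        x = self.knots
        nk = self.n_knots
        Hvec = np.zeros((nk, 3))
        area = np.zeros(nk)
        for c in range(3):
            i = tri[:, c]
            j = tri[:, (c + 1) % 3]
            k = tri[:, (c + 2) % 3]
            # angle at k, opposite edge (i, j)
            u = x[i] - x[k]
            v = x[j] - x[k]
            cross = np.linalg.norm(np.cross(u, v), axis=1)
            cot = np.einsum("ij,ij->i", u, v) / np.maximum(cross, 1e-30)
            w = 0.5 * cot
            d = x[i] - x[j]
            _scatter3(Hvec, i, w[:, None] * d)
            _scatter3(Hvec, j, -w[:, None] * d)
        a3 = self.triangle_areas() / 3.0
        for c in range(3):
            np.add.at(area, tri[:, c], a3)
        Hvec /= np.maximum(2.0 * area, 1e-30)[:, None]
        mag = np.linalg.norm(Hvec, axis=1)
        sign = np.sign(np.einsum("ij,ij->i", Hvec, self.knot_normals()))
        kappa = np.where(sign == 0, 0.0, sign) * mag
        kappa[self.boundary_knot_mask] = np.nan
        return kappa

    # ------------------------------------------------------------------
    # externally forced radial growth

    def apply_radial_growth(self, r: float, dt: float, axis: str = "z") -> "BMNetwork":
        """Grow the stress-free circumference at fractional rate ``r`` per day.

        Rest lengths are scaled by ``1 + r*dt*w`` where ``w`` is the
        squared circumferential component of the edge direction, so the
        relaxed radius grows by ``(1 + r*dt)`` while axial rest lengths
        are untouched.  ``r = 0`` is the identity.
        """
        if r < 0:
            raise ValueError("growth rate r must be >= 0")
        if r == 0 or dt == 0:
            return self
        assert axis == "z"
        mid = 0.5 * (self.knots[self.edges[:, 0]] + self.knots[self.edges[:, 1]])
        phi = np.stack([-mid[:, 1], mid[:, 0], np.zeros(len(mid))], axis=1)
        phi /= np.maximum(np.linalg.norm(phi, axis=1, keepdims=True), 1e-30)
        vec = self.edge_vectors()
        l = np.maximum(np.linalg.norm(vec, axis=1), 1e-30)
        w = (np.einsum("ij,ij->i", vec, phi) / l) ** 2
        factor = 1.0 + r * dt * w
        self.edge_rest = self.edge_rest * factor
        return self

    # ------------------------------------------------------------------
    # remeshing

    def _rest_dict_from_array(self) -> None:
        """Refresh the per-edge rest-length dict from the authoritative
        array (callers may scale ``edge_rest`` in place between topology
        edits)."""
        self._rest = {
            (int(i), int(j)): float(r)
            for (i, j), r in zip(self.edges, self.edge_rest)
        }

    def remesh(self, rng: np.random.Generator | None = None,
               max_passes: int = 30) -> "BMNetwork":
        """Split/collapse edges until all lengths lie in [l_min, l_max].

        Long edges (> l_max) are split at their midpoint; the new
        elements inherit the parent edge's stretch ratio.  Short interior edges
        (< l_min) are collapsed subject to the usual link-condition and
        length guards.  Boundary rings are preserved (boundary edges may
        be split but never collapsed).  Stores a knot index map
        (old -> new, -1 for none) in :attr:`last_remesh_knot_map`.

        Raises MeshError if bounds cannot be met within ``max_passes``.
        """
        nk_before = self.n_knots
        total_map = np.arange(nk_before, dtype=np.int64)
        self._rest_dict_from_array()
        skip: set = set()
        for _ in range(max_passes):
            changed, pass_map = self._remesh_pass(rng, skip)
            if pass_map is not None:
                total_map = np.where(total_map >= 0, pass_map[total_map], -1)
            if not changed:
                break
        else:
            lengths = self.edge_lengths()
            if lengths.max() > self.l_max * 1.001:
                raise MeshError(
                    "remesh failed to satisfy mesh bounds within "
                    f"{max_passes} passes (lengths in "
                    f"[{lengths.min():.3g}, {lengths.max():.3g}])"
                )
        self.last_remesh_knot_map = total_map
        return self

    def _remesh_pass(self, rng, skip: set | None = None
                     ) -> tuple[bool, np.ndarray | None]:
        """One split/collapse sweep.  ``skip`` carries edges whose edit
        failed its guards earlier in this remesh call, so they are not
        retried pass after pass."""
        if skip is None:
            skip = set()
        lengths = self.edge_lengths()
        too_long = lengths > self.l_max
        too_short = lengths < self.l_min
        actionable = (too_long | too_short)
        if actionable.any() and skip:
            keys = [self._key(int(i), int(j))
                    for i, j in self.edges[actionable]]
            if all(k in skip for k in keys):
                return False, None
        if not actionable.any():
            return False, None

        knots = [row for row in self.knots]
        tris = [tuple(t) for t in self.triangles]
        rest = dict(self._rest)
        # edge -> incident triangle indices
        edge_tris: dict[tuple[int, int], list[int]] = {}
        for ti, (a, b, c) in enumerate(tris):
            for key in (self._key(a, b), self._key(b, c), self._key(c, a)):
                edge_tris.setdefault(key, []).append(ti)
        dead_tri: set[int] = set()
        merged: dict[int, int] = {}  # removed knot -> surviving knot

        def resolve(i: int) -> int:
            while i in merged:
                i = merged[i]
            return i

        candidates = list(np.nonzero(too_long | too_short)[0])
        if rng is not None:
            rng.shuffle(candidates)
        else:
            candidates.sort(key=lambda k: -lengths[k])

        changed = False
        for ei in candidates:
            a0, b0 = int(self.edges[ei, 0]), int(self.edges[ei, 1])
            a, b = resolve(a0), resolve(b0)
            if a == b:
                continue
            key = self._key(a, b)
            if key in skip:
                continue
            inc = [t for t in edge_tris.get(key, []) if t not in dead_tri]
            if not inc:
                continue
            d = float(np.linalg.norm(knots[a] - knots[b]))
            if d > self.l_max:
                # --- split at midpoint (strain preserving: new elements
                # inherit the parent edge's stretch ratio, so remeshing
                # never relaxes elastic stress into permanent growth) ---
                m = len(knots)
                mid = 0.5 * (np.asarray(knots[a]) + np.asarray(knots[b]))
                knots.append(mid)
                rest_old = rest.get(key, d)
                scale = rest_old / d
                rest[self._key(a, m)] = 0.5 * rest_old
                rest[self._key(m, b)] = 0.5 * rest_old
                for ti in inc:
                    tri = tris[ti]
                    dead_tri.add(ti)
                    # replace edge (a,b) by (a,m),(m,b), keep orientation
                    order = list(tri)
                    ia = order.index(a)
                    if order[(ia + 1) % 3] == b:
                        c = order[(ia + 2) % 3]
                        new1, new2 = (a, m, c), (m, b, c)
                    else:
                        c = order[(ia + 1) % 3]
                        new1, new2 = (m, a, c), (b, m, c)
                    rest[self._key(m, c)] = scale * float(
                        np.linalg.norm(mid - np.asarray(knots[c])))
                    for nt in (new1, new2):
                        ti_new = len(tris)
                        tris.append(nt)
                        for kk in (
                            self._key(nt[0], nt[1]),
                            self._key(nt[1], nt[2]),
                            self._key(nt[2], nt[0]),
                        ):
                            edge_tris.setdefault(kk, []).append(ti_new)
                rest.pop(key, None)
                changed = True
            elif d < self.l_min:
                # --- collapse (interior, guarded) ---
                if len(inc) != 2:
                    skip.add(key)
                    continue  # never collapse boundary edges
                # neighbour sets and link condition
                nbrs: dict[int, set[int]] = {a: set(), b: set()}
                tri_of: dict[int, list[int]] = {a: [], b: []}
                for ti, tri in enumerate(tris):
                    if ti in dead_tri:
                        continue
                    rt = tuple(resolve(v) for v in tri)
                    for v in (a, b):
                        if v in rt:
                            tri_of[v].append(ti)
                            nbrs[v].update(u for u in rt if u != v)
                opp = set()
                for ti in inc:
                    rt = [resolve(v) for v in tris[ti]]
                    opp.update(u for u in rt if u not in (a, b))
                if nbrs[a] & nbrs[b] != opp or len(opp) != 2:
                    skip.add(key)
                    continue  # link condition violated
                # do not touch the boundary rings
                boundary = set(np.nonzero(self.boundary_knot_mask)[0])
                if a in boundary or b in boundary:
                    skip.add(key)
                    continue
                mid = 0.5 * (np.asarray(knots[a]) + np.asarray(knots[b]))
                # guard: no resulting edge longer than l_max
                far = max(
                    float(np.linalg.norm(mid - np.asarray(knots[u])))
                    for u in (nbrs[a] | nbrs[b]) - {a, b}
                )
                if far > self.l_max:
                    skip.add(key)
                    continue
                knots[a] = mid
                merged[b] = a
                for ti in inc:
                    dead_tri.add(ti)
                # re-register triangles of b under merged edges
                for ti in tri_of[b]:
                    if ti in dead_tri:
                        continue
                    rt = tuple(resolve(v) for v in tris[ti])
                    for kk in (
                        self._key(rt[0], rt[1]),
                        self._key(rt[1], rt[2]),
                        self._key(rt[2], rt[0]),
                    ):
                        lst = edge_tris.setdefault(kk, [])
                        if ti not in lst:
                            lst.append(ti)
                rest.pop(key, None)
                changed = True

        if not changed:
            return False, None

        # compact: drop dead triangles, resolve merges, drop orphan knots
        new_tris = []
        for ti, tri in enumerate(tris):
            if ti in dead_tri:
                continue
            rt = tuple(resolve(v) for v in tri)
            if len(set(rt)) == 3:
                new_tris.append(rt)
        used = sorted({v for tri in new_tris for v in tri})
        remap = -np.ones(len(knots), dtype=np.int64)
        remap[used] = np.arange(len(used))
        self.knots = np.asarray([knots[u] for u in used], dtype=float)
        self.triangles = np.asarray(
            [[remap[v] for v in tri] for tri in new_tris], dtype=np.int64
        )
        new_rest = {}
        for (i, j), v in rest.items():
            ri, rj = resolve(i), resolve(j)
            if ri == rj or remap[ri] < 0 or remap[rj] < 0:
                continue
            new_rest[self._key(int(remap[ri]), int(remap[rj]))] = v
        self._rest = new_rest
        self._build_topology()
        # old knot -> new index map for this pass
        pass_map = -np.ones(len(remap), dtype=np.int64)
        for old in range(len(remap)):
            r = resolve(old)
            pass_map[old] = remap[r] if remap[r] >= 0 else -1
        return True, pass_map

    # ------------------------------------------------------------------
    # export

    def write_vtk(self, path: str, point_data: dict[str, np.ndarray] | None = None) -> None:
        """Write the mesh as legacy ASCII VTK polydata."""
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\nbasal membrane\nASCII\n")
            fh.write("DATASET POLYDATA\n")
            fh.write(f"POINTS {self.n_knots} float\n")
            for p in self.knots:
                fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
            nf = len(self.triangles)
            fh.write(f"POLYGONS {nf} {4 * nf}\n")
            for t in self.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
            if point_data:
                fh.write(f"POINT_DATA {self.n_knots}\n")
                for name, values in point_data.items():
                    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    for v in np.asarray(values, dtype=float):
                        fh.write(f"{0.0 if not np.isfinite(v) else v:.6g}\n")

    def write_ply(self, path: str) -> None:
        """Write the mesh as ASCII PLY."""
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {self.n_knots}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(f"element face {len(self.triangles)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for p in self.knots:
                fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
            for t in self.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def build_cylinder_mesh(
    radius: float,
    length: float,
    target_edge: float,
    k_stretch: float = 5.0,
    k_bend: float = 20.0,
) -> BMNetwork:
    """Build an open triangulated cylinder along the z axis.

    The tube spans ``z in [0, length]`` with the epithelial (luminal) side
    inside; triangle normals point radially outward.  Rows of knots are
    staggered to give near-equilateral triangles with edge lengths close
    to ``target_edge``; mesh bounds are set to ``[0.6, 1.4] * target_edge``.
    """
    if not (radius > 2 * target_edge and length > 2 * target_edge):
        raise ValueError("radius and length must exceed 2 * target_edge")
    n_circ = max(6, int(round(2 * math.pi * radius / target_edge)))
    dphi = 2 * math.pi / n_circ
    row_h = target_edge * math.sqrt(3) / 2
    n_rows = max(3, int(round(length / row_h)) + 1)
    h = length / (n_rows - 1)

    knots = np.empty((n_rows * n_circ, 3))
    for i in range(n_rows):
        off = 0.5 * dphi if (i % 2) else 0.0
        ang = np.arange(n_circ) * dphi + off
        base = i * n_circ
        knots[base : base + n_circ, 0] = radius * np.cos(ang)
        knots[base : base + n_circ, 1] = radius * np.sin(ang)
        knots[base : base + n_circ, 2] = i * h

    tris = []
    for i in range(n_rows - 1):
        for j in range(n_circ):
            j1 = (j + 1) % n_circ
            a, b = i * n_circ + j, i * n_circ + j1
            c, d = (i + 1) * n_circ + j, (i + 1) * n_circ + j1
            if i % 2 == 0:
                # upper row shifted by +dphi/2: c sits between a and b
                tris.append((a, b, c))
                tris.append((b, d, c))
            else:
                # upper row shifted back: d sits between a and b
                tris.append((a, d, c))
                tris.append((a, b, d))
    tris = np.asarray(tris, dtype=np.int64)

    # orient normals radially outward (away from the epithelial side)
    p = knots[tris]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    centroid = p.mean(axis=1)
    radial = centroid.copy()
    radial[:, 2] = 0.0
    flip = np.einsum("ij,ij->i", n, radial) < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]

    net = BMNetwork(
        knots,
        tris,
        k_stretch=k_stretch,
        k_bend=k_bend,
        l_min=0.6 * target_edge,
        l_max=1.4 * target_edge,
    )
    net.audit_manifold()
    return net
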