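"""Cell-cell, cell-membrane and apical-network forces; compression; motion.

Cells are elastic spheres moving in the overdamped (inertia-free) regime:
velocity = force / friction.  Pairwise cell-cell interaction combines a
Hertz-type repulsion with a short-range adhesion well,

    f(d) = k_rep * ((d0 - d)/d0)^(3/2)           for d < d0   (repulsive)
         - eps_adh * (1 - d/d_cut)^2             for d < d_cut (attractive)

with contact distance d0 = R_a + R_b and cutoff d_cut = 1.2 * d0; f > 0
pushes the pair apart.  Cells adhere to the basal membrane through a
zero-rest-length spring to a selected attachment knot (re-selected when
stretched beyond the interaction range r_int) and are repelled by all
other knots within r_int, which renders the membrane impenetrable.
Epithelial neighbours are additionally connected by a contractile
'apical' polymer network of harmonic links; links to a shrinking
(BM-detached) cell contract with an amplified force, pulling the
neighbours together over the gap the dying cell leaves.

A cell's actual volume V_A is its target volume V_T minus the spherical
caps it loses to overlapping neighbours and to the membrane plane at its
attachment knot (floored at 0.1 V_T); the relative compression
(V_T - V_A)/V_0 is the model's pressure proxy.

Units: um, hours, and an arbitrary force unit F* with friction expressed
in F*.h/um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ForceParams", "pair_force", "cell_cell_forces", "pair_potential",
    "cell_bm_forces", "apical_forces", "actual_volume", "integrate_motion",
    "contact_pairs",
]


@dataclass(frozen=True)
class ForceParams:
    """Mechanical parameters.

    eps_adh : cell-cell adhesion force scale (F*).
    k_rep : Hertz compression stiffness (F*).
    gamma : cell friction coefficient (F*.h/um).
    gamma_knot : membrane-knot friction coefficient (F*.h/um).
    r_int : cell-BM interaction range (um).
    d_reattach : attachment-link stretch (um) beyond which the nearest
        knot is re-selected (lets cells slide along the membrane).
    d_detach : nearest-knot distance (um) beyond which a cell has lost
        contact with the membrane and starts shrinking.
    k_bm_adh : attachment-spring constant (F*/um).
    k_bm_rep : knot repulsion force scale (F*).
    k_apical : apical link spring constant (F*/um).
    s_apical : apical rest length as fraction of R_a + R_b.
    d_apical_max : apical link cutoff (um).
    f_shrink : contraction amplification of links to shrinking cells.
    dt_mech : mechanics timestep (h).
    """

    eps_adh: float = 1.0
    k_rep: float = 50.0
    gamma: float = 1.0
    gamma_knot: float = 2.5
    r_int: float = 6.0
    d_reattach: float = 4.6
    d_detach: float = 10.0
    k_bm_adh: float = 2.0
    k_bm_rep: float = 20.0
    k_apical: float = 1.0
    s_apical: float = 0.9
    d_apical_max: float = 9.0
    f_shrink: float = 2.0
    dt_mech: float = 0.02

    def __post_init__(self) -> None:
        for name in ("eps_adh", "k_rep", "gamma", "gamma_knot", "r_int", "d_reattach", "d_detach",
                     "k_bm_adh", "k_bm_rep", "k_apical", "d_apical_max",
                     "f_shrink", "dt_mech"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


CONTACT_FACTOR = 1.2  # contact graph cutoff: d < 1.2 * (R_a + R_b)


def _scatter3(out: np.ndarray, idx: np.ndarray, vec: np.ndarray) -> None:
    """out[idx] += vec with repeated indices (bincount; faster than ufunc.at)."""
    n = len(out)
    for c in range(3):
        out[:, c] += np.bincount(idx, weights=vec[:, c], minlength=n)


def contact_pairs(pos: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Contact-graph pairs (i < j) with centre distance < 1.2*(R_i + R_j).

    One spatial query at the maximal cutoff followed by per-pair
    filtering; this single graph backs forces, fate rules and V_A.
    """
    if len(pos) < 2:
        return np.empty((0, 2), dtype=np.int64)
    rmax = float(radii.max())
    tree = cKDTree(pos)
    pairs = tree.query_pairs(CONTACT_FACTOR * 2 * rmax, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.astype(np.int64)
    d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
    keep = d < CONTACT_FACTOR * (radii[pairs[:, 0]] + radii[pairs[:, 1]])
    return pairs[keep].astype(np.int64)


def pair_force(d, Ra, Rb, p: ForceParams):
    """Scalar radial force law; positive pushes the pair apart."""
    d = np.asarray(d, dtype=float)
    d0 = Ra + Rb
    dcut = CONTACT_FACTOR * d0
    overlap = np.clip((d0 - d) / d0, 0.0, None)
    rep = p.k_rep * overlap ** 1.5
    adh = -p.eps_adh * np.clip(1.0 - d / dcut, 0.0, None) ** 2
    return rep + adh


def pair_potential(d, Ra, Rb, p: ForceParams):
    """Pair potential with force = -dU/dd (finite-difference oracle hook)."""
    d = np.asarray(d, dtype=float)
    d0 = Ra + Rb
    dcut = CONTACT_FACTOR * d0
    overlap = np.clip((d0 - d) / d0, 0.0, None)
    u_rep = p.k_rep * d0 / 2.5 * overlap ** 2.5
    u_adh = -p.eps_adh * dcut / 3.0 * np.clip(1.0 - d / dcut, 0.0, None) ** 3
    return u_rep + u_adh


def cell_cell_forces(pos: np.ndarray, radii: np.ndarray, pairs: np.ndarray,
                     p: ForceParams,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Pairwise antisymmetric forces accumulated per cell.

    Coincident centres are separated along a random unit vector (seeded
    RNG) so daughters placed on top of each other cannot lock."""
    F = np.zeros_like(pos)
    if len(pairs) == 0:
        return F
    i, j = pairs[:, 0], pairs[:, 1]
    dvec = pos[i] - pos[j]
    d = np.linalg.norm(dvec, axis=1)
    zero = d < 1e-9
    if np.any(zero):
        gen = rng if rng is not None else np.random.default_rng(0)
        rnd = gen.normal(size=(int(zero.sum()), 3))
        rnd /= np.linalg.norm(rnd, axis=1, keepdims=True)
        dvec[zero] = 1e-6 * rnd
        d[zero] = 1e-6
    u = dvec / d[:, None]
    f = pair_force(d, radii[i], radii[j], p)
    _scatter3(F, i, f[:, None] * u)
    _scatter3(F, j, -f[:, None] * u)
    return F


def cell_bm_forces(
    pos: np.ndarray,
    attach: np.ndarray,
    knots: np.ndarray,
    knot_tree: cKDTree,
    p: ForceParams,
    knot_normals: np.ndarray | None = None,
    rest_height: float | np.ndarray = 0.0,
    side: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Adhesion to the attachment knot, repulsion from nearby knots.

    With ``knot_normals`` given, the adhesion spring acts only along the
    membrane normal at the attachment knot: cells are tethered to the
    membrane surface but free to slide along it (they hop attachment
    knots as they move); without normals the spring is isotropic with
    zero rest length.  ``rest_height`` sets the preferred hovering
    distance from the membrane plane (one cell radius keeps the sphere
    tangent to the membrane instead of squashed into it); ``side`` gives
    the sign of the preferred offset along the knot normal (+1 for the
    fibroblast side the normals point to, -1 for the epithelial side).

    Returns ``(F_cell, F_knot, attach_new)``.  Attachment knots are
    re-selected (nearest knot) where the link is stretched beyond
    ``d_reattach`` or invalid; reaction forces on the knots guarantee
    F_cell = -sum(F_knot) pairwise (momentum bookkeeping).
    """
    F_cell = np.zeros_like(pos)
    F_knot = np.zeros_like(knots)
    attach = attach.copy()
    n = len(pos)
    if n == 0:
        return F_cell, F_knot, attach

    # (re-)select attachment knots
    bad = (attach < 0) | (attach >= len(knots))
    if not bad.all():
        ok = ~bad
        stretch = np.linalg.norm(pos[ok] - knots[attach[ok]], axis=1)
        re_ok = np.zeros(n, dtype=bool)
        re_ok[np.nonzero(ok)[0][stretch > p.d_reattach]] = True
        bad |= re_ok
    if bad.any():
        _, nearest = knot_tree.query(pos[bad])
        attach[bad] = nearest

    # adhesion spring
    delta = pos - knots[attach]
    if knot_normals is not None:
        nrm = knot_normals[attach]
        dn = np.einsum("ij,ij->i", delta, nrm)
        target = np.asarray(rest_height, dtype=float)
        if side is not None:
            target = target * side
        f_adh = (-p.k_bm_adh * (dn - target))[:, None] * nrm
    else:
        f_adh = -p.k_bm_adh * delta
    F_cell += f_adh
    _scatter3(F_knot, attach, -f_adh)

    # repulsion from all other knots within r_int (nearest K suffice)
    K = min(16, len(knots))
    dists, cols = knot_tree.query(pos, k=K, distance_upper_bound=p.r_int)
    dists = np.atleast_2d(dists)
    cols = np.atleast_2d(cols)
    valid = np.isfinite(dists)
    ci, sub = np.nonzero(valid)
    kj = cols[ci, sub]
    if len(ci):
        keep = kj != attach[ci]
        ci, kj = ci[keep], kj[keep]
    if len(ci):
        dvec = pos[ci] - knots[kj]
        d = np.maximum(np.linalg.norm(dvec, axis=1), 1e-9)
        f = p.k_bm_rep * (1.0 - d / p.r_int) ** 2
        contrib = (f / d)[:, None] * dvec
        _scatter3(F_cell, ci, contrib)
        _scatter3(F_knot, kj, -contrib)
    return F_cell, F_knot, attach


def apical_forces(pos: np.ndarray, radii: np.ndarray, links: np.ndarray,
                  shrinking: np.ndarray, p: ForceParams) -> np.ndarray:
    """Harmonic attraction along apical links.

    ``links`` are index pairs (within one cell population side).  Rest
    length is ``s_apical * (R_a + R_b)``; a link with a shrinking endpoint
    contracts toward zero rest length with force amplified by
    ``f_shrink``, closing the epithelium over dying cells.
    """
    F = np.zeros_like(pos)
    if len(links) == 0:
        return F
    i, j = links[:, 0], links[:, 1]
    dvec = pos[i] - pos[j]
    d = np.maximum(np.linalg.norm(dvec, axis=1), 1e-9)
    u = dvec / d[:, None]
    rest = p.s_apical * (radii[i] + radii[j])
    shrink_link = shrinking[i] | shrinking[j]
    # links to a shrinking cell are stiffer by f_shrink; since the rest
    # length tracks the shrinking radius, the neighbours are ratcheted
    # together as the dying cell deflates, closing the epithelium
    f = np.where(shrink_link, p.f_shrink, 1.0) * p.k_apical * (d - rest)
    _scatter3(F, i, -f[:, None] * u)
    _scatter3(F, j, f[:, None] * u)
    return F


def _cap_volume(R, h):
    """Volume of the spherical cap of height ``R - h`` cut off a sphere of
    radius R by a plane at distance h (0 <= h <= R) from the centre."""
    h = np.clip(h, -R, R)
    return np.pi * (R - h) ** 2 * (2 * R + h) / 3.0


def actual_volume(VT: np.ndarray, radii: np.ndarray, pos: np.ndarray,
                  pairs: np.ndarray,
                  plane_dist: np.ndarray | None = None) -> np.ndarray:
    """Actual (compressed) volume V_A per cell.

    Subtracts, per overlapping neighbour pair, each cell's own spherical
    cap beyond the radical plane (no multi-overlap correction), plus the
    cap cut off by the membrane plane at the attachment knot
    (``plane_dist`` = unsigned distance of the centre to that plane, NaN
    or inf for unattached cells), floored at 0.1 * V_T.
    """
    VA = VT.astype(float).copy()
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        d = np.linalg.norm(pos[i] - pos[j], axis=1)
        Ra, Rb = radii[i], radii[j]
        touch = d < Ra + Rb
        ii, jj = i[touch], j[touch]
        dd, RA, RB = np.maximum(d[touch], 1e-9), Ra[touch], Rb[touch]
        xa = (dd ** 2 + RA ** 2 - RB ** 2) / (2 * dd)  # radical-plane offset
        np.subtract.at(VA, ii, _cap_volume(RA, xa))
        np.subtract.at(VA, jj, _cap_volume(RB, dd - xa))
    if plane_dist is not None:
        h = np.asarray(plane_dist, dtype=float)
        cut = np.isfinite(h) & (h < radii)
        VA[cut] -= _cap_volume(radii[cut], h[cut])
    return np.maximum(VA, 0.1 * VT)


def integrate_motion(pos: np.ndarray, forces: np.ndarray, gamma: float,
                     dt: float, frozen: np.ndarray | None = None,
                     max_step: float | np.ndarray | None = None) -> np.ndarray:
    """Overdamped update: displacement = force / gamma * dt.

    ``frozen`` marks entities that must not move (fibroblasts stopped at
    the cylinder openings).  If any displacement exceeds ``max_step``
    (e.g. one cell radius) the timestep is unstable and a RuntimeError is
    raised rather than silently integrating garbage.
    """
    disp = forces / gamma * dt
    if frozen is not None and frozen.any():
        disp[frozen] = 0.0
    if max_step is not None:
        step = np.linalg.norm(disp, axis=1)
        limit = np.asarray(max_step, dtype=float)
        if np.any(step > limit):
            worst = float((step / limit).max())
            raise RuntimeError(
                f"timestep unstable: displacement {worst:.2f}x the allowed "
                "maximum; reduce dt_mech")
    return pos + disp
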