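"""Coupled mechanics/fate/growth loop on the cylindrical tissue.

The simulation starts from a cylindrical basal membrane of fixed length
(the inter-villus junction present before birth): epithelial cells tile
the inner surface -- stem cells inside a central external-Wnt region,
enterocytes elsewhere -- and fibroblasts tile the outer surface.  External
forces grow the stress-free circumference of the membrane at fractional
rate ``r`` per day.  Epithelial cells crossing the open cylinder ends are
removed ('turnover' onto the villi); fibroblasts instead stop and remain
at the openings.  In ``blocked`` turnover mode the ends reflect instead,
so density and compression build up.

During the initial phase, Paneth cells cannot specify on the almost-flat
tube; membrane re-organization (driven by division pressure and by the
spontaneous curvature of PC-contacted membrane) eventually produces spots
of sufficient curvature.  Once N_PC Paneth cells exist, the external Wnt
source switches off and the clock is reset to t = 0: the postnatal growth
simulation proper starts, and observations are recorded every 1.2 h.

Each biology step executes, in order: mechanics substeps (forces ->
overdamped motion), remeshing, actual-volume update, contact inhibition,
cycle/divisions, Wnt/Notch/specification (+ Wnt switch check), lifecycle
and boundary turnover.  Runs are deterministic for a given seed, and a
running simulation can be checkpointed to disk and resumed bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import fate as F
from . import mechanics as M
from .fate import CellPopulation, FateParams
from .mechanics import ForceParams
from .mesh import BMNetwork, build_cylinder_mesh

__all__ = [
    "GeometryParams", "SimulationConfig", "SimulationState",
    "ObservationRecord", "Trajectory", "Simulation",
    "NicheFormationError",
]


class NicheFormationError(RuntimeError):
    """Pre-switch cap exceeded without specifying N_PC Paneth cells."""


@dataclass(frozen=True)
class GeometryParams:
    """Initial cylinder geometry (um)."""

    radius: float = 15.0
    length: float = 64.0
    target_edge: float = 4.0

    def __post_init__(self) -> None:
        if not (self.radius > 2 * self.target_edge
                and self.length > 2 * self.target_edge):
            raise ValueError("degenerate cylinder geometry")


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of one run.

    ``r`` is the radial tissue growth rate (fraction of circumference per
    day).  ``external_wnt_frac`` is the central fraction of the cylinder
    axis covered by the external Wnt source.  ``theta0_pc`` is the
    spontaneous hinge angle (radians) of membrane regions in contact with
    Paneth cells; it encodes the specific biomechanics of the BM at the
    crypt base that drive invagination.  ``bm_growth_rate_pc`` (per hour)
    lets stretched membrane in contact with Paneth cells grow plastically
    toward its current length: proliferation pressure inside a niche
    expands the crypt-base membrane, making room for further stem cells
    -- the positive feedback behind exponential niche growth.
    """

    geometry: GeometryParams = field(default_factory=GeometryParams)
    fate: FateParams = field(default_factory=FateParams)
    forces: ForceParams = field(default_factory=ForceParams)
    r: float = 0.1
    turnover_mode: str = "open"
    include_fibroblasts: bool = True
    external_wnt_frac: float = 0.5
    seed: int = 0
    cell_radius: float = 3.5
    theta0_pc: float = 0.3
    bm_growth_rate_pc: float = 1.0
    k_stretch: float = 30.0
    k_bend: float = 3.0
    pre_switch_cap_days: float = 14.0
    run_days: float = 5.0
    observation_interval: float = 1.2
    fate_every: int = 5

    def __post_init__(self) -> None:
        if self.turnover_mode not in ("open", "blocked"):
            raise ValueError("turnover_mode must be 'open' or 'blocked'")
        if self.r < 0:
            raise ValueError("radial growth rate r must be >= 0")
        if not 0 < self.external_wnt_frac <= 1:
            raise ValueError("external_wnt_frac must lie in (0, 1]")
        if self.fate_every < 1:
            raise ValueError("fate_every must be >= 1")
        n_sub = self.observation_interval / self.dt_bio
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError("observation_interval must be an integer "
                             "multiple of fate_every * dt_mech")

    @property
    def dt_bio(self) -> float:
        """Biology timestep (h): fate_every mechanics substeps."""
        return self.fate_every * self.forces.dt_mech

    @property
    def steps_per_observation(self) -> int:
        return int(round(self.observation_interval / self.dt_bio))

    @property
    def cell_volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.cell_radius ** 3

    @property
    def wnt_region(self) -> tuple[float, float]:
        half = 0.5 * self.external_wnt_frac * self.geometry.length
        mid = 0.5 * self.geometry.length
        return (mid - half, mid + half)


@dataclass
class SimulationState:
    """Cells + membrane + clock + RNG + cumulative removal ledger."""

    pop: CellPopulation
    net: BMNetwork
    clock: float = 0.0           # absolute simulated hours
    switch_time: float | None = None
    external_wnt_on: bool = True
    removals: dict = field(default_factory=lambda: {
        "turnover_low": 0, "turnover_high": 0,
        "pc_death": 0, "detachment": 0})
    births: int = 0
    n_initial: int = 0

    @property
    def time_since_switch(self) -> float:
        if self.switch_time is None:
            return -np.inf
        return self.clock - self.switch_time

    @property
    def turnover_total(self) -> int:
        return self.removals["turnover_low"] + self.removals["turnover_high"]


@dataclass
class ObservationRecord:
    """Per-observation (1.2 h) snapshot of the running statistics."""

    time: float                       # hours since the Wnt switch
    census: dict
    turnover_increment: int           # end removals since last observation
    removals_cum: dict
    sc_compression: np.ndarray        # (V_T - V_A)/V_0 per SC
    radial_profile: np.ndarray        # per-5um-slice mean radius
    radial_mean: float
    pc_ids: np.ndarray
    pc_pos: np.ndarray
    n_cells: int


@dataclass
class Trajectory:
    """Result of a run: config, seed, observations and the event log."""

    config: SimulationConfig
    observations: list = field(default_factory=list)
    events: list = field(default_factory=list)
    state: SimulationState | None = None

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations])

    def census_series(self, lineage_name: str) -> np.ndarray:
        return np.array([o.census[lineage_name] for o in self.observations])


class Simulation:
    """One deterministic simulation run."""

    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        ss = np.random.SeedSequence(cfg.seed)
        s_init, s_cycle, s_div, s_pc = ss.spawn(4)
        self.rng_init = np.random.default_rng(s_init)
        self.rng_cycle = np.random.default_rng(s_cycle)
        self.rng_div = np.random.default_rng(s_div)
        self.rng_pc = np.random.default_rng(s_pc)
        self.events: list = []
        self.state = self.initialize()
        self._last_turnover_total = 0
        self._step_count = 0

    # ------------------------------------------------------------------
    def initialize(self) -> SimulationState:
        """Build the initial cylindrical tissue.

        The inner surface is tiled with SCs (inside the Wnt region) and
        ECs (outside) at contact density, the outer surface with
        fibroblasts; growth-step phases are randomized so divisions do
        not synchronize.  Raises ValueError for infeasible packing.
        """
        cfg = self.cfg
        g = cfg.geometry
        net = build_cylinder_mesh(g.radius, g.length, g.target_edge,
                                  k_stretch=cfg.k_stretch, k_bend=cfg.k_bend)
        pop = CellPopulation()
        Rc = cfg.cell_radius
        V0 = cfg.cell_volume
        h0 = 0.7 * Rc  # initial offset of cell centres from the membrane
        z0, z1 = cfg.wnt_region

        def tile(radius: float) -> np.ndarray:
            if radius <= Rc:
                raise ValueError("cell radius incompatible with geometry")
            spacing = 2.0 * Rc * 1.0
            n_circ = max(3, int(round(2 * np.pi * radius / spacing)))
            n_rows = max(2, int(round(g.length / spacing)))
            dz = g.length / n_rows
            pts = []
            for i in range(n_rows):
                off = (i % 2) * np.pi / n_circ
                ang = 2 * np.pi * np.arange(n_circ) / n_circ + off
                z = (i + 0.5) * dz
                pts.append(np.stack([
                    radius * np.cos(ang), radius * np.sin(ang),
                    np.full(n_circ, z)], axis=1))
            pts = np.concatenate(pts)
            pts += self.rng_init.normal(0.0, 0.15, pts.shape)
            return pts

        inner = tile(g.radius - h0)
        lineage = np.where(
            (inner[:, 2] >= z0) & (inner[:, 2] <= z1), F.SC, F.EC
        ).astype(np.int8)
        pop.add(inner, lineage, V0)
        if cfg.include_fibroblasts:
            outer = tile(g.radius + h0)
            pop.add(outer, F.FIB, V0)
        # desynchronize the cell cycle
        gs = self.rng_init.integers(0, max(1, cfg.fate.N_P // 3), size=pop.n)
        pop.growth_step[:] = gs
        pop.VT[:] = pop.V0 * (1.0 + gs / cfg.fate.N_P)
        # attach to nearest knot
        tree = cKDTree(net.knots)
        _, pop.attach[:] = tree.query(pop.pos)

        state = SimulationState(pop=pop, net=net)
        state.n_initial = pop.n
        return state

    # ------------------------------------------------------------------
    def wnt_switch_check(self) -> None:
        """Switch the external source off once N_PC Paneth cells exist."""
        st = self.state
        if not st.external_wnt_on:
            return
        n_pc = int(np.sum(st.pop.lineage == F.PC))
        if n_pc >= self.cfg.fate.N_PC:
            st.external_wnt_on = False
            st.switch_time = st.clock
            self.events.append((0.0, -1, "wnt_switch_off",
                                f"n_pc={n_pc}", None, None, None))

    # ------------------------------------------------------------------
    def boundary_turnover(self) -> None:
        """Remove epithelial cells crossing the open ends (open mode) or
        reflect them (blocked mode); fibroblasts stop at the openings."""
        st = self.state
        pop = st.pop
        L = self.cfg.geometry.length
        z = pop.pos[:, 2]
        epi = pop.epithelial()
        if self.cfg.turnover_mode == "open":
            out_low = epi & (z < 0.0)
            out_high = epi & (z > L)
            st.removals["turnover_low"] += int(out_low.sum())
            st.removals["turnover_high"] += int(out_high.sum())
            t = st.time_since_switch
            for i in np.nonzero(out_low | out_high)[0]:
                end = "low" if z[i] < 0 else "high"
                self.events.append((t, int(pop.ids[i]), "remove",
                                    f"turnover_{end}", None, None, None))
            fib_out = ~epi & ((z < 0.0) | (z > L))
            if fib_out.any():
                pop.pos[fib_out, 2] = np.clip(pop.pos[fib_out, 2], 0.0, L)
                pop.stopped[fib_out] = True
            pop.remove(out_low | out_high)
        else:
            pop.pos[:, 2] = np.abs(pop.pos[:, 2])
            over = pop.pos[:, 2] > L
            pop.pos[over, 2] = 2 * L - pop.pos[over, 2]

    # ------------------------------------------------------------------
    def step(self) -> None:
        """One biology timestep.

        Runs ``fate_every`` mechanics substeps (forces, motion, membrane
        growth, remeshing), then the biological update (volumes, contact
        inhibition, cycling, fate, lifecycle, boundary turnover) at the
        coarser biology timestep dt_bio = fate_every * dt_mech.  Cell
        state changes on the hour scale, so sub-sampling the biology
        relative to the mechanical relaxation loses nothing.
        """
        for _ in range(self.cfg.fate_every):
            self._mech_substep()
        self._bio_update()

    def _mech_substep(self) -> None:
        cfg = self.cfg
        fp = cfg.forces
        st = self.state
        pop = st.pop
        net = st.net
        dt = fp.dt_mech

        radii = pop.radii()
        pairs = M.contact_pairs(pop.pos, radii)

        # --- forces on cells and knots
        F_cell = M.cell_cell_forces(pop.pos, radii, pairs, fp, self.rng_div)
        if len(pairs):
            same_epi = pop.epithelial()[pairs[:, 0]] & pop.epithelial()[pairs[:, 1]]
            same_fib = ~pop.epithelial()[pairs[:, 0]] & ~pop.epithelial()[pairs[:, 1]]
            links = pairs[same_epi | same_fib]
        else:
            links = pairs
        F_cell += M.apical_forces(pop.pos, radii, links, pop.shrinking, fp)

        knot_tree = cKDTree(net.knots)
        attached = ~pop.shrinking
        F_bm = np.zeros_like(pop.pos)
        F_knot_r = np.zeros_like(net.knots)
        if attached.any():
            side = np.where(pop.epithelial()[attached], -1.0, 1.0)
            fb, fk, new_attach = M.cell_bm_forces(
                pop.pos[attached], pop.attach[attached], net.knots,
                knot_tree, fp, knot_normals=net.knot_normals(),
                rest_height=radii[attached], side=side)
            F_bm[attached] = fb
            F_knot_r = fk
            pop.attach[attached] = new_attach
        F_cell += F_bm

        # spontaneous curvature of PC-contacted membrane
        pc_pos = pop.pos[pop.lineage == F.PC]
        pc_knots = np.zeros(net.n_knots, dtype=bool)
        if len(pc_pos):
            hits = knot_tree.query_ball_point(pc_pos, fp.r_int)
            for h in hits:
                pc_knots[h] = True
        theta0 = net.theta0_from_knot_mask(pc_knots, cfg.theta0_pc)
        F_knot = net.elastic_forces(theta0) + F_knot_r

        # --- overdamped motion (stopped fibroblasts immobile)
        pop.pos = M.integrate_motion(
            pop.pos, F_cell, fp.gamma, dt, frozen=pop.stopped,
            max_step=np.maximum(radii, cfg.cell_radius))
        net.knots = M.integrate_motion(
            net.knots, F_knot, fp.gamma_knot, dt,
            max_step=cfg.geometry.target_edge)

        st.clock += dt
        self._step_count += 1

    def _maybe_remesh(self) -> None:
        """Remesh when edges stray well outside their bounds.

        The hysteresis (especially on the short side, where collapse
        guards can legitimately refuse an edit in a tight pocket) avoids
        re-running topology passes every substep."""
        st = self.state
        pop = st.pop
        net = st.net
        lengths = net.edge_lengths()
        if not (lengths.max() > 1.05 * net.l_max
                or lengths.min() < 0.8 * net.l_min):
            return
        nk = net.n_knots
        net.remesh()
        kmap = net.last_remesh_knot_map
        if kmap is not None and len(kmap) == nk:
            a = pop.attach
            valid = (a >= 0) & (a < nk)
            a[valid] = kmap[a[valid]]
            pop.attach = a
        bad = (pop.attach < 0) | (pop.attach >= net.n_knots)
        if bad.any():
            tree = cKDTree(net.knots)
            _, pop.attach[bad] = tree.query(pop.pos[bad])

    def _bio_update(self) -> None:
        cfg = self.cfg
        fp = cfg.forces
        st = self.state
        pop = st.pop
        net = st.net
        dt = cfg.dt_bio
        radii = pop.radii()
        if cfg.r > 0:
            net.apply_radial_growth(cfg.r, dt / 24.0)
        self._maybe_remesh()
        knot_tree = cKDTree(net.knots)
        self._grow_pc_membrane(knot_tree, dt)

        # --- detachment: nearest knot beyond contact distance
        not_shrunk = ~pop.shrinking
        if not_shrunk.any():
            d_attach = np.linalg.norm(
                pop.pos - net.knots[np.clip(pop.attach, 0, net.n_knots - 1)],
                axis=1)
            maybe = not_shrunk & (d_attach > fp.d_detach)
            if maybe.any():
                dn, _ = knot_tree.query(pop.pos[maybe])
                lost = np.nonzero(maybe)[0][dn > fp.d_detach]
                pop.shrinking[lost] = True

        # --- actual volume and contact inhibition
        knot_norm = net.knot_normals()
        ak = np.clip(pop.attach, 0, net.n_knots - 1)
        plane_dist = np.abs(np.einsum(
            "ij,ij->i", pop.pos - net.knots[ak], knot_norm[ak]))
        plane_dist[pop.shrinking] = np.inf
        pairs = M.contact_pairs(pop.pos, radii)
        pop.VA = M.actual_volume(pop.VT, radii, pop.pos, pairs, plane_dist)
        inhibited = F.contact_inhibited(pop, cfg.fate)

        # --- cycle and divisions
        t_rel = st.time_since_switch
        dividing = F.cycle_step(pop, inhibited, cfg.fate, dt, self.rng_cycle)
        if len(dividing):
            axes = self._division_axes(dividing, knot_norm)
            new_ids = F.divide(pop, dividing, axes, self.events, t_rel)
            st.births += len(new_ids)

        # --- fate specification (tissue curvature = local mean around cell)
        pairs = M.contact_pairs(pop.pos, pop.radii())
        z0, z1 = cfg.wnt_region
        in_region = (pop.pos[:, 2] >= z0) & (pop.pos[:, 2] <= z1)
        wnt = F.wnt_active(pop, pairs, cfg.fate, st.external_wnt_on, in_region)
        notch = F.notch_active(pop, pairs, cfg.fate)
        cell_curv = self._local_curvature(knot_tree)
        F.specify(pop, wnt, notch, cell_curv, cfg.fate, self.rng_pc,
                  self.events, t_rel)
        self.wnt_switch_check()

        # --- lifecycle and removal
        removed = F.lifecycle_update(pop, dt, cfg.fate, self.events, t_rel)
        st.removals["pc_death"] += len(removed["pc_death"])
        st.removals["detachment"] += len(removed["detachment"])
        self.boundary_turnover()

    def _pc_knot_mask(self, knot_tree: cKDTree) -> np.ndarray:
        """Knots within r_int of any Paneth cell."""
        net = self.state.net
        pop = self.state.pop
        mask = np.zeros(net.n_knots, dtype=bool)
        pc_pos = pop.pos[pop.lineage == F.PC]
        if len(pc_pos):
            _, cols = knot_tree.query(
                pc_pos, k=min(16, net.n_knots),
                distance_upper_bound=self.cfg.forces.r_int)
            cols = np.atleast_2d(cols)
            mask[cols[cols < net.n_knots]] = True
        return mask

    def _grow_pc_membrane(self, knot_tree: cKDTree, dt: float) -> None:
        """Plastic growth of stretched membrane in PC contact.

        Rest lengths of edges whose knots touch a Paneth cell creep
        toward the current (stretched) length at rate bm_growth_rate_pc;
        the crypt-base membrane thereby yields to niche pressure and the
        pocket area grows, while PC-free membrane stays purely elastic.
        """
        rate = self.cfg.bm_growth_rate_pc
        if rate <= 0:
            return
        net = self.state.net
        mask = self._pc_knot_mask(knot_tree)
        both = mask[net.edges[:, 0]] & mask[net.edges[:, 1]]
        if not both.any():
            return
        l = net.edge_lengths()[both]
        rest = net.edge_rest[both]
        grow = np.minimum(rate * dt, 1.0) * np.maximum(l - rest, 0.0)
        net.edge_rest[both] = rest + grow

    def _local_curvature(self, knot_tree: cKDTree) -> np.ndarray:
        """Mean signed membrane curvature over knots within r_int of each
        cell -- the tissue curvature a cell senses (NaN without knots in
        range)."""
        pop = self.state.pop
        net = self.state.net
        curv = net.knot_curvature()
        n = pop.n
        dists, cols = knot_tree.query(
            pop.pos, k=min(16, net.n_knots),
            distance_upper_bound=self.cfg.forces.r_int)
        dists = np.atleast_2d(dists)
        cols = np.atleast_2d(cols)
        ci, sub = np.nonzero(np.isfinite(dists))
        kj = cols[ci, sub]
        out = np.full(n, np.nan)
        if len(ci):
            vals = curv[kj]
            fin = np.isfinite(vals)
            sums = np.bincount(ci[fin], weights=vals[fin], minlength=n)
            cnts = np.bincount(ci[fin], minlength=n)
            ok = cnts > 0
            out[ok] = sums[ok] / cnts[ok]
        return out

    def _division_axes(self, idx: np.ndarray, knot_norm: np.ndarray) -> np.ndarray:
        """Random directions in the tangent plane of the attachment knot."""
        net = self.state.net
        pop = self.state.pop
        u = self.rng_div.normal(size=(len(idx), 3))
        ak = np.clip(pop.attach[idx], 0, net.n_knots - 1)
        n = knot_norm[ak]
        n[pop.attach[idx] < 0] = 0.0
        u -= np.einsum("ij,ij->i", u, n)[:, None] * n
        norm = np.linalg.norm(u, axis=1, keepdims=True)
        small = norm[:, 0] < 1e-9
        u[small] = np.array([1.0, 0.0, 0.0])
        norm[small] = 1.0
        return u / norm

    # ------------------------------------------------------------------
    def observe(self) -> ObservationRecord:
        st = self.state
        pop = st.pop
        sc = pop.lineage == F.SC
        compression = (pop.VT[sc] - pop.VA[sc]) / pop.V0[sc]
        from .observables import radial_extension
        profile, rmean = radial_extension(st.net)
        pcs = pop.lineage == F.PC
        turnover_now = st.turnover_total
        rec = ObservationRecord(
            time=st.time_since_switch,
            census=pop.census(),
            turnover_increment=turnover_now - self._last_turnover_total,
            removals_cum=dict(st.removals),
            sc_compression=compression.copy(),
            radial_profile=profile,
            radial_mean=rmean,
            pc_ids=pop.ids[pcs].copy(),
            pc_pos=pop.pos[pcs].copy(),
            n_cells=pop.n,
        )
        self._last_turnover_total = turnover_now
        return rec

    # ------------------------------------------------------------------
    def run(self, progress: bool = False) -> Trajectory:
        """Pre-switch phase until N_PC Paneth cells, then the postnatal
        growth phase for ``run_days``, recording observations every 1.2 h.

        Raises NicheFormationError if the cap is exceeded before the
        switch (the parameter set cannot form a niche).
        """
        cfg = self.cfg
        st = self.state
        spo = cfg.steps_per_observation
        cap_steps = int(round(cfg.pre_switch_cap_days * 24 / cfg.dt_bio))
        k = 0
        while st.external_wnt_on:
            if k >= cap_steps:
                raise NicheFormationError(
                    f"no niche after {cfg.pre_switch_cap_days} days "
                    f"(PCs: {int(np.sum(st.pop.lineage == F.PC))}/"
                    f"{cfg.fate.N_PC})")
            self.step()
            k += 1
        traj = Trajectory(config=cfg, events=self.events, state=st)
        self._last_turnover_total = st.turnover_total
        traj.observations.append(self.observe())
        n_obs = int(round(cfg.run_days * 24 / cfg.observation_interval))
        for io in range(n_obs):
            for _ in range(spo):
                self.step()
            traj.observations.append(self.observe())
            if progress:
                o = traj.observations[-1]
                print(f"t={o.time:7.1f} h cells={o.n_cells:4d} "
                      f"census={o.census}", flush=True)
        return traj


    # ------------------------------------------------------------------
    # checkpointing

    def save_state(self, path) -> None:
        """Checkpoint the full mutable state (cells, membrane, clock,
        RNG streams) to an .npz file; the event log is not included."""
        import json as _json

        st = self.state
        pop = st.pop
        rng_states = [_json.dumps(g.bit_generator.state) for g in
                      (self.rng_init, self.rng_cycle, self.rng_div,
                       self.rng_pc)]
        meta = _json.dumps({
            "clock": st.clock,
            "switch_time": st.switch_time,
            "external_wnt_on": st.external_wnt_on,
            "removals": st.removals,
            "births": st.births,
            "n_initial": st.n_initial,
            "next_id": pop._next_id,
            "last_turnover_total": self._last_turnover_total,
            "step_count": self._step_count,
        })
        arrays = {name: getattr(pop, name) for name in pop._FIELDS}
        np.savez(
            path,
            knots=st.net.knots, triangles=st.net.triangles,
            edge_rest_edges=st.net.edges, edge_rest=st.net.edge_rest,
            meta=np.array(meta), rng=np.array(rng_states), **arrays)

    def restore_state(self, path) -> None:
        """Load a checkpoint written by :meth:`save_state`; stepping on
        from here reproduces the uninterrupted run exactly."""
        import json as _json

        data = np.load(path, allow_pickle=False)
        meta = _json.loads(str(data["meta"]))
        net = self.state.net
        net.knots = data["knots"].copy()
        net.triangles = data["triangles"].copy()
        net._rest = {
            (int(i), int(j)): float(r)
            for (i, j), r in zip(data["edge_rest_edges"],
                                 data["edge_rest"])}
        net._build_topology()
        pop = CellPopulation()
        for name in pop._FIELDS:
            setattr(pop, name, data[name].copy())
        pop._next_id = int(meta["next_id"])
        st = self.state
        st.pop = pop
        st.clock = meta["clock"]
        st.switch_time = meta["switch_time"]
        st.external_wnt_on = meta["external_wnt_on"]
        st.removals = dict(meta["removals"])
        st.births = meta["births"]
        st.n_initial = meta["n_initial"]
        self._last_turnover_total = meta["last_turnover_total"]
        self._step_count = meta["step_count"]
        for g, state in zip((self.rng_init, self.rng_cycle, self.rng_div,
                             self.rng_pc), data["rng"]):
            g.bit_generator.state = _json.loads(str(state))


def run_simulation(cfg: SimulationConfig, progress: bool = False) -> Trajectory:
    """Convenience wrapper: build and run one simulation."""
    return Simulation(cfg).run(progress=progress)
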