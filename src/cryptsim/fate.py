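"""Lineage state machine of the model epithelium.

Cell types: stem cells (SC), Paneth cells (PC), goblet cells (GC),
pseudo-goblet cells (pseudo-GC), enterocytes (EC) and sub-epithelial
fibroblasts (FIB).  SC maintenance requires simultaneously active Wnt and
Notch signalling, both modelled as boolean neighbour-count thresholds:

* Wnt is active if the cell sits in the external Wnt source region (while
  that source is on) or has >= N_W Paneth-cell neighbours.
* Notch is active if the cell has >= N_N secretory neighbours
  (secretory = {PC, GC, pseudo-GC}).

When either activity is lost, SCs specify; specification of the
proliferative lineages is reversible until terminal differentiation
(secretory PC/GC commitment is final from the moment of specification):

    (Wnt, Notch) = (high, high) -> SC (remain / revert)
    (high, low)  -> PC if tissue curvature at the attachment knot >= C_0,
                    else pseudo-GC (curvature-gated Paneth specification
                    prevents unbounded SC-PC niche growth on flat tissue)
    (low, high)  -> EC
    (low, low)   -> GC

Proliferation advances the target volume V_T from V_0 to 2 V_0 in N_P
stochastic steps (per-step success probability N_P*dt/tau, i.e. the
uninhibited cycle time is Erlang(N_P, N_P/tau) distributed with mean tau),
then the cell splits.  Proliferation-capable cells are contact-inhibited
-- fully reversibly -- while their actual volume V_A drops below
V_0*(1 - dV_frac).  ECs differentiate terminally a fixed time t_prol
after specification; PCs, GCs and pseudo-GCs finish one last cell cycle
and then differentiate terminally; PCs additionally die after an
exponentially distributed lifetime with mean t_PC.  Cells that lose
contact with the basal membrane shrink rapidly (V_T halves every 0.5 h)
and are removed once V_T < 0.05 V_0.  Fibroblasts never change fate.

Times are in hours, volumes in um^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SC", "PC", "GC", "PSEUDO_GC", "EC", "FIB",
    "LINEAGE_NAMES", "SECRETORY", "EPITHELIAL",
    "FateParams", "CellPopulation",
    "wnt_active", "notch_active", "specify", "contact_inhibited",
    "cycle_step", "lifecycle_update",
]

SC, PC, GC, PSEUDO_GC, EC, FIB = range(6)
LINEAGE_NAMES = {SC: "SC", PC: "PC", GC: "GC", PSEUDO_GC: "pseudoGC",
                 EC: "EC", FIB: "FIB"}
SECRETORY = (PC, GC, PSEUDO_GC)
EPITHELIAL = (SC, PC, GC, PSEUDO_GC, EC)

SHRINK_HALFLIFE_H = 0.5     # V_T halving time of BM-detached cells
SHRINK_REMOVAL_FRAC = 0.05  # removed once V_T < this fraction of V_0


@dataclass(frozen=True)
class FateParams:
    """Thresholds and clocks of the fate rules.

    N_W, N_N : neighbour-count thresholds (inclusive) for Wnt / Notch.
    C_0 : curvature threshold for PC specification (1/um).
    N_PC : PC count at which the external Wnt source switches off.
    tau : minimal (uninhibited mean) cell cycle time (h).
    N_P : growth steps per cycle.
    dV_frac : tolerated relative compression dV/V_0 before growth arrest.
    t_prol : EC proliferation window after specification (h).
    t_PC : mean PC lifetime (h).
    """

    N_W: int = 1
    N_N: int = 2
    C_0: float = 0.05
    N_PC: int = 20
    tau: float = 10.0
    N_P: int = 20
    dV_frac: float = 0.10
    t_prol: float = 24.0
    t_PC: float = 14 * 24.0

    def __post_init__(self) -> None:
        if self.N_W < 1 or self.N_N < 1 or self.N_PC < 1 or self.N_P < 1:
            raise ValueError("integer thresholds must be >= 1")
        if not 0 < self.dV_frac < 1:
            raise ValueError("dV_frac must lie in (0, 1)")
        for name in ("tau", "t_prol", "t_PC", "C_0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


class CellPopulation:
    """Struct-of-arrays container for all cells of a simulation.

    Every per-cell attribute is a numpy array over the currently alive
    cells; ``ids`` are stable across the whole run (removed cells never
    recycle an id).
    """

    _FIELDS = (
        "pos", "lineage", "V0", "VT", "VA", "growth_step", "terminal",
        "t_since_spec", "pc_death_time", "attach", "shrinking",
        "stopped", "last_cycle", "ids",
    )

    def __init__(self):
        self.pos = np.empty((0, 3))
        self.lineage = np.empty(0, dtype=np.int8)
        self.V0 = np.empty(0)
        self.VT = np.empty(0)
        self.VA = np.empty(0)
        self.growth_step = np.empty(0, dtype=np.int32)
        self.terminal = np.empty(0, dtype=bool)
        self.t_since_spec = np.empty(0)
        self.pc_death_time = np.empty(0)
        self.attach = np.empty(0, dtype=np.int64)
        self.shrinking = np.empty(0, dtype=bool)
        self.stopped = np.empty(0, dtype=bool)
        self.last_cycle = np.empty(0, dtype=bool)
        self.ids = np.empty(0, dtype=np.int64)
        self._next_id = 0

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def add(self, pos, lineage, V0, VT=None, attach=-1, growth_step=0,
            terminal=False, last_cycle=False, t_since_spec=0.0,
            pc_death_time=np.inf) -> np.ndarray:
        """Append cells; returns the new stable ids."""
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        k = len(pos)
        lineage = np.broadcast_to(np.asarray(lineage, dtype=np.int8), k)
        V0 = np.broadcast_to(np.asarray(V0, dtype=float), k)
        VT = V0 if VT is None else np.broadcast_to(np.asarray(VT, float), k)
        new_ids = np.arange(self._next_id, self._next_id + k, dtype=np.int64)
        self._next_id += k
        self.pos = np.concatenate([self.pos, pos])
        self.lineage = np.concatenate([self.lineage, lineage])
        self.V0 = np.concatenate([self.V0, V0])
        self.VT = np.concatenate([self.VT, VT])
        self.VA = np.concatenate([self.VA, VT.copy()])
        self.growth_step = np.concatenate(
            [self.growth_step, np.broadcast_to(np.int32(growth_step), k)])
        self.terminal = np.concatenate(
            [self.terminal, np.broadcast_to(bool(terminal), k)])
        self.t_since_spec = np.concatenate(
            [self.t_since_spec, np.broadcast_to(float(t_since_spec), k)])
        self.pc_death_time = np.concatenate(
            [self.pc_death_time, np.broadcast_to(float(pc_death_time), k)])
        self.attach = np.concatenate(
            [self.attach, np.broadcast_to(np.int64(attach), k)])
        self.shrinking = np.concatenate(
            [self.shrinking, np.zeros(k, dtype=bool)])
        self.stopped = np.concatenate([self.stopped, np.zeros(k, dtype=bool)])
        self.last_cycle = np.concatenate(
            [self.last_cycle, np.broadcast_to(bool(last_cycle), k)])
        self.ids = np.concatenate([self.ids, new_ids])
        return new_ids

    def remove(self, mask: np.ndarray) -> None:
        keep = ~mask
        for name in self._FIELDS:
            setattr(self, name, getattr(self, name)[keep])

    # -- derived quantities -------------------------------------------

    def radii(self) -> np.ndarray:
        """Sphere-equivalent radius from the target volume."""
        return (3.0 * self.VT / (4.0 * np.pi)) ** (1.0 / 3.0)

    def epithelial(self) -> np.ndarray:
        return self.lineage != FIB

    def secretory(self) -> np.ndarray:
        return np.isin(self.lineage, SECRETORY)

    def census(self) -> dict[str, int]:
        return {name: int(np.sum(self.lineage == code))
                for code, name in LINEAGE_NAMES.items()}

    def proliferation_capable(self) -> np.ndarray:
        """SCs always; ECs and fibroblasts until terminally
        differentiated; PC/GC/pseudo-GC during their last cycle.
        Terminal and shrinking cells never."""
        cap = np.zeros(self.n, dtype=bool)
        cap |= self.lineage == SC
        cap |= np.isin(self.lineage, (EC, FIB)) & ~self.terminal
        cap |= np.isin(self.lineage, SECRETORY) & self.last_cycle
        cap &= ~self.terminal & ~self.shrinking
        return cap


# ----------------------------------------------------------------------
# neighbour-count signalling

def _neighbor_counts(pop: CellPopulation, pairs: np.ndarray,
                     of_mask: np.ndarray) -> np.ndarray:
    """Per-cell count of contact-graph neighbours satisfying ``of_mask``."""
    counts = np.zeros(pop.n, dtype=np.int64)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        np.add.at(counts, i, of_mask[j].astype(np.int64))
        np.add.at(counts, j, of_mask[i].astype(np.int64))
    return counts


def wnt_active(pop: CellPopulation, pairs: np.ndarray, p: FateParams,
               external_on: bool, in_region: np.ndarray) -> np.ndarray:
    """Wnt activity per epithelial cell (False for fibroblasts).

    Active if inside the external Wnt region while the source is on, or
    with at least N_W Paneth-cell neighbours in the contact graph.
    """
    pc_nbrs = _neighbor_counts(pop, pairs, pop.lineage == PC)
    active = pc_nbrs >= p.N_W
    if external_on:
        active |= np.asarray(in_region, dtype=bool)
    return active & pop.epithelial()


def notch_active(pop: CellPopulation, pairs: np.ndarray,
                 p: FateParams) -> np.ndarray:
    """Notch activity: >= N_N secretory neighbours (epithelial cells only)."""
    sec_nbrs = _neighbor_counts(pop, pairs, pop.secretory())
    return (sec_nbrs >= p.N_N) & pop.epithelial()


def specify(pop: CellPopulation, wnt: np.ndarray, notch: np.ndarray,
            curvature: np.ndarray, p: FateParams,
            rng: np.random.Generator,
            log: list | None = None, time: float = 0.0) -> np.ndarray:
    """Apply the fate mapping to all non-terminal epithelial cells.

    ``curvature`` is the signed tissue curvature at each cell's attachment
    knot (NaN where undefined, treated as below threshold).  Cells whose
    mapped lineage differs from their current one change lineage, reset
    ``t_since_spec`` and -- for newly specified PCs -- draw an exponential
    death time with mean ``t_PC``; PC/GC/pseudo-GC specification arms the
    last-cycle flag.  Returns the boolean mask of changed cells.
    """
    curv_ok = np.nan_to_num(np.asarray(curvature, float), nan=-np.inf) >= p.C_0
    target = np.where(
        wnt & notch, SC,
        np.where(wnt & ~notch, np.where(curv_ok, PC, PSEUDO_GC),
                 np.where(notch, EC, GC)),
    ).astype(np.int8)
    # SCs, EC progenitors and pseudo-GCs re-evaluate their fate; PCs and
    # GCs are committed once specified (they are completing their last
    # cycle), so established niches do not dissolve by reversion
    committed = pop.last_cycle & np.isin(pop.lineage, (PC, GC))
    eligible = (pop.epithelial() & ~pop.terminal & ~pop.shrinking
                & ~committed)
    changed = eligible & (target != pop.lineage)
    idx = np.nonzero(changed)[0]
    if log is not None:
        for i in idx:
            log.append((time, int(pop.ids[i]), "specify",
                        f"{LINEAGE_NAMES[int(pop.lineage[i])]}->"
                        f"{LINEAGE_NAMES[int(target[i])]}",
                        bool(wnt[i]), bool(notch[i]), float(curvature[i])))
    pop.lineage[idx] = target[idx]
    pop.t_since_spec[idx] = 0.0
    # pseudo-GCs are stalled PC precursors: they stay reversible (no
    # last cycle, no terminal differentiation) and convert to PC once
    # the local tissue curvature rises above C_0
    pop.last_cycle[idx] = np.isin(target[idx], (PC, GC))
    new_pc = idx[target[idx] == PC]
    if len(new_pc):
        pop.pc_death_time[new_pc] = rng.exponential(p.t_PC, size=len(new_pc))
    pop.pc_death_time[idx[target[idx] != PC]] = np.inf
    return changed


def contact_inhibited(pop: CellPopulation, p: FateParams) -> np.ndarray:
    """Reversible growth arrest: V_A strictly below V_0*(1 - dV_frac).

    A cell exactly at the threshold still proliferates.  Recomputed every
    step, so release of compression immediately restarts cycling.
    """
    return pop.VA < pop.V0 * (1.0 - p.dV_frac)


def cycle_step(pop: CellPopulation, inhibited: np.ndarray, p: FateParams,
               dt: float, rng: np.random.Generator) -> np.ndarray:
    """Advance the stochastic cell cycle by ``dt`` hours.

    Each proliferation-capable, non-inhibited cell increments its growth
    step with probability ``N_P * dt / tau`` and gains V_0/N_P of target
    volume; cells reaching N_P steps are returned (indices) for division.
    """
    prob = p.N_P * dt / p.tau
    if prob > 1:
        raise ValueError("N_P*dt/tau exceeds 1; reduce the timestep")
    active = pop.proliferation_capable() & ~inhibited
    draw = rng.random(pop.n) < prob
    stepping = active & draw
    pop.growth_step[stepping] += 1
    pop.VT[stepping] += pop.V0[stepping] / p.N_P
    return np.nonzero(stepping & (pop.growth_step >= p.N_P))[0]


def divide(pop: CellPopulation, idx: np.ndarray, axes: np.ndarray,
           log: list | None = None, time: float = 0.0) -> np.ndarray:
    """Split the cells ``idx`` along the unit ``axes``.

    The mother is reset in place (one daughter), the second daughter is
    appended; daughters start at V_T = V_0, growth step 0, inherit the
    lineage and specification clock, and become terminally differentiated
    if the mother was in her last cycle.  Returns appended daughter ids.
    """
    if len(idx) == 0:
        return np.empty(0, dtype=np.int64)
    R = pop.radii()[idx]
    offset = 0.4 * R[:, None] * axes
    mother_pos = pop.pos[idx].copy()
    was_last = pop.last_cycle[idx].copy()
    lineage = pop.lineage[idx].copy()
    V0 = pop.V0[idx].copy()
    tss = pop.t_since_spec[idx].copy()
    pdt = pop.pc_death_time[idx].copy()

    pop.pos[idx] = mother_pos - offset
    pop.VT[idx] = V0
    pop.growth_step[idx] = 0
    pop.terminal[idx] |= was_last
    pop.last_cycle[idx] = False

    new_ids = pop.add(
        mother_pos + offset, lineage, V0,
        attach=-1, t_since_spec=0.0,
    )
    k = len(idx)
    pop.t_since_spec[-k:] = tss
    pop.terminal[-k:] = pop.terminal[idx]
    pop.pc_death_time[-k:] = pdt
    pop.attach[-k:] = pop.attach[idx]
    if log is not None:
        for m, i in enumerate(idx):
            log.append((time, int(pop.ids[i]), "divide",
                        f"daughter={int(new_ids[m])}", None, None, None))
    return new_ids


def lifecycle_update(pop: CellPopulation, dt: float, p: FateParams,
                     log: list | None = None,
                     time: float = 0.0) -> dict[str, np.ndarray]:
    """Clocks, terminal differentiation, PC death and shrink removal.

    Returns removed cell ids per cause (``pc_death``, ``detachment``).
    The shrink law halves V_T every 0.5 h once a cell has lost BM contact;
    removal triggers below ``SHRINK_REMOVAL_FRAC * V_0``.
    """
    pop.t_since_spec += dt

    # ECs -- and fibroblasts, which are modelled like ECs -- lose their
    # proliferative capacity a fixed time t_prol after specification
    # (for fibroblasts: after their birth or the simulation start)
    ec_done = np.isin(pop.lineage, (EC, FIB)) & ~pop.terminal & (
        pop.t_since_spec >= p.t_prol)
    if log is not None:
        for i in np.nonzero(ec_done)[0]:
            log.append((time, int(pop.ids[i]), "terminal",
                        LINEAGE_NAMES[int(pop.lineage[i])],
                        None, None, None))
    pop.terminal[ec_done] = True

    pop.VT[pop.shrinking] *= 0.5 ** (dt / SHRINK_HALFLIFE_H)

    pc_dead = (pop.lineage == PC) & (pop.t_since_spec >= pop.pc_death_time)
    gone_shrunk = pop.shrinking & (pop.VT < SHRINK_REMOVAL_FRAC * pop.V0)
    removed = {"pc_death": pop.ids[pc_dead].copy(),
               "detachment": pop.ids[gone_shrunk].copy()}
    if log is not None:
        for i in np.nonzero(pc_dead)[0]:
            log.append((time, int(pop.ids[i]), "remove", "pc_death",
                        None, None, None))
        for i in np.nonzero(gone_shrunk)[0]:
            log.append((time, int(pop.ids[i]), "remove", "detachment",
                        None, None, None))
    pop.remove(pc_dead | gone_shrunk)
    return removed
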