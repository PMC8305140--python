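# Methods

`cryptsim` models the postnatal growth of the mouse small-intestinal
epithelium: the formation of crypts from the flat inter-villus epithelium
after birth, the expansion of the stem-cell (SC) pool, and the onset of
crypt fission, driven by the interplay of tissue growth, cell fate rules
and contact inhibition of growth.  It combines a 3D individual cell-based
simulator with closed-form/ODE descriptions of tissue-scale growth and
the estimators used to analyze simulated trajectories.

## 1. Analytic growth models

Surface growth of the young intestine is approximated by a growth rate
that decays exponentially in time,

    dA/dt = r_G exp(-t/tau_G) A
    =>  A(t) = A_0 exp( r_G tau_G (1 - exp(-t/tau_G)) ),

with initial surface growth rate `r_G` (per week) and decay constant
`tau_G` (weeks).  The total fold expansion is `exp(r_G tau_G)`; both the
external and internal surface of the mouse small intestine expand about
five-fold after birth, so `r_G = 1-2 /wk` for `tau_G = 1-2 wk` are the
physiologic ranges and `r_G tau_G = ln 5` is the canonical default.  If
the crypt density `n_C = N_C/A` is constant, the fission activity needed
to keep up is `n_C dA/dt`; it peaks at `t_mf = tau_G ln(r_G tau_G)`
(clamped to 0 when `r_G tau_G < 1`, where activity decays from the
start).

The crypt-density-controlled model couples fission to crowding:

    dN_C/dt = r_M (1 - n_C/n_CE) N_C,      c = r_M (1 - n_C/n_CE),
    dA/dt   = r_C N_C exp(-t/tau_G),

with maximum fission rate `r_M`, per-crypt surface production `r_C`, and
equilibrium crypt density `n_CE`.  `c` is the instantaneous fission rate
and equals the inverse SC doubling time; `t_d = ln2 / c` (infinite where
`c <= 0`).  Runs start at `n_C(0) = n_CE`: the density dips while the
non-epithelial layers grow and reconstitutes as growth decays; longer
growth (larger `tau_G`) only lengthens the recovery.  Defaults `r_C = 1
area/crypt/wk`, `n_CE = 1 crypt/area`, `tau_G = 2 wk`, `r_M = 5 /wk`,
`N_C0 = 100` make the dip clearly visible; all are configurable.  The
integrator is a fixed-step classical RK4 (`dt = 1e-3 wk`): the system is
non-stiff and fixed steps keep results bit-reproducible; the step is
~1e-4 of the fastest time scale, and agreement with an adaptive
high-accuracy integrator is verified to relative error < 1e-6.

## 2. The individual cell-based tissue model

### Geometry and membrane

The tissue is an open cylinder (the inter-villus junction present at
birth): a triangulated basal membrane (BM) with epithelium covering the
inner and fibroblasts the outer surface.  The BM is a network of harmonic
edge springs (`k_stretch`) with dihedral bending (`k_bend`, spontaneous
angle 0).  Remeshing splits edges stretched beyond `l_max` and collapses
edges below `l_min` (guarded by the link condition; boundary rings are
never collapsed), keeping the mesh impenetrable for cells of comparable
radius.  Splits are strain-preserving — new elements inherit the parent
stretch ratio — so re-organization never converts transient elastic
stress into permanent growth.  Stress-free membrane area is produced by
exactly two mechanisms:

* externally forced radial growth at rate `r` (fraction of circumference
  per day), modelling expansion of the outer tissue layers: rest lengths
  of circumferential edge components are scaled each step;
* plastic yielding of stretched membrane in contact with Paneth cells
  (`bm_growth_rate_pc = 1 /h`): the crypt-base BM grows under the
  pressure of the proliferating niche.  This local growth is the
  geometric half of the positive feedback that makes the niche expand
  (see Fate rules below); without it the niche is capped by the fixed
  membrane area and SC expansion is impossible.

Membrane orientation: triangle normals point away from the epithelial
side.  Signed mean curvature (cotangent-Laplacian estimate) is positive
where the surface is concave toward the lumen, i.e. a crypt-like
invagination is positive, a villus-like luminal bulge negative; the
undeformed cylinder of radius `R` has `+1/(2R)`.

Membrane regions in contact with Paneth cells additionally prefer an
invaginated shape (spontaneous hinge angle `theta0_pc = 0.3 rad` on
edges whose knots lie within `r_int` of a PC); this encodes the specific
biomechanics of the BM at the crypt base and drives pocket formation.

### Cell mechanics

Cells are elastic spheres in the overdamped regime (displacement =
force/friction x dt; no inertia, no thermal noise — stochasticity enters
only through cycle progression, division orientation and PC lifetimes).
Pairwise interaction is Hertz-type repulsion plus a short-range adhesion
well (cutoff `1.2 (R_a+R_b)`, which also defines the contact graph used
by the fate rules).  Cells adhere to the BM through a tether to their
nearest attachment knot acting along the membrane normal with rest
height equal to the cell radius — the sphere hovers tangent to the
membrane, free to slide laterally (hopping knots as it moves), and is
neither squashed into the plane at rest nor able to leave it without
opposing force.  All knots within `r_int = 6 um` repel the cell, which
renders the membrane impenetrable; every cell-knot force has an explicit
reaction on the knot, so cells shape the membrane exactly as strongly as
it holds them.  Epithelial neighbours (and fibroblast neighbours among
themselves) are linked by a contractile apical network: harmonic links
with rest length `0.90 (R_a+R_b)`.  The mild pre-tension is what
distinguishes the fibroblast-free tissue (net luminal pull, inward
villus-like lobes) from the full tissue, where the fibroblast layer
mirrors the pull and PC-driven invaginations dominate.  Links to a cell
that has lost BM contact contract with a five-fold amplified force,
closing the epithelium over the dying cell.

The actual volume is `V_A = V_T` minus the spherical caps lost to each
overlapping neighbour (own cap beyond the radical plane, no multi-overlap
correction) and to the membrane plane at the attachment knot, floored at
`0.1 V_T`.  The relative compression `(V_T - V_A)/V_0` is the model's
pressure proxy; its per-SC median over the last two simulated days is
reported as the niche pressure.

### Fate rules

Lineages: SC, Paneth (PC), goblet (GC), pseudo-goblet, enterocyte (EC),
fibroblast (FIB).  Wnt is active for an epithelial cell inside the
external Wnt source region (while on) or with `>= N_W` PC neighbours;
Notch is active with `>= N_N` secretory (PC/GC/pseudo-GC) neighbours.
Non-terminal cells map as: (Wnt,Notch) high/high -> SC; high/low -> PC
if the local tissue curvature `>= C_0`, else pseudo-GC; low/high -> EC;
low/low -> GC.  "Local tissue curvature" is the mean signed curvature of
membrane knots within `r_int` of the cell: the single attachment knot
sits in a cell-scale dimple of systematically negative curvature and
cannot express the pocket-scale geometry the PC gate is about.

Threshold defaults are `N_W = 1`, `N_N = 2`.  The asymmetry is
structural, not cosmetic: with `N_N <= N_W` every SC next to a PC (its
Wnt source) automatically has a secretory neighbour (a Notch source), so
the state (Wnt high, Notch low) required to specify further PCs is
unreachable once the external source is off — the niche freezes and
decays to extinction.  With `N_N = 2` an SC touching exactly one PC
specifies PC (given curvature), i.e. PC clusters grow at their rim.
Together with PC-contact membrane growth this is the positive feedback
of niche expansion: pocket pressure grows the membrane, the pocket
spreads curvature, rim cells convert, more Wnt is provided, more SCs are
maintained.

PC and GC commitment is final from the moment of specification (they are
completing their terminal-bound last cycle); SCs, EC progenitors and
pseudo-GCs re-evaluate every fate update.  Pseudo-GCs are stalled PC
precursors: Wnt-high secretory cells specified where curvature is too
low, which stay reversible and convert to PC once the local curvature
rises.  ECs differentiate terminally `t_prol = 24 h` after
specification.  Fibroblasts never change lineage; they are modelled like
ECs, including the finite proliferation window `t_prol` after birth — an
immortal fibroblast layer facing the open exterior of the tube never
reaches contact inhibition and inflates the membrane without bound.
PCs die after an exponential lifetime (mean `t_PC = 14 d`).

Proliferation increments the target volume `V_0 -> 2 V_0` in `N_P = 20`
stochastic steps (success probability `N_P dt/tau` per step), so the
uninhibited cycle time is Erlang-distributed with mean `tau = 10 h` and
CV `1/sqrt(N_P)`.  At `2 V_0` the cell divides: daughters at `V_0`,
offset `±0.4 R` along a random direction in the attachment knot's
tangent plane.  Proliferation-capable cells are arrested — fully
reversibly — while `V_A < V_0 (1 - dV_frac)` with tolerated compression
`dV_frac = 0.10` (a cell exactly at the threshold still cycles).

Cells whose nearest membrane knot is farther than `d_detach = 10 um`
have lost BM contact: they shrink (`V_T` halves every 0.5 h) and are
removed below `0.05 V_0`.  Epithelial cells crossing the open cylinder
ends are removed ("turnover" onto the villi; counted per end);
fibroblasts stop and remain at the openings.  In `blocked` mode the ends
reflect instead and nothing leaves.

### Scenario

Runs start with SCs tiling the inner surface inside the central external
Wnt region (50% of the axis) and ECs outside it, fibroblasts on the
outer surface, cell-cycle phases randomized over the first third of the
cycle.  On the initial cylinder the curvature is everywhere below `C_0`,
so no PCs can specify; membrane re-organization under division pressure
eventually produces spots above threshold.  When `N_PC = 20` Paneth
cells exist, the external source switches off and the clock resets to
t = 0; observations are recorded every 1.2 h from then on.  Each
biology step (0.1 h) comprises five mechanics substeps (0.02 h) —
forces, overdamped motion, remeshing — followed by volumes, contact
inhibition, cycling/divisions, Wnt/Notch/specification, lifecycle and
boundary turnover.  Runs are deterministic given the seed (one root seed
split into subsystem streams for initialization, cycle noise, division
axes and PC lifetimes).

## 3. Trajectory analysis

Turnover counts only epithelial removals at the cylinder ends (BM-
detachment losses are excluded) and is smoothed over 20 observations
(one day); the same 20-observation window smooths SC counts before
growth-rate estimation.  The SC growth rate `q` (decades/day) is the
slope of log10(SC) vs time starting at the first index from which the
fit over all later points reaches Pearson `R > 0.95`; the doubling time
is `t_d = ln 2/(ln 10 q)` (infinite sentinel for `q <= 0`; a flat series
has undefined correlation and reports no onset).  Compression statistics
pool per-SC `(V_T - V_A)/V_0` over the last 40 observations.  Crypts are
single-linkage clusters of PC positions at cutoff `10.5 um` (3 cell
radii); clusters are tracked by member overlap and a fission event is a
split into fragments that each persist 10 observations (12 h) without
re-merging.  The dependence of growth on niche pressure is summarized by
fitting `1/t_d` linearly against the median compression; the x-intercept
estimates the compression at which SC expansion vanishes (`t_d -> inf`).

## 4. Problem sizes and what desk-scale runs show

The full-scale phenomenology (hundreds of crypts, multi-week growth)
requires cluster-scale computing.  The package's default tissue is
deliberately small — cylinder radius 15 um, length 64 um, ~170
epithelial plus ~170 fibroblast cells, ~460 membrane knots — so that a
complete run (niche formation plus 5 simulated days of postnatal growth)
takes about 1.5 minutes on one core, and the multi-condition comparisons
(growth rates r = 0/0.1/0.2 per day, cycle times tau = 10/14 h,
tolerated compressions dV/V0 = 0.10/0.15, open/blocked turnover,
with/without fibroblasts) remain runnable as an ordinary test suite.
Because the geometry is small, the undeformed tube's own curvature
(1/(2R) = 0.033/um) is larger than in a full-size tissue; the PC
curvature gate default is `C_0 = 0.05/um`, above that baseline, so
Paneth specification still requires genuine membrane deformation.

At this scale the model reproduces the qualitative biology: niche
formation and Wnt hand-over at 20 PCs, an initial SC drop after the
switch followed by exponential SC expansion with a doubling time of a
few days, a stable cell turnover at the open ends, PC-cluster crypts
that deepen and occasionally split, and compression-limited growth.
Quantities tied to absolute tissue size (crypt counts, turnover per
crypt, the two-week crypt-formation time of full-scale runs) are not
reproduced quantitatively; comparative statements (invariance of t_d
under r; acceleration under shorter tau or larger tolerated
compression) are evaluated across seeds and these are what the test
suite asserts.  SC census fluctuations at ~50-250 cells are relatively
large; the 20-observation smoothing (itself part of the analysis
procedure) and restriction of the onset fit to the expansion phase
(the smoothed census truncated at its maximum, see
``observables.expansion_doubling_time``) are what make onset detection
stable at this size — in the short tube the SC pool saturates once the
crypts fill it, and the whole-tail onset rule was designed for runs
that never reach that ceiling.

Two desk-scale caveats are worth stating explicitly.  First, in the
blocked-turnover/zero-growth condition the arrested steady state is
macroscopic: net cell production stops and the large majority of
proliferation-capable cells is inhibited at any instant, but a minority
is always transiently decompressed by a neighbour's recent division, so
an instantaneous census never reads literally 100% inhibited.  Second,
raising the tolerated compression visibly accelerates niche growth
(larger final SC pools and crypt counts at dV/V0 = 0.15), but the
doubling-time estimator often cannot resolve the acceleration: the
faster runs saturate earlier and their crypts interact strongly, which
is exactly the situation the non-interacting-crypts filter of the
full-scale analysis exists to exclude; at desk scale that filter would
discard essentially every run.  The corresponding comparison in the
test suite is kept in its strict form and documents this limit.

## 5. Known limitations

* The membrane has no self-contact handling beyond knot-cell repulsion;
  very deep pockets can approach each other unphysically.
* `V_A` subtracts pairwise caps without multi-overlap correction and cuts
  only the attachment-knot plane, so compression is approximate in
  highly concave pockets.
* Fibroblast-free runs still specify Paneth cells at this scale; the
  fibroblast effect appears as a statistical shift of the deformation
  field (inward-dominated vs invagination-dominated), not as a complete
  absence of crypts.
* The external Wnt region, pre-switch composition and the unstated
  parameter values of the source model (thresholds, mechanical moduli)
  are package defaults chosen as described above, not literature values.
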