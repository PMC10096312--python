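# Methods

`mdgraphs` implements two complementary procedures: the *forward* direction
— reducing each frame of a molecular-dynamics trajectory to a topological
2D molecular graph and tracking conformers as graph-isomorphism classes —
and the *reverse* direction — generating a 3D structure from a molecular
graph alone, by a sequential game with Linear-Reward-Inaction (LRI)
learning and no energy function. This note records the models, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic fixtures do and do not demonstrate.

## The 2D molecular graph

A configuration of atoms is encoded as a colored mixed graph
`G = (V, EC, AH, EI, EO)`:

* `V` — all heavy (non-hydrogen) atoms, colored by element;
* `EC` — covalent bonds (undirected);
* `AH` — hydrogen bonds as *directed arcs*, donor-heavy → acceptor-heavy;
* `EI` — electrostatic contacts of flagged ions (undirected);
* `EO` — organometallic contacts of flagged metals (undirected).

Hydrogens never appear as vertices; an H-bond's hydrogen is retained only
in a side table (arc → mediating H id) and is deliberately *not* part of
the isomorphism signature: two frames whose H-bond networks agree as
directed arcs are the same conformer even if a different covalent hydrogen
mediates an arc.

### Interaction perception

All perception is geometric, driven by a per-element table (covalent
radius, valence cap, ion/metal flags) and a threshold set. Defaults:

| parameter | default | meaning |
|---|---|---|
| `covalent_tolerance` | 0.40 Å | slack added to the covalent radii sum |
| `hbond_heavy_max` | 3.5 Å | donor-heavy to acceptor-heavy distance cap |
| `hbond_angle_min` | 140° | minimum D–H···A angle at the hydrogen |
| `electrostatic_max` | 3.0 Å | ion contact cutoff |
| `organometallic_max` | 2.8 Å | metal contact cutoff |
| acceptors | N, O, F, S, Cl | H-bond acceptor elements |

Covalent radii are the Cordero consensus values; valence caps are chemical
maxima (`H`=1, `O`=2, `C`=4, `N`=4 to admit protonated amine termini,
metals 8). These are practitioner defaults, overridable from a YAML file;
they are stand-ins for whatever database a given study would calibrate.

Bond overflow is resolved *nearest-first*: candidate pairs within cutoff
are granted in ascending (distance, partner-id) order, each atom stopping
at its cap. The id tie-break makes perception deterministic; identical
inputs give bit-identical graphs.

H-bond arcs point donor → acceptor. (The two conventions that circulate —
"heavy to donor" vs "donor to acceptor" — differ only by a global
reversal; the donor → acceptor form matches how transition labels such as
"N1→O1 formed" read chemically.)

Per-atom *orbits* (all atoms within `orbit_radius` = largest cutoff +
2.0 Å) restrict the candidate search. Orbits are recomputed when any
atom's displacement since the reference frame exceeds
`(orbit_radius − largest cutoff)/2`, or every 100 frames, whichever comes
first. The margin guarantees soundness: two atoms must *jointly* close at
least the full slack before a contact invisible to the orbit lists could
form, so orbit-restricted perception provably equals the all-pairs result
(property-tested on random-walk trajectories).

## Conformer identification

Two frames are the same conformer iff their graphs are isomorphic under a
vertex bijection preserving element colors, every typed edge set, and arc
direction. Engine: the mixed graph is encoded as a digraph whose edges
carry the set of interaction types per direction (undirected types
contribute both directions, arcs one), and VF2 decides isomorphism with
node/edge attribute matching.

Registry lookup does not run VF2 against every known conformer: a
*canonical key* — computed by iterated color refinement (vertex color
refined by the multiset of (edge-type, neighbor-color) over in- and
out-edges) with individualization backtracking at non-discrete partitions
— is equal for two graphs iff they are isomorphic, so lookup is one
dictionary access. The previous frame's conformer is tried first (frames
are autocorrelated), and the number of registry lookups avoided this way
is instrumented.

The graph of transitions has one vertex per conformer (labelled with its
percentage of frames) and a directed edge per observed adjacent-frame
interconversion, counting occurrences and carrying the typed interactions
formed/broken between the two representatives. Consecutive identical
conformers are residence, not transitions, so there are no self-loops.
Percentages count frames, not integrated time (the analyzed trajectories
have constant time steps, so the two coincide up to a constant). Exports
highlight vertices at or above `p_min` (default 4%) in red, below in
green.

## Cycle analytics

All edge types pooled and taken undirected, the minimum cycle basis (unit
weights) is computed by Horton's construction: candidates
`C(v,e) = SP(v,x) + (x,y) + SP(y,v)` for every vertex/edge combination,
kept when simple, then accepted greedily in ascending (length,
lexicographic vertex sequence) order subject to GF(2) independence
(bitmask elimination over edge space). Shortest paths are made unique by a
smallest-id parent rule; the fundamental cycles of a spanning tree are
appended to the candidate pool so it provably spans the cycle space.
Minimum cycle bases are not unique; the lexicographic tie-breaks make this
one deterministic. Total basis weight is cross-checked in the tests
against networkx's independent minimum-cycle-basis implementation, and
against exhaustive search on small graphs.

On top of the basis: ring-size histograms (pooled per-frame bases,
normalized over all cycles), connected-component size histograms, the
percentage of vertices lying on at least one basis cycle ("polygon
membership", averaged over frames), and the coarse-grained *graph of
cycles* — one vertex per basis cycle containing at least one H-bond arc,
an edge when two cycles share a vertex or an edge. An "H-bonded cycle" is
defined here as a basis cycle containing ≥ 1 arc; the term is used
loosely in the literature and this is the weakest non-trivial reading.
Cross-conformer cycle matching (polymorphic cycles, the trajectory
polygraph) is out of scope. Interfacial-layer selection is an input: the
caller provides the atom subset (a convenience z-slab filter exists, with
no claim to reproduce any published layer definition).

## 3D generation: the sequential game

Input: a hydrogen-*inclusive* connected graph of covalent bonds plus
target H-bonds. A BFS covering tree `T` is built (deterministic
ascending-id neighbor order; root = highest-degree vertex, ties to lowest
id; root position fixed at the origin). Every tree edge `(u, v)`, `v` a
child of `u`, is a player with 42 strategies: the unit directions of an
icosphere (12 icosahedron vertices + 30 edge midpoints, re-normalized)
scaled by the edge's ideal length — the covalent radii sum for covalent
edges, 2.9 Å heavy–heavy for H-bonds (configurable; discretization tends
to make learned H-bonds short). Each round, every player samples a
direction from its strategy vector; children are placed on their parent's
icosphere after the *minimal-angle rotation* taking the grid's designated
parent slot to the actual parent direction (identity at the root, and the
minimal rotation is the one minimizing mean grid-point displacement).

Costs couple two terms, both purely geometric:

* `Direct(u)` — VSEPR discomfort: directions from `u` to all its graph
  neighbors, normalized to the unit sphere, compared against the element's
  ideal electron-domain template (linear 180°, bent 104.5°/107°, trigonal
  planar 120°, trigonal pyramidal 107°, tetrahedral 109.47°; template
  selected by bonded-neighbor count and a small per-element lone-pair
  table: C 0, N 1, O/S 2). The value is the minimum over
  neighbor-to-slot assignments and rigid template rotations of the summed
  chord distances. Per assignment the rotation is obtained by Kabsch
  (least-squares) alignment; the public function then polishes the best
  assignment by direct minimization of the *summed* (not squared)
  distances, verified against brute force in the tests. Inside the game
  loop the Kabsch value is used unpolished — the difference is far below
  the 42-direction discretization error and the loop runs ~10⁴–10⁵ rounds.
* `Local(w)` — non-tree bond violations (distance between a non-tree
  neighbor's position and its projection onto `w`'s ideal-length sphere)
  plus a steric term: any non-bonded vertex inside `w`'s grid radius adds
  its distance to `w`. `Indirect(u)` sums `Local(v)/dist_T(u,v)` over
  *proper* descendants `v` of `u` (including `u` itself would divide by
  `dist_T(u,u) = 0`; `u`'s own discomfort is already `Direct(u)`).

Player cost `R(u,v) = (Direct(u) + Indirect(u))/2` — identical for all
players sharing `u`.

### Learning, utility normalization and its degenerate case

After each round the player's utility is

    U = (Max(s) − R) / (Max(s) − Min(s))

with `Max(s)/Min(s)` the running extremes of `R` over the rounds in which
this player played this strategy, current round included, and the LRI
update reinforces the played strategy: `V(s) += (1−V(s))·b·U`, all others
`V(s′) −= V(s′)·b·U` (slowing factor `b`, default 0.1; the update provably
stays on the probability simplex, tested to 1e-12 over 10⁵ steps).

`Max(s) = Min(s)` makes the formula undefined. Besides the harmless
first-play case, this situation is *persistent* for any player whose cost
is a deterministic function of its own strategy — e.g. a two-neighbor
chain atom with a clash-free subtree, whose `Direct` depends only on the
angle its own strategy makes with the parent slot. A flat fallback
(U = 0.5 always) would give such players no learning signal whatsoever:
their strategy vectors perform a martingale random walk and lock onto an
arbitrary direction (measured on the 5-carbon chain: recovery of the
linear geometry dropped to roughly chance). The fallback used here is the
player's running cost extremes across *all* its strategies,
`U = (GMax − R)/(GMax − GMin)`, which ranks deterministic strategies by
cost while leaving the non-degenerate formula untouched; only a player
that has seen a single cost value in its life gets the neutral 0.5.

### Blocks, stopping, and reporting

The game runs over independent blocks (default 10 × 5 000 rounds for this
package's problem sizes; the round budget is configurable upward for
larger molecules). Each block restarts strategy vectors and cost
histories. Within a block the best round is tracked by the key
(`m_k` = mean player utility, then lower mean player cost): `m_k` is a
*relative* measure that saturates at 1.0 when systems have few players, so
the cost — the quantity players actually minimize — resolves ties. A block
stops after `t` = 500 consecutive rounds without improvement of this
tracked best, or at its round budget. The best block (same key) supplies
the reported structure; per-block best-`m` values and RMSDs against an
optional target are reported in a per-block table, and the running-best
`m_k` trace per round is kept for diagnostics (non-decreasing by
construction).

Bond lengths along tree edges are exact by construction (children sit on
the icosphere), so all structural error is angular; the 42-direction grid
quantizes achievable angles to roughly 30° steps, which is why the water
test tolerates 15° about the 104.5° template (nearest achievable pairs sit
at 90°, 108°, 116.6°).

RMSD uses least-squares rigid superposition (Kabsch via
`scipy.spatial.transform.Rotation.align_vectors` after centering), with the
deviation recomputed from the rotated coordinates rather than taken from
the solver's residual (avoids cancellation noise near zero).

## Synthetic fixtures: what they show and what they do not

All inputs are generated in code:

* **Small molecules** (water, methane, ammonia, water dimer) at canonical
  geometries (O–H 0.9572 Å / 104.5°, C–H 1.09 Å tetrahedral, N–H 1.01 Å /
  107°, dimer O–O 2.9 Å with a collinear bridge).
* **Peptide-like chains** built by internal-coordinate (NeRF) placement in
  extended conformations: an NH3+–Ala3–COOH-like chain (C9H18N3O4, 34
  atoms) and a benzyl-capped hexa-alanine-like chain assembled as
  Ph–CH2–NH–CO–(Ala)6–OH, which reproduces the composition C26H39N7O8
  (80 atoms) exactly. Each carries one terminus-to-terminus target H-bond
  in its graph. These are topology-faithful stand-ins — correct
  composition and covalent graph, verified by running the perception
  pipeline on their coordinates — not quantum-quality geometries.
* **Hexagonal water sheets**: a honeycomb of waters (O–O 2.8 Å) whose
  donated hydrogens realize every lattice edge as exactly one H-bond arc.
  Donor assignment is an Eulerian orientation of the lattice (out-degree
  ≤ 2 everywhere, so every oxygen keeps exactly two hydrogens); spare
  hydrogens point out of plane where no acceptor is reachable.
* **Scripted trajectories**: a base molecule plus named, reversible
  geometric toggles per frame (break the dimer's H-bond; separate the
  monomers; add a back-donated second H-bond). The expected conformer-id
  sequence follows from the schedule alone, and the builder verifies that
  distinct toggle states give non-isomorphic graphs — an ineffective
  toggle fails loudly at build time.
* **Bare carbon chains** for geometry recovery: two-neighbor carbons have
  no lone pairs, so the VSEPR reference is exactly linear and the target
  is well-defined (a substituted chain would have free dihedrals that the
  method, by design, does not constrain).

Passing tests on these fixtures demonstrates the algorithms' contracts —
exact perception on clean geometries, exact conformer bookkeeping on known
schedules, exact basis dimensions, recovery of discretization-limited
geometries. They do not demonstrate robustness to thermal noise near
perception thresholds (real trajectories flicker near cutoffs, inflating
conformer counts), to condensed-phase periodicity (no periodic images in
v1), or to the conformational richness of real peptides; and the
structure generator is validated on molecules far smaller than anything of
practical interest — at peptide scale the game needs block budgets on the
order of 10⁵ rounds, which is outside what the default test sizes probe.

## Known limitations

* No bond orders, no periodic boundary conditions, no binary trajectory
  formats.
* Canonical labeling is exponential in the worst case; molecular graphs
  refine to discrete partitions almost immediately, but adversarial highly
  regular colored graphs could be slow.
* The steric term rewards *shallower* intrusions less than deep ones only
  weakly (it adds the intruder's distance, which vanishes as the overlap
  becomes total); it deters clashes mainly by making clash-free rounds
  strictly cheaper. A repulsive (inverted) term would be more natural but
  is not what the method specifies.
* `m_k` is relative to each player's own history, so it is comparable
  neither across molecules nor, strictly, across blocks; the cost
  tie-break mitigates this at small scale.
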