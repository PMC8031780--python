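# Methods

This note records the conventions, model choices and numerical decisions
behind `secgeom`, and what the synthetic test bed does and does not show.

## Coordinate conventions and units

All internal geometry is in ångström (PDB native); reported distances and
radii are converted to nm and angles to degrees at the measurement boundary.
Structures are assumed membrane-oriented — normal along +z, in-plane
reference along +x — as membrane-embedding pipelines produce them. Both
directions are configurable through `MembraneFrame`; tilt angles are
meaningless in an arbitrary deposited frame, and the fetch script therefore
prefers membrane-oriented copies of the reference entries. Distances between
residue windows are frame-independent.

Residue identity is author numbering as printed in the PDB file, with
insertion codes part of the identity; residue ranges are numeric only
(insertion-code ordering inside a range is not modelled — none of the
target structures needs it). Missing residues inside a window are tolerated
with a logged warning; only an empty selection is an error.

## Helix endpoints, axes and angle descriptors

A transmembrane helix endpoint is the centre of mass of the Cα atoms of the
terminal helical turn (four residues by default); the axis joins the N- and
C-endpoints and is oriented N→C. Centres of mass are mass-weighted by
default; for all-Cα windows this is indistinguishable from the unweighted
mean, and a `geometric` option exposes the distinction.

Angles are reported over the full [0°, 180°] range with no folding at 90°:
an axis anti-parallel to the reference reads 180°. This signed convention is
required for gate-helix tilts that exceed 90°.

`θ_cTM4nTM1` (orientation of the TM4 C-terminal turn relative to the TM1
N-terminal turn) is named by its two turn windows only, which leaves the
vector construction open. Three conventions are implemented behind one enum:
`local_turns` (angle between the two one-turn local axes, each the COM
difference of adjacent turns, both oriented N→C; the default, as the most
direct reading of "orientation of a terminus"), `axis_to_com_line` (full
TM4 axis against the line joining the two turn COMs) and `full_axes` (full
TM4 axis against full TM1 axis). The default can be calibrated against the
three deposited channel states once the reference entries are fetched; the
cryo-EM acceptance test performs exactly that comparison.

`IS3` is defined on whole residues, so it uses heavy-atom COMs of the two
single residues rather than Cα atoms (the other interaction sites are
Cα-window COMs); a Cα-only option exists.

## Pore-ring radius

Cα atoms of the N-terminal turns of TM2, TM5, TM7 and TM10, plus every
other Cα within 0.5 nm (Cα–Cα) of any ring Cα, are projected on the plane
orthogonal to the membrane normal and fitted with a circle. The fit is the
algebraic Kåsa least-squares solution — the linear system
`2ax + 2by + c = x² + y²` — which is closed-form, deterministic and exact
on points that lie on a circle. An iterative geometric refinement exists in
the tests as an oracle but is deliberately not the production path: no
iteration tolerance, no initialisation sensitivity. Degenerate input
(fewer than three points, collinear points, non-positive squared radius)
raises rather than returning a fabricated value.

The 0.5 nm "contact residues" criterion is interpreted as Cα–Cα distance to
the ring-turn Cα atoms, matching the Cα-based projection; growing the
cutoff can only add points.

## Secondary structure (Kabsch–Sander)

The assignment is implemented from the original energy model. Amide
hydrogens, when absent, are constructed 1.0 Å from N along the normalised
sum of the unit vectors N−C(prev) and N−O(prev); prolines and chain-start
residues do not donate. The hydrogen-bond energy is
`0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol, floored at −9.9
(any pairwise distance under 0.5 Å is a clash), with bonds below −0.5;
each donor keeps its two lowest-energy acceptors. Donor/acceptor pairs are
pre-filtered at 9 Å Cα separation.

n-turns (n = 3, 4, 5) require the bond CO(i)→NH(i+n); helices require two
consecutive n-turns. Bridges follow the parallel/antiparallel two-bond
patterns; consecutive bridges form ladders, ladders joined across a β-bulge
(gap ≤ 1 residue on one strand and ≤ 4 on the other) merge, residues of
multi-bridge ladders code E and isolated bridges B. Priority is
H > E > B > G > I > T > S, with π-helices below α as in modern assignments.
Chain breaks — numbering gaps, missing backbone atoms, or a peptide C–N
distance beyond 2.5 Å — terminate all patterns; residues with incomplete
backbone are coded C and flagged, and still count in region denominators
only when assignable.

Against mdtraj's assignment (an independent implementation) the synthetic
library agrees at ≈ 98% per residue; the remaining differences sit at
ladder edges, where this implementation assigns E to a terminal bridge
residue that the reference starts one residue later. The region β-sheet
fraction counts code E only over assignable window residues; isolated
bridges (B) can be included by flag, which matters only for edge cases.

## Replica statistics

Analysis windows are inclusive on both endpoints, and times are read from
frame metadata, never inferred. The per-state estimate is the mean of
per-replica windowed means; its uncertainty is the sample standard deviation
of the replica means divided by √R. With five replicas this standard error
is itself noisy (4 degrees of freedom), which is why the recovery tests
check seed-averaged unbiasedness and nominal per-seed coverage rather than
demanding ±3 SE in every seed.

Distributions default to a Gaussian kernel density with Silverman bandwidth
(the smooth-curve presentation of per-replica distributions); an explicit
bin-width histogram mode exists, and a degenerate constant series yields a
delta-like density with a warning. Per-state average curves are pointwise
means of per-replica densities on a common grid.

Superposition is the Kabsch optimum (proper rotation, det +1) via SVD;
RMSF uses the time-average structure after one superposition pass (frames
aligned to the first frame, averaged, re-aligned to the average once) —
deterministic, standard, and documented rather than iterated to
convergence.

The replica-level comparison of two states is an upper-tail hypergeometric
enrichment: N = all replicas of both states, K = replicas whose windowed
mean satisfies the threshold predicate, n = replicas of the focal state,
k = focal successes, p = P(X ≥ k). With five replicas per state this
framing reproduces the characteristic p = 1/252 ≈ 0.004 when all five focal
replicas and no others satisfy the predicate. A predicate satisfied by no
replica returns p = 1 with a warning. The implementation is
`scipy.stats.hypergeom`; an exhaustive draw-enumeration oracle fixes the
definition in the tests for every N ≤ 12.

## Docking-pose contacts

Residue–residue distance is the minimum over heavy-atom pairs (hydrogens
and solvent excluded, OXT included). A pose contacts the lateral gate when
any peptide residue is within the cutoff (default 0.3 nm) of **either**
gate window — cTM2 (I91–T98) or nTM7 (T291–A298); poses occupying the
inter-helix volume approach one flank first, so the OR reading is the
default and an AND mode is a flag. Pose–pose RMSD is computed without
re-superposition because poses docked into a rigid receptor grid share its
frame; a superposed mode exists for completeness. Group enrichment reuses
the same hypergeometric routine at pose level (one source of truth).

## Synthetic test bed

The generators produce every input class with ground truth computed by
direct enumeration from the generated coordinates (plain array arithmetic),
never through the measurement code they test.

*Peptides* are poly-alanine backbones (N, Cα, C, O) built from internal
coordinates (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å,
standard angles, ω = 180°): α-helices at φ = −57°, ψ = −47°, strands at
φ = −139°, ψ = 135°. Helices are oriented on their exact screw axis
(computed from cross products of successive bond-difference vectors, which
are purely transverse). The centroid of the terminal-turn Cα atoms sits
slightly off-axis, so the endpoint-based axis of a short helix deviates
from the screw axis by up to ~1°; helix lengths with (n−4) a multiple of 18
residues make the two turn phases cancel exactly, and the bundle fixtures
use n = 22.

*Sheets* are built by rigidly registering a partner strand against a target
window, minimising the deviation of the alternating N···O pair distances
from 2.9 Å (Nelder–Mead over the six rigid degrees of freedom from a
deterministic multi-start). In the partial-sheet fixture the 13-residue
window is extended throughout and a 7-residue partner is registered against
residues 203–209; the C-terminal paired residue loses its edge bridge, so
exactly 6 of 13 window residues are assigned E — the sheet content the
lumenal interaction site shows in the partner-bound channel, with the idle
analogue an unpaired (all-helical) window at 0 of 13.

*Descriptor series* are Ornstein–Uhlenbeck processes — the minimal
autocorrelated stationary model consistent with windowed-mean analysis —
with exact discretisation. Defaults encode the study conditions of the
pore-ring diagonal: five replicas per state, means 1.89 nm (partner-bound)
and 1.71 nm (free) separated by 2σ (σ = 0.09 nm), relaxation time 1 ns,
501 frames at 0.1 ns covering a 50 ns analysis window. What the OU bed does
*not* emulate: non-stationarity and slow drift of real trajectories,
state-switching within a replica, and between-replica heterogeneity beyond
sampling noise — so passing recovery tests demonstrates correctness of the
statistics, not adequacy of 50 ns windows for real dynamics.

*Pose sets* place helical peptides at an exact minimum heavy-atom distance
from the gate windows (bisection along a ray from a randomly chosen gate
atom): contacting poses in [0.2, 0.3] nm, the rest beyond 0.5 nm, with the
achieved distance verified at construction. Pose order is shuffled
deterministically. Poses may clip the receptor elsewhere — only the gate
distance is controlled, which is all the contact statistic reads.

## Problem sizes

The test suite and the acceptance script run on: four-helix bundles of
22-residue helices (~350 atoms), 13+7-residue sheet fixtures, OU ensembles
of 10 × 501 frames (100 seeds for the detection-rate experiment), pose sets
of 30 poses per substrate (180 poses for the six-substrate enrichment), and
a ≥ 20-structure secondary-structure comparison library. These sizes keep
every quantity deterministic and exact while exercising the same code paths
as full-size structures.

## Known limitations

- Tilt angles require membrane-oriented input; no internal membrane
  detection is attempted.
- The `θ_cTM4nTM1` default convention awaits calibration against the three
  deposited channel states (the acceptance test performs it once the
  entries are fetched).
- DSSP solvent accessibility is not computed; sheet-edge assignment differs
  from the reference implementation at single terminal bridge residues.
- mmCIF is read only via pre-conversion in the fetch script; the analysis
  layer consumes PDB.
- No channel-lumen radius profiling along the pore axis; the pore-ring
  radius is a single planar fit.
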