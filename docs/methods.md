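# Methods

This note documents the models implemented in `allokit`, the parameter
choices that matter, what the synthetic test structures do and do not
emulate, and the numerical conventions.

## Residue interaction graph and local closeness

The RIG connects two residues whenever any pair of their atoms lies
within the sum of elemental van der Waals radii (C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80, H 1.20 Å; 1.70 Å for anything else) plus a tolerance
(default 0.5 Å).  Hydrogens participate when present; most crystal
structures lack them, and the same rule on heavy atoms alone gives a
slightly sparser but structurally equivalent graph.

Local closeness of degree m is the truncated harmonic centrality
LC_m(i) = Σ_{k≤m} n_k/k, computed by breadth-first search cut at depth
m.  It reduces to the node degree at m = 1 and is monotone in m.  The
default m = 4 limits contributions to residues within roughly 30–40 Å —
the scale of a single domain; smaller m focuses the measure on small
surface cavities.  Unreachable nodes simply contribute nothing.

## Elastic network and normal modes

The dynamics model is the Cα anisotropic network model: uniform springs
(γ = 1, arbitrary units) connect Cα pairs within a cutoff (default
12.0 Å, standard ANM practice).  An anisotropic (vector) model is
required because binding leverage needs the projection of per-residue
displacements onto inter-residue directions; a Gaussian network would
only give magnitudes.  The Hessian is assembled from per-contact 3×3
blocks −γ·r̂r̂ᵀ and diagonalized with a subset eigensolver.  Rigid-body
modes are identified by eigenvalue < 1e−8 × the Gershgorin upper bound
of the spectrum (the subset solver does not produce the true maximum
eigenvalue; the Gershgorin bound is within a factor of two, which is
ample for a 10⁸ separation).  A connected, non-degenerate network must
yield exactly six; any other count raises an error rather than silently
misassigning modes.  The network must form a single connected component
— with several components, rigid-body and internal motions mix.

Retained eigenvectors are unit-norm; their sign is fixed (first
appreciable component positive) purely for reproducible serialization —
every downstream quantity is sign-invariant.  Degenerate eigenvalues
mean individual eigenvectors are arbitrary within the subspace; tests
therefore compare invariant subspaces, not vectors.

## Binding leverage

Springs are selected by the 3.5 Å segment rule: Cα pair (i, j) gets a
spring iff the finite segment between the two Cα passes within 3.5 Å of
at least one ligand/probe atom.  The finite segment (rather than the
infinite line) is deliberate: an infinite line would select pairs on the
far side of the protein, contradicting the locality of binding-site
deformation.  The O(N²·P) pair scan is bounded by a conservative
pair-level prefilter based on the ellipse inequality
dist(p, segment AB) ≥ (|pA| + |pB| − |AB|)/2: a pair is discarded only
when it provably cannot come within the shell, so the prefilter never
changes the selected set (property-tested against an unfiltered scan).

ΔU_μ uses the linearized spring-length change
Δd_ij = (u_i − u_j)·(r_i − r_j)/d_ij on unit-norm eigenvectors with
κ = 1.  Both κ and the mode amplitude are arbitrary scale factors, so
all leverage values are relative (dimensionless); only comparisons and
rankings are meaningful.  The linearization is validated against a
finite-difference oracle (exact spring energies of explicitly displaced
coordinates, ratio → 1 as ε → 0).

### Monte Carlo probe docking

Candidate sites are found by docking a peptide-like probe of 2–6 beads
(3.8 Å spacing, initialized as a 120° zigzag — a straight chain would
make every torsion axis pass through all beads and freeze the internal
degree of freedom).  Per step one move is drawn uniformly from rigid
translation (Gaussian, σ 0.5 Å), rigid rotation (≤ 10°), and a single
torsion rotation (≤ 20°) about a random virtual bond.  The energy
rewards burial and penalizes clashes: −1 per protein heavy atom within
4.5–7.5 Å of a bead, +10 per atom within 4.5 Å; ligand atoms already in
the structure are invisible to the probe.  Acceptance is Metropolis with
temperature annealed linearly from 2 to 0.2 over the run (default 10
runs × 10,000 steps); each run returns its lowest-energy pose, and
identical seeds give bit-identical results.

A practical property of this configuration, established empirically on
the synthetic fixtures: once a probe engages a surface spot worth more
than a few tens of energy units, escape barriers dwarf the temperature
range, so each run acts as a local optimizer of the basin it first
lands in.  Per-run recall of a cavity therefore measures the cavity's
capture cross-section, not only its energetic depth.  This is the
documented reason the pocket fixture (below) is shaped to make its
cavity both the energetic optimum and the dominant capture target, and
it bounds what per-run recall can reach on any compact structure.

Docked poses are greedily clustered by bead-centroid distance (< 5 Å,
seeded in order of increasing energy); each cluster representative
induces a site from residues within 4.5 Å of its beads — the same
contact shell used for ligand-derived sites — and sites are ranked by
total leverage.

## Leverage coupling

Each site's per-mode leverage vector divides ΔU_μ by the number of
elements of the spring set (the size normalization; a per-residue
alternative is selectable with `norm="residues"`).  D_PQ is the plain
dot product of leverage vectors; since every component is non-negative,
D is non-negative and grows monotonically with the mode set.

C_PQ is realized as the cosine of the two leverage vectors — the unique
standard normalization of a dot product that guarantees [0, 1] for
non-negative vectors.  Numerically, the diagonal is set to exactly 1
where D_PP > 0 and off-diagonal entries are clipped into [0, 1] after
verifying no entry exceeds 1 by more than 1e−9 (pure floating-point
rounding; a larger excess raises).  Sites with an empty spring set get a
zero vector, zero rows in C, and are flagged.

The background (BG) pseudo-site collects all residues not in any
annotated site; its probe atoms follow the same pseudo-ligand rule as
user-defined sites (side-chain heavy atoms; Cα for glycine), so the
3.5 Å spring rule applies uniformly to ligand, user, docked and
background sites.  Display scaling divides by the maximal off-diagonal
entry; optional background subtraction removes the mean of the two
sites' BG couplings and clamps at zero (the subtraction arithmetic is a
package convention — only the existence of the control is inherent to
the method).

## Synthetic structures

All fixtures are poly-alanine chains (every 7th residue glycine, to
exercise the Cα fallback of the pseudo-ligand rule) built from a Cα
path with idealized local backbone geometry, and are deterministic
functions of their parameters and seed.

* **hinge_dimer** — two jittered cubic-lattice clusters (3.8 Å spacing)
  joined by a linker across a 13.2 Å cleft.  The cleft width is chosen
  so cluster faces exceed the 12 Å ENM cutoff (no direct inter-cluster
  springs — the hinge stays soft) while every linker residue anchors to
  both clusters.  The anchoring matters: a point node tethered to a
  rigid body contributes at most three independent constraints no
  matter how many springs reach it, and linkers whose nodes see only
  one cluster leave an exact internal mechanism (a spurious seventh
  zero mode).  For the same reason linkers shorter than three residues
  are rejected.
* **pocket_cluster** — a ring-stack cage: three stacked 12-residue
  rings whose common axis encloses an open bore of ~5 Å free radius.
  The bore is the docking target: wide enough for the probe, narrow
  enough to reward it from all sides, and reachable from both ends.
  The deliberately minimal outer wall reflects the capture-limited
  docking dynamics described above — on large convex bodies the probe
  freezes on the surface before ever sampling a cavity.  The
  depth-zero control is a solid convex lattice ball.
* **ideal_helix** — textbook α-helix (rise 1.5 Å, 100°/residue, radius
  2.3 Å); used for backbone-contact assertions.
* **random_cluster** — featureless jittered-lattice ball; the null
  model and the workhorse of the randomized coupling-bound survey.

What the fixtures do not emulate: real packing density and side-chain
chemistry, secondary-structure topology, crystallographic artifacts
(altlocs, missing atoms beyond what the parser handles), and realistic
energy scales.  Passing tests demonstrate the algorithms' contracts —
graph/mode/energy mathematics, determinism, and mechanistic
discrimination on idealized geometry — not predictive performance on
real proteins.

## Numerical conventions and edge cases

* Residue identity is (chain, sequence number, insertion code);
  numbering follows the input file verbatim.
* PDB parsing takes the first MODEL; alternate locations resolve to the
  highest-occupancy conformer (ties: first encountered); elements are
  inferred from atom names when the element column is blank.  HETATM
  groups on the solvent/ion exclusion list (HOH, DOD, NA, K, CL, MG,
  ZN, CA, SO4, PO4, GOL, EDO by default) are dropped; the rest become
  ligand groups.
* Ligand-derived sites use a 4.5 Å heavy-atom contact shell; user
  sphere sites default to 6.0 Å around the chosen residue.
* All output writers are deterministic (fixed float formats, sorted
  JSON keys, no timestamps); pipeline reruns with the same seed are
  byte-identical.
* Problem sizes in the validation sweep (1,000 structures × 40 residues
  × 10 modes) were chosen so the full survey completes in well under a
  minute while sampling thousands of site pairs.

## Known limitations

* The coarse docking energy has no chemistry (no electrostatics,
  solvation or side-chain flexibility); it finds geometrically buried
  probe positions only, and its per-run recall of a given cavity is
  capture-limited (see above).
* Leverage values are relative; comparing absolute numbers between
  different structures (or cutoffs) is meaningless.
* On structures with several near-degenerate soft modes, a small mode
  set can underrepresent communication; raise `n_modes` and check that
  rankings are stable.
* Very large background sites are computed exactly but can dominate the
  display normalization; use background subtraction when reading the
  matrices.
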