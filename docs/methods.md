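# Methods

This note documents the models, parameter choices and numerical decisions
behind `pathweaver`, and what the synthetic test fixtures do and do not
establish about behaviour on real proteins.

## Representation and kinematics

Proteins are reduced to backbone heavy atoms (N, CA, C, O) plus C&beta;
(absent in glycine).  Carbonyl oxygens are retained beyond the minimal
backbone because both the hydrogen-bond energy term and the rigidity
analysis's hydrogen-bond detection need them.  Residue indices are 0-based
internally; PDB numbers and insertion codes are preserved for reporting.
Coordinates are in Å and torsions in degrees throughout.

The sampling degrees of freedom are &phi;/&psi;.  A torsion change rotates
every atom C-terminal to the bond rigidly about the bond axis, so the
N-terminus is the fixed laboratory frame; this start-anchored convention is
standard in torsion-space samplers.  Chemically, a &phi; rotation carries
the residue's own C, O and C&beta; plus all downstream residues, while a
&psi; rotation carries only the carbonyl O plus downstream residues
(C&beta; sits on the nitrogen side of the CA–C bond).  Chain breaks
(C–N distance > 1.8 Å) act as rotation barriers: propagation stops there
and the gap-adjacent torsions are undefined, so disconnected segments are
never torn.

lRMSD is computed over CA atoms of *paired* residues after optimal
superposition (Kabsch, proper rotations only).  CA-only lRMSD is the common
convention for comparing conformations of the same protein; the tolerance
used when comparing against published initial distances (±0.3 Å) absorbs
the difference to backbone or all-atom conventions.  Residue pairing
prefers identical PDB numbering where the residue names agree (mismatched
names, e.g. point mutations, are excluded); when numbering is unreliable it
falls back to the longest common ungapped sequence block.  How two crystal
constructs of the same protein should be aligned is genuinely
under-determined; this rule is the package's own choice.

## Energy model

The potential is a sum of six components,

```
E_total = E_HB + E_burial + E_water + E_bond + E_angle + E_VdW ,
```

whose only consumer is the acceptance gate `E_total < k · n_residues`
(`k = 5`, strict).  Units are nominal kcal/mol; absolute calibration is
irrelevant, finiteness and clash sensitivity are what matter.

* **Bond/angle**: harmonic, `k_b = 300 kcal/mol/Å²`, `k_θ = 80 kcal/mol/rad²`,
  with equilibrium values taken from one ideal-geometry table shared with
  the synthetic peptide builder — a freshly built fixture therefore has
  exactly zero bonded strain, which the tests exploit.
* **Van der Waals**: 12-6 Lennard-Jones over pairs at least 3 bonds apart,
  8 Å cutoff, Lorentz–Berthelot mixing over the five atom classes.  The
  repulsion is *clamped* to its value at `0.8·σ` below that distance
  ("soft collisions"): energy stays finite for any input, including exactly
  overlapping atoms, at the cost of a zero gradient inside the clamp.
  Pairs exactly 3 bonds apart (1-4 pairs) use scaled parameters
  (σ×0.75, ε×0.5), the usual force-field device: several 1-4 contacts
  (e.g. the intra-residue O–C&beta; pair at 2.71 Å) are fixed by bonded
  geometry and would otherwise contribute a large constant penalty that
  drowns the conformational signal.
* **Hydrogen bond**: −1 kcal/mol per backbone O(i)···N(j) pair with
  |i−j| ≥ 3, distance in [2.6, 3.5] Å and CA–O···N angle > 90° (a square
  well; no orientation-dependent strength).
* **Burial**: per residue, −0.5 · w · sigmoid((c − 6)/2) where c counts
  C&beta; neighbours within 8 Å and w is the Kyte–Doolittle hydropathy
  rescaled to [0, 1]; buried hydrophobics are rewarded.
* **Water-mediated**: −0.05 kcal/mol per C&beta; pair in the 6.5–9.5 Å
  shell, a minimal second-solvation-shell attraction.

The hydrogen-bond, burial and water terms are deliberately simple
knowledge-based forms behind one frozen dataclass (`EnergyParams`,
YAML-loadable), so a more detailed potential can be substituted without
touching the search.  The search only requires a finite, rotation-invariant,
clash-penalising score with these components.

**Relaxation** is plain steepest descent on `E_bond + E_angle + E_VdW`
only — the cheap, local terms — with analytic gradients: at most 10 accepted
steps of 0.01 Å along the normalised negative gradient, halving a rejected
step up to 5 times and stopping at the first fully rejected step.  One
Verlet-style neighbour list with a safety margin serves the whole
relaxation, since total displacement is bounded by 0.1 Å.  The step-size
rule and the exclusion of the non-bonded knowledge terms keep the move
local: relaxation resolves clashes, it does not re-fold.

## Rigidity analysis

The constraint network places each atom as a 6-DOF rigid body: rotatable
covalent bonds (N–CA, CA–C, CA–C&beta;) contribute 5 bars, the
partial-double peptide bond and C=O 6 bars, geometrically detected hydrogen
bonds (same criteria as the energy term's well, detection cutoff 3.5 Å) 5
bars, and C&beta;–C&beta; contacts < 6 Å between hydrophobic residues
(|i−j| ≥ 2) 2 bars.  The (6,6) body-bar pebble game then identifies
independent constraints; two bodies are mutually rigid when a seventh
pebble can no longer be gathered on the pair, and since mutual rigidity is
an equivalence whose classes are graph-connected, testing the pairs that
share an edge suffices for the full cluster decomposition.  The
implementation is validated exhaustively against a generic rigidity-matrix
rank oracle on small multigraphs.

Clusters below `min_cluster_atoms` (default 6, configurable 6–8) are
disregarded as noise, and a residue is *flexible* iff at least one of its
atoms lies outside every retained cluster.  Because the analysis runs on
the same coarse model as the search — no hydrogens, no side chains beyond
C&beta; — it reproduces the qualitative hinge-versus-domain decomposition,
not any all-atom tool's exact flexible set.  A terminal C&beta; kept by a
5-bar bond formally retains a spin DOF and joins a cluster only through
hydrophobic contacts; in practice helical and packed cores recruit their
C&beta;s this way (in an ideal helix the i,i+3 C&beta; distance is 5.78 Å),
while exposed loops stay flexible.  A user-supplied flexible-residue list
(one PDB number per line) bypasses the analysis entirely, e.g. to inject
output of an external all-atom rigidity service.

## Search

Cost follows the A\*-style form `cost(n) = g(n) + h(n)` with
`h(n) = lRMSD(n, goal)` and the accumulated cost defined by the recurrence
`g(n) = g(parent(n)) + lRMSD(n, start)`.  This literal recurrence counts
distance-to-start at every hop; because it can double-count progress, a
conventional edge-length alternative (`g_mode="edge"`:
`g(parent) + lRMSD(n, parent)`) is provided and covered by the same
consistency tests.  Rewiring reparents a neighbour when routing through the
new node strictly lowers its g, updating the whole subtree; ancestors of
the new node are excluded, so cycles cannot form.

Monte-Carlo acceptance compares the candidate against the *selected* node
(its eventual tree parent may differ — parent choice happens after
acceptance).  Pruning removes pool members redundant under the 10% rule in
increasing-h order but never severs tree edges, so previously extracted
path segments survive; pruning triggers when the pool first reaches
`n_residues` members and thereafter at 3× the previous trigger.

Perturbation draws `m` torsions uniformly from [1, `perturb_max_angles`]
(default `max(2, ⌈0.05·n⌉)`) without replacement from the eligible set and
applies independent uniform steps of at most ±10°.  Both knobs are
configuration values; small moves keep the energy gate passable.
Iterations that produce no accepted node (no eligible angle, gate or MC
rejection) still count toward the 500-iteration stall limit.  In adaptive
mode, rigidity is recomputed when the *best* node (the pool's h-minimum)
has drifted more than 2 Å (strict) since the last analysis; the trigger
conformation is a design choice, as is resolving the goal threshold, when
not given, to `0.25 × initial lRMSD` clamped into [1.7, 3.65] Å.  A failed
energy gate discards the candidate outright (the stricter of the two
plausible readings of the acceptance rule; the Monte-Carlo step applies
only to the lRMSD score).

A single seeded NumPy generator drives every stochastic choice, so runs
are bit-reproducible given the configuration; the seed is echoed in the
result.

## Synthetic fixtures

The peptide builder places atoms sequentially from internal coordinates
(NeRF), realising requested torsions to 1e-6° with ideal bond geometry and
L-chirality (improper C–N–CA–C&beta; = −122.6°), ω fixed at 180°.
Transition pairs offset hinge torsions only, so ground-truth flexibility is
known by construction and goal conformations are exactly reachable by
hinge moves — the closure test of the whole kinematics stack.

The 20-residue two-domain benchmark toy (two hydrophobic helices joined by
a 3-glycine extended hinge) emulates what separates two crystal forms of a
real protein: large hinge rotations (+90°/−70°/+50° spread over the hinge,
initial lRMSD ≈ 2.1 Å) superimposed on small "decoy" torsion differences on
the domains.  Decoys are crankshaft-compensated (+δ on ψ(i), −δ on
φ(i+1), 5.5–9°) so they stay above the 5° eligibility cutoff — an unguided
search will spend moves on them — while deforming only locally, leaving the
hinge-only reachable floor near 0.2 Å.  On this fixture rigidity-guided
runs converge in a ~3–4× smaller median number of iterations than unguided
runs (10 seeds, threshold 0.6 Å), reproducing the qualitative benefit of
guidance.  What these fixtures do *not* establish: behaviour under real
crystallographic noise (missing residues, alternate conformers, non-ideal
geometry), side-chain packing effects (absent by construction), and
convergence on proteins hundreds of residues long, where the same
algorithm runs with the published thresholds (1.7–3.65 Å) but wall-clock
cost grows with both chain length and pool size.  The published-pair
comparisons in `pathweaver.benchmarks` cover that regime when the PDB
entries are available.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on the 8-residue
hinge fixture and the 20-residue two-domain toy (5–10 seeds per
comparison, iteration caps 3000–5000); the pebble-game/rank-oracle
equivalence is exercised exhaustively on 3-body multigraphs and on random
graphs of up to 6 bodies, sizes at which the dense rank oracle is exact.

## Known limitations

* The energy model has no electrostatics, torsional potentials or
  side-chain packing; the gate is a plausibility filter, not a free-energy
  surface, and extracted paths are geometric, not kinetic.
* The LJ clamp zeroes the repulsive gradient below 0.8σ, so steepest
  descent cannot push apart atoms that start deeply overlapped (the gate
  rejects such conformations instead).
* Rigidity on the coarse model under-constrains side-chain-mediated
  stiffness; polar surface residues of rigid domains may be reported
  flexible.
* The pairing rule can mis-pair structures whose numbering overlaps
  accidentally but disagrees biologically; supplying structures with
  consistent numbering avoids this.
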