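# Methods

This note documents the models and conventions the package implements,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the known limitations.

## Data model and geometry

Coordinates are in Å, times in ns, charges in elementary units, energies
in kcal/mol. Atoms partition into molecules: one protein chain
(chain-ID/TER-delimited) is one molecule; non-protein residues are
molecules, merged by CONECT records when bonded records span residues.
Species labels (`protein_chain`, `water`, `cation`, `anion`, `polyamine`,
`other`) come from residue names through a user-extensible map.

Periodic cells are general triclinic, built from CRYST1 lengths/angles;
the truncated octahedron common in solvated simulations is just a special
triclinic cell here, so one code path covers all geometries. Minimum-image
displacements use fractional rounding, refined by an exhaustive 27-image
search for skewed cells. Rounding alone is exact for orthorhombic cells;
the 27-cell search is sufficient whenever the distance of interest is
below half the minimal box height, which every cutoff-taking routine
enforces as a precondition and rejects otherwise.

Bond records come from CONECT plus a covalent-radius heuristic inside
each residue: a hydrogen bonds to its nearest heavy atom within 1.2 Å,
heavy–heavy pairs bond within 1.9 Å. Donors are N/O/S heavy atoms with at
least one bonded hydrogen; acceptors are all N/O/S heavy atoms. Bare
phosphate oxygens are therefore acceptors and never donors; bare metal
cations (no N/O/S, no H) take part in neither role — the package detects
hydrogen-bond-mediated bridging only, and does not implement a
distance-only ion-contact criterion.

## Hydrogen bonds and bridging events

A hydrogen bond is donor–acceptor heavy-atom distance ≤ 3.0 Å (default)
with the donor–H–acceptor angle, measured **at the hydrogen**, ≥ 135°
(default). Intramolecular pairs are excluded by default. Neighbor search
uses a periodic cell list for orthorhombic boxes when the pair count is
large, and a vectorized all-pairs pass otherwise; both paths are proven
equivalent to a brute-force double loop in the test suite.

A candidate molecule *bridges* in a frame when its hydrogen bonds reach
two or more distinct protein chains; bridging three or more chains still
counts once (the predicate is per molecule, not per chain pair). Events
are maximal uninterrupted runs of bridging frames per molecule, with zero
gap tolerance: one non-bridging frame ends the event. Event identity is
the molecule alone — the bridged chain pair may change mid-event without
splitting it. Lifetime = run length × frame spacing, so occupancy in
frames {511, 600, 650, 651, 700, 701, 702, 703} at 0.1 ns yields four
events of 0.1, 0.1, 0.2 and 0.4 ns. Conservation law (tested): the sum of
lifetimes divided by the frame spacing equals the number of
(molecule, frame) bridging incidences.

Lifetime distributions are densities per unit log10-duration over
log-spaced bins (default 5 per decade), normalized to integrate to one —
the natural representation for residence times spanning several decades.

## Radial distribution functions

g(r) for bin [r, r+Δ) is the per-frame, per-reference-atom mean count of
partner atoms at minimum-image distance in the bin divided by
ρ_B·V_shell, V_shell = (4π/3)((r+Δ)³−r³). ρ_B uses the instantaneous box
volume averaged over frames (constant-pressure cells fluctuate).
Intramolecular pairs are excluded. Defaults: bin width 0.1 Å; r_max
0.45 × minimal box height. Note a finite excluded volume (e.g. the
protein itself) makes the bulk plateau sit slightly above 1 at
V/(V−V_excl), since the normalization uses the full box volume; this is
visible and exactly predictable on the synthetic depleted fixture.

Block analysis splits the trajectory into equal contiguous frame blocks
(default 4; a remainder goes to the last block) and reports pairwise
max-abs and RMS curve differences. The convergence flag compares the last
two blocks against a user tolerance; bins below an optional `r_min` can
be ignored because tiny shell volumes make small-r bins pure counting
noise.

## Diffusion

Molecule center-of-geometry paths are unwrapped by accumulating, per
consecutive frame pair, the lattice translation minimizing the jump;
jumps of half the box height or more are ambiguous and raise (centers of
geometry, not mass — masses are not part of the data model and the
difference is negligible for small molecules). MSD averages over
molecules and multiple time origins (default stride 10 frames; a stride
equal to the trajectory length reproduces single-origin estimates), for
lags up to half the trajectory.

D = slope/6 with 1 Å²/ns = 1e-7 cm²/s, reported with the fit standard
error so unreliable estimates (few molecules, confined species) are
visibly unreliable rather than silently precise. The default fit window
is **5–25% of the maximum lag**: below ~5% the MSD reflects short-time
noise, and beyond ~25% each molecule contributes only a handful of
independent displacement intervals, so the per-lag variance grows roughly
linearly with lag and the fitted slope becomes several times noisier. At
the package's reference recovery conditions (100 walkers × 2000 frames,
D = 1e-5 cm²/s) this window recovers D with ≈3% standard deviation across
seeds, versus ≈5.5% for a 10–50% window; the window is a parameter for
users who prefer other conventions. Negative fitted slopes are reported
as fitted, with a warning.

## Interaction enthalpy

The receptor–ligand interaction enthalpy proxy is the gas-phase MM cross
term (Coulomb + Lennard-Jones) summed pairwise over minimum-image
distances with no cutoff — appropriate at desk scale. Conventions are
Amber-compatible: Coulomb constant 332.0636 kcal·Å/(mol·e²),
Lorentz–Berthelot combination (arithmetic σ, geometric ε). No 1–4 scaling
arises because receptor and ligand are disjoint molecules. An optional
distance-dependent dielectric ε(r) = r provides crude solvent screening.

**Deliberately not implemented:** generalized-Born polar solvation,
nonpolar SASA terms, and entropy estimates. Those are what a full
end-point free-energy workflow adds; re-implementing a GB model is a
project of its own, and the sign/trend questions this package targets
(does a polycation bind a phosphoprotein favorably, which residues
contribute) are answered by the MM term with optional screening on the
systems the package handles. Absolute binding free energies are out of
scope, and computed magnitudes should not be compared against
solvation-corrected literature values.

Per-residue decomposition assigns half of every pair energy to each
partner's residue, every frame, then averages over frames; the residue
sum therefore reproduces the mean total exactly (tested to 1e-8 kcal/mol,
with the pair energies themselves verified against an independent double
loop to 1e-10 relative). Negative contributions are favorable.

## Composition arithmetic

Side-chain charges at pH 7: Lys/Arg +1, Glu/Asp −1. Phosphosites
contribute −2 by default (fully deprotonated; configurable to −1).
Termini are treated as jointly neutral. With 21 Lys, 1 Arg, 7 Glu, 3 Asp
and 17 phosphosites this gives +12 unmodified and −22 phosphorylated per
chain; eight such chains are exactly neutralized by 44 tetravalent
polyamines. Concentrations are n/(V·N_A) with V in Å³, reported in mM:
8 copies in 1.6×10⁶ Å³ ≈ 8.3 mM, 44 copies ≈ 45.7 mM.

## Synthetic generators: what they emulate, what they do not

The generators produce kinematic constructions, not dynamics — their
value is that the ground truth is exact:

- **Bridge scenarios** realize a frame schedule as geometry: rigid
  pseudo-peptide chains carry acceptor-only carbonyl sites 5.6 Å apart;
  a scheduled molecule sits midway with both hydrogens aimed at the two
  acceptors (D···A = 2.8 Å, angle ≈172° from a 5° tilt), and parks ≥6 Å
  away otherwise. Decoys never approach. What this does not emulate:
  marginal geometries near the cutoffs, competing intra-protein hydrogen
  bonds, and thermal jitter — passing tests show the counting and
  segmentation machinery is exact, not that the cutoffs themselves are
  well-chosen for any particular force field.
- **Pair structures** give closed-form RDF answers: uniform gas (g ≡ 1),
  a delta shell at r₀ (peak = V/V_shell in the peak bin), depletion
  spheres (g = 0 inside, V/(V−V_excl) outside), and a drifting shell as
  planted non-stationarity for the convergence flag.
- **Brownian walkers** with per-axis step variance 2 D Δt test D
  recovery and unwrapping (wrapped and unwrapped paths are both kept);
  a two-population variant (free walkers vs. site-tethered jitter)
  plants a ≥10× mobility contrast. Real cosolute diffusion is neither
  memoryless at 0.1 ns nor homogeneous; the tests certify the estimator,
  not any physical system.
- **Charged systems** store double-loop reference energies computed with
  independently coded minimum-image search, so the vectorized energy
  path is checked against a genuinely separate implementation.

Generators draw all randomness from one explicit seed and regenerate
byte-identical files (hash-tested). Simulation sizes throughout the test
suite (e.g. 100 walkers × 2000 frames, 400 partners × ≤1000 frames,
≤40 waters × 100 random systems plus one 500-water system) were chosen
as the smallest sizes at which the statistical assertions have
comfortable margins.

## Numerical choices

- PDB coordinates round-trip at the format's 1e-3 Å precision; fixtures
  are compared at that tolerance.
- The half-box cutoff guard uses a 1e-9 Å tolerance so an exactly-half
  cutoff is rejected despite floating-point noise in cell volumes.
- RDF bins are half-open [r, r+Δ); lifetime bins are log-spaced and
  half-open; block splitting gives the remainder to the last block.
- Energy routines treat missing LJ parameters as zero contribution but
  refuse to run with missing charges (error lists the offending atoms).
- Degenerate inputs raise early with specific messages: empty
  selections, empty candidate species, empty event lists, atom-count
  mismatches (naming the model), malformed PDB lines (naming the line).

## Limitations

- Hydrogen-bond detection is purely geometric; energetic definitions and
  salt-bridge-specific criteria are not provided.
- Bridging events are not resolved by chain pair (a possible extension);
  no gap tolerance is offered.
- The energy module's magnitudes are gas-phase MM values; see above.
- No binary trajectory formats (NetCDF/DCD/XTC); the package
  standardizes on multi-MODEL PDB plus a plain-text parameter sidecar,
  which keeps fixtures inspectable and diffable.
- Protonation states, pKa shifts and ionic-strength activity corrections
  are out of scope; composition arithmetic is formal-charge bookkeeping.
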