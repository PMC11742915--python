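# Methods

This note documents the models and numerical conventions behind each
analysis, the choices made where more than one convention is defensible,
and what the synthetic fixtures do and do not establish about real data.

## Structures, selections, units

Structures are parsed with gemmi (PDB and mmCIF) and flattened to an
ordered atom list. Author residue numbering is authoritative everywhere
(Ala46, Tyr82 are author numbers); no renumbering is ever applied, and
insertion codes are part of residue identity. Alternate locations keep
the highest-occupancy conformer, ties resolved towards altloc `A`.
Hydrogens are retained on parsing but excluded from surface and contact
computations by default, since cryoEM depositions carry none. Coordinates
are Å throughout, masses in Daltons.

Van der Waals radii come from a bundled Bondi-style element table
(`complexlens._radii`), overridable per element at parse time. An atom
whose element cannot be resolved, or has no radius, is a parse error
naming the atom rather than a silent default.

Selections are declarative (a small string grammar or a dict) and resolve
deterministically to strictly increasing atom-index tuples. The Cα filter
matches atoms named `CA` in amino-acid residues only, so calcium ions can
never leak into a backbone selection. A filter (ions, waters) may match
nothing; naming a chain the structure lacks is an error.

## Solvent-accessible and buried surface area

SASA follows Shrake–Rupley: each atom's surface is the sphere of radius
r_vdw + r_probe (probe 1.4 Å), sampled at `sphere_points` quasi-uniform
points, and a point is buried when inside any neighbour's extended
sphere. The point set is a deterministic Fibonacci (golden-spiral)
lattice, so results are exactly reproducible with no seed. The default of
960 points resolves one part in 960 of each extended sphere (~0.1% of its
full area); analyses of very small buried caps (a few Å²) should raise
`sphere_points` — the test-suite oracles use 5000.

Buried surface area of an interface A:B is

    BSA_two-sided = SASA(A alone) + SASA(B alone) − SASA(A ∪ B),

with each term computed with *only* those atoms present: waters, ions and
all other chains are excluded so the number measures the pairwise
interface alone. Both conventions are always reported — the two-sided
total above and the one-sided "interface area" (half of it) that PISA
prints — because published totals rarely state which they use, while
ratios and fold changes are convention-invariant. Per-residue BSA is the
residue's SASA loss; its burial fraction divides that loss by the
residue's SASA in the isolated group (defined as 0 when the residue was
already surface-inaccessible alone). Fold changes between two complexes
divide matched residues' BSA values; a zero denominator is flagged
infinite rather than raised.

Polar contacts are inter-group N/O heavy-atom pairs within 3.5 Å, sorted
by distance, each pair once. No angular term and no donor/acceptor typing
is applied: without hydrogens a geometric distance criterion is the
honest proxy, and both the cutoff and the element set are parameters.
Counts from this criterion are comparable between two structures analysed
the same way, but not necessarily to counts from graphics programs with
different criteria.

## Superposition and geometry angles

Rigid-body superposition is the Kabsch SVD solution over paired atoms
(equal-length ordered selections, ≥ 3 atoms), with the determinant sign
correction so reflections are never returned. The implementation is
cross-checked in the tests against an independent quaternion-method
(Horn) RMSD oracle.

The *static receptor rotation* between two complexes superposes complex B
onto complex A on the shared receptor chain's Cα atoms (pairing by author
residue number over a user-chosen common range). The vertex is the
midpoint of the two post-alignment Cα positions of a user-named vertex
residue (Tyr82 of IL10Rβ, which occupies nearly the same position in both
complexes; the midpoint makes the measure symmetric in its inputs), and
the angle is subtended there by the two Cα positions of a probe residue
on the rotating chain's outermost loop (Ala46). Identical inputs give 0°
by definition.

The *geometry angle* of a single complex is the angle at the ligand's
center of mass between the COM of the IFNλR1 D1 domain and the COM of the
IL10Rβ SD1 domain. COMs are mass-weighted by default (an unweighted
centroid is available for sensitivity checks). Domain residue boundaries
are user configuration, not constants: deposited entries do not fix them.
Over a trajectory the angle is evaluated per frame; the series carries
mean/min/max and a histogram with 1° bins over the observed range, and a
paired helper reports the difference of means between two series.

## Trajectory observables

Frames are (n_frames, n_atoms, 3) arrays against a fixed topology;
multi-model PDB, DCD (Å) and XTC (nm, converted) are read, frame 0 being
the file's first frame.

* **RMSF** is referenced to the *first frame*, not the time mean:
  RMSF_i = sqrt(⟨|r_i(t) − r_i(0)|²⟩ over all frames). By default every
  frame is first superposed onto frame 0 on the analysis selection so
  rigid-body drift does not read as fluctuation (translation-only when
  the selection has fewer than 3 atoms). The default selection is all
  Cα atoms, giving one value per residue.
* **DCC** is the normalised covariance of displacement vectors about each
  atom's trajectory mean, C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩),
  after the same superposition. Computed on Cα by default. A
  zero-variance atom's row and column are set to 0 (diagonal 1) with a
  warning instead of dividing by zero.
* **Contact frequency** scores, per inter-group residue pair, the
  fraction of frames within a 10 Å cutoff, with the distance either the
  minimum heavy-atom distance (default, CPPTRAJ-like) or the residue-COM
  distance. Fractions are monotone in the cutoff by construction.
* **Ion occupancy** counts, per residue, the percentage of frames in
  which *any* selected ion is within 1.0 Å of that residue's per-frame
  center of mass. The 1 Å default is deliberately tight — it flags ions
  sitting essentially on the residue's mass center, which is how anion
  condensation onto the basic Helix E segment is scored — and is a plain
  parameter for sensitivity analysis.

Replicate simulations are handled by concatenating per-replicate series;
no block averaging or frame weighting is applied.

## Sequence metrics

Net charge is the Henderson–Hasselbalch sum over ionizable side chains
(D, E, C, Y, H, K, R) and both termini; it is strictly decreasing in pH,
so the isoelectric point is the unique root, found by bisection on
pH ∈ [0.1, 13.9] to 1e-4. The default pKa table is the EMBOSS set; a
Lehninger-style alternative is bundled, and every output names the table
used, because a pI is only meaningful together with its table (different
published tables shift a basic protein's pI by a pH unit or more).
Pairwise identity is Needleman–Wunsch global alignment through
Biopython's `PairwiseAligner` (BLOSUM62; gap open 10, extend 0.5, both
exposed), with matches divided by the full alignment length including
gapped columns; dividing by the shorter sequence is available, since
published identity percentages rarely state their denominator.

## Synthetic fixtures: what they establish

Each generator is a pure function of its spec (seed included, Philox
counter-based bit generator), returns machine-readable ground truth, and
is what the tests measure against:

* the **two-domain pair** constructs a rotation of exactly θ about an
  axis through the vertex residue's Cα, with the probe Cα perpendicular
  to the axis — so the static-rotation pipeline must return θ;
* the **ternary toy** places pair-symmetric equal-mass clusters so the
  three domain COMs subtend an exact requested angle;
* the **Gaussian trajectory** draws isotropic per-atom displacements with
  requested pairwise correlations imposed by a Cholesky factor applied
  identically to x, y, z; frame 0 is pinned at each atom's mean, giving
  the closed form E[RMSF_i] = σ_i √(3(n−1)/n) and E[DCC] equal to the
  imposed correlation matrix (a non-PSD request is an error);
* the **ion trajectory** places ions exactly on scripted residues' COMs
  in scripted frames (round-robin over the ion pool, sized to the largest
  number of simultaneous contacts) and parks them hundreds of Å away
  otherwise;
* the **sphere interface** yields 2–4 atom complexes whose buried area
  has the closed-form spherical-cap value, with layouts chosen so no
  surface point is buried by two partners at once (the regime where
  pairwise cap addition is exact).

These fixtures verify the estimators and conventions, not the biology:
they contain no side-chain packing, no solvent structure, no force field,
and Gaussian fluctuations are memoryless where real trajectories are
correlated in time. Agreement on them shows the arithmetic and plumbing
are right at the stated tolerances; numbers on deposited structures
additionally depend on the conventions above (probe radius, point count,
contact criterion, one- vs two-sided areas), which is why every report
echoes its parameters.

## Numerical choices and problem sizes

Default lattice 960 points (SASA convergence ≲ 0.5% on totals when
doubled); sphere oracles run at 5000 points. Gaussian RMSF/DCC checks use
5000 frames (statistical error ~1.4% at 5σ tolerance); angle-series
checks use 360–500 frames. The pI grid-scan oracle steps 0.001 pH units.
Angle arccos arguments are clipped to [−1, 1]; a zero-length angle vector
is an error, except that the static rotation returns exactly 0° for
bitwise-identical probe positions. All analysis is single-threaded numpy
/ scipy (cKDTree neighbour searches); a full two-complex comparison of
deposited-size structures (~5000 atoms each) takes on the order of a
minute.

## Known limitations

* No ΔG or solvation-energy estimates; BSA is purely geometric.
* Polar contacts have no angular criterion, so π-stacking or C–H···O
  interactions are invisible and some close N/O pairs counted here would
  fail a strict hydrogen-bond definition.
* The static rotation summarises the receptor reorientation as a single
  angle at a user-chosen vertex; it is not a screw-axis decomposition,
  and its value depends (weakly) on the choice of vertex and probe
  residues.
* Ion occupancy with the literal 1 Å COM cutoff is a conservative lower
  bound on ion association; shell-based definitions with larger radii
  will report higher percentages.
* Sequence charge uses fixed model pKa values; no environment-dependent
  pKa shifting, and no structure-based electrostatics.
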