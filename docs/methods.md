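# Methods

This note documents the models and procedures mdligand implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions that affect results.

## Units and conventions

Coordinates and distances in nm, times in ps, energies in kcal/mol,
charges in elementary charges.  Hydrogen-bond cutoffs, GB radii and SASA
are handled in Å internally (the field's customary units for those
quantities) and converted at the module boundary.  The Coulomb constant is
fixed at 332.0637 kcal·Å·mol⁻¹·e⁻².  Residues are indexed densely from 0
internally; the original structure numbering is kept as a display
attribute so reports print labels such as `PHE9` in author numbering.

## Superposition metrics

**Kabsch superposition.**  The optimal rigid transform minimizing the
least-squares deviation over a fit selection is computed by SVD of the
cross-covariance with the usual determinant correction, so the returned
rotation is always proper.  Fit sets with fewer than three atoms or with a
second singular value numerically zero (collinear) are rejected: for a
collinear fit set the rotation about the line is undefined.

**RMSD** is computed per frame over a measure selection after fitting on a
(possibly different) fit selection — by default both are the protein
backbone (N, CA, C, O).  The reference is the first frame of the supplied
trajectory; when that frame is unequilibrated the series rises from zero
to a plateau, which is exactly how convergence is judged.

**RMSF** is the per-residue root-mean-square fluctuation of the Cα atom
about its time mean after superposing every frame onto the time-mean
structure, with one alignment iteration: frames are first aligned to frame
0, the mean is formed, and all frames are re-aligned to that mean.  The
reference is configurable to "first frame".  The caller is expected to
discard burn-in first; the pipeline does this for every equilibrium
statistic.

*Estimator bias.*  Fitting each frame to the mean removes six rigid-body
degrees of freedom from the displacement field.  For N residues the
removed variance fraction at residue i is approximately
(1 + 3·r_i²/⟨r²⟩)/N, where r_i is the residue's distance from the
geometric centre — i.e. largest at the extremities of an elongated chain
(≈ 4/N at the ends of a straight rod).  Recovery tests therefore use a
200-residue chain, where the worst-case bias (~1%) is small against the
5% verification band; at 20 residues the end bias alone reaches ~7% in
variance.  This is a property of superposed RMSF itself, not of the
implementation.

**Radius of gyration** is mass-weighted by default (element masses),
optionally unweighted.  **SASA** is Shrake–Rupley with a 1.4 Å probe and a
deterministic 960-point golden-spiral sphere lattice; per-atom areas sum
exactly to the total.  A surface point lying exactly on a neighbour sphere
counts as accessible, except against an exactly coincident duplicate atom,
which keeps coincident atoms counted once and makes pair burial monotone
down to zero separation.  Because the lattice is fixed in the laboratory
frame, SASA is rigid-invariant only to quadrature resolution (≲ 0.1% of
the total at 960 points).

**Densities** are normalized histograms (probabilities sum to 1; 100 bins
by default); the reported peak is the modal bin centre.  A series constant
to numerical precision occupies a single bin centred on the value.
H-bond count densities use one bin per integer count.

## Interaction analysis

**Contacts.**  A residue pair (or residue–ligand pair) is in contact in a
frame when the minimum inter-group heavy-atom distance is below the
cutoff; the map entry is the fraction of frames in contact.  Two cutoffs
are carried as separate configuration fields because the two map types use
different conventions: 0.46 nm for residue–residue contacts and 0.54 nm
for residue–ligand binding probability.  Hydrogens are excluded by default
(configurable to all-atom).  Residue–residue maps exclude sequence
neighbours |i−j| ≤ 2 by default to suppress trivial backbone contacts.
Minimum-image distances are used when the trajectory carries an
orthorhombic box.  The vectorized implementation is exact (it reduces the
full distance matrix), and is tested for equality against an explicit
all-pairs double loop.

**Hydrogen bonds.**  Donor/hydrogen/acceptor roles are derived from
elements and geometry: N and O are acceptors; an N or O with a hydrogen
within 1.25 Å covalent range is a donor paired with that hydrogen.  A bond
exists when the donor-heavy to acceptor distance is ≤ 3.5 Å and the
D–H⋯A angle (vertex at the hydrogen) lies in [150°, 180°].  Each passing
triple is reported once per frame.

**Salt bridges** report the per-frame minimum distance between the basic
side-chain nitrogens (NH1/NH2/NE for Arg, NZ for Lys) and the carboxylate
oxygens (OD1/OD2 for Asp, OE1/OE2 for Glu) of a chosen residue pair,
with its density.  Note a formed salt bridge generally also satisfies the
hydrogen-bond criterion through the guanidinium/ammonium protons — the
demo's H-bond count baseline of 1 is exactly this.

**Covariance.**  C_ij = ⟨Δr_i·Δr_j⟩ over Cα displacements (3-D dot
products, one scalar per residue pair) after superposing all frames onto
the mean structure; normalized mode divides by √(C_ii·C_jj), giving a unit
diagonal and entries in [−1, 1].  Residues with variance below a 1e−12
relative floor are flagged undefined rather than propagating NaN.
Superposition can be disabled for pre-aligned frames.  As with RMSF,
alignment absorbs a small part of spatially coherent cluster motion, so
recovered block correlations are biased toward zero by O(1/N).

## Stacking analysis

Ring centroids are unweighted means; the normal is the smallest-variance
principal axis of the ring atoms, sign-normalized into the +z hemisphere
(ties toward +x, then +y); planarity is the RMS residual of the best-fit
plane (√λ_min).  The inter-ring angle is arccos |n_a·n_b| ∈ [0°, 90°] —
invariant to atom order and normal sign — and the distance is the centroid
separation.

The free-energy landscape over two reaction coordinates is the Boltzmann
inversion G = −RT ln H of the raw 2-D count histogram (R = 1.9872×10⁻³
kcal·mol⁻¹·K⁻¹, T = 310 K default), shifted so the global minimum is zero.
Empty bins are undefined (serialized as missing), not +∞, to avoid fake
barriers in sparse regions.  Basins are 4-connected components of bins
within a depth threshold (default 1 kcal/mol) of the minimum.

Stacking classes partition [0°, 90°] at 30° and 60° into parallel,
herringbone and perpendicular, with class "none" beyond a 0.85 nm centroid
distance ceiling.  No numeric boundaries are standard in the literature;
the symmetric tripartition is a declared, configurable choice.  TRP is
treated as two rings (5- and 6-membered) analysed separately.

## MM/GB-SA binding energy

Per frame, in the single-trajectory approximation (receptor and ligand
coordinates extracted from the complex frame):

* ΔE_elec — Coulomb sum over receptor×ligand cross pairs, no cutoff.
* ΔE_vdW — 12-6 Lennard-Jones with Lorentz–Berthelot combination.
* ΔG_polar — Still's generalized Born, G = −½·332.0637·(1/ε_in − 1/ε_out)
  Σ_ij q_i q_j / f_GB with f_GB = √(r² + R_iR_j exp(−r²/4R_iR_j)) and self
  terms included; ΔG_polar = G(complex) − G(receptor) − G(ligand), each
  with Born radii recomputed for that topology.  Born radii follow the
  Hawkins–Cramer–Truhlar pairwise-descreening scheme with a 0.09 Å
  dielectric offset and element screening factors (H 0.85, C 0.72, N 0.79,
  O 0.85, S 0.96, P 0.86); an isolated atom's radius is its intrinsic
  radius minus the offset.  ε_in = 1, ε_out = 78.5 by default.
* ΔG_surf — γ·(SASA_complex − SASA_receptor − SASA_ligand) with
  γ = 0.0072 kcal·mol⁻¹·Å⁻² and zero offset.

The per-frame identity ΔG_bind = ΔE_elec + ΔE_vdW + ΔG_polar + ΔG_surf
holds by construction to machine precision.  The solute entropy term is
omitted: the quantity is a relative binding energy for ranking poses and
residues, not an absolute affinity.

**Per-residue decomposition.**  Every component is attributed to atoms by
symmetric shares — half of each pair term to each partner atom, self terms
fully owned — and the per-atom differences (complex minus isolated state)
are aggregated by residue, with the ligand as one entry.  This makes the
decomposition exactly closed (the entries sum to the total, including the
GB contributions that arise from radii changing upon complexation, which a
cross-term-only attribution would miss).  Because of the half-split, a
residue's entry is its half-share of the interface; the ligand entry holds
the mirror half.  `rank_binding_residues` lists protein residues below a
threshold (default −1.0 kcal/mol), strongest first.

Energies ignore periodic images (desk-scale systems, no cutoff).  PB-based
polar solvation and normal-mode entropy are out of scope.

## Synthetic trajectory generator

The generator emulates an equilibrating protein–ligand complex with fully
known ground truth:

* **Topology** — an extended chain (0.38 nm residue spacing, small
  alternating z offset so the Cα trace is never collinear) of idealized
  backbone (N, H, CA, C, O) plus side-chain stubs for
  GLY/ALA/SER/PHE/TRP/ARG/LYS/ASP/GLU; PHE and TRP carry their real
  aromatic ring atom sets (TRP as a fused pentagon/hexagon), charged
  residues their terminal groups (±1 e per group, AMBER-like backbone
  charges, neutral residues net zero).  The ligand is a row of fused
  six-membered carbon rings plus an acceptor oxygen and a tail carbon,
  uncharged by default.  LJ parameters and GB radii come from a built-in
  per-element table.
* **Dynamics** — a drift phase (a linear translation of the N-terminal
  third of the chain, decaying to zero over `drift_frames`) followed by a
  stationary phase of per-residue rigid isotropic Gaussian displacements.
  Correlated blocks are realized through an eigendecomposition square root
  of the block covariance; infeasible block specifications (non-PSD, e.g.
  pairwise ρ < 0 over more than two residues) are rejected.  Displacements
  move whole residues rigidly, so Cα statistics are analytic: RMSF → σ√3,
  block correlations → ρ.  A whole-body rigid drift would be absorbed
  exactly by superposition; restricting the drift to a subset of residues
  is what makes burn-in discarding observable in RMSD/RMSF.
* **Planted interactions**, realized by construction relative to the
  current frame (hence exact under the Gaussian jitter): hydrogen bonds
  (acceptor placed at 2.9 Å / 165° when on, 4.5 Å when off — comfortably
  inside/outside the criterion) with an independent Bernoulli draw per
  frame; a salt bridge at an exact distance trace; residue–ligand contacts
  via the ligand tail atom at 0.35 nm (in) / 0.90 nm (out) of a residue's
  Cα; stacking poses placed by rigidly transporting the whole ligand so a
  chosen ligand ring sits at an exact (angle, distance) from a protein
  ring.  Multiple stacking poses on one ring pair are drawn exclusively
  (fractions must sum to ≤ 1).  Stacking distances below the sum of ring
  circumradii are rejected as infeasible.
* Same seed ⇒ bit-identical output (`numpy.random.default_rng`).

**What it does not emulate:** bonded energetics, solvent, realistic
backbone dihedrals, anisotropic or time-correlated fluctuations, ligand
internal flexibility.  Passing recovery tests therefore demonstrates the
*estimators* are correct and unbiased at realistic magnitudes (σ ≈ 0.02 nm
fluctuations, 0.18 nm salt bridges, 0.4–0.7 nm stacking), not that any
biological conclusion transfers; on real trajectories the inputs carry all
the physics the generator omits.

## Pipeline

Stages run in the study-narrative order: load → burn-in → RMSD/RMSF/Rg/
SASA + densities → contact and covariance maps → H-bonds + salt bridges →
stacking landscapes → MM/GB-SA → residue ranking.  All constants live in
one YAML config; analysis defaults encode the study conditions (100 ns
burn-in, 310 K, 0.46/0.54 nm, 3.5 Å and 150–180°, −1.0 kcal/mol ranking
threshold) — the demo config overrides burn-in to match its own 100 ps
drift.  Canonical outputs are tidy CSV and JSON; `report.json` contains no
timestamps and is byte-identical across reruns with the same config and
seed (timings go to `pipeline.log`).  The energy stage evaluates every
8th equilibrium frame by default and the SASA series every 5th frame —
MM/GB-SA and SASA are the costly stages, and end-state averages converge
quickly in frames; both strides are configurable.

The demo complex (20 residues, 3-ring ligand, 500 frames) plants its
stacking pose at (0°, 0.42 nm): mid-basin for a parallel pose and close
enough for the ring–ring dispersion contact to put the stacking partner
clearly past the −1.0 kcal/mol listing threshold in the half-share
decomposition.

## Known limitations

* GB radii use HCT descreening without neck or high-radius corrections;
  adequate for desk-scale complexes, less accurate for deeply buried atoms
  of large proteins.
* The sidecar/built-in parameter table is minimal (per-element LJ and
  radii, charged-group charges); it is a stand-in for a real force field
  and energies on real systems are only as good as the supplied sidecar.
* Orthorhombic boxes only; periodic images are honoured for distances but
  ignored in energy sums.
* Ligand ring definitions for structures read from PDB must be supplied
  programmatically (standard aromatic residues are auto-detected by atom
  name); there is no perception of arbitrary ligand chemistry.
* The trajectory is held in memory; appropriate for the 10²–10⁴ frame,
  10²–10⁴ atom scale this package targets.
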