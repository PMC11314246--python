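# Methods

## System model

The peptide is Aβ(10–40), the 31-residue amyloid-beta fragment
`YEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV`, indexed 10..40. Residues are classified
four ways (hydrophobic / polar / negative / positive) by a single editable
table: `AVLIMFWCP` hydrophobic, `GSTNQYH` polar, `DE` negative, `KR`
positive. Ala is treated as hydrophobic and Gly as polar; His is neutral
polar, as appropriate at pH 7. The termini are charged (protonated
N-terminus, deprotonated C-terminus), giving the chain its formal net
charge of −1.

The reduced topology carries backbone N, amide H, CA, C, O per residue plus
one pseudo-sidechain bead ("CB") per non-glycine residue, placed 2.4 Å along
the CA→CB direction — roughly the sidechain heavy-atom centroid — and
carrying the sidechain mass. Nominal partial charges sum to zero per
backbone; charged sidechains and termini carry their formal charge. These
parameters are deliberately generic: they support the energetics estimator
and mass-weighted centers of mass, not a specific force field.

The SAM surface is reduced to a hexagonal (√3×√3 R30°-type) anchor lattice
of n_x·n_y chains with lattice constant 4.97 Å (the standard
alkanethiol-on-Au(111) spacing; the ligand chain length is not modelled —
the surface acts through its terminal-atom plane). Each chain contributes
one terminal heavy atom (united-atom CH₃ carbon, or hydroxyl O plus H for
the polar surface). The surface reference plane z₀ is the arithmetic mean
of the terminal heavy-atom z values; all separations are measured from this
plane rather than from individual ligand atoms.

## Synthetic trajectory generator

The generator emulates the phenomenology the analyses are designed to
measure; it is not molecular dynamics. Its defaults define the study
conditions:

- **Secondary structure.** Designed segments draw ideal helix (−57°, −47°)
  or ideal strand (−135.2°, +135.2°) dihedrals at their propensity, with
  wrapped-Gaussian jitter of sd 10° — typical of stable secondary structure.
  All other residues are coil, drawn 50/50 from broad (sd 35°) basins around
  the two references. Coil residues immediately flanking a designed helix
  draw only from the extended basin, emulating helix capping; this makes the
  designed helix boundary structurally sharp in every frame, so the segment
  labels are exact per-frame ground truth rather than labels that the
  geometry contradicts whenever a flanking coil residue happens to continue
  the helix.
- **Chain building.** Backbones are rebuilt each frame by sequential
  internal-coordinate (NeRF) placement with standard bond lengths and
  angles; measured (φ, ψ) reproduce the sampled targets to < 10⁻⁶ rad, and
  an ideal helix places O(i)···H(i+4) at 2.105 Å.
- **Adsorption kinetics.** The peptide height above z₀ follows a two-state
  Markov chain (per-frame probabilities k_ads, k_des) between z_adsorbed
  (default 7 Å, matching the typical center-of-mass height on a hydrophobic
  SAM) and z_bulk (30 Å), with Gaussian noise (sd 0.5 Å).
- **Placement.** Each conformation is canonically oriented (smallest
  principal extent vertical), randomly rotated about z and offset in-plane,
  and placed with its center of mass at the simulated height. A minimal
  vertical correction then keeps the lowest atom within [0.5, 3.4] Å of the
  plane on adsorbed frames and ≥ 0.5 Å on all frames. Consequences: no atom
  is ever below the plane, and an adsorbed frame always satisfies the 3.5 Å
  contact criterion, so the Markov adsorbed flag is recoverable exactly by
  the contact-based filter.
- **Planted contacts.** For binomial ground truth, selected residues can be
  forced into contact (lowest heavy atom at 2.0 Å) with a given per-frame
  rate, and held ≥ 6 Å away otherwise. This deforms the chain locally and is
  a test mode, off by default.
- **Presets.** `samch3-like`: helices Q15–A21 and I31–V36 at propensity 1.0,
  permanently adsorbed. `samoh-like`: weak N-terminal helix (E11–K16, 0.2),
  weak strands (V18–F20, L34–V35, 0.3), transient adsorption
  (k_ads = 0.06, k_des = 0.04). `bulk`: no surface. 5000 frames at a nominal
  10 ps spacing by default.

What the generator does **not** emulate: excluded volume between
non-bonded atoms, real sidechain geometry, energy-consistent ensembles
(Boltzmann weights), solvent, or surface corrugation. Passing recovery
tests therefore demonstrates that the analysis stack measures what it
claims on geometrically controlled input — not that any physical prediction
about the real peptide/surface system is reproduced. In particular,
MM-PBSA means evaluated on synthetic adsorbed frames are dominated by
steric clashes with the surface atoms (the generator controls heights, not
energies); the energetics module is validated on controlled geometries and
closed-form limits instead.

## Analysis conventions and numerical choices

- **Contacts:** a residue is in contact when its nearest heavy atom is
  within 3.5 Å (≈ the van der Waals diameter of carbon) of z₀. A frame is
  adsorbed when any residue is in contact — the same cutoff reused rather
  than a second free parameter.
- **Contact clustering** is unspecified in the underlying methodology, so
  the simplest parameter-free choice is used: exact fingerprint grouping
  followed by single-linkage merging at Hamming distance ≤ 1, ranked by
  population. Populations are fractions of all frames, so they sum to the
  adsorbed fraction.
- **Hydrogen bonds:** D···A ≤ 3.5 Å and ∠D–H···A ≥ 150°, both configurable.
- **Switching function:** the removable singularity at r = r₀ is evaluated
  as n/m; the implementation is continuous there to ≤ 10⁻⁹ and monotone
  decreasing.
- **Dihedral offset:** the sum runs over the N−1 defined (φ, ψ) pairs of an
  N-residue chain (φ of residues 2..N, ψ of 1..N−1); undefined dihedrals
  are skipped. IUPAC convention, radians internally.
- **Secondary structure** is a deliberately simplified assigner, not a
  STRIDE/DSSP re-implementation: a residue is H when an i→i+4 bond
  (switching > 0.5) covers it and its dihedrals lie within 40° of the
  helix references, in runs of ≥ 2; G likewise via i→i+3 bonds; E when
  dihedrals are within 40° of the strand references for ≥ 2 consecutive
  residues; T for residues covered by isolated helical bonds; else C.
  Propensity-level recovery on synthetic truth is the intended accuracy,
  not per-residue parity with STRIDE.
- **Gyration:** unweighted by default (each atom counts equally), with
  mass-weighting available by flag; eigenvalues from `numpy.linalg.eigvalsh`
  are clipped at zero before the square root.
- **RMSD/clustering:** Kabsch superposition via 3×3 SVD with a determinant
  fix (proper rotations only); the default atom selection is the backbone
  N, CA, C, O of all residues. The pairwise matrix is computed exactly in
  blocks with a memory cap. Daura ties (equal neighbour counts) break to
  the lowest frame index for determinism. The pipeline subsamples to
  ≤ 1000 frames before clustering because the matrix is O(F²).
- **Entropy:** Shannon entropy of cluster populations in k_B units —
  consistent with entropy values quoted per k_B and monotone in the number
  of conformations. No temperature weighting is applied.
- **Equilibration:** a cluster is "low free energy" when
  p/p_max ≥ exp(−2/(k_B·300 K)) = 0.0349 (k_B = 0.0019872041 kcal/mol/K).
- **REST ladder:** geometric spacing T_i = T₀(T_max/T₀)^{i/(n−1)}.
  Published ladders of this kind round inconsistently in the third decimal
  for interior replicas; the endpoints and the geometrically consistent
  interior entries (e.g. 0.840 at 357 K, 0.706 at 425 K for the 12-replica
  300–440 K ladder) are reproduced exactly at 3 decimals.
- **Toy REST:** symmetric double well E_pp = B((x/x₀)²−1)² with
  B = 5 kcal/mol and x₀ = 1, harmonic coupling E_ps = 1·(x−y)² and solvent
  term E_ss = 1·y² (k = 2 kcal/mol/Å² each) — chosen so the marginal well
  weights are exactly ½ by symmetry. Gaussian-proposal Metropolis at
  T₀ = 300 K, exchanges every 100 steps with alternating pair parity.
  Occupancy uncertainties use the number of well-to-well transitions as the
  effective sample size.
- **MM-PBSA:** single-trajectory construction, so ΔE_int ≡ 0; inter-group
  12-6 LJ (Lorentz–Berthelot) + Coulomb (332.06 kcal·Å·mol⁻¹·e⁻²) with no
  cutoff on these finite systems; Shrake–Rupley SASA with a deterministic
  golden-spiral point set (default 960 points, ≥ 92 enforced; Bondi-type
  radii, 2.0 Å for the sidechain bead), probe 1.4 Å; γ = 0.005
  kcal mol⁻¹ Å⁻² . The polar term is a pluggable backend, zero by default; a
  crude Coulomb-field/Born-style estimate exposing the 1/80 dielectric pair
  is provided but is not a Poisson–Boltzmann solver, which is out of scope.
  Conformational entropy is neglected. Uncertainties are standard errors of
  the frame-wise mean.

## Problem sizes

Default test and acceptance workloads: 5000-frame synthetic scenarios for
recovery statistics, 600-frame subsamples for clustering demonstrations,
100 random instances of ≤ 20 frames for clustering-oracle equivalence, and
5 × 30 000-step toy-REST runs. These sizes give 3-standard-error recovery
bounds of a few percent while keeping the whole suite fast on one CPU.

## Known limitations

- The synthetic coil ensemble is more diverse than a physical 100 ns
  production run, so cluster counts on synthetic data are much larger than
  trajectory-derived values for equal frame counts; clustering outputs are
  validated by oracle equivalence and invariants, not by comparison with
  any published ensemble.
- The secondary-structure assigner trades STRIDE parity for transparency;
  edge residues of genuine helices can be assigned T when their single
  covering bond fluctuates.
- The surface is a rigid terminal-atom monolayer: no ligand tilt,
  conformational dynamics, or image-charge effects.
- `mm_energy` is O(N_A·N_B) with no neighbour lists and is intended for the
  reduced topologies used here, not for condensed-phase systems.
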