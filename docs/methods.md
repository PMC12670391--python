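# Methods

This note records the models implemented in `pfklab`, the defaults and
the reasoning behind choices that were genuinely open. No empirical
number appears here that the test suite or `scripts/acceptance.py` does
not itself compute.

## Units and conventions

Lengths are nm throughout (PDB ångströms converted on read), energies
kJ/mol, areas nm², temperatures K, k_B = 0.0083144626 kJ mol⁻¹ K⁻¹.
Residue numbering follows the source file (1-based author numbering);
chains are identified by author chain ID. All randomness flows through
`numpy.random.default_rng(seed)`; every generator is bit-reproducible
under a fixed seed.

## Contact statistics

Two beads are in contact when their distance is **strictly less than**
the cutoff (default 0.7 nm); a pair at exactly the cutoff is not a
contact. Minimum-image distances are used whenever the trajectory
declares a periodic box; otherwise a KD-tree query is used, and both
paths are checked against an all-pairs oracle in the tests.

The normalized contact number between residue groups divides the
per-frame **mean** contact count by the product of the two group SASAs.
Whether the numerator is a per-frame mean or a grand total is a
presentation choice (a fixed rescale by the frame count); the per-frame
mean is used so trajectories of different lengths are comparable. Group
SASAs are computed once on a static reference conformation, not per
frame: the normalization is meant to be a fixed property of the two
surfaces, and a per-frame SASA would make the statistic depend on the
trajectory in a way the definition does not require. Both choices are
configurable. Contacts are counted between all particles, not backbone
beads only.

Per-residue contact probability for a two-tetramer system: for residue
r, monomer m and frame f, the indicator is whether any particle of m's
copy of r lies within the cutoff of any particle of the other tetramer.
The profile averages over frames, the eight monomers, and replicas when
several trajectories are pooled. The SEM is the standard deviation of
the monomer×replica sample means divided by √n — the finest grouping at
which the average is defined. Because only two copies of a residue per
tetramer can physically reach the partner at once, the averaged
probability cannot exceed 0.5; the saturating synthetic schedule attains
it exactly.

"Tetramers in contact" for the contact-time fraction means at least
`min_pairs` (default 1) inter-tetramer particle pairs inside the cutoff;
the threshold is configurable because the notion is not standardized.

## SASA and rSASA

Shrake–Rupley quadrature: each particle is inflated by the probe radius
(water, 0.14 nm) and covered with a deterministic golden-spiral point
set (default 960 points); its accessible area is the inflated-sphere
area times the fraction of points outside all neighboring inflated
spheres. Isolated spheres are exact at any point count; for packed beads
the tests require doubling the point count to move the total by < 0.5%.
Per-residue and per-group areas are sums over members. An independent
cross-check against mdtraj's implementation on random bead sets is part
of the test suite.

Radii: atomistic inputs use Bondi van der Waals radii inferred from atom
names; coarse beads use half the LJ σ of the bead size class (regular
0.235 nm, small 0.205 nm, tiny 0.170 nm), with a config-overridable
per-type table. Source models rarely carry radii, so they are assigned
explicitly before any SASA call.

rSASA divides a residue's area by the fully-exposed reference maximum of
its type (Tien et al.; theoretical Gly-X-Gly maxima by default, the
empirical set selectable). Ratios above 1 — possible for distorted
conformations or quadrature error — are clamped to 1 with a logged
warning.

## Interface dissection

Interaction criteria are geometric, with defaults at the field's
standard values (they are deliberately configurable because published
pipelines differ):

- hydrogen bond: donor–acceptor ≤ 0.35 nm and donor–H–acceptor angle
  ≥ 120°; when the structure carries no hydrogens at all, a heavy-atom
  fallback (distance plus donor-capability check) applies. One record
  per donor/acceptor atom pair, so a bidentate arrangement counts twice.
- salt bridge: side-chain N–O ≤ 0.40 nm between Asp/Glu and
  Lys/Arg/His; one record per residue pair at the minimum distance.
- aromatic stacking: ring-centroid distance ≤ 0.55 nm with interplanar
  angle ≤ 30° (parallel) or 60–120° (T-shaped); ring normals from the
  smallest principal axis of the ring atoms.

Stable pairs: occupancy = distinct frames present / frames analyzed;
pairs at or above a persistence threshold (default 0.5) are reported in
descending occupancy. A helper reproduces the even 16-frame-per-replica
subsampling scheme used for interaction inventories.

Region classification follows the hydration convention with a burial
threshold of rSASA < 0.25 (configurable): interface residues (those
losing SASA upon complexation) are *support* if already buried in the
free monomer, *core* if exposed free but buried in the complex, and
*interacting rim* otherwise; non-interface surface residues with a
particle within 0.7 nm of an interface residue form the *NIS rim*;
everything else is surface or interior. The three interface classes
partition the interface residue set by construction. Counts on real
interfaces depend on the (unpublished) thresholds of the upstream
tools, so the tests assert the rule table and the partition property,
not literature counts.

## Force-field patch

The elastic network places one harmonic bond (default k = 700
kJ mol⁻¹ nm⁻², the value used for the tetramer simulations this package
accompanies) between every intra-chain backbone pair within a cutoff,
excluding sequence-adjacent residues that carry real bonds. The cutoff
is not part of the published setup; 0.9 nm — the common Martini
elastic-network default — is used and configurable.

The hydrogen-bonding patch adds, per selected residue (default Asn702),
one massless virtual site at the mass-weighted side-chain center
(GROMACS `virtual_sitesn` funct 2), a new particle type whose LJ
interaction is σ = 0.39630469 nm, ε = 22.76096 kJ/mol with itself and
exactly zero with every other type (explicit zero pair rows), and an
exclusion between the site and its constructing beads. This realizes
"added on top" semantics: no pre-existing topology entry changes, which
the tests verify by exact diff. The patch refuses when the selected
position is not an asparagine, so the N702T mutant cannot receive the
term — the same isoform specificity the mutation experiment exploits.
Masslessness is a choice (the alternative, redistributing mass, is not
described anywhere); a massless site leaves the dynamics of the
constructing beads to the engine's virtual-site machinery. The
flat-bottom restraint used in the source workflow is representable as a
record but ships no default radius or force constant, because none are
published.

Energy evaluation covers only the analytic added terms (LJ pair,
harmonic network); full force-field energies are engine territory.

## Umbrella sampling and WHAM

`wham_solve` iterates the standard two self-consistent equations on
binned histograms until the window free energies move by less than the
tolerance (default 1e-7 kJ/mol, max 1e5 iterations), with bin count
defaulting to twice the window count. Non-overlapping window coverage is
diagnosed before iterating, with the uncovered gaps reported. The
profile is anchored so the mean over the largest-distance 10% of
populated bins — the unbound plateau — is zero (`'min'` anchoring is
available for parameter-recovery tests); the anchor is a convention,
and the tests verify the profile is invariant under a constant offset of
the true potential.

Bootstrap: each replicate resamples every window's samples with
replacement (per-window case resampling, default 200 replicates) and
re-solves WHAM on the same bin grid; the band is the per-bin standard
deviation. Split-half convergence re-solves on the first and second half
of each window's samples and reports the maximum discrepancy over common
bins — the check that justifies analyzing only the second half of each
umbrella trajectory.

Binding ΔG = mean free energy over the unbound region − minimum over
the bound region; ΔΔG between native and mutant profiles is the
difference of their ΔG values. No standard-state or volume-entropy
correction is applied by default, matching presentation as raw profile
differences. Temperatures default to 300 K (298 K is appropriate for
OPEP-style contexts).

Per-window bias force constants in the source workflow were
window-specific but unpublished; the synthetic generator uses a uniform
configurable constant, which is sufficient for parameter-recovery
testing and explicitly not a claim about the original values.

## Synthetic data

The two-body generator realizes a contact schedule exactly: each
(monomer, residue) copy owns a lateral slot 2 nm from its neighbors;
body B's copy sits on a reference plane and body A's copy approaches to
cutoff − margin when designated (default margin 0.05 nm) or stays at
cutoff + margin otherwise. Designation is applied symmetrically — the
paired copies approach each other — which realizes the saturating
2-of-4 schedule exactly and keeps every frame brute-force checkable.
Asymmetric (one-sided) schedules are outside the generator's contract.
The geometry is a checkable idealization, not a protein: it has no
excluded volume, no rotational diffusion, and contacts switch
instantaneously, so passing tests demonstrate the *statistics'*
definitions and bounds, not force-field behavior on real assemblies.

Umbrella samples are drawn from the exact biased density
exp(−[V(x) + k(x−c)²/2]/kT) by inverse-CDF lookup on a 10⁴-point grid —
exact to grid resolution and free of autocorrelation, which keeps WHAM
recovery tests sharp where an MD sampler would blur them. Real umbrella
time series are autocorrelated; the error bands here therefore
demonstrate the estimator's statistical behavior, not the effective
sample sizes of real simulations.

The interaction fixtures plant geometries a stated margin inside (or
outside) the default criteria: the reciprocal Asn–Asn amide pair
exchanges two hydrogen bonds at 0.29 nm with donor angles near 165°; the
Glu/Arg pair sits at 0.37 nm N–O, inside the salt-bridge cutoff but
outside the hydrogen-bond distance; the Phe rings stack parallel at
0.45 nm.

## Problem sizes and numerical checks

Default test problem sizes — 32 windows × 5000 samples for double-well
recovery, 100 random instances per geometric oracle, 8-residue
two-tetramer trajectories of 100 frames — were chosen as the smallest
sizes at which the statistical assertions are comfortably sharp.
Double-well feature recovery (both well depths and the 12 kJ/mol
barrier) is asserted to 0.5 kJ/mol; at 64 bins mid-bin discretization
contributes about 0.2 kJ/mol of that budget. Bootstrap √n scaling is
asserted as a ratio of 2 ± 30% between 500- and 2000-sample windows.

## Known limitations

- No MD engine integration: the package analyzes and patches, it does
  not simulate, and topology semantics are validated structurally, not
  by running GROMACS.
- The topology dialect covers the sections the patch touches
  (`atomtypes`, `nonbond_params`, `moleculetype`, `atoms`, `bonds`,
  `constraints`, `angles`, `virtual_sitesn`, `exclusions`, `system`,
  `molecules`); preprocessor directives (`#include`, `#ifdef`) are not
  expanded.
- Hydrogen-bond detection with explicit hydrogens trusts conventional
  atom naming (HD21 bonded to ND2, etc.) rather than a bond graph.
- Sequence-level mutation drops side-chain atoms beyond the backbone;
  rebuilding side chains is out of scope.
- Isoform loop correspondence uses a supplied mapping or a BLOSUM62
  global alignment; structure-based correspondence is not implemented.
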