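# Methods

## Electrostatic model

The pKa engine treats the protein as a low-dielectric cavity (relative
permittivity 4) in high-dielectric solvent (78.4) with 0.15 M 1:1 salt at
298.15 K. The linearised Poisson–Boltzmann equation is discretised on a
regular grid with a 7-point stencil; face dielectrics are harmonically
interpolated from the fraction of each node-to-node segment inside the
union of atom spheres (sampled at five points per segment), which largely
removes the grid-placement sensitivity of Born self-energies. Ionic
screening acts only at solvent nodes beyond a 2 Å Stern layer around every
atom; Dirichlet boundary potentials come from the Debye–Hückel expression.
The discrete operator is symmetric positive-definite and is solved with
Jacobi-preconditioned conjugate gradients to a residual well below the
10⁻⁴ kT/e level (rtol 10⁻¹⁰); non-convergence raises with the residual
norm. Default grids: 0.5 Å spacing with a 10 Å border around each site's
charges. On the 2 Å Born-sphere oracle the default grid is within 0.8% of
the closed form and halving the spacing moves the value by ~0.5%.

Desolvation uses identical-grid subtraction: the site's ionised charges are
solved once in the full protein dielectric map and once in a model-compound
map containing only the site's own residue as cavity. Because the charge
node's local dielectric is identical in both runs, the grid self-energy
cancels exactly and the difference is the transfer energy. The background
term is the interaction of the site's ionised charges with all
non-titrating charges (hydroxyl dipoles, user-supplied fixed charges),
blended between the FDPB potential map and the screened-Coulomb form by the
site's fractional burial.

Charge model (formal charges on ionised-form representative atoms):
Cys SG −1; Asp OD1/OD2 and Glu OE1/OE2 −0.5 each; Lys NZ +1; Arg NH1/NH2
and His ND1/NE2 +0.5 each; N-terminus +1 on backbone N; C-terminus −1 at
the O/OXT midpoint. Ser/Thr/Tyr hydroxyls contribute a ±0.4 e dipole on
O/H after the hydrogen is placed by a discrete 30° torsion scan minimising
Coulomb energy against all ionised site charges (0.96 Å bond, 109.5° angle;
ties broken toward the smaller torsion). Sites missing a charge-bearing
atom are excluded and logged, never approximated from backbone atoms.
Ligand heteroatoms occupy protein-dielectric volume but carry no charge;
they can be excluded entirely (`exclude_ligands`). Waters never occlude.

Fractional burial of a site is `1 − SASA(atom in context) / SASA(atom in
the residue extracted in isolation)`, clamped to [0, 1] and averaged over
the site's charge atoms. The isolated-residue reference is computed by the
same SASA algorithm; it plays the role a Gly-X-Gly tripeptide reference
would, without requiring tripeptide geometry the package never otherwise
builds.

## Titration

At a given pH the energy of a protonation microstate x is

    E(x) = Σ_i 2.303·RT·γ_i(x_i)·(pH − pKa_intr,i)
         + Σ_{i<j} W_ij·c_i(x_i)·c_j(x_j)

with γ the protonation indicator and c the ionised-form charge (acids
ionise on deprotonation, bases on protonation). Intrinsic pKas follow
`pKa_model + s·ΔΔG/(2.303 RT)` with s = +1 for acids and −1 for bases:
destabilising an anion raises an acid's pKa, destabilising a cation lowers
a base's. Metropolis Monte Carlo samples microstates over a pH ladder
(−2 to 20, step 0.25 by default — the ladder deliberately extends past 15
to support the high flag). One Monte Carlo step is a *sweep* of n attempted
moves; defaults are 10⁵ sweeps after 10⁴ burn-in per pH, with 10% of moves
being double flips over strongly coupled pairs (|W| > 2 kcal/mol). Under
this convention 10-site protonation fractions agree with exact
partition-function enumeration to better than 0.01. The per-pH seed is
derived from the configured seed and ladder index, so identical
configuration gives bit-identical fractions. The pKa is the linearly
interpolated pH of half-protonation; sites not crossing 0.5 by the ladder
end (or crossing above 15) are flagged and printed `">15"`, and sites
already below 0.5 at the ladder start are flagged low. Equivalent sites in
chains of identical sequence are averaged; a group mixing flagged and
numeric predictions is reported as a range rather than a mean.

## Surface area and structural bookkeeping

SASA uses a deterministic golden-spiral lattice (960 points per atom by
default) on probe-expanded spheres, with van der Waals radii C 1.70,
N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å and a 1.4 Å probe; hydrogens are
ignored (no united-atom inflation) and waters are excluded from occlusion
and heteroatom counts unless requested. Sample points falling exactly on
several coincident expanded surfaces are split evenly between the owning
atoms. With a fixed global lattice, total SASA is rotation-stable to ~0.2%
at 960 points, but a nearly buried atom's area (~1 Å²) is only stable in
absolute terms (≤ ~1 Å²); tests therefore assert 0.5% on totals and an
absolute per-atom tolerance at the default density.

PDB input is parsed with gemmi (MODEL 1 only); alternate locations keep
the highest-occupancy conformer, ties broken by altLoc letter. Secondary
structure comes exclusively from HELIX/SHEET records — no DSSP
recomputation — and records referencing residues absent from the model are
flagged dangling. Residue identity is (chain, number, insertion code).
Nonstandard residues are excluded from amino-acid statistics and pooled
with the heteroatoms. Disulphide detection unions SSBOND records (trusted
even beyond the geometric cutoff) with a greedy closest-first screen for
SG–SG pairs within 2.8 Å, each cysteine joining at most one pair. The
asymmetric-unit size filter is strict: structures with ≥ 1500 standard
residues are rejected.

## Sequence analyses

Windows are odd-width (21 default, 11 supported), 1-based, and must fit
entirely inside the sequence; terminal sites are excluded rather than
padded. Charges: D/E −1, K/R +1, H 0; nonstandard letters score 0 (and the
hydropathy midpoint) and are logged instead of dropping the window. The
NUL set comprises all other cysteines in proteins that contain at least
one modified site, deduplicated at (accession, position); the same
cysteine may appear under two modification types. The fold-propensity
discriminant uses constants a = 2.785, b = 1.151 with min-max-normalised
Kyte–Doolittle hydropathy; an index of exactly 0 is called ordered, and
the same charge rule (His neutral) feeds both the net-charge and
fold-propensity calculations. The per-protein comparison counts a protein
as "greater" only when the mean MOD window net charge strictly exceeds the
mean NUL value; ties count against. Ubiquitination proximity is pure
sequence separation |Δposition|, binned half-open [10k, 10k + 10); the
optional terminal exclusion drops cysteines within 50 residues of either
terminus. Proteins without ubiquitination data contribute no distances.
Mann–Whitney tests are exact for tie-free samples with n·m ≤ 400 and use
the tie- and continuity-corrected normal approximation otherwise; pKas
flagged ">15" enter rank tests tied above the largest numeric value.

## Synthetic data

The generators define the study conditions for all tests. Sequences are
drawn from uniform amino-acid frequencies (a database-like composition can
be swapped in), length 400, with non-overlapping cysteine sites placed so
every window is eligible. The planted basic excess δ moves probability
mass from non-charged residues to Lys/Arg (half each), so the expected
per-position MOD−NUL mean-charge difference equals δ exactly and binomial
standard errors are analytic; a negative δ mirrors the mass onto Asp/Glu.
The per-protein preset gives +δ windows to an `enriched_protein_fraction`
of proteins and −δ to the rest, with δ = 0.5 strong enough that each
protein's MOD-vs-NUL comparison is essentially deterministic — the
measured "greater" fraction then estimates the planted fraction directly
(0.8 → ≈4:1). Ubiquitinated lysines are placed at geometric distances
(mean 15) from modified cysteines plus uniform background sites; placement
can be disabled to isolate the charge signal, since a planted lysine
inside the ±10 window would otherwise inflate the charge difference.
Half-life and abundance tables are log-normal with a configurable log₁₀
shift for modified proteins. Every generator is a pure function of its
configuration, and truth tables carry enough to recompute each planted
effect independently of the pipeline. What the generators do *not* emulate:
real amino-acid composition, fold geometry beyond ideal helices, orthologue
correlation between sequences, and annotation noise — so passing tests
demonstrate correctness of the machinery and recoverability of planted
effects, not agreement with database-scale biology.

## Problem sizes and numerical choices

Default test problem sizes were chosen to keep every stage exact or
oracle-checkable: Born sphere at 0.5/0.25 Å grids, ≤ 10 coupled sites for
enumeration cross-checks, 1000–2000 windows for δ recovery, 500 proteins
for the ratio preset, 10⁴ replicates for the Mann–Whitney type-I
calibration. Temperature is fixed at 298.15 K and the Coulomb constant at
332.06 kcal·mol⁻¹·Å·e⁻². Degenerate inputs fail loudly: empty models,
empty window sets, non-monotone pH ladders, overlapping site charges
(< 0.5 Å) and uncovered histogram ranges all raise.

## Known limitations

Absolute agreement with any particular published per-structure pKa set is
not claimed: the burial weighting of the hybrid scheme and the full charge
set of the original FDDH implementation are not public, and continuum pKas
are sensitive to both. The solver is linear-response only (no nonlinear
PB), conformational relaxation is limited to hydroxyl torsions, and
helices are the only secondary structure the synthetic generator builds.
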