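# Methods

## The problem

Bullvalene (BV) is the tricyclic C10H10 cage whose degenerate [3,3]-sigmatropic
Cope rearrangements interconvert all ten carbon positions: the parent compound
fluctuates among 10!/3 = 1 209 600 equivalent valence isomers. A substituted
bullvalene instead shapeshifts between *nondegenerate* constitutional isomers
with genuinely different 3D shapes and substituent orientations, which makes BV
an unusual scaffold for fragment-based drug discovery: rigid at any instant,
dynamic over time. `bvstereo` quantifies this stereodynamics — how many isomers
exist, how they interconvert, what shapes they adopt, and how strongly each is
populated at equilibrium.

## Barcodes and symmetry

Each substitution state is a ten-digit barcode over the fixed position order
`[alpha, beta1, gamma1, delta1, beta2, gamma2, delta2, beta3, gamma3, delta3]`
(0 = hydrogen, non-H substituent types numbered by input order). The digit
order within and across arms is an internal convention; any order consistent
with the symmetry operations is equivalent up to relabelling, and
`reorder_barcode` is the documented hook for emitting strings in another
convention. The cage's C3 axis makes barcodes related by the arm rotation
`rho` (arms 1→2→3 sitewise, alpha fixed) the same isomer; the canonical
representative is the lexicographic **minimum** over `{b, rho(b), rho^2(b)}`.
Reflections are deliberately *not* quotiented out, so enantiomers are distinct
isomers throughout; a barcode is achiral exactly when the arm-swap mirror
`sigma` maps its rotation orbit onto itself, and otherwise
`canonical_form(sigma(b))` is its enantiomer.

The isomer count is

    N_iso = ( 10! / prod_t N_t!  +  2 S ) / 3,

where the product runs over all substituent types including hydrogen and `S`
counts the C3-symmetric arrangements (alpha occupant plus three identical arm
triples; always 0, 1, 3 or 6). The 1/3 removes triple counting of rotationally
related arrangements, and `2S` restores the arrangements that the multinomial
counted only once because all three arms are identical. The closed form is
never trusted alone: `enumerate_isomers` iterates the distinct multiset
permutations of the digits and keeps orbit minima, and the test suite checks
the two routes against each other over all 42 substitution variations
(integer partitions of 10), the largest being the fully heterosubstituted case
with 1 209 600 canonical barcodes (~5 s to enumerate).

## Cope steps and networks

A Cope step happens on one of three 1,5-hexadiene faces, each involving two
"participating" arms i, j and one spectator arm k. Breaking delta_i–delta_j
while forming beta_i–beta_j gives a position permutation that realizes the
four elementary exchanges (alpha↔delta and beta↔gamma on non-participating
sites, beta↔delta and the degenerate gamma↔gamma on participating sites). The
permutation table is arranged so that applying the same face twice is the
identity on all ten positions — the rearrangement is its own reverse across
the newly formed cyclopropane bond.

The interconversion network has one node per canonical isomer and one edge per
face-induced transition, with self-loops for degenerate steps. A subtlety
follows from working with rotation-orbit representatives: face counts are
*directional*. A monosubstituted alpha isomer (orbit size 1) reaches the delta
isomer by all three faces, while the delta isomer (orbit size 3) reaches alpha
by exactly one; in general `count(u→v)·|orbit(u)| = count(v→u)·|orbit(v)|`.
Edges therefore store both direction counts, every node has exactly three
outgoing faces, and the orbit-scaled balance relation is asserted as a test
property. Networks are built either from the full enumeration or by BFS from
a single barcode; the two constructors must agree, which doubles as a
connectivity (full-shapeshifting) check.

## 3D structures

Substituents are supplied as SMILES with the first atom as the attachment
point, grafted onto the ten-carbon scaffold graph, embedded with RDKit's
ETKDGv3 distance geometry (N conformers, default 10, fixed seed) and optimized
with a classical force field; the M lowest-energy conformers are kept after
RMS deduplication at 0.1 Å (default M = 1, matching a one-structure-per-isomer
treatment of conformationally simple substituents; flexible substituents need
larger N).

**Force field.** MMFF94 is the default; UFF is available via
`forcefield="uff"`. For the methyl ensembles the MMFF geometries track
reference-quality (hybrid-DFT) cage geometry markedly better — e.g. the
beta,gamma' dimethyl exit-vector dihedral comes out at ±27.5° (reference
~±30°) where UFF gives ±17°, and the gamma,delta' pair at ±0.3° (reference
±0.5°) — so MMFF is the right surrogate when no external quantum-chemistry
refinement follows. UFF remains useful as a cheap pre-optimizer when
structures will be re-optimized externally anyway.

**Enantiomer handedness.** Enantiomeric barcodes share one molecular graph, so
distance-geometry embedding alone cannot decide which mirror image a barcode
denotes. The package fixes a convention: the signed volume
`det[beta1−alpha, beta2−alpha, beta3−alpha]` over the position-mapped core
must match the sign of the parent scaffold template; conformers embedded with
the opposite sign are mirror-flipped (x → −x), which leaves force-field
energies unchanged. Because enantiomeric barcodes assign digits to
mirror-related position maps, this single convention makes the two members of
a pair come out as mirror-image structures — their force-field energies agree
to ~1e-9 kcal/mol and their PMI ratios to ~1e-7 in practice.

**External energies.** The toolkit writes XYZ files and template-substituted
quantum-chemistry inputs (bundled default: a PBE0 D3 def2-SV(P) optimization
header) and ingests energies back either from a `barcode,energy,unit` CSV
(kJ/mol, kcal/mol or Hartree; 1 Hartree = 2625.4996 kJ/mol) or from ORCA /
Gaussian output files by final-energy line. Energies are stored relative to
the ensemble minimum; whether they are electronic or free energies is the
caller's choice and is recorded as an opaque `energy_kind` tag.

## Shape descriptors

**PMI.** The inertia tensor is computed over *all* atoms with standard atomic
masses about the center of mass; eigenvalues ascending give I1 ≤ I2 ≤ I3 and
the normalized ratios NPR1 = I1/I3, NPR2 = I2/I3. Exact vertex cases (two
equal point masses → (0,1); regular hexagon → (0.5,0.5) by the
perpendicular-axis theorem; regular tetrahedron → (1,1)) are tested
analytically, and the triangle bounds 0 ≤ NPR1 ≤ NPR2 ≤ 1, NPR1+NPR2 ≥ 1 are
asserted for every generated structure. Collinear inputs return the rod
vertex and are flagged.

**Exit vectors.** For substituted scaffold carbons C1, C2 with attachment
atoms X1, X2: r = |C1C2|; theta = the signed right-handed dihedral
X1–C1–C2–X2 (−180..180°, sign taken with the lower barcode position first;
mirror images negate it, which is how enantiomer pairs appear at ±theta);
phi_i = angle between the exit vector Ci→Xi and the internuclear axis
directed *away* from the partner carbon. The "away" convention was the
genuinely open choice here; it is the one that places the bullvalene methyl
ensembles in the expected 15–60° plane-angle band (reaching ~67° for
higher-energy isomers), and it is isolated behind a single switch
(`phi_convention="toward"` gives the supplement). For multi-atom substituents
X is the attachment atom, not a centroid. Report rounding follows common
practice: r to 0.1 Å, angles to 1°.

## Populations

Boltzmann weights `p_i = exp(−dE_i/RT)/Σ_j exp(−dE_j/RT)` with
R = 8.314462618 J/(mol K), T default 298 K, energies in kJ/mol relative to
the minimum. Each canonical isomer is a separate ensemble member — enantiomer
partners each carry their own (equal) weight — and no statistical factors for
degenerate self-loops are folded in. Tested properties: weights sum to 1
(1e-12), invariance under a common energy offset, uniform and RT·ln 2
closed forms, and the T → 0 / T → ∞ limits. Weighted descriptor tables join
populations onto PMI/EV rows (marker size ∝ p, minority flag below 0.1%), and
weighted networks carry node populations plus a mirror-symmetric layout hint
(achiral isomers on the central axis, enantiomer pairs mirrored).

## Problem sizes and determinism

Default workloads are deliberately desk-scale: the full combinatorial oracle
over all 42 variations enumerates ~9M multiset permutations (tens of
seconds); the complete di-/tri-/tetramethyl build (15 + 42 + 72 isomers,
10 conformers each, MMFF) takes well under a minute. All randomness enters
through the single embedding seed; identical (barcode, substituents, seed)
inputs reproduce coordinates bit-for-bit, and the build manifest records
per-file SHA-256 checksums.

## What the force-field surrogate does and does not show

Force-field geometries stand in for externally optimized (hybrid-DFT)
structures. At this level the *geometric* claims are reproduced within modest
tolerances (key dimethyl r values to 0.1 Å, |theta| clusters at ~0° and
~27–31° versus the reference 0°/30°, the ±60° cage bound on all pair
dihedrals, the dimethyl ΣNPR band 1.44–1.57) and the *qualitative* energetic
ordering is recovered (the four most stable dimethyl isomers are the
beta,beta' / gamma,gamma' achiral pair plus the beta,gamma' enantiomer pair).
Quantitative populations differ from reference values (force-field weighting
concentrates ~99% in the top four dimethyl isomers versus ~93% at the
reference level); reproducing printed percentages requires feeding externally
computed energies into `populate`. Force-field energetics, not the package
machinery, is the limiting approximation.

## Known limitations

- No CIP R/S assignment at the alpha stereocenter; chirality is classified at
  the barcode level only (mirror test), though generated geometries do
  realize the intended handedness.
- No conformational partition function: population weighting uses one
  structure per isomer.
- No kinetics: the network is connectivity only, with no rates or barriers.
- The comparison regions of exit-vector plots for common disubstituted
  cycloalkanes (from crystallographic surveys) are not bundled; they can be
  drawn from user-supplied overlay data.
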