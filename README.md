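# bvstereo

Stereodynamic analysis of substituted bullvalenes.

Bullvalene is the fluxional C10H10 cage whose degenerate Cope rearrangements
interconvert all ten carbon positions (1 209 600 equivalent valence isomers
for the parent compound). Substituted bullvalenes instead shapeshift between
nondegenerate constitutional isomers with distinct 3D shapes — a dynamic
covalent library from a single compound, of interest wherever rigid but
shape-diverse scaffolds are valued (fragment-based drug discovery,
bioisostere design, functional materials). `bvstereo` is a toolkit for
chemists who want to pre-screen that library computationally:

- **count and enumerate** all unique isomers of a substitution pattern as
  ten-digit position barcodes, canonical under the cage's C3 rotation, with
  enantiomers kept distinct and classified (achiral / enantiomer pairs);
- **build the Cope interconversion network** from the four elementary
  positional exchanges (alpha↔delta, beta↔gamma, beta↔delta, gamma↔gamma),
  exported as GraphML / TSV / DOT;
- **generate 3D structures** for every isomer by grafting SMILES substituents
  onto the scaffold, ETKDGv3 embedding and force-field optimization (MMFF94
  default, UFF optional), with correct enantiomer handedness and
  reproducible coordinates; write XYZ or quantum-chemistry input files and
  read external energies back;
- **compute shape descriptors**: principal-moment-of-inertia ratios
  (NPR1 = I1/I3, NPR2 = I2/I3; rod/disc/sphere triangle) and exit-vector
  geometry (r, signed dihedral theta, plane angles phi1/phi2) for every
  substituent pair;
- **weight by Boltzmann populations** p = exp(−dE/RT)/Σexp(−dE/RT) at a given
  temperature and produce population-weighted tables, plots and networks.

The isomer count for per-type substituent counts `N_t` (hydrogen included) is

    N_iso = ( 10! / prod_t N_t!  +  2 S ) / 3

where `S` ∈ {0, 1, 3, 6} counts the C3-symmetric arrangements; the package
always cross-checks this closed form against exhaustive canonical-barcode
enumeration. See `docs/methods.md` for the science and conventions in detail.

## Worked example: dimethylbullvalene

```sh
$ bvstereo count -s C:2
substituents: [('C', 2)]
N_iso      = 15
S          = 0
achiral    = 9
chiral     = 6 (3 enantiomer pairs)
```

Two methyl groups and eight hydrogens give 10!/(2!·8!) = 45 arrangements, no
C3-symmetric ones (S = 0), hence 45/3 = 15 unique isomers: 9 achiral and 3
enantiomeric pairs.

```sh
$ bvstereo build    -s C:2 -o run/        # 15 structures + manifest
$ bvstereo network  -s C:2 -o run/
$ bvstereo describe -b run/ -o run/       # pmi.csv, ev.csv
$ bvstereo populate -b run/ -o run/       # Boltzmann weights at 298 K
INFO bvstereo: top populations: 0000100100=39.6%; 0000100010=23.0%;
               0000010100=23.0%; 0000010010=14.1%
$ bvstereo plot -o run/                   # pmi.svg, ev.svg, phi.svg, ...
```

The four most stable isomers at the MMFF level are the beta,beta' isomer
(barcode `0000100100`), the gamma,gamma' isomer (`0000010010`) and the
beta,gamma' enantiomer pair (`0000100010` / `0000010100`, equally weighted) —
the same top-4 set found when the ensemble is weighted with external DFT
energies. Per-isomer geometry, from `run/ev.csv` and `run/pmi.csv`:

| isomer | r / Å | theta / deg | sum NPR |
|---|---|---|---|
| beta,beta' (`0000100100`) | 2.5 | 0 | 1.48 |
| beta,gamma' (`0000100010`) | 3.1 | −27 | 1.50 |
| gamma,beta' (`0000010100`) | 3.1 | +27 | 1.50 |

Enantiomers appear at mirrored dihedrals ±theta with identical r and PMI; all
pair dihedrals across the di-, tri- and tetramethyl ensembles stay within the
±60° imposed by the cage. External (e.g. DFT) energies can replace the
force-field ones via `bvstereo populate --energies energies.csv` (columns
`barcode,energy,unit`; unit kJ/mol, kcal/mol or Hartree).

The same pipeline is available as a library:

```python
from bvstereo import SubstituentSet, count_isomers, build_isomer, all_pairs_ev

me2 = SubstituentSet.from_spec(["C:2"])
count_isomers(me2)                        # 15
st = build_isomer("0000100100", me2).best
all_pairs_ev(st)[0].r                     # 2.51 (Å, beta-beta' distance)
```

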