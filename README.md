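# helichir

Quantifying the **sign and magnitude of helical chirality** — for protein
backbones and for helix-like supramolecular assemblies such as
diphenylalanine (FF) peptide nanotubes.

Deciding whether a helical structure is right- or left-handed, and *how
chiral* it is, matters in structural biology and bionanotechnology: the two
FF enantiomers (L-FF, D-FF) self-assemble into nanotubes of opposite twist
(enantiomorphic space groups P6₁/P6₅) with different packing and kinetics.
`helichir` computes a pseudoscalar chirality measure built from scalar
triple products of consecutive vectors and classifies the handedness from
its sign.

## The measure

For three vectors the scalar triple product ([**a**, **b**], **c**) is the
determinant of the 3×3 matrix with rows **a**, **b**, **c**. It is
invariant under proper rotations and changes sign under mirror reflection —
a natural chirality detector.

**Backbone mode.** For a polypeptide helix with *n* residues, build the
*n* − 1 difference vectors **v**ᵢ between consecutive Cα atoms and sum over
the *n* − 3 consecutive triples:

χ_total = Σᵢ ([**v**ᵢ, **v**ᵢ₊₁], **v**ᵢ₊₂)   (Å³)

**Dipole mode.** For one turn ("coil") of a helix-like supramolecular
assembly — six FF molecules per turn in an FF nanotube — take the molecular
dipole-moment vectors **D**ᵢ (Debye), anchored at each molecule's center of
mass, in helix traversal order, and sum over the *n* − 2 consecutive
triples:

c_total = Σᵢ ([**D**ᵢ, **D**ᵢ₊₁], **D**ᵢ₊₂)   (Debye³)

Normalizing by the cube of the mean dipole magnitude
D_av = (1/n) Σ |**D**ᵢ| gives the dimensionless, method-independent

c_norm = c_total / D_av³

Positive c_total (or χ_total) ⇒ right-handed twist, symbol **D**; negative
⇒ left-handed, symbol **L**.

The package bundles the published PM3 (restricted Hartree–Fock) and Amber
per-molecule dipole tables for one coil of the L-FF and D-FF nanotubes as
TSV fixtures, plus generators for ideal dipole rosettes and Cα helices so
every test runs without downloads.

## Worked example

```sh
$ helichir dipoles src/helichir/fixtures/lff_pm3.tsv
structure:  L-FF (PM3-RHF)
molecules:  6 (triple-product terms: 4)
c_total:    16035.28 Debye^3
D_av:       22.728 Debye
D_coil:     70.851 Debye
c_norm:     1.37
sign:       positive
handedness: right
symbol:     D
```

Reading: the six PM3 dipoles of one L-FF coil give a positive chirality sum
of ≈1.60 × 10⁴ Debye³ over the four consecutive triples, so the nanotube is
right-handed (symbol D) even though it is built from "left-handed" L-FF
molecules — the chirality sign alternates between hierarchical levels. The
mean molecular dipole is 22.73 D; the coil's total dipole (70.85 D) points
almost along the tube axis because the in-plane components of the six
dipoles, each rotated ~60° from its neighbor, nearly cancel. The normalized
measure c_norm = 1.37 is dimensionless; running the same command on the
Amber table (`lff_amber.tsv`) gives 1.32, within ~4 % — the measure barely
depends on how the dipoles were computed. The D-FF tables give negative
values (−1.23 PM3, −1.16 Amber): the mirror-image nanotube is left-handed,
and its smaller |c_norm| indicates a slightly tighter twist.

Other entry points: `helichir backbone` (χ_total of a PDB/mmCIF Cα trace),
`helichir structure-dipoles` (point-charge dipole table from a structure +
PQR charges — an estimator *not* equivalent to quantum-chemical dipoles),
`helichir synth` (seeded synthetic rosettes/helices), `helichir fixtures`
(list or copy the bundled tables). The same functionality is available from
Python via `helichir.full_dipole_analysis`, `helichir.chi_total_backbone`,
etc.

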