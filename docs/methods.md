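# Methods

## The chirality measure

The package computes a pseudoscalar handedness measure for helical
structures from scalar triple products of consecutive vectors.

For an ordered sequence of vectors u₁ … u_m the measure is

S = Σ_{i=1}^{m-2} det[uᵢ; uᵢ₊₁; uᵢ₊₂],

the sum of 3×3 determinants of consecutive vector triples, with **no
wrap-around term**: the triple (u_{m-1}, u_m, u₁) is never included.
Recomputing the published coil results from the published per-molecule
tables confirms that exactly m − 2 = 4 triples of the 6-molecule coil enter
the sum; adding periodic closure terms does not reproduce them.

Two vector sequences are supported:

* **Backbone mode** (`chi_total_backbone`): uᵢ are the n − 1 difference
  vectors between consecutive Cα positions of an n-residue chain, so there
  are n − 3 terms and the result χ_total is in Å³. At least 4 residues are
  required.
* **Dipole mode** (`c_total_dipoles` / `full_dipole_analysis`): uᵢ are the
  molecular dipole-moment vectors of the n molecules of one helical turn,
  in traversal order, giving n − 2 terms and c_total in Debye³. At least 3
  molecules are required. The published formulation is written for the
  6-molecule diphenylalanine coil; the implementation accepts any n ≥ 3 and
  generalizes the 1/6 in the mean magnitude to 1/n, since nothing in the
  construction is specific to n = 6.

Sign convention: S > 0 ⇒ right-handed (symbol D), S < 0 ⇒ left-handed
(symbol L). S = 0 is classified *indeterminate* rather than arbitrarily
assigned, because the sign convention is undefined at zero (a mirror
symmetric, i.e. achiral, arrangement).

**Normalization.** Dipole-mode results are normalized to the dimensionless

c_norm = c_total / D_av³,  D_av = (1/n) Σᵢ |Dᵢ|.

D_av is the **mean of the per-molecule magnitudes**, not the magnitude of
the mean vector. The two differ greatly for a coil (the in-plane components
nearly cancel around a turn), and only the mean-of-magnitudes choice
reproduces the published normalized values from the published tables; the
componentwise means are reported separately in `CoilSummary`.

**Ordering is a semantic input.** Reversing the traversal order flips the
sign of S (each determinant's rows reverse, an odd permutation per term
after reindexing), so the caller — or the structure pipeline below — must
supply vectors in helix traversal order. The core never re-sorts.

## Units and numerical contracts

Vectors carry a unit tag (Debye, Å, or dimensionless) and a computation
refuses to mix units. Dipole magnitudes stored alongside components must
agree with the component norm to 1e−9 relative; published (printed,
3-decimal) magnitude columns are treated as advisory on input, recomputed,
and flagged with a warning when they disagree beyond 0.002 Debye — the
printed-rounding worst case. The bundled D-FF PM3 table contains two such
rows (i = 2 and i = 4, the latter off by 0.38 Debye); the recomputed
magnitudes are the ones that reproduce the published normalized chirality,
which is why recomputation, not the printed column, is authoritative.

Internal identities (rotation invariance, parity, scaling) are tested at
1e−9–1e−12 relative tolerance; reproduction of printed tables uses 0.1%
relative tolerance for c_total (its inputs are printed to 3 decimals) and
printed-precision rounding (2 decimals) for c_norm.

## Structure pipeline

For assemblies given as atomic structures (PDB/mmCIF, parsed with gemmi):

1. **Partition** into molecules by chain, by fixed-size residue blocks, or
   by single-linkage distance clustering with a bond-length cutoff
   (default 2.0 Å). Exactly-coincident atom positions make
   distance-clustering ambiguous and raise an error rather than guessing.
2. **Center of mass** per molecule: the standard-atomic-weight-weighted
   mean position. Weights come from gemmi's element table; isotopic
   composition is irrelevant here since the chirality sum uses only dipole
   vectors, and small mass changes shift centers of mass but not the
   dipole components themselves.
3. **Point-charge dipole** (optional): D = Σ qⱼ (rⱼ − r_ref) over partial
   charges from a PQR file, converted with 1 e·Å = 4.80320 Debye. Charges
   are never guessed from the element — silently invented charges would
   make dipoles non-reproducible. This classical estimator is *not*
   equivalent to the quantum-chemical (PM3) or force-field (Amber) dipoles
   of the published tables and is tagged `point-charge` in all output; for
   net-neutral molecules it is independent of the reference point.
4. **Traversal order**: molecules are ordered by ascending azimuthal angle
   of their centers of mass about the coil axis, starting from the molecule
   with the lowest axial coordinate. The axis for ordering is the normal of
   the best-fit plane of the centers of mass (smallest principal
   component), which is order-independent and correct for single-turn
   arrangements, where the molecules spread around the axis far more than
   they rise along it.

**Helix-parameter fit** (`fit_helix_params`): given ≥ 4 ordered points
(e.g. dipole origins), the axis is refined by least-squares cylinder
fitting — minimizing the spread of point-to-axis distances over axis
orientations — started from two seeds: the mean consecutive displacement
(whose tangential parts cancel over whole turns, leaving the axial
direction) and the smallest principal component of the point cloud. The
lower-residual solution wins; one seed alone fails on flat clouds (for a
single short helix the radial variance exceeds the axial variance, so a
principal direction is in-plane) and the other on many-turn helices.
Radius is the mean point-to-axis distance; pitch is the mean per-point
axial rise times the points-per-turn inferred from the mean azimuthal
step. Residuals (radius RMS, rise and azimuthal-step spread) are reported.
Collinear points, planar points (rise below 1e−6 of the radius) and
non-winding points raise degenerate-fit errors.

## Synthetic generators

The generators produce the idealized geometry the measure was designed
for, with all defaults at the published coil's conditions:

* **Dipole rosette** (`make_dipole_rosette`): n = 6 molecules per turn, the
  dipole of each next molecule rotated by 360/n = 60° in the XOY plane,
  in-plane magnitude 19 Debye, axial component −12 Debye (the approximate
  decomposition of the published ~22.7 Debye molecular dipoles), origins on
  a helix of radius 8.15 Å and pitch 5.456 Å — the fitted geometry of the
  published L-FF dipole origins. For the ideal rosette the chirality sum
  has the closed form c_total = (n−2)·z·m²·(2 sin Δ − sin 2Δ) with signed
  azimuthal step Δ, used as an independent oracle in tests.
* **Cα helix** (`make_calpha_helix`): circular helix with α-helix-like
  defaults (radius 2.3 Å, rise 1.5 Å per residue, 3.6 residues per turn),
  serializable as a minimal PDB.
* **Molecular coil** (`make_molecular_coil`): 6 × 43-atom random compact
  clusters on a helix, optionally with exactly-neutral random partial
  charges — scaffolding for the partition/center-of-mass/dipole pipeline,
  with no attempt at realistic chemistry or hydrogen bonding.

**Handedness convention.** For Cα helices, "right" is the ordinary
right-handed screw (azimuth increasing counterclockwise viewed from +z as z
rises), which makes χ_total positive. For dipole rosettes, "right" labels
the arrangement whose chirality sum is positive under the published L-FF
pattern (axial dipole component negative): this requires the dipole azimuth
to *decrease* by 60° per molecule — as the published L-FF table itself
shows — so the generator uses step −360/n for "right" and +360/n for
"left". Both conventions are asserted by tests, not assumed.

Noise, where requested, is isotropic per-component Gaussian with a seeded
generator; identical spec + seed gives bit-identical output.

**What the synthetic data does not emulate:** conformational variation of
real molecules, anharmonic displacements, hydrogen-bond networks, or
method-dependent dipole errors. Passing tests on synthetic data therefore
demonstrate the correctness and invariances of the *measure*, not the
accuracy of any dipole-computation method; accuracy against real
structures is exercised only through the published tables.

## Known limitations and open choices

* The published center-of-mass example for molecule 1 of the L-FF coil
  presupposes a coordinate frame and molecule indexing of the underlying
  crystallographic model that is not bundled here; it is not reproduced.
* Whether long nanotubes should be scored per coil or averaged over coils
  is left to the caller: the measure is computed per supplied vector
  sequence.
* The TSV reader accepts the Unicode minus sign (U+2212) because published
  tables use it; output always uses the ASCII hyphen.
* File-format parsing is delegated to gemmi (PDB/mmCIF) and pandas (TSV);
  PQR is parsed directly (whitespace-separated, charge and radius in place
  of occupancy/B-factor). No crystallographic symmetry expansion is
  performed — input models must already contain the full coil.
* Problem sizes throughout the suite are the published ones (6-molecule
  coils, 10–12-point helices, 258-atom assemblies); the mathematics is
  O(n) in the number of vectors and needs nothing larger.
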