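# Methods

This note records the models, algorithms, parameter choices and limitations
behind `molkernel`, at the level of detail a user needs to judge what the
package computes and what its tests demonstrate.

## Structures and molecule partitioning

Crystals are periodic cells (row-vector lattice, Cartesian Å coordinates).
Before any kernel work, atoms are partitioned into molecule copies by
covalent connectivity under periodic boundary conditions: a bond exists when
an interatomic distance (over all relevant lattice images) is below the sum
of covalent radii plus a tolerance (default 0.4 Å, configurable).  Each
connected group is unwrapped across cell boundaries so molecules are
geometrically intact, then reindexed against the reference molecule by
element-preserving graph isomorphism.  When the bond graph has automorphisms
there are several valid reindexings; the one whose coordinates best
superpose (O(3) Kabsch RMSD) onto the reference conformation is chosen, with
a lexicographic tie-break for exact ties.  Any residual ambiguity between
*geometrically equivalent* reindexings is handled downstream by the mapping
set Q, over which the adapted kernel averages.  Molecule copies are ordered
by cell-folded centroid so partitions are deterministic under input atom
permutations.

Z′ is the number of molecules per asymmetric unit; for P1 inputs (including
everything the synthetic generator produces) the asymmetric unit is the full
cell.  Environments and kernels use one copy of the asymmetric unit per
molecule index — symmetry copies would contribute identical comparisons, so
the per-copy factors s, t of the kernel formulas are set to one.

## Analogous-atom mappings

The mapping set Q contains the atom permutations induced by molecular
point-group operations: element-preserving automorphisms of the bond graph
that are *geometrically realized*, i.e. best-fit superposition of the
permuted reference coordinates onto the originals (proper or improper
rotations allowed) gives RMSD below a tolerance.  The default tolerance is
0.1 Å — loose enough to absorb coordinate noise in relaxed geometries,
tight enough that no distance is distorted by more than ~0.2 Å.  Distinct
operators inducing the same permutation collapse to one mapping (the kernel
depends only on the permutation).  Mappings are computed from a single
reference conformation; this is sound for rigid or asymmetric molecules,
which is the package's supported domain.  Flexible *symmetric* molecules,
whose mapping sets would require a direct-product construction over
conformers, are out of scope, and structure sets mixing Z′ values with a
symmetric molecule are refused for the adapted kernel because positive
semidefiniteness is not guaranteed there.

## SOAP descriptor

Each atomic environment is the sum of Gaussian densities (width
`sigma_atom`, default 0.5 Å) of all neighbors within `r_cut`, including
periodic images and the central atom itself, one channel per species.
Neighbors are found by explicit supercell replication sized from the
reciprocal-lattice perpendicular widths, so arbitrarily skewed or small
cells are handled exactly.

The density is expanded in real spherical harmonics (l ≤ `l_max`) and an
orthonormal radial basis: Gaussian primitives equispaced on [0, r_cut] with
width equal to their spacing, symmetrically (Löwdin) orthonormalized under
the r² measure.  Radial integrals use fixed Gauss–Legendre quadrature (100
points).  The angular part of a displaced Gaussian has a closed form in
modified spherical Bessel functions; the implementation uses exponentially
scaled Bessel functions so no argument overflows at any neighbor distance.
The tests verify these coefficients to ~1e-14 against an independent oracle
that integrates the density numerically on an angular quadrature grid.

The rotation-invariant power spectrum contracts coefficients over m with the
standard π√(8/(2l+1)) prefactor and is stored as a flat vector ordered by
(species pair α ≤ β, b₁, b₂, l); cross terms carry √2 so the plain dot
product equals the full double sum.  Defaults `n_max=8`, `l_max=6`; the
tests and shipped examples use reduced sizes (n_max 3–4, l_max 2–3) that
keep runtimes in seconds while exercising every code path — kernel *values*
depend on these parameters, but every property the tests assert
(invariances, PSD, oracle agreement, planted-signal recovery) holds at any
basis size.  Cutoff radii of 4–10 Å are typical for molecular crystals;
4 Å (roughly first-neighbor shells) is the default in the examples.

## Global kernels

The average kernel is the mean local kernel over all atom pairs between the
compared cell contents.  The adapted kernel restricts comparisons to
analogous atoms: for each mapping q, K_q(A,B) sums k(A_{a,i}, B_{b,q(i)})
over the S×T molecule-copy pairs and the N intramolecular indices, divided
by N·S·T; the kernel is the mean of K_q over Q.  The mean over the group —
rather than the maximum over mappings — is what preserves positive
semidefiniteness.  Matrices are built from per-structure molecule-summed
spectra (an exact algebraic regrouping, verified against explicit
enumeration to 1e-10 in the tests), the upper triangle is mirrored for exact
symmetry, and normalization divides by the geometric mean of the
self-similarities once, on the final operator-averaged matrix — the operator
average is defined on raw kernels, so normalizing last is the consistent
order.

## Generalized convex hull

kPCA double-centers the normalized kernel and eigendecomposes; coordinates
are eigenvectors scaled by √eigenvalue, so their Gram matrix reproduces the
centered kernel (asserted to 1e-8).  Eigenvalues below 1e-12·λ_max are
treated as numerical zeros and dropped; anything more negative than
−1e-8·λ_max raises, since it signals an invalid kernel.  Components are
defined only up to sign; every downstream result is sign-invariant and the
tests flip signs to prove it.

The hull is built in (d descriptors, energy) space with raw kPCA coordinates
and energies in kJ/mol — no rescaling; results depend on this convention and
it is recorded here deliberately.  Lower facets are those whose outward
normal has energy component < −1e-12 (vertical facets excluded), and the
lower envelope at any descriptor point is the maximum over lower-facet
hyperplanes.  Dressed energy = energy − envelope, clipped to zero below
1e-9 to absorb float noise; the facet route is verified against a
linear-programming lower-envelope oracle on random instances.  Affinely
degenerate descriptor geometry falls back to the spanned subspace with a
warning; zero descriptor spread reduces the envelope to the constant global
minimum.

Candidate pools take the *smallest dressed-energy window containing all
known polymorphs*; boundary ties are included (≤).  Baselines: the
energy-cutoff pool (window above the global minimum) and the energy-density
pool (same hull machinery with density — or any user-supplied intuitive
descriptor — as the single coordinate).

Energy-noise resampling adds i.i.d. noise uniform on [−σ√3, +σ√3] to every
energy per iteration — the unique uniform distribution centered at zero
with standard deviation σ — rebuilds the hull and pool, and records pool
sizes (default 250 iterations).  Descriptors are computed once: energies do
not enter the kernel, so the embedding is noise-independent.  One seeded
generator draws one array per iteration in fixed order, making runs bitwise
reproducible.  Ensembles are compared by the two-sided, tie-corrected
Mann–Whitney U test; known-structure rankings (dressed energy vs relative
energy) by Kendall's τ.

## Descriptor interpretability

Density relationships are scored by ordinary-least-squares R² of density
against each of the first 32 kPCA components singly, reporting the best
(equivalently squared Pearson correlation, hence sign-invariant).
Categorical relationships use a linear soft-margin SVC over either each
single component of the first 32 or every nonempty subset of the top 5, with
C ∈ {0.01, 0.1, 1, 10, 100}, scored by balanced accuracy under stratified
5-fold cross-validation.  Cross-validation is a deliberate choice where an
in-sample protocol would also have been defensible; CV avoids rewarding
overfit single-component models, and the protocol is fixed and reported so
numbers are comparable across kernels.  Torsion classes assign class 1 when
the absolute molecule-averaged dihedral is ≥ 90° (averaging over asymmetric
unit copies when Z′ > 1; the boundary counts as class 1).  An approximate
geometric hydrogen-bond detector (H···A < 2.5 Å, D–H···A > 120°,
intermolecular, periodic images included) is provided for convenience;
motif-based assignments should be supplied as input data when available.

## Gaussian process regression

The normalized kernel is the prior covariance; there are no kernel
hyperparameters to fit.  Targets are energies relative to the training
pool's minimum, recomputed whenever the pool changes; the prior mean is zero
on that scale (a constant-mean alternative is available via `prior_mean`).
Observation noise α defaults to 1e-6 (kJ/mol)² — effectively a numerical
jitter; users with noisy energies should raise it.  Fitting is a Cholesky
solve of (K + αI)w = y; prediction is the cross-kernel block times w, both
verified against direct linear algebra.  The learning-curve protocol draws a
fixed random test set, grows the training set in random disjoint blocks, and
reports RMSE/MAE per cumulative size; k-fold cross-validation re-references
energies to each training fold's minimum.  Energy-window subsetting (keep
structures within W kJ/mol of the global minimum) serves both low-energy
evaluation and preprocessing against unphysical structures; the threshold is
user-set.

## Synthetic landscapes

The generator packs rigid copies of a template molecule into cubic P1 cells
whose volume is set from a target density drawn uniformly from
`density_range`, with small random rotations (orientation jitter, default
σ = 10°) and center offsets, resampled until all intermolecular contacts
clear 2.0 Å.  Templates: a bent C–N–O triatomic (C1, Q = 1), a water-like
OH₂ (Q = 2), a square-planar CO₄ toy (Q = 8), and a 4-atom C–N–O–F chain
with a rotatable terminal torsion (Q = 1) — the chain exists because a
dihedral needs four atoms, making planted conformational classes possible.
Energies follow a declared functional form: e₀ + a·ρ + optional smooth
sine term in ρ + optional torsion term + Gaussian noise.  Defaults:
a = −30 kJ/mol per g/cm³ (denser packings bind more strongly), noise σ =
1 kJ/mol (comparable to random errors in computed lattice energies),
densities 0.35–0.85 g/cm³ (loose toy packings; the small molecules cannot
pack to organic-crystal densities without clashes).  The sine term (off by
default) gives regression tasks short-scale structure so learning curves
are informative rather than instantly saturated.

These landscapes are *not* CSP minima: there is no force field, no energy
minimization, no polymorph-like basin structure, and density is the dominant
planted degree of freedom.  Passing tests therefore demonstrate the
correctness of the machinery — kernels, hulls, pools, regressions and their
statistical properties — not the empirical performance of any kernel on
real CSP landscapes, which depends on data the package consumes as input.

## Known limitations

* Mapping detection assumes a rigid (or asymmetric) molecule; flexible
  symmetric molecules are unsupported.
* Hull results depend on the unscaled (descriptor, energy) convention and on
  the hull dimensionality d; both must be reported with any result.
* The SVC accuracy protocol (stratified 5-fold CV) is one of several
  defensible choices; absolute accuracies are protocol-dependent.
* SOAP basis-size parameters (`n_max`, `l_max`, `sigma_atom`) change kernel
  values; comparisons are only meaningful at fixed parameters, which the
  kernel files record as a provenance hash.
* CIF input is symmetry-expanded to P1 on read; space-group information is
  not retained.
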