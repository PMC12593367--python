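# molkernel

Similarity kernels and landscape analysis for molecular crystal structure
prediction (CSP).

CSP methods overpredict: a search for the crystal structures of one molecule
returns thousands of local lattice-energy minima, of which only a handful are
ever observed.  `molkernel` implements a physically motivated structure
similarity — the **analogous-atom (adapted) SOAP kernel** — and the analysis
stack built on it for narrowing prediction sets and predicting lattice
energies:

* per-atom **SOAP** power spectra and local kernels;
* global **average** and **adapted** kernels with normalization and PSD
  checking;
* **kernel PCA** descriptors and the **generalized convex hull (GCH)**:
  dressed energies, candidate pools, energy-cutoff and energy-density
  baselines, energy-noise resampling, Mann–Whitney and Kendall-τ comparisons;
* descriptor **interpretability** scores (density R², torsion/H-bond class
  SVC balanced accuracy);
* **Gaussian process regression** of lattice energies with the precomputed
  kernel as prior covariance;
* a **synthetic-landscape generator** that plants controlled
  density–descriptor, conformation–class and energy–structure relationships
  so the whole pipeline is testable offline.

## The model

The local similarity of two atomic environments is the dot product of their
SOAP power spectra, k(A_i, B_j) = ρ(A_i)·ρ(B_j), with

ρ(x)_{b₁b₂l}^{αβ} = π √(8/(2l+1)) Σ_m (c_{b₁lm}^α)† c_{b₂lm}^β,

where c^s_{blm} expand the Gaussian-smeared density of species *s* within a
cutoff radius in an orthonormal radial basis and spherical harmonics.

A conventional global kernel averages k over *all* atom pairs between two
cells — including pairs that occupy chemically incomparable intramolecular
positions.  The adapted kernel only compares **analogous atoms**: atoms with
the same intramolecular index up to a molecular point-group operation.  For
each atom mapping q in the molecular point group (Q operations in total),

K_q(A,B) = 1/(N·S·T) Σ_{a∈A} Σ_{b∈B} Σ_i k(A_{a,i}, B_{b,q(i)}),

with N the molecule size and S, T the Z′ of the two structures, and the
final kernel is the *mean* over the Q mappings — averaging (not maximizing)
keeps the kernel positive semidefinite on sets of consistent Z′ and on any
set whose molecule is asymmetric.  Kernel matrices are normalized so
self-similarities equal one.

Downstream, kPCA of the centered kernel yields descriptor coordinates; a
convex hull over (descriptors, energy) assigns each structure a *dressed
energy* (height above the lower hull envelope), and the *candidate pool* is
the smallest dressed-energy window containing all known polymorphs.  GPR
solves (K + αI)w = y on energies relative to the training-set minimum and
predicts via the cross-kernel block.

## Worked example

`examples/04_descriptor_interpretability.py` generates two synthetic
landscapes, builds adapted kernels, and scores descriptor interpretability:

```
density vs kPCA: best R^2 = 0.963 on component 1
torsion classes: balanced accuracy 1.000 from component 1 (C = 100.0)
```

The first line says the top machine-learned descriptor of the
density-driven landscape is almost a linear readout of crystal density
(R² = 0.963), so a density-coupled constraint (e.g. pressure) would act
along that descriptor.  The second line says a linear SVC separates the two
planted torsional conformers perfectly from a single kPCA component — the
kernel sees molecular conformation.  The other examples cover symmetry
mappings (`01`), kernel construction and PSD checks (`02`), GCH candidate
pools with noise resampling (`03`), and GPR learning curves (`05`); each
prints a short explanation with its numbers.

A thin CLI wraps the same workflows:

```sh
molkernel synth --out land/ --n 40 --seed 1
molkernel kernel --config config.yaml --structures land/ --type adapted --out K.npz
molkernel gch --kernel K.npz --properties land/properties.csv \
    --known s0003,s0017 --dim 1 --noise-sd 0.5 --out gch.json
```

## Scope

The package analyzes *given* structure sets.  It does not generate CSP
trial structures, compute force-field or DFT lattice energies, match
predictions to experimental polymorphs, or handle flexible symmetric
molecules (mapping sets are derived from a single reference conformation).
See `docs/methods.md` for the model details, parameter choices, and
limitations.
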