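"""Find the analogous-atom mappings of a molecule.

Atoms related by a molecular point-group operation are interchangeable when
comparing crystal structures; the mapping set Q enumerates those atom
permutations.  An asymmetric molecule has only the identity (Q = 1); the
square-planar AB4 toy has the 8 operations of C4v acting on its four B atoms.
"""
from molkernel import find_mappings, make_molecule, verify_closure

for template in ("asymmetric_triatomic", "symmetric_AB2", "square_AB4"):
    mol = make_molecule(template)
    mset = find_mappings(mol)
    print(f"{template}: {''.join(mol.elements)}  Q = {mset.Q}  "
          f"closed group: {verify_closure(mset)}")
    for m in mset.mappings:
        print("   ", m.perm)

# Q counts the valid ways to line up intramolecular atom indices between two
# crystals of the same molecule; the adapted kernel averages over all of them.
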