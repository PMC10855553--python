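"""Binding-pocket definition and pocket RMSD on a ligand-bearing toy.

Generates a toy native carrying a 4-atom HETATM ligand, perturbs it into a
'model', selects the pocket residues (any atom within 4.0 A of the ligand in
the reference) and reports the all-atom pocket RMSD after superposition.
"""

import numpy as np

from ensavg import (Structure, ToySpec, lddt, make_toy_native,
                    pocket_residues, pocket_rmsd)

native = make_toy_native(ToySpec(n_residues=20, geometry="pocket_toy", seed=11))
ligand = Structure([a for a in native.atoms if a.is_hetero], "ligand")
print(f"toy native: {len(native)} atoms incl. {len(ligand)} ligand atoms")

pocket = pocket_residues(native, ligand, cutoff=4.0)
print(f"pocket residues (<= 4.0 A of any ligand atom): "
      f"{sorted(int(r) for _, r in pocket)}")

rng = np.random.default_rng(5)
model = native.with_coords(native.coords + rng.normal(scale=0.6,
                                                      size=(len(native), 3)))
print(f"model pocket RMSD: {pocket_rmsd(model, native, pocket):.2f} A "
      f"(all pocket atoms, after least-squares superposition)")
print(f"model global lDDT: {lddt(model, native):.3f}")
print("the pocket RMSD isolates how well the ligand-contacting residues are")
print("reproduced, independent of the rest of the chain")
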