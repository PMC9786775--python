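"""Permeant descriptors: why the methyl-ester prodrug crosses more easily.

Prints donor/acceptor counts, rotatable bonds, Ertl TPSA and molecular
weight for 5-aminolevulinic acid and its methyl ester.  The ester swaps
the acid O-H (20.23 A^2 fragment) for a bridging O (9.23 A^2), losing
one H-bond donor and exactly 11 A^2 of polar surface — the structural
change that weakens its anchoring in the polar lipid headgroups.
"""

from permeapath.descriptors import compute_descriptors, five_ala, methyl_five_ala

for mol in (five_ala(), methyl_five_ala()):
    d = compute_descriptors(mol)
    print(f"{mol.name:8s} donors={d.hbond_donors}  acceptors={d.hbond_acceptors}  "
          f"rotatable={d.rotatable_bonds}  TPSA={d.tpsa:.1f} A^2  "
          f"MW={d.molecular_weight:.2f} g/mol")
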