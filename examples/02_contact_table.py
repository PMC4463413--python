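"""Measure the labelled loop-contact distance table on a bound complex.

Builds the synthetic closed-state oxamate/cofactor complex (its planted
geometry reproduces the closed-state contact distances) and measures each
labelled atom-pair distance.  On real data the same call takes a parsed PDB
entry and a criteria config.
"""

from pose_triage import measure_contact_table
from pose_triage.synthetic_data import make_reference_complex

for kind in ("oxamate", "88N"):
    structure, table, expected = make_reference_complex(kind, seed=1)
    frame = measure_contact_table(structure, "A", table)
    print(f"\n{kind} complex ({structure.id}):")
    print(frame[["label", "receptor_atom", "ligand_atom", "distance_A"]].to_string(index=False))

print(
    "\nEach row is one closed-state loop interaction: hydrogen bonds sit below "
    "3.5 Å, hydrophobic and charged-group contacts below 4.5 Å. These distances "
    "are the selection criteria the screening funnel tests candidate poses against."
)
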