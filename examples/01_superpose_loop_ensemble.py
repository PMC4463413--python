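"""Superpose a loop-conformer ensemble and report loop Cα RMSDs.

Builds a small Cα-trace ensemble in which the mobile loop (residues 96-111)
of each conformer is displaced from the reference by a known amount, fits
every conformer to the reference on the non-loop Cα atoms, and reports the
loop RMSDs.  The same call works on parsed crystal-structure subunits.
"""

from pose_triage import ensemble_loop_analysis
from pose_triage.synthetic_data import make_open_loop_pair

reference, conformers, expected, fit_sel, report_sel = make_open_loop_pair(seed=1)
report = ensemble_loop_analysis(
    [(c, "A") for c in conformers], (reference, "A"), fit_sel, report_sel
)

for label, value in zip(report.labels, report.rmsd_to_reference):
    print(f"{label}: loop RMSD to reference = {value:.2f} Å")
print("pairwise loop RMSD matrix (Å):")
print(report.to_frame().to_string())
print(
    f"\nThe two open conformers differ by {report.pairwise[0, 1]:.2f} Å over the "
    "16 loop Cα atoms — the planted open-state variability. Values near 2 Å "
    "mean the loop adopts visibly different open arrangements, which is why a "
    "closed-state receptor is the safer docking template."
)
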