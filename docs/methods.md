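# Methods

## The problem

Human lactate dehydrogenase A binds NADH, then pyruvate; the Arg168 side
chain anchors the substrate carboxylate with a bidentate pair of hydrogen
bonds, and the mobile loop 96–111 closes over the site, adding contacts
through Ala97, Arg98, Gln99 and Arg105 that stabilise the transition state.
Substrate-competitive inhibitors are expected to reproduce the Arg168 anchor
and at least some loop contacts. `pose-triage` turns that expectation into an
auditable geometric procedure applied to docked poses: it never docks, scores
or minimises — it measures.

## Superposition and ensemble analysis

`kabsch_fit` computes the proper rigid motion minimising RMSD between paired
point sets via the SVD of the cross-covariance of the centred coordinates.
When the optimal orthogonal matrix is a reflection, the sign of the singular
vector of the smallest singular value is flipped (the standard determinant
correction), so the result is always a rotation. Degenerate inputs (fewer
than 3 points, length mismatch) are rejected. The test suite checks the fit
against an independent numerical minimiser over rotation vectors
(Nelder–Mead with multi-start; translation eliminated in closed form by
centroid alignment) to 1e-6 on random instances of up to 10 points.

`ensemble_loop_analysis` fits each subunit *independently* onto one common
reference — not onto each other — using the atoms of a fit selector
(typically all Cα common to subunit and reference), then reports RMSD over a
report selector (typically loop 96–111 Cα). Atom correspondence is by author
residue number, insertion code and atom name; subunits are identical chains,
so no sequence alignment is attempted. Missing residues reduce each
comparison to the pairwise-common subset, which is logged; a subunit sharing
fewer than 3 fit atoms is recorded as an error, not raised. The pairwise
matrix built this way is symmetric with a zero diagonal, but because the fits
are independent it need not obey the triangle inequality; that property is
documented, not asserted.

## Interaction detection

All default criteria are heavy-atom distance criteria, because crystal
structures and most docking outputs carry no hydrogens:

| kind          | pair                                  | default cutoff |
|---------------|---------------------------------------|---------------|
| hydrogen bond | N/O ··· N/O                           | 3.5 Å |
| hydrophobic   | non-polar C ··· non-polar C           | 4.5 Å |
| electrostatic | charged-group atoms, opposite signs   | 4.5 Å |

The defaults are the smallest round conventional values that admit every
contact of the closed-state reference complexes (hydrogen bonds up to
3.14 Å, hydrophobic contacts 3.56–4.45 Å, the electrostatic contact at
4.0 Å). Every criterion may override its cutoff in the criteria table. No
donor/acceptor distinction and no angle term is applied by default; with
heavy-atom coordinates neither is resolvable.

Ligand chemical roles are resolved from geometry-inferred connectivity
(heavy-atom pairs within 1.8 Å, 2.0 Å when P or S is involved): a
carboxylate is a carbon with two oxygens whose only heavy neighbour is that
carbon; non-polar carbons have no bonded N/O; phosphate means phosphorus and
its bonded oxygens. An atom-name heuristic stands in only when no bond at all
can be inferred (a bare fragment), with a logged warning. Receptor-side
charges come from residue identity (Arg/Lys positive, Asp/Glu negative).

The bidentate ("twin") Arg168 test requires two *distinct* guanidinium
nitrogens (NE/NH1/NH2) each within the hydrogen-bond cutoff of two *distinct*
oxygens of one carboxylate group; a single oxygen bridging both nitrogens
does not qualify, which is what distinguishes the salt-bridge chelation from
a single polar contact. A ligand with no carboxylate fails with the explicit
reason `no carboxylate`, so chemistry failures are distinguishable from
geometric ones downstream.

`fingerprint_pose` marks each criteria-table entry satisfied when any ligand
atom of the entry's role is within its cutoff of the named receptor atom.
The loop-interaction count is the number of distinct satisfied criteria whose
receptor residue lies on the loop — criteria, not atom pairs, so duplicated
ligand atoms cannot inflate it. The count is monotone in every cutoff, and
the whole fingerprint is invariant under a common rigid motion of receptor
and pose; both properties are enforced by property-based tests.

## The screening funnel

Stages run in a fixed order: rule of five → pose intake → Arg168 distance
filtration → bidentate requirement → loop-interaction selection. All
threshold comparisons are inclusive: MW 500 passes, a 4.5 Å carboxyl-carbon
to Arg168-CZ distance passes (the filter discards poses *exceeding* 4.5 Å).
Model 1 (holo receptor, cofactor present) requires at least one satisfied
loop criterion; Model 2 (apo receptor) requires two. Because both the
distance filter and the twin-bond test must pass, the selected set does not
depend on their relative order; only intermediate counts do, and the cheap
distance filter runs first.

A ligand may carry several poses; it passes a geometric stage if any pose
passes that stage and every earlier one, and the reported pose is the best
survivor (lowest Arg168 distance, then highest loop count, then input
order). Rule-of-five descriptors come from SD tags or planted blocks when
present, otherwise from connectivity: molecular weight from standard atomic
masses, logP by the Crippen atom-contribution method, donors as N/O atoms
bearing at least one hydrogen (so water counts 1), acceptors as the classic
nitrogen-plus-oxygen count. The report conserves ligands at every stage
(pass + fail + not-reached = intake), survivor counts are non-increasing,
and with the `reproducible` flag (default) output files are byte-identical
across runs. The final step of a real campaign — expert visual inspection of
the surviving complexes — is deliberately not automated; the report ends at
the loop-criterion stage.

## Synthetic study conditions

The generators stand in for inputs that cannot ship: crystal structures and
a commercial compound library. They emulate exactly the features the
pipeline consumes and nothing else.

* `make_active_site` places Ala97/Arg98/Gln99/Arg105/Arg168 analogs on a
  spread-out layout (interaction centres ≥ 9 Å apart) with ideal planar
  guanidinium groups (C–N 1.33 Å), plus the six-entry criteria table naming
  their probe atoms. The spacing guarantees a ligand atom planted against
  one criterion cannot accidentally satisfy another residue's criterion;
  same-residue ambiguity is removed by pointing planted atoms away from
  sibling criterion atoms.
* `plant_pose` realises requested outcomes by exact construction: the
  carboxylate sits on the guanidinium axis at the requested CZ–C distance,
  chelating (both N···O pairs at CZ–C − 1.25 Å) or turned away (nearest
  N···O ≈ CZ–C), and one probe atom of the right role is placed at
  cutoff − 0.6 Å from each requested criterion atom. Geometry makes some
  combinations impossible — a twin bond beyond CZ–C ≈ 4.75 Å, or *no*
  hydrogen bond below ≈ 3.7 Å — and those raise `InfeasiblePoseError`
  naming the conflict. Every pose is verified by the pipeline's own
  detectors before it is returned.
* `make_reference_complex` builds two bound complexes whose labelled contact
  distances equal the closed-state values of the oxamate/NADH and 88N
  complexes (2.86/2.93 Å Arg105 hydrogen bonds, 3.56–4.45 Å hydrophobic
  contacts, the 4.0 Å guanidinium–phosphate contact, and so on — eleven rows
  in all). Multi-constraint placements use analytic sphere–sphere
  intersections and two-anchor rigid placement of the guanidinium unit; the
  free spin is chosen to maximise clearance from already-placed atoms, and
  the construction self-verifies to 0.005 Å at generation time. Side-chain
  linker atoms between constrained groups are interpolated and only loosely
  ideal; the guanidinium geometry itself is exact.
* `make_loop_ensemble` builds a Cα trace (residues 85–125, seeded 3.8 Å
  random-walk geometry) whose conformers share non-loop atoms exactly, so the
  non-loop fit recovers the identity and the loop RMSD equals the plan in
  closed form: a uniform shift of magnitude d gives RMSD d, per-atom
  magnitudes d_i give sqrt(mean d_i²), and two uniformly shifted conformers
  differ by |v_i − v_j|. The default open-state pair is displaced ±1.045 Å so
  its mutual loop RMSD is 2.09 Å, the planted open-state variability between
  apo subunits.
* `make_library` plants a stage-failure plan. The default 83-compound plan —
  10 rule-of-five failures, 20 Arg168-distance failures (CZ–C planted at
  4.8–6.5 Å), 30 twin-bond failures (carboxylate turned away at 3.8–4.4 Å),
  15 single-loop-contact poses, 8 full passes with 2–4 loop contacts —
  exercises every funnel stage on a library the size of a
  rule-of-five-filtered set of pyruvate/oxamate derivatives. Descriptor
  blocks are planted to straddle each Lipinski boundary (including exact
  boundary values, which pass); SMILES give the records realistic
  connectivity. The manifest records all planted truth and the expected
  survivor counts per model, and the funnel must reproduce it exactly.

All randomness flows from one `numpy` generator seeded explicitly and touches
only nuisance quantities (spin angles, decoy placement, group shuffling,
which loop criteria a pose gets) — never planted distances. A fixed seed
therefore reproduces every structure, pose and manifest byte for byte.

What the fixtures do **not** emulate: real ligand chemistry and flexibility,
crystallographic noise, alternate conformations beyond the single-conformer
altloc policy, water-mediated contacts, and docking-pose error. Passing tests
show the measurement and filtering machinery is correct on geometry whose
ground truth is known, not that any particular docking protocol is accurate.

## Numerical and design notes

* Distances are reported to 2 decimals in tables (the convention for printed
  contact distances); full precision is kept internally.
* Altloc policy: blank or 'A' kept, others dropped. Hydrogens are retained
  when present but all default criteria use heavy atoms only. Waters and
  ions are parsed but excluded from interaction detection. NADH hetero codes
  (NAI/NAD/NDH) are normalised to one label.
* PDB parsing is delegated to gemmi; coordinate columns are pre-validated so
  malformed fields raise an error naming the line instead of being silently
  zero-filled. Only the first MODEL is read. Writing uses a fixed-column
  formatter; round-trips preserve names and coordinates to 3 decimals.
* Ties in best-pose selection break by input order, making reports
  deterministic; report files embed no timestamp by default.
* Problem sizes in the test suite and acceptance script (83-compound
  library, 50 superposition instances, 100 property-test fixtures,
  41-residue Cα traces) were chosen as the smallest sizes that exercise
  every code path and stage of the funnel while keeping the whole suite
  comfortably interactive.

## Known limitations

* No π-stacking, halogen bonds or water-mediated bridges; no energy or
  scoring model of any kind.
* Hydrogen-bond detection without hydrogens cannot distinguish donors from
  acceptors; an N···N pair at 3.4 Å counts even if both nitrogens are
  donors. The optional angle check applies only when explicit hydrogens
  exist.
* Atom correspondence by residue number and name restricts ensemble analysis
  to identical chains (the intended use: subunits of one enzyme).
* mmCIF input, assembly expansion, protonation and tautomer assignment are
  out of scope; upstream tools own those steps.
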