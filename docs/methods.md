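# Methods

## Structure model

A PDB entry is parsed (with gemmi) into a `StructureEnsemble`: an ordered
list of `Model`s, one per `MODEL`/`ENDMDL` block (a file without `MODEL`
records — typically X-ray — yields one model).  Hydrogens are retained,
waters always dropped, other HETATM records and non-standard residues dropped
unless requested: every downstream criterion is defined on protein residues.
Residue identity is `(chain_id, author residue number, insertion code)` with
no renumbering, so residue numbers in reports match the deposition's author
numbering.  Chain roles (which chain is SMN, which is Gemin2) are data
supplied by the caller, never hard-coded.  Alternate locations are resolved
at selection time to the highest-occupancy altloc, first-in-file on ties — a
deterministic rule chosen because the analysed NMR entries carry no altlocs
and any fixed rule is better than an ambiguous result.  If models of an
ensemble disagree in residue topology a warning is recorded on the ensemble
rather than raised, since a partial topology mismatch does not invalidate
per-model detection.

## Salt bridges

Titratable side chains carry charged groups: Asp `{OD1,OD2}` and Glu
`{OE1,OE2}` negative; Lys `{NZ}`, Arg `{NE,NH1,NH2}` and His `{ND1,NE2}`
positive.  The Arg group is the three guanidinium nitrogens (rather than a
CZ-centered definition) so that every member is a nitrogen nucleus; His is
treated as positive at both ring nitrogens with no pKa prediction, because
His–Asp bridges are part of the analysis and protonation assignment is out of
scope.  The group center is the unweighted mean of the member atoms present;
a group whose members are all missing is skipped with a warning, and a group
reduced to one atom centers on that atom.

A bridge exists when two oppositely charged groups of different residues are
within the cutoff (default 4.0 Å, **inclusive** — a pair printed as exactly
4.0 must count).  Two modes are exposed because both conventions appear in
ensemble reports: `group_center` (one bridge per residue pair, center-to-
center distance) and `atom_pair` (one bridge per negative-O/positive-N pair
under the cutoff; the default, since per-atom bridge tables enumerate N–O
pairs).  Scope is `intermolecular` iff the chain identifiers differ.

## Hydrogen bonds

Donors are side-chain heavy atoms with a covalently bound hydrogen — Lys NZ,
Arg NE/NH1/NH2, His ND1/NE2, Trp NE1, Asn ND2, Gln NE2, Ser OG, Thr OG1, Tyr
OH, Cys SG — where covalency is resolved by distance (same residue, D–H
< 1.3 Å) instead of a connectivity dictionary; this is exact for standard
nomenclature and keeps the code independent of residue templates.  Donors
without a resolvable hydrogen (all of them, in a hydrogen-free X-ray model)
are skipped with one summary warning per model.  Acceptors are the side-chain
O/N/S listed per residue type, His ring nitrogens only when unprotonated, and
— by default — the backbone carbonyl O.  The backbone-O inclusion is a
deliberate deviation from a strictly side-chain acceptor set: reported
interface bonds use a backbone carbonyl acceptor, so the default scope is
`sidechain_plus_backbone_O` while `sidechain_only` reproduces the strict
reading.  A bond is emitted iff `d(D,A) ≤ 3.0 Å` and `∠ADH ≤ 30°`, both
inclusive.  ∠ADH is computed at the donor vertex between the D→A and D→H
rays (small angles mean near-linear bonds); the H–A distance is recorded for
reporting only.

## SASA

Per-atom SASA uses the Shrake–Rupley construction: each atom's accessible
sphere (van der Waals radius + 1.4 Å probe) is sampled on a deterministic
golden-section spiral (default 960 points; no random state, so results are
bitwise reproducible), a point is accessible when outside every neighbour's
expanded sphere (neighbours found with a k-d tree), and the atom's area is
the accessible fraction of the sphere area.  Radii follow the
NACCESS/Chothia set — O 1.40, N 1.65, S 1.85, tetrahedral C 1.87,
trigonal/aromatic C (including the backbone carbonyl carbon) 1.76 — because
the intrinsic reference values are NACCESS's; a custom radius function can be
injected.  Hydrogens are excluded from surface and occlusion by default so
hydrogen-bearing NMR models and hydrogen-free X-ray models are comparable.

Residue SASA is the sum over member atoms; ensemble profiles carry mean and
(population) standard deviation over models, and the ratio of the mean to the
packaged intrinsic (standard-state) SASA of the residue type.  A residue is
*buried* when the ratio is strictly below 0.30.  An isolated residue can have
a ratio above 1 because the reference state already includes flanking-residue
occlusion.  The surface algorithm differs from DSSP's, which the original
workflow used as a SASA calculator; on identical radii this implementation
agrees with an independent Shrake–Rupley (Bio.PDB) to well under 2% per
residue, and relative-SASA comparisons at two decimals absorb the remaining
algorithmic difference.

## Ensemble statistics

Per-model detections are pooled per partner identity — the residue pair in
`group_center` mode, (residue pair, atom pair) in `atom_pair` mode, and the
full donor/hydrogen/acceptor triple for hydrogen bonds — into summaries
carrying the detecting model indices, total instance count, and distance mean
± std **over detected instances only**.  A separate per-pair geometry report
covers **all** models whether or not the bond forms in them; both conventions
are needed because an ensemble census ("3 bridges at 3.50 ± 0.23 Å") and a
distribution argument ("8.33 ± 2.55 Å over 32 models") answer different
questions with the same atoms.  Standard deviations are population (ddof 0)
by default and configurable, since deposition reports rarely state their
convention.

## Importance and mutation impact

A residue is potentially important iff its **side chain** joins ≥ 1 detected
interaction in ≥ 1 model, or it is buried on the ensemble-mean ratio.
Salt-bridge participation is always side-chain; a hydrogen bond flags the
donor's residue always, and the acceptor's only when the acceptor atom is not
the backbone O.  The packaged mutation catalogue holds the SMA-linked point
mutations with structural coverage (A2G, D44V, W92S, W102X, A111G, I116F,
E134K, Q136E, G279C, G279V); users may pass their own TSV.  Matching is by
residue number on caller-named chains, with warnings for positions outside
the modelled fragments or wild-type mismatches.

Impact annotation is a pure function of (wild type, mutant, interaction
roles) over a fixed residue-chemistry table: stop → `truncation`; negative →
positive → `charge_reversal_neg_to_pos` (attraction → repulsion); polar donor
→ negative → `charge_reversal_donor_to_neg` (attraction → repulsion); charged
→ uncharged hydrophobic → `charge_removal` (attraction lost); hydrophobic →
Gly/Ser/Ala → `hydrophobic_removal` (no sign change); anything else →
`other`.  Sign changes are asserted only when the wild type actually has
affected interactions.  No energies are estimated — the typology is the
qualitative sign logic only.

## Chemical-shift audit

NMR-STAR v3 assigned-chemical-shift loops are parsed with gemmi's STAR
reader (saveframes included); a simplified `entity/residue/res_type/atom/
shift` TSV dialect is also accepted.  The expected-nuclei table per residue
type contains all side-chain carbons, nitrogens and hydrogens (O and S have
no routinely assigned nuclei) in PDB v3 nomenclature; it is packaged data and
editable, deliberately a superset of any particular "crucial nuclei" choice
so users can restrict it.  The audit reports, per selected residue, every
expected nucleus with no assignment; a per-entity numbering offset reconciles
depositions whose author numbering differs from the structure's.  Adding an
assignment can only shrink the report (monotonicity is property-tested).

## Synthetic fixtures

The generators stand in for deposited inputs in tests and produce text only:

* charged-pair fixtures place an Asp and a Lys/Arg/His partner with group
  centers at an exact target distance (partner templates are recentered so
  the group mean is exactly on target);
* hydrogen-bond fixtures place NZ at the origin, OE1 at the target distance
  on the x-axis and HZ1 at 1 Å from NZ at the exact target ∠ADH; the
  in-memory model is exact, while PDB text (3 decimals) reproduces distances
  to ~1e-3 Å and angles to ~0.05°;
* burial fixtures enclose an alanine in a golden-spiral shell of occluding
  carbons (default radius 6 Å, 150 atoms: fully occluding; a 7.5 Å shell
  occludes partially and exposes density effects);
* ensemble fixtures replicate a base model with seeded isotropic Gaussian
  jitter (`numpy.random.default_rng(seed)`), giving byte-identical output per
  spec — jitter is per-atom and unphysically simple on purpose, since only
  the straddling of cutoffs matters;
* assignment fixtures emit complete expected assignments minus an explicit
  (or seeded random, logged) drop set.

What the fixtures do **not** emulate: realistic covalent geometry, rotamers,
correlated backbone motion, or restraint-driven model spread.  Passing tests
therefore demonstrate the correctness of the criteria, the aggregation and
the bookkeeping — not that any particular biological contact exists; the
checks against the deposited SMN ensembles (run when the published files are
present under `data/pdb/`) cover that ground.

## Numerical choices and limitations

* All cutoff comparisons are inclusive; boundary cases are constructed on
  exactly representable coordinates and tested at 4.0 Å / 3.0 Å / 30°.
* Quadrature: 960 sphere points give < 1% error on an isolated atom and
  < 0.5% total drift on doubling; heavy structures cost O(atoms × neighbours
  × points).
* Degenerate inputs: empty selections return empty lists (not errors);
  zero-assignment files and zero-ATOM files raise format errors; ambiguous
  atom selectors raise.
* The acceptance script's problem sizes (32-model jittered ensembles, a
  150-atom occlusion shell, 960-point quadrature) were chosen as the smallest
  sizes at which the measured quantities are stable to well inside their
  tolerances.
* Known limitations: no pKa/protonation analysis, no π-type interactions or
  C–H···O bonds, no hydrogen placement for hydrogen-free structures (X-ray
  models simply contribute no donors), no mmCIF input, no ΔΔG or
  conservation scoring.
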