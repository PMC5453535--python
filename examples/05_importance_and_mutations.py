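"""Residue importance, mutation cross-reference and impact annotation.

A residue is potentially important if its side chain joins a salt bridge or a
hydrogen bond, or if it is buried (relative SASA < 0.30).  Important residues
are matched against the packaged catalogue of disease-linked SMN point
mutations, and each mutation gets a qualitative electrostatic impact category.
"""

from smnprofiler import (
    annotate_mutation_impact,
    classify_important_residues,
    cross_reference_mutations,
    load_mutation_catalogue,
)
from smnprofiler.ensemble_stats import InteractionSummary
from smnprofiler.sasa import SasaProfile

# A miniature SMN-like scene, stated as data (normally computed from an ensemble):
# Asp44 bridges an interface Arg, Glu134/Gln136 hydrogen-bond Tyr127, Ala111 is buried.
def profile(chain, num, res_type, ratio):
    return SasaProfile(chain_id=chain, number=num, icode="", res_type=res_type,
                       sasa_mean=ratio * 150, sasa_std=0.0, sasa_intrinsic=150,
                       per_model=[ratio * 150])

def bond(kind, a, b, atom_a=None, atom_b=None, h=None, scope="intramolecular"):
    return InteractionSummary(kind=kind, residue_a=a, residue_b=b, atom_a=atom_a,
                              atom_b=atom_b, hydrogen=h, scope=scope,
                              model_indices=[1], n_instances=1,
                              distance_mean=3.2, distance_std=0.1)

profiles = [profile("B", 44, "ASP", 0.72), profile("B", 111, "ALA", 0.01),
            profile("B", 134, "GLU", 0.45), profile("B", 136, "GLN", 0.50),
            profile("B", 50, "SER", 0.90)]
summaries = [
    bond("salt_bridge", "B44Asp", "A213Arg", scope="intermolecular"),
    bond("hydrogen_bond", "B127Tyr", "B134Glu", "OH", "OE1", "HH"),
    bond("hydrogen_bond", "B136Gln", "B127Tyr", "NE2", "OH", "HE21"),
]

records = classify_important_residues(profiles, summaries)
for r in records:
    flags = [name for name, on in [("salt-bridge", r.in_salt_bridge),
                                   ("H-bond", r.in_hydrogen_bond),
                                   ("buried", r.buried)] if on]
    print(f"{r.label}: important={r.important}" + (f" via {', '.join(flags)}" if flags else ""))

# catalogue positions outside this miniature scene (A2G, W92S, ...) warn and
# are skipped; a real run covers the full modelled fragments
import warnings
from smnprofiler import ProfilerWarning

with warnings.catch_warnings():
    warnings.simplefilter("ignore", ProfilerWarning)
    matched = cross_reference_mutations(records, load_mutation_catalogue(),
                                        smn_chains={"B"})
print("\nmutation impacts at important positions:")
for rec in matched:
    for mut in rec.matched_mutations:
        ann = annotate_mutation_impact(mut, summaries)
        print(f"  {mut.label} at {rec.label}: {ann.category} "
              f"({ann.predicted_sign_change})")
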