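"""Detect salt bridges in both modes and summarize them over an ensemble.

A salt bridge is an Asp/Glu carboxylate within 4.0 A of a Lys/Arg/His
positive group.  ``group_center`` mode measures the distance between the two
charged-group centers; ``atom_pair`` mode reports each N-O atom pair under
the cutoff separately, the convention used in per-atom bridge tables.
"""

import tempfile
from pathlib import Path

from smnprofiler import (
    DetectionConfig,
    FixtureSpec,
    make_ensemble_fixture,
    read_multimodel_pdb,
    summarize_interactions,
)

spec = FixtureSpec(kind="ensemble", distance=4.0, n_models=20, jitter_sd=0.35, seed=7)
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "pair.pdb"
    path.write_text(make_ensemble_fixture(spec))
    ensemble = read_multimodel_pdb(path)

for mode in ("group_center", "atom_pair"):
    summaries = summarize_interactions(
        ensemble, DetectionConfig(sb_mode=mode), "salt_bridge")
    print(f"-- {mode} mode --")
    for s in summaries:
        atoms = f" [{s.atom_a}-{s.atom_b}]" if s.atom_a else ""
        print(f"{s.residue_a} / {s.residue_b}{atoms}: detected in "
              f"{s.n_models_detected}/{ensemble.num_models} models, "
              f"distance {s.distance_mean:.2f} +/- {s.distance_std:.2f} A ({s.scope})")

print("\nThe pair was built at exactly 4.0 A with 0.35 A jitter, so roughly half")
print("the models fall under the (inclusive) cutoff; the detected-instance mean")
print("sits slightly below 4.0 A because only the close conformers count.")
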