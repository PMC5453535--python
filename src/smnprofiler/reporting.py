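"""TSV / JSON report writers and loaders for the packaged reference tables."""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .ensemble_stats import InteractionSummary
from .sasa import SasaProfile

SASA_TSV_HEADER = ["Residue", "SASA-Mean", "SASA-Std", "SASA-Intrinsic", "SASA-Ratio"]


def sasa_profiles_to_tsv(profiles: list[SasaProfile]) -> str:
    """Relative-SASA table with two-decimal ratios (full precision in JSON)."""
    lines = ["\t".join(SASA_TSV_HEADER)]
    for p in profiles:
        lines.append("\t".join([
            p.label, f"{p.sasa_mean:.2f}", f"{p.sasa_std:.2f}",
            f"{p.sasa_intrinsic:.2f}", f"{p.sasa_ratio:.2f}",
        ]))
    return "\n".join(lines) + "\n"


def sasa_profiles_to_json(profiles: list[SasaProfile]) -> str:
    return json.dumps([
        {"residue": p.label, "chain": p.chain_id, "number": p.number,
         "res_type": p.res_type, "sasa_mean": p.sasa_mean, "sasa_std": p.sasa_std,
         "sasa_intrinsic": p.sasa_intrinsic, "sasa_ratio": p.sasa_ratio}
        for p in profiles
    ], indent=2)


def summaries_to_tsv(summaries: list[InteractionSummary]) -> str:
    header = ["kind", "residue_a", "residue_b", "atom_a", "atom_b", "hydrogen",
              "scope", "n_models_detected", "n_instances", "model_indices",
              "distance_mean", "distance_std"]
    lines = ["\t".join(header)]
    for s in summaries:
        lines.append("\t".join([
            s.kind, s.residue_a, s.residue_b, s.atom_a or "-", s.atom_b or "-",
            s.hydrogen or "-", s.scope, str(s.n_models_detected),
            str(s.n_instances), ",".join(map(str, s.model_indices)),
            f"{s.distance_mean:.3f}", f"{s.distance_std:.3f}",
        ]))
    return "\n".join(lines) + "\n"


def summaries_to_json(summaries: list[InteractionSummary]) -> str:
    return json.dumps([
        {"kind": s.kind, "residue_a": s.residue_a, "residue_b": s.residue_b,
         "atom_a": s.atom_a, "atom_b": s.atom_b, "hydrogen": s.hydrogen,
         "scope": s.scope, "n_models_detected": s.n_models_detected,
         "n_instances": s.n_instances, "model_indices": s.model_indices,
         "distance_mean": s.distance_mean, "distance_std": s.distance_std}
        for s in summaries
    ], indent=2)


def write_report(text: str, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)
    return path


# ---------------------------------------------------------------------------
# Packaged published-geometry tables (SMN-Gemin2 interface, 2leh ensemble)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PublishedHbondGeometry:
    """One published interface hydrogen-bond geometry row."""

    bond_id: str
    kind: str           # "model" (single-model geometry) | "ensemble" (mean over models)
    model: int
    acceptor: str
    donor: str
    hydrogen: str
    d_da: float
    d_ha: float
    angle_adh: float
    d_da_std: float | None = None
    d_ha_std: float | None = None
    angle_adh_std: float | None = None


def load_published_hbond_geometries() -> list[PublishedHbondGeometry]:
    text = resources.files("smnprofiler.data").joinpath(
        "interface_hbond_geometries.tsv").read_text()
    rows = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        rows.append(PublishedHbondGeometry(
            bond_id=f[0], kind=f[1], model=int(f[2]), acceptor=f[3], donor=f[4],
            hydrogen=f[5], d_da=float(f[6]), d_ha=float(f[7]), angle_adh=float(f[8]),
            d_da_std=float(f[9]) if len(f) > 9 else None,
            d_ha_std=float(f[10]) if len(f) > 10 else None,
            angle_adh_std=float(f[11]) if len(f) > 11 else None,
        ))
    return rows


@dataclass(frozen=True)
class PublishedSaltBridge:
    """One published interface atom-pair salt-bridge row."""

    bridge_id: str
    atom_a: str
    atom_b: str
    distance_model15: float
    distance_mean: float
    distance_std: float


def load_published_salt_bridges() -> list[PublishedSaltBridge]:
    text = resources.files("smnprofiler.data").joinpath(
        "interface_saltbridge_distances.tsv").read_text()
    rows = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        rows.append(PublishedSaltBridge(f[0], f[1], f[2], float(f[3]),
                                        float(f[4]), float(f[5])))
    return rows
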