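"""Ensemble-level aggregation of per-model interaction detections.

An NMR ensemble yields one detection list per model; this module pools them
into per-partner summaries: in how many models a given contact appears, which
models those are, and the distance statistics over the detected instances.
For hydrogen-bond pairs it can also tabulate the geometry in every model
(detected or not), the "distribution row" convention used when a single-model
contact is contrasted with its whole-ensemble geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .interactions import (
    AtomSelector,
    DetectionConfig,
    HydrogenBond,
    SaltBridge,
    detect_hydrogen_bonds,
    detect_salt_bridges,
    hbond_geometry,
)
from .structure_io import StructureEnsemble


def mean_std(values, ddof: int = 0) -> tuple[float, float]:
    """Shared mean/std routine (population std by default)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    std = float(arr.std(ddof=ddof)) if arr.size > ddof else float("nan")
    return float(arr.mean()), std


@dataclass
class InteractionSummary:
    """Pooled detections of one partner pair across an ensemble."""

    kind: str                        # "salt_bridge" | "hydrogen_bond"
    residue_a: str                   # compact labels, e.g. "B36Asp"
    residue_b: str
    atom_a: str | None               # atom-level identity where applicable
    atom_b: str | None
    hydrogen: str | None             # hydrogen bonds only
    scope: str
    model_indices: list[int]         # models with >= 1 detection (sorted, unique)
    n_instances: int                 # total detected instances across models
    distance_mean: float             # over detected instances
    distance_std: float

    @property
    def n_models_detected(self) -> int:
        return len(self.model_indices)


def _sb_identity(bridge: SaltBridge) -> tuple:
    a, b = bridge.group_a.residue, bridge.group_b.residue
    if bridge.mode == "atom_pair":
        return (a.label, b.label, bridge.atom_a, bridge.atom_b)
    return (a.label, b.label, None, None)


def _hb_identity(bond: HydrogenBond) -> tuple:
    return (bond.donor_residue.label, bond.acceptor_residue.label,
            bond.donor_atom, bond.acceptor_atom, bond.hydrogen_atom)


def summarize_interactions(ensemble: StructureEnsemble,
                           config: DetectionConfig | None = None,
                           kind: str = "salt_bridge") -> list[InteractionSummary]:
    """Pool per-model detections into per-pair summaries.

    Pair identity is the residue pair in ``group_center`` salt-bridge mode,
    the (residue pair, atom pair) in ``atom_pair`` mode, and the full
    donor/hydrogen/acceptor atom triple for hydrogen bonds.  Distance
    statistics (the salt-bridge distance, or the donor-acceptor distance) are
    computed over detected instances only; pairs never detected are omitted.
    """
    config = config or DetectionConfig()
    if kind not in ("salt_bridge", "hydrogen_bond"):
        raise ValueError(f"unknown interaction kind {kind!r}")

    buckets: dict[tuple, list] = {}
    for model in ensemble:
        if kind == "salt_bridge":
            for sb in detect_salt_bridges(model, config):
                buckets.setdefault(_sb_identity(sb), []).append(sb)
        else:
            for hb in detect_hydrogen_bonds(model, config):
                buckets.setdefault(_hb_identity(hb), []).append(hb)

    summaries = []
    for identity, hits in buckets.items():
        models = sorted({h.model_index for h in hits})
        if kind == "salt_bridge":
            distances = [h.distance for h in hits]
            atom_a, atom_b, hydrogen = identity[2], identity[3], None
        else:
            distances = [h.d_da for h in hits]
            atom_a, atom_b, hydrogen = identity[2], identity[3], identity[4]
        mean, std = mean_std(distances, ddof=config.ddof)
        summaries.append(InteractionSummary(
            kind=kind, residue_a=identity[0], residue_b=identity[1],
            atom_a=atom_a, atom_b=atom_b, hydrogen=hydrogen,
            scope=hits[0].scope, model_indices=models, n_instances=len(hits),
            distance_mean=mean, distance_std=std))
    summaries.sort(key=lambda s: (s.residue_a, s.residue_b, s.atom_a or "", s.atom_b or "", s.hydrogen or ""))
    return summaries


@dataclass
class HbondPairReport:
    """Per-model geometry of one donor/hydrogen/acceptor triple plus its distribution."""

    donor: AtomSelector
    hydrogen: AtomSelector
    acceptor: AtomSelector
    model_indices: list[int]
    d_da: list[float]
    d_ha: list[float]
    angle_adh: list[float]
    d_da_mean: float
    d_da_std: float
    d_ha_mean: float
    d_ha_std: float
    angle_mean: float
    angle_std: float


def summarize_hbond_pair(ensemble: StructureEnsemble, donor: AtomSelector,
                         hydrogen: AtomSelector, acceptor: AtomSelector,
                         ddof: int = 0) -> HbondPairReport:
    """Geometry of one candidate hydrogen bond in every model of an ensemble.

    Unlike :func:`summarize_interactions`, the statistics here run over *all*
    models whether or not the bond passes the acceptance criteria in them.
    Raises ``ValueError`` when a selector cannot be resolved in some model.
    """
    indices, d_da, d_ha, angles = [], [], [], []
    for model in ensemble:
        atoms = [sel.resolve(model) for sel in (donor, hydrogen, acceptor)]
        if any(a is None for a in atoms):
            missing = [s for s, a in zip((donor, hydrogen, acceptor), atoms) if a is None]
            raise ValueError(f"model {model.index}: unresolved selector(s) {missing}")
        dd, dh, ang = hbond_geometry(*atoms)
        indices.append(model.index)
        d_da.append(dd)
        d_ha.append(dh)
        angles.append(ang)
    dd_m, dd_s = mean_std(d_da, ddof)
    dh_m, dh_s = mean_std(d_ha, ddof)
    an_m, an_s = mean_std(angles, ddof)
    return HbondPairReport(donor, hydrogen, acceptor, indices, d_da, d_ha, angles,
                           dd_m, dd_s, dh_m, dh_s, an_m, an_s)
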